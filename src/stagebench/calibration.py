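"""Calibration curves: loess-smoothed observed vs predicted probability.

A model is calibrated when patients given probability p experience the
outcome with frequency p. Because individual outcomes are binary, the
observed probability at each predicted value is estimated by locally
weighted polynomial regression (loess with tricube weights, default span
0.75 and degree 2) of the outcome on the predicted probability, evaluated
on an even grid over the observed prediction range and clamped to [0, 1].
Binned summaries (quantile bins with Wilson 95% intervals on the observed
fraction) provide the error bars.

The loess smoother here is a self-contained tricube local-polynomial fit:
the commonly available lowess implementations are limited to local lines,
while a local quadratic tracks curvature in the calibration relation
without the flattening a line induces at the range ends.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .modelling import PredictionSet

__all__ = [
    "CalibrationCurve",
    "DegeneratePredictionsError",
    "binned_calibration",
    "loess_calibration",
    "loess_smooth",
]

logger = logging.getLogger(__name__)


class DegeneratePredictionsError(ValueError):
    """Raised when too few distinct predicted values support a curve."""


def loess_smooth(
    x: np.ndarray, y: np.ndarray, grid: np.ndarray, span: float = 0.75, degree: int = 2
) -> np.ndarray:
    """Tricube-weighted local polynomial regression evaluated on ``grid``.

    For each grid point the ``ceil(span * n)`` nearest observations (by
    distance in x) receive tricube weights ``(1 - (d/dmax)^3)^3`` and a
    weighted polynomial of the given degree is fitted; the smoothed value
    is its prediction at the grid point. A window whose x values are all
    identical, or a rank-deficient local fit, falls back to the weighted
    mean. ``span >= 1`` uses every observation at every point, so the curve
    tends to the global polynomial fit.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n == 0:
        raise ValueError("loess requires at least one observation")
    if not 0.0 < span:
        raise ValueError(f"span must be positive, got {span}")
    q = min(n, max(degree + 2, int(np.ceil(span * n))))
    out = np.empty(len(grid), dtype=float)
    for i, g in enumerate(np.asarray(grid, dtype=float)):
        d = np.abs(x - g)
        idx = np.argpartition(d, q - 1)[:q]
        dmax = d[idx].max()
        if dmax == 0.0:
            out[i] = y[idx].mean()
            continue
        w = (1.0 - (d[idx] / dmax) ** 3) ** 3
        w = np.clip(w, 0.0, None)
        if w.sum() == 0.0:  # all window points at dmax
            out[i] = y[idx].mean()
            continue
        xc = x[idx] - g
        design = np.vander(xc, degree + 1, increasing=True)
        sw = np.sqrt(w)
        coef, _, rank, _ = np.linalg.lstsq(design * sw[:, None], y[idx] * sw, rcond=None)
        if rank < degree + 1:
            out[i] = float(np.average(y[idx], weights=w))
        else:
            out[i] = float(coef[0])  # polynomial value at xc = 0
    return out


@dataclass
class CalibrationCurve:
    """Smoothed calibration curve plus binned error-bar summaries."""

    model: str
    grid: np.ndarray
    smoothed: np.ndarray
    bins: pd.DataFrame
    span: float
    degree: int

    def max_diagonal_deviation(self) -> float:
        """Largest |smoothed - predicted| over the grid; 0 is perfect."""
        return float(np.max(np.abs(self.smoothed - self.grid)))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"model": self.model, "predicted": self.grid, "observed_smoothed": self.smoothed}
        )


def binned_calibration(preds: PredictionSet, n_bins: int = 10) -> pd.DataFrame:
    """Quantile-binned observed outcome fractions with Wilson 95% CIs.

    Bins are quantile bins of the predicted probability; bins left empty by
    ties are merged into their neighbours (logged). Columns: bin_low,
    bin_high, mean_predicted, observed_fraction, ci_low, ci_high, count.
    """
    n = len(preds)
    if n < n_bins:
        raise ValueError(f"need at least {n_bins} predictions, got {n}")
    edges = np.quantile(preds.prob, np.linspace(0, 1, n_bins + 1))
    edges = np.unique(edges)
    if len(edges) < n_bins + 1:
        logger.info("merged %d empty quantile bins", n_bins + 1 - len(edges))
    if len(edges) < 2:  # all predictions identical: a single degenerate bin
        edges = np.array([edges[0], edges[0]])
    assignment = np.clip(np.searchsorted(edges, preds.prob, side="right") - 1, 0, len(edges) - 2)
    rows = []
    for b in range(len(edges) - 1):
        mask = assignment == b
        count = int(mask.sum())
        if count == 0:
            continue
        events = int(preds.label[mask].sum())
        lo, hi = proportion_confint(events, count, alpha=0.05, method="wilson")
        rows.append(
            {
                "bin_low": float(edges[b]),
                "bin_high": float(edges[b + 1]),
                "mean_predicted": float(preds.prob[mask].mean()),
                "observed_fraction": events / count,
                "ci_low": float(lo),
                "ci_high": float(hi),
                "count": count,
            }
        )
    table = pd.DataFrame(rows)
    assert int(table["count"].sum()) == n
    return table


def loess_calibration(
    preds: PredictionSet,
    span: float = 0.75,
    degree: int = 2,
    grid_size: int = 101,
    min_distinct: int = 10,
    n_bins: int = 10,
) -> CalibrationCurve:
    """Loess calibration curve on an even grid over the prediction range.

    Raises :class:`DegeneratePredictionsError` when fewer than
    ``min_distinct`` distinct predicted values are available — the situation
    of a nearly constant model, whose calibration cannot be resolved over a
    narrow probability band.
    """
    distinct = np.unique(preds.prob)
    if len(distinct) < min_distinct:
        raise DegeneratePredictionsError(
            f"only {len(distinct)} distinct predicted values (< {min_distinct}); "
            "calibration curve omitted"
        )
    grid = np.linspace(distinct[0], distinct[-1], grid_size)
    smoothed = loess_smooth(preds.prob, preds.label.astype(float), grid, span, degree)
    smoothed = np.clip(smoothed, 0.0, 1.0)
    bins = binned_calibration(preds, n_bins=n_bins)
    return CalibrationCurve(
        model=preds.model, grid=grid, smoothed=smoothed, bins=bins, span=span, degree=degree
    )
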