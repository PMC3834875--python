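"""Decision curve analysis: net benefit over threshold probabilities.

The threshold probability Pt is the predicted probability at which a
clinician would advise treatment; it encodes how the harms of a false
positive weigh against those of a false negative. At each Pt the net
benefit of classifying positive when probability >= Pt is

    net benefit = TP/n - (FP/n) * Pt / (1 - Pt)

in units of true positives per patient. Plotting net benefit against Pt
gives the decision curve, compared against two reference strategies:
treat-all (every patient classified positive) and treat-none (net benefit
identically zero). At any Pt the strategy with the highest net benefit is
preferred.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .modelling import PredictionSet

__all__ = [
    "DecisionCurve",
    "best_model_at",
    "decision_curve",
    "default_grid",
    "net_benefit",
    "treat_all_net_benefit",
]

logger = logging.getLogger(__name__)


def default_grid() -> np.ndarray:
    """Threshold probabilities 0.01 to 0.50 in steps of 0.005 — the range
    over which staging models are plausibly decision-relevant."""
    return np.round(np.arange(0.01, 0.50 + 1e-9, 0.005), 10)


def net_benefit(preds: PredictionSet, pt: float) -> float:
    """Net benefit of classifying positive at probability >= pt."""
    if not 0.0 < pt < 1.0:
        raise ValueError(f"threshold probability must lie in (0, 1), got {pt}")
    n = len(preds)
    if n == 0:
        raise ValueError("empty prediction set")
    pred_pos = preds.prob >= pt
    tp = int(np.sum(pred_pos & (preds.label == 1)))
    fp = int(np.sum(pred_pos & (preds.label == 0)))
    return tp / n - (fp / n) * pt / (1.0 - pt)


def treat_all_net_benefit(prevalence: float, pt: np.ndarray) -> np.ndarray:
    """Net benefit of treating everyone: pi - (1 - pi) * pt / (1 - pt)."""
    pt = np.asarray(pt, dtype=float)
    return prevalence - (1.0 - prevalence) * pt / (1.0 - pt)


@dataclass
class DecisionCurve:
    model: str
    grid: np.ndarray
    model_nb: np.ndarray
    treat_all: np.ndarray
    n: int

    @property
    def treat_none(self) -> np.ndarray:
        return np.zeros_like(self.grid)

    def to_frame(self) -> pd.DataFrame:
        """Long-form (model, pt, net_benefit) including the references."""
        frames = [
            pd.DataFrame({"model": self.model, "pt": self.grid, "net_benefit": self.model_nb}),
            pd.DataFrame({"model": "treat_all", "pt": self.grid, "net_benefit": self.treat_all}),
            pd.DataFrame({"model": "treat_none", "pt": self.grid, "net_benefit": self.treat_none}),
        ]
        return pd.concat(frames, ignore_index=True)


def decision_curve(preds: PredictionSet, grid: np.ndarray | None = None) -> DecisionCurve:
    """Model and reference net-benefit curves over a threshold grid."""
    if grid is None:
        grid = default_grid()
    grid = np.asarray(grid, dtype=float)
    if len(grid) == 0 or grid.min() <= 0 or grid.max() >= 1:
        raise ValueError("grid must lie strictly inside (0, 1)")
    if np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be strictly increasing")
    model_nb = np.array([net_benefit(preds, float(pt)) for pt in grid])
    treat_all = treat_all_net_benefit(preds.prevalence, grid)
    return DecisionCurve(
        model=preds.model, grid=grid, model_nb=model_nb, treat_all=treat_all, n=len(preds)
    )


def best_model_at(curves: list[DecisionCurve], pt: float, include_references: bool = True) -> str:
    """Identifier of the strategy with the highest net benefit at pt.

    Treat-all and treat-none compete as candidate strategies by default.
    Ties break by declared order: the curves in the given order, then
    treat-all, then treat-none. Off-grid pt snaps to the nearest grid
    point (logged).
    """
    if not curves:
        raise ValueError("no curves supplied")
    grid = curves[0].grid
    for c in curves[1:]:
        if not np.array_equal(c.grid, grid):
            raise ValueError("all curves must share the same threshold grid")
    i = int(np.argmin(np.abs(grid - pt)))
    if abs(grid[i] - pt) > 1e-12:
        logger.info("pt=%g off-grid; using nearest grid point %g", pt, grid[i])
    candidates = [(c.model, float(c.model_nb[i])) for c in curves]
    if include_references:
        candidates.append(("treat_all", float(curves[0].treat_all[i])))
        candidates.append(("treat_none", 0.0))
    best_name, best_nb = candidates[0]
    for name, nb in candidates[1:]:
        if nb > best_nb + 1e-15:
            best_name, best_nb = name, nb
    return best_name
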