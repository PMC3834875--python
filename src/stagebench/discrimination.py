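"""Discrimination metrics for staging classifiers.

Seven metrics summarise how well pooled out-of-fold probabilities separate
non-organ-confined from organ-confined disease: sensitivity, specificity,
Youden index (sens + spec - 1), positive and negative predictive value,
Brier score and AUC. The first five require a classification threshold; the
default rule picks the threshold maximising the Youden index on the pooled
predictions (smallest such threshold on ties), with fixed- and
prevalence-threshold rules available. Ties at the threshold classify
positive (probability >= t).

AUC is the Mann-Whitney estimator: over all (positive, negative) pairs, the
fraction in which the positive patient received the higher probability,
counting ties as 1/2 — identical to the trapezoidal area under the
empirical ROC curve. Ratios with zero denominator (e.g. PPV when nothing is
predicted positive) are reported as NaN, the flagged not-available value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .modelling import PredictionSet

__all__ = [
    "ConfusionCounts",
    "DiscriminationReport",
    "auc",
    "basic_metrics",
    "brier_score",
    "confusion_at_threshold",
    "discrimination_report",
    "youden_threshold",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int
    threshold: float

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class DiscriminationReport:
    model: str
    threshold: float
    sensitivity: float
    specificity: float
    youden: float
    ppv: float
    npv: float
    brier: float
    auc: float

    def as_dict(self) -> dict[str, float]:
        return {
            "threshold": self.threshold,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "youden": self.youden,
            "ppv": self.ppv,
            "npv": self.npv,
            "brier": self.brier,
            "auc": self.auc,
        }


def confusion_at_threshold(preds: PredictionSet, t: float) -> ConfusionCounts:
    """Confusion counts classifying positive iff probability >= t."""
    if not 0.0 <= t <= 1.0:
        raise ValueError(f"threshold must lie in [0, 1], got {t}")
    pred_pos = preds.prob >= t
    pos = preds.label == 1
    return ConfusionCounts(
        tp=int(np.sum(pred_pos & pos)),
        fp=int(np.sum(pred_pos & ~pos)),
        tn=int(np.sum(~pred_pos & ~pos)),
        fn=int(np.sum(~pred_pos & pos)),
        threshold=float(t),
    )


def _ratio(num: int, den: int) -> float:
    return num / den if den else math.nan


def basic_metrics(counts: ConfusionCounts) -> dict[str, float]:
    """Sensitivity, specificity, PPV, NPV and Youden from confusion counts.

    The Youden index satisfies youden = sensitivity + specificity - 1
    exactly; undefined ratios are NaN.
    """
    sens = _ratio(counts.tp, counts.tp + counts.fn)
    spec = _ratio(counts.tn, counts.tn + counts.fp)
    return {
        "sensitivity": sens,
        "specificity": spec,
        "ppv": _ratio(counts.tp, counts.tp + counts.fp),
        "npv": _ratio(counts.tn, counts.tn + counts.fn),
        "youden": sens + spec - 1.0,
    }


def brier_score(preds: PredictionSet) -> float:
    """Mean squared difference between probability and binary outcome."""
    if len(preds) == 0:
        raise ValueError("empty prediction set")
    return float(np.mean((preds.prob - preds.label) ** 2))


def auc(preds: PredictionSet) -> float:
    """Mann-Whitney AUC with ties counted as 1/2.

    Computed from mid-ranks: AUC = (R_pos - n_pos(n_pos+1)/2) / (n_pos n_neg)
    where R_pos is the rank sum of the positives — algebraically equal to the
    exhaustive pairwise count and to the trapezoidal ROC area.
    """
    pos = preds.label == 1
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC requires both outcome classes to be present")
    ranks = rankdata(preds.prob)
    r_pos = ranks[pos].sum()
    return float((r_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def youden_threshold(preds: PredictionSet) -> float:
    """Smallest threshold maximising the Youden index on these predictions.

    Candidates are the distinct predicted probabilities (classification is
    at prob >= t, so only those change the confusion counts).
    """
    candidates = np.unique(preds.prob)
    best_t, best_j = float(candidates[0]), -np.inf
    for t in candidates:
        m = basic_metrics(confusion_at_threshold(preds, float(t)))
        j = m["youden"]
        if j > best_j + 1e-12:
            best_t, best_j = float(t), j
    return best_t


def discrimination_report(
    preds: PredictionSet, threshold_rule: str = "youden", fixed_threshold: float = 0.5
) -> DiscriminationReport:
    """All seven metrics at a threshold chosen by the configured rule.

    Rules: ``"youden"`` (default) maximises the Youden index over the pooled
    predictions; ``"fixed"`` uses ``fixed_threshold``; ``"prevalence"`` uses
    the observed outcome prevalence.
    """
    if threshold_rule == "youden":
        t = youden_threshold(preds)
    elif threshold_rule == "fixed":
        t = fixed_threshold
    elif threshold_rule == "prevalence":
        t = preds.prevalence
    else:
        raise ValueError(f"unknown threshold rule {threshold_rule!r}")
    m = basic_metrics(confusion_at_threshold(preds, t))
    return DiscriminationReport(
        model=preds.model,
        threshold=t,
        sensitivity=m["sensitivity"],
        specificity=m["specificity"],
        youden=m["youden"],
        ppv=m["ppv"],
        npv=m["npv"],
        brier=brier_score(preds),
        auc=auc(preds),
    )
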