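"""Cohort characterisation: descriptive summaries and Gleason concordance.

Two reporting products: a Table-1-style summary (continuous variables as
mean/median/range with normal-approximation 95% CIs and OC-vs-NOC group
comparisons; categorical variables as counts and percentages with chi-square
comparisons) and a Table-2-style biopsy-vs-prostatectomy Gleason transition
table over the five conventional reporting groups <=6, 3+4, 4+3, 8, 9-10.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import (
    BIOPSY_GS_LEVELS,
    CLINICAL_STAGE_LEVELS,
    FAMILY_HISTORY_LEVELS,
    PATH_STAGE_LEVELS,
    noc_labels,
)

__all__ = [
    "CohortSummary",
    "GleasonTransitionTable",
    "TRANSITION_GROUPS",
    "gleason_transition",
    "round_pct",
    "summarize_cohort",
    "transition_from_counts",
]

logger = logging.getLogger(__name__)

CONTINUOUS_VARS = ("age", "psa")
CATEGORICAL_VARS = {
    "family_history": FAMILY_HISTORY_LEVELS,
    "clinical_stage": CLINICAL_STAGE_LEVELS,
    "biopsy_gs": BIOPSY_GS_LEVELS,
    "prostatectomy_gs": BIOPSY_GS_LEVELS,
    "path_stage": PATH_STAGE_LEVELS,
}

#: Gleason reporting groups, in grade order.
TRANSITION_GROUPS = ("<=6", "3+4", "4+3", "8", "9-10")
_GROUP_INDEX = {"<=5": 0, "6": 0, "3+4": 1, "4+3": 2, "8": 3, "9": 4}


def round_pct(x: float, ndigits: int = 1) -> float:
    """Round half away from zero, the convention of the printed tables."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class CohortSummary:
    """Per-variable descriptives split by overall / OC / NOC.

    ``continuous`` maps variable -> {split -> {mean, median, range, ci95, n}}
    plus the comparison test name and p-value; ``categorical`` maps variable
    -> a DataFrame of counts and percentages per split plus chi-square p.
    ``notes`` records any split too small to test.
    """

    n: int
    continuous: dict = field(default_factory=dict)
    categorical: dict = field(default_factory=dict)
    notes: list[str] = field(default_factory=list)

    def to_frames(self) -> dict[str, pd.DataFrame]:
        """Flatten to DataFrames, one per variable, for CSV export."""
        frames: dict[str, pd.DataFrame] = {}
        for var, entry in self.continuous.items():
            rows = []
            for split, s in entry["splits"].items():
                rows.append(
                    {
                        "split": split,
                        "n": s["n"],
                        "mean": s["mean"],
                        "median": s["median"],
                        "min": s["range"][0],
                        "max": s["range"][1],
                        "ci95_low": s["ci95"][0],
                        "ci95_high": s["ci95"][1],
                    }
                )
            df = pd.DataFrame(rows)
            df["test"] = entry["test"]
            df["p_value"] = entry["p_value"]
            frames[var] = df
        for var, entry in self.categorical.items():
            df = entry["table"].copy()
            df["test"] = entry["test"]
            df["p_value"] = entry["p_value"]
            frames[var] = df
        return frames

    def to_json(self) -> str:
        def default(o):
            if isinstance(o, pd.DataFrame):
                return o.to_dict(orient="records")
            if isinstance(o, (np.floating, np.integer)):
                return o.item()
            if isinstance(o, tuple):
                return list(o)
            raise TypeError(type(o))

        payload = {
            "n": self.n,
            "continuous": self.continuous,
            "categorical": self.categorical,
            "notes": self.notes,
        }
        return json.dumps(payload, default=default, indent=2)


def _normality_ok(x: np.ndarray, alpha: float) -> bool:
    if len(x) < 3 or np.ptp(x) == 0:
        return False
    if len(x) <= 5000:
        p = stats.shapiro(x).pvalue
    else:  # Shapiro-Wilk is unreliable above ~5000; D'Agostino is order-free
        p = stats.normaltest(x).pvalue
    return p > alpha


def _continuous_split(x: np.ndarray) -> dict:
    n = len(x)
    mean = float(np.mean(x)) if n else math.nan
    sd = float(np.std(x, ddof=1)) if n > 1 else math.nan
    half = 1.959963984540054 * sd / math.sqrt(n) if n > 1 else math.nan
    return {
        "n": n,
        "mean": mean,
        "median": float(np.median(x)) if n else math.nan,
        "range": (float(np.min(x)), float(np.max(x))) if n else (math.nan, math.nan),
        "ci95": (mean - half, mean + half),
    }


def summarize_cohort(cohort: pd.DataFrame, normality_alpha: float = 0.05) -> CohortSummary:
    """Compute the Table-1-style summary with OC-vs-NOC comparisons.

    Continuous variables are compared with the two-sample t-test when both
    groups pass a Shapiro-Wilk normality check at ``normality_alpha``, and
    with the Mann-Whitney U test otherwise. Categorical variables use the
    chi-square test on the full contingency table (no continuity correction);
    expected counts below 5 are logged, not escalated to an exact test.
    A group with fewer than two members yields no test, noted in ``notes``.
    """
    if len(cohort) == 0:
        raise ValueError("cannot summarize an empty cohort")
    labels = noc_labels(cohort)
    groups = {"overall": np.ones(len(cohort), bool), "OC": labels == 0, "NOC": labels == 1}
    summary = CohortSummary(n=len(cohort))
    testable = groups["OC"].sum() >= 2 and groups["NOC"].sum() >= 2
    if not testable:
        summary.notes.append(
            "a stage group has fewer than 2 members; group comparisons omitted"
        )

    for var in CONTINUOUS_VARS:
        x = cohort[var].to_numpy(dtype=float)
        splits = {name: _continuous_split(x[mask]) for name, mask in groups.items() if mask.any()}
        test, p = None, math.nan
        if testable:
            a, b = x[groups["OC"]], x[groups["NOC"]]
            if _normality_ok(a, normality_alpha) and _normality_ok(b, normality_alpha):
                test = "t-test"
                p = float(stats.ttest_ind(a, b).pvalue)
            else:
                test = "mann-whitney"
                p = float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
        summary.continuous[var] = {"splits": splits, "test": test, "p_value": p}

    for var, levels in CATEGORICAL_VARS.items():
        rows = []
        for level in levels:
            row = {"level": level}
            for name, mask in groups.items():
                count = int(((cohort[var] == level) & mask).sum())
                total = int(mask.sum())
                row[f"count_{name}"] = count
                row[f"pct_{name}"] = round_pct(100.0 * count / total) if total else math.nan
            rows.append(row)
        table = pd.DataFrame(rows)
        test, p = None, math.nan
        if testable and var != "path_stage":  # path stage defines the split
            contingency = np.array(
                [
                    [int(((cohort[var] == lv) & groups[g]).sum()) for lv in levels]
                    for g in ("OC", "NOC")
                ]
            )
            contingency = contingency[:, contingency.sum(axis=0) > 0]
            if contingency.shape[1] >= 2:
                chi2 = stats.chi2_contingency(contingency, correction=False)
                if (chi2.expected_freq < 5).any():
                    logger.warning("chi-square for %s has expected counts < 5", var)
                test, p = "chi-square", float(chi2.pvalue)
        summary.categorical[var] = {"table": table, "test": test, "p_value": p}
    return summary


@dataclass
class GleasonTransitionTable:
    """Biopsy-vs-prostatectomy grade concordance over the reporting groups.

    One column per biopsy group; rows hold the group total and the counts of
    downgrades, concordant grades and upgrades at prostatectomy.
    """

    groups: tuple[str, ...]
    totals: np.ndarray
    decrease: np.ndarray
    no_change: np.ndarray
    increase: np.ndarray
    n_excluded: int = 0

    def __post_init__(self):
        self.totals = np.asarray(self.totals, dtype=int)
        self.decrease = np.asarray(self.decrease, dtype=int)
        self.no_change = np.asarray(self.no_change, dtype=int)
        self.increase = np.asarray(self.increase, dtype=int)
        if not np.array_equal(self.decrease + self.no_change + self.increase, self.totals):
            raise ValueError("decrease + no change + increase must equal N in every column")
        if self.decrease[0] != 0:
            raise ValueError("the lowest grade group cannot be downgraded")
        if self.increase[-1] != 0:
            raise ValueError("the highest grade group cannot be upgraded")

    @property
    def n(self) -> int:
        return int(self.totals.sum())

    def overall_percentages(self) -> dict[str, float]:
        """Marginal (decrease, no change, increase) percentages, 1 dp."""
        n = self.n
        return {
            "decrease": round_pct(100.0 * self.decrease.sum() / n),
            "no_change": round_pct(100.0 * self.no_change.sum() / n),
            "increase": round_pct(100.0 * self.increase.sum() / n),
        }

    def discordance_percentage(self) -> float:
        """Share of patients whose biopsy grade was wrong at prostatectomy."""
        return round_pct(100.0 * (self.decrease.sum() + self.increase.sum()) / self.n)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            [self.totals, self.decrease, self.no_change, self.increase],
            index=["N", "decrease", "no_change", "increase"],
            columns=list(self.groups),
        )
        df["total"] = df.sum(axis=1)
        return df

    def to_json(self) -> str:
        payload = {
            "groups": list(self.groups),
            "totals": self.totals.tolist(),
            "decrease": self.decrease.tolist(),
            "no_change": self.no_change.tolist(),
            "increase": self.increase.tolist(),
            "n": self.n,
            "n_excluded": self.n_excluded,
            "overall_percentages": self.overall_percentages(),
            "discordance_percentage": self.discordance_percentage(),
        }
        return json.dumps(payload, indent=2)


def transition_from_counts(
    totals, decrease, no_change, increase, n_excluded: int = 0
) -> GleasonTransitionTable:
    """Build a transition table directly from per-group counts."""
    return GleasonTransitionTable(
        groups=TRANSITION_GROUPS,
        totals=totals,
        decrease=decrease,
        no_change=no_change,
        increase=increase,
        n_excluded=n_excluded,
    )


def gleason_transition(cohort: pd.DataFrame) -> GleasonTransitionTable:
    """Classify each patient by the sign of the grade change at surgery.

    Biopsy and prostatectomy grades are mapped to the five reporting groups
    and the change sign taken on group indices. Records with either grade
    missing are excluded and counted in ``n_excluded``.
    """
    biopsy = cohort["biopsy_gs"]
    rp = cohort["prostatectomy_gs"]
    ok = biopsy.isin(_GROUP_INDEX) & rp.isin(_GROUP_INDEX)
    n_excluded = int((~ok).sum())
    b_idx = biopsy[ok].map(_GROUP_INDEX).to_numpy()
    r_idx = rp[ok].map(_GROUP_INDEX).to_numpy()
    delta = np.sign(r_idx - b_idx)
    k = len(TRANSITION_GROUPS)
    totals = np.bincount(b_idx, minlength=k)
    decrease = np.bincount(b_idx[delta < 0], minlength=k)
    increase = np.bincount(b_idx[delta > 0], minlength=k)
    no_change = totals - decrease - increase
    return GleasonTransitionTable(
        groups=TRANSITION_GROUPS,
        totals=totals,
        decrease=decrease,
        no_change=no_change,
        increase=increase,
        n_excluded=n_excluded,
    )
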