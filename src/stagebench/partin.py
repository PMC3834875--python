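"""Partin-style lookup-table staging predictions.

The Partin tables map (clinical stage, PSA band, biopsy Gleason category)
to published probabilities of each pathological stage (OC, ECE, SVI, LNI).
This module loads such a table from CSV, validates it, and applies it to a
cohort so its stage-specific predictions can be evaluated with the same
discrimination and calibration machinery as the cross-validated models.

The published probability values are not redistributed here: transcribe the
table you wish to evaluate into the CSV layout documented on
:func:`load_partin_table`. The test-suite fixture is synthetic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .modelling import PredictionSet

__all__ = [
    "PARTIN_GS_MAP",
    "PartinTable",
    "load_partin_table",
    "partin_predict",
]

#: Default mapping from the six generator Gleason categories to the
#: four-category grouping conventional in published Partin tables.
PARTIN_GS_MAP = {"<=5": "5-6", "6": "5-6", "3+4": "3+4", "4+3": "4+3", "8": "8-10", "9": "8-10"}

_OUTCOME_COLS = {"OC": "p_oc", "ECE": "p_ece", "SVI": "p_svi", "LNI": "p_lni"}
_SUM_TOL = 3.0  # percentage points; published cells are rounded


@dataclass
class PartinTable:
    """Validated lookup table; probabilities on the percent scale.

    ``cells`` has columns clinical_stage, psa_low, psa_high, gs_category,
    p_oc, p_ece, p_svi, p_lni. PSA bands are half-open (low, high],
    upper-inclusive; within each (stage, GS) cell set the bands tile
    (0, inf). ``flagged`` lists rows whose four probabilities sum outside
    100 +/- 3 points.
    """

    cells: pd.DataFrame
    flagged: pd.DataFrame

    @property
    def stages(self) -> tuple[str, ...]:
        return tuple(sorted(self.cells["clinical_stage"].unique()))

    @property
    def gs_categories(self) -> tuple[str, ...]:
        return tuple(sorted(self.cells["gs_category"].unique()))

    def lookup(self, clinical_stage: str, psa: float, gs_category: str) -> pd.Series:
        """The probability row for one patient; KeyError when uncovered."""
        sub = self.cells[
            (self.cells["clinical_stage"] == clinical_stage)
            & (self.cells["gs_category"] == gs_category)
            & (self.cells["psa_low"] < psa)
            & (psa <= self.cells["psa_high"])
        ]
        if len(sub) != 1:
            raise KeyError(
                f"no table cell for stage={clinical_stage!r}, psa={psa}, gs={gs_category!r}"
            )
        return sub.iloc[0]


def load_partin_table(source) -> PartinTable:
    """Load and validate a Partin-style CSV.

    Expected columns: clinical_stage, psa_low, psa_high, gs_category,
    p_oc, p_ece, p_svi, p_lni (percent scale). ``psa_high`` may be the
    string ``inf`` (or empty) for the open top band. Overlapping or gapped
    bands within a (stage, GS) cell set are rejected; cells whose
    probabilities sum beyond 100 +/- 3 points are flagged, not rejected.
    """
    df = pd.read_csv(source)
    required = ["clinical_stage", "psa_low", "psa_high", "gs_category", *_OUTCOME_COLS.values()]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"Partin table is missing columns {missing}")
    df = df.copy()
    df["psa_high"] = df["psa_high"].replace({"": math.inf}).fillna(math.inf).astype(float)
    df["psa_low"] = df["psa_low"].astype(float)
    for col in _OUTCOME_COLS.values():
        bad = (df[col] < 0) | (df[col] > 100)
        if bad.any():
            raise ValueError(f"{col} outside [0, 100] in row {int(np.flatnonzero(bad)[0])}")
    for (stage, gs), group in df.groupby(["clinical_stage", "gs_category"]):
        bands = group.sort_values("psa_low")[["psa_low", "psa_high"]].to_numpy()
        if bands[0, 0] != 0.0:
            raise ValueError(f"bands for ({stage}, {gs}) must start at 0, got {bands[0, 0]}")
        if not math.isinf(bands[-1, 1]):
            raise ValueError(f"bands for ({stage}, {gs}) must end at inf")
        for (lo, hi), (nlo, _) in zip(bands[:-1], bands[1:]):
            if hi > nlo:
                raise ValueError(f"overlapping PSA bands for ({stage}, {gs}) at {hi} > {nlo}")
            if hi < nlo:
                raise ValueError(f"gap in PSA bands for ({stage}, {gs}) between {hi} and {nlo}")
        if np.any(bands[:, 0] >= bands[:, 1]):
            raise ValueError(f"empty PSA band for ({stage}, {gs})")
    sums = df[list(_OUTCOME_COLS.values())].sum(axis=1)
    flagged = df[(sums - 100.0).abs() > _SUM_TOL]
    return PartinTable(cells=df.reset_index(drop=True), flagged=flagged.reset_index(drop=True))


def partin_predict(
    cohort: pd.DataFrame,
    table: PartinTable,
    outcome: str = "ECE",
    gs_map: dict[str, str] | None = None,
) -> tuple[PredictionSet, int]:
    """Apply the lookup table to a cohort for one pathological outcome.

    Each covered patient receives their cell's probability for ``outcome``
    (divided by 100); the evaluation label is outcome-specific (e.g. ECE vs
    not-ECE). Patients whose clinical stage is absent from the table (such
    as NOT_REPORTED) are excluded; returns ``(prediction_set,
    n_excluded)``. The published tables condition on clinical stage, so
    evaluation is normally stratified by stage (pass a single-stage cohort
    slice).
    """
    if outcome not in _OUTCOME_COLS:
        raise ValueError(f"outcome must be one of {tuple(_OUTCOME_COLS)}, got {outcome!r}")
    gs_map = PARTIN_GS_MAP if gs_map is None else gs_map
    covered_stages = set(table.cells["clinical_stage"].unique())
    covered = cohort["clinical_stage"].isin(covered_stages)
    n_excluded = int((~covered).sum())
    sub = cohort[covered]
    col = _OUTCOME_COLS[outcome]
    probs = np.empty(len(sub), dtype=float)
    for j, (_, patient) in enumerate(sub.iterrows()):
        gs_cat = gs_map[patient["biopsy_gs"]]
        cell = table.lookup(patient["clinical_stage"], float(patient["psa"]), gs_cat)
        probs[j] = cell[col] / 100.0
    labels = (sub["path_stage"] == outcome).astype(int).to_numpy()
    preds = PredictionSet(
        ids=sub["id"].to_numpy(),
        prob=probs,
        label=labels,
        fold=np.zeros(len(sub), dtype=int),
        model=f"partin_{outcome.lower()}",
    )
    return preds, n_excluded
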