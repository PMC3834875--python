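"""Partin-style lookup table: loading, validation, prediction."""

import io

import numpy as np
import pandas as pd
import pytest

from stagebench import (
    auc,
    default_params,
    load_partin_table,
    loess_calibration,
    partin_predict,
    sample_cohort,
)

from .conftest import make_predictions


def synthetic_table_csv(stages=("T1c", "T2a")) -> str:
    """Synthetic toy Partin-style table (values invented for testing).

    Three PSA bands x four GS categories per stage; ECE probability rises
    with PSA and grade, stages differ by a constant shift.
    """
    rows = []
    bands = [(0.0, 6.0), (6.0, 10.0), (10.0, float("inf"))]
    gs_cats = ["5-6", "3+4", "4+3", "8-10"]
    for s_idx, stage in enumerate(stages):
        for b_idx, (lo, hi) in enumerate(bands):
            for g_idx, gs in enumerate(gs_cats):
                p_ece = 10 + 8 * b_idx + 9 * g_idx + 5 * s_idx
                p_svi = 2 + 2 * g_idx
                p_lni = 1 + g_idx
                p_oc = 100 - p_ece - p_svi - p_lni
                rows.append(
                    {
                        "clinical_stage": stage,
                        "psa_low": lo,
                        "psa_high": hi,
                        "gs_category": gs,
                        "p_oc": p_oc,
                        "p_ece": p_ece,
                        "p_svi": p_svi,
                        "p_lni": p_lni,
                    }
                )
    return pd.DataFrame(rows).to_csv(index=False)


@pytest.fixture()
def toy_table():
    return load_partin_table(io.StringIO(synthetic_table_csv()))


class TestLoadPartinTable:
    def test_toy_fixture_loads_clean(self, toy_table):
        assert toy_table.stages == ("T1c", "T2a")
        assert len(toy_table.flagged) == 0
        assert len(toy_table.cells) == 24

    def test_gapped_bands_rejected(self):
        csv = synthetic_table_csv().replace("6.0,10.0", "7.0,10.0")
        with pytest.raises(ValueError, match="gap"):
            load_partin_table(io.StringIO(csv))

    def test_overlapping_bands_rejected(self):
        csv = synthetic_table_csv().replace("6.0,10.0", "5.0,10.0")
        with pytest.raises(ValueError, match="overlap"):
            load_partin_table(io.StringIO(csv))

    def test_rounded_cells_within_tolerance_accepted(self):
        # (50, 30, 15, 5) sums to 100; published rounding up to +/-3 is fine
        df = pd.read_csv(io.StringIO(synthetic_table_csv()))
        df.loc[0, ["p_oc", "p_ece", "p_svi", "p_lni"]] = [50, 30, 15, 7]  # sums 102
        table = load_partin_table(io.StringIO(df.to_csv(index=False)))
        assert len(table.flagged) == 0

    def test_cells_far_from_100_flagged(self):
        df = pd.read_csv(io.StringIO(synthetic_table_csv()))
        df.loc[0, ["p_oc", "p_ece", "p_svi", "p_lni"]] = [50, 30, 15, 15]  # sums 110
        table = load_partin_table(io.StringIO(df.to_csv(index=False)))
        assert len(table.flagged) == 1


class TestPartinPredict:
    def test_direct_cell_lookup(self, toy_table):
        cohort = pd.DataFrame(
            {
                "id": ["A"],
                "age": [60],
                "psa": [7.0],
                "clinical_stage": ["T1c"],
                "biopsy_gs": ["4+3"],
                "prostatectomy_gs": ["4+3"],
                "family_history": ["NONE"],
                "path_stage": ["ECE"],
            }
        )
        preds, n_exc = partin_predict(cohort, toy_table, outcome="ECE")
        # band (6,10], gs 4+3, T1c: p_ece = 10 + 8*1 + 9*2 = 36
        assert preds.prob[0] == pytest.approx(0.36)
        assert preds.label[0] == 1
        assert n_exc == 0

    def test_not_reported_stage_fully_excluded(self, toy_table):
        cohort = sample_cohort(default_params(n=50, seed=3))
        cohort["clinical_stage"] = "NOT_REPORTED"
        preds, n_exc = partin_predict(cohort, toy_table)
        assert len(preds) == 0
        assert n_exc == 50

    def test_same_cell_same_prediction(self, toy_table):
        cohort = sample_cohort(default_params(n=400, seed=4))
        preds, _ = partin_predict(cohort, toy_table)
        df = preds.to_frame().merge(cohort[["id", "clinical_stage", "biopsy_gs"]], on="id")
        df["band"] = pd.cut(
            cohort.set_index("id").loc[df["id"], "psa"].to_numpy(), [0, 6, 10, np.inf]
        )
        grouped = df.groupby(["clinical_stage", "biopsy_gs", "band"], observed=True)["prob"]
        assert (grouped.nunique() <= 1).all()

    def test_per_stage_auc_pipeline_composition(self, toy_table):
        # label each patient from their own cell probability, then check the
        # table discriminates within each clinical stage
        rng = np.random.default_rng(5)
        cohort = sample_cohort(default_params(n=4000, seed=5))
        cohort = cohort[cohort["clinical_stage"] != "NOT_REPORTED"]
        preds, _ = partin_predict(cohort, toy_table, outcome="ECE")
        for stage in ("T1c", "T2a"):
            stage_ids = set(cohort.loc[cohort["clinical_stage"] == stage, "id"])
            mask = np.array([i in stage_ids for i in preds.ids])
            labels = (rng.random(mask.sum()) < preds.prob[mask]).astype(int)
            stage_preds = make_predictions(preds.prob[mask], labels)
            assert auc(stage_preds) > 0.55

    def test_table_self_calibration(self, toy_table):
        # labels drawn from the table's own probabilities give a curve near
        # the diagonal over the covered probability range
        rng = np.random.default_rng(6)
        cohort = sample_cohort(default_params(n=8000, seed=6))
        preds, _ = partin_predict(cohort, toy_table, outcome="ECE")
        labels = (rng.random(len(preds)) < preds.prob).astype(int)
        jitter = np.clip(preds.prob + rng.normal(0, 0.003, len(preds)), 0, 1)
        curve = loess_calibration(make_predictions(jitter, labels))
        assert curve.max_diagonal_deviation() < 0.07

    def test_unknown_outcome_rejected(self, toy_table, small_cohort):
        with pytest.raises(ValueError):
            partin_predict(small_cohort, toy_table, outcome="XYZ")
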