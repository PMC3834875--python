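"""Cross-validation design: folds, encoding, out-of-fold predictions."""

from collections import Counter

import numpy as np
import pandas as pd
import pytest

from stagebench import (
    ModelSpec,
    assign_folds,
    auc,
    cross_validated_predictions,
    default_params,
    encode_features,
    sample_cohort,
    univariate_predictions,
)


class TestAssignFolds:
    def test_603_patients_split_121_120(self):
        cohort = sample_cohort(default_params(n=603, seed=1))
        folds = assign_folds(cohort, k=5, seed=2)
        sizes = sorted(Counter(folds.mapping.values()).values())
        assert sizes == [120, 120, 121, 121, 121]

    def test_singleton_folds(self):
        cohort = sample_cohort(default_params(n=5, seed=1))
        folds = assign_folds(cohort, k=5, seed=0)
        assert sorted(folds.mapping.values()) == [1, 2, 3, 4, 5]

    def test_deterministic_given_seed(self):
        cohort = sample_cohort(default_params(n=100, seed=1))
        assert assign_folds(cohort, 5, 7).mapping == assign_folds(cohort, 5, 7).mapping
        assert assign_folds(cohort, 5, 7).mapping != assign_folds(cohort, 5, 8).mapping

    def test_partition_property(self):
        cohort = sample_cohort(default_params(n=97, seed=4))
        folds = assign_folds(cohort, k=5, seed=1)
        assert set(folds.mapping) == set(cohort["id"])
        assert set(folds.mapping.values()) == {1, 2, 3, 4, 5}

    def test_k_below_two_rejected(self):
        cohort = sample_cohort(default_params(n=10, seed=1))
        with pytest.raises(ValueError):
            assign_folds(cohort, k=1, seed=0)


class TestEncodeFeatures:
    def test_full_dimension_is_eight(self, small_cohort):
        X, names = encode_features(small_cohort)
        assert X.shape == (len(small_cohort), 8)
        assert names[0] == "psa"

    def test_reference_levels_all_zero(self, small_cohort):
        X, names = encode_features(small_cohort)
        t1c = small_cohort["clinical_stage"] == "T1c"
        stage_cols = [i for i, n in enumerate(names) if n.startswith("clinical_stage")]
        assert (X[np.asarray(t1c)][:, stage_cols] == 0).all()

    def test_deterministic(self, small_cohort):
        Xa, _ = encode_features(small_cohort)
        Xb, _ = encode_features(small_cohort)
        np.testing.assert_array_equal(Xa, Xb)

    def test_unknown_predictor_rejected(self, small_cohort):
        with pytest.raises(ValueError):
            encode_features(small_cohort, predictors=("age",))


class TestModelSpec:
    def test_univariate_requires_single_predictor(self):
        with pytest.raises(ValueError):
            ModelSpec(family="UNIVARIATE", predictors=("psa", "biopsy_gs"))

    def test_multivariable_requires_all_three(self):
        with pytest.raises(ValueError):
            ModelSpec(family="LOGISTIC", predictors=("psa",))


@pytest.fixture(scope="module")
def cohort_and_folds():
    cohort = sample_cohort(default_params(n=400, seed=13))
    return cohort, assign_folds(cohort, k=5, seed=13)


class TestCrossValidatedPredictions:
    @pytest.mark.parametrize("family", ["LOGISTIC", "RANDOM_FOREST", "KNN"])
    def test_every_patient_predicted_once(self, cohort_and_folds, family):
        cohort, folds = cohort_and_folds
        hp = {"n_estimators": 50} if family == "RANDOM_FOREST" else {}
        preds = cross_validated_predictions(
            cohort, ModelSpec(family=family, hyperparameters=hp), folds
        )
        assert sorted(preds.ids) == sorted(cohort["id"])
        assert preds.prob.min() >= 0 and preds.prob.max() <= 1

    def test_planted_psa_signal_gives_auc_above_half(self):
        # NOC PSA shifted far above OC PSA: logistic regression must find it
        params = default_params(n=600, seed=5).with_(
            psa_logmean_noc=np.log(20.0), psa_logsd_noc=0.3
        )
        cohort = sample_cohort(params)
        folds = assign_folds(cohort, 5, 5)
        preds = univariate_predictions(cohort, "psa", folds)
        assert auc(preds) > 0.75

    def test_no_signal_null_auc_near_half(self):
        # outcome independent of covariates: shuffle the stage labels
        cohort = sample_cohort(default_params(n=2000, seed=6))
        rng = np.random.default_rng(0)
        cohort["path_stage"] = rng.permutation(cohort["path_stage"].to_numpy())
        folds = assign_folds(cohort, 5, 6)
        preds = cross_validated_predictions(cohort, ModelSpec(family="LOGISTIC"), folds)
        assert abs(auc(preds) - 0.5) < 0.05

    def test_full_run_deterministic(self, cohort_and_folds):
        cohort, folds = cohort_and_folds
        spec = ModelSpec(family="RANDOM_FOREST", hyperparameters={"n_estimators": 30})
        a = cross_validated_predictions(cohort, spec, folds)
        b = cross_validated_predictions(cohort, spec, folds)
        np.testing.assert_array_equal(a.prob, b.prob)

    def test_single_class_training_fold_aborts(self):
        cohort = sample_cohort(default_params(n=50, seed=7))
        cohort["path_stage"] = "OC"
        folds = assign_folds(cohort, 5, 7)
        with pytest.raises(ValueError, match="single outcome class"):
            cross_validated_predictions(cohort, ModelSpec(family="LOGISTIC"), folds)

    def test_out_of_fold_discipline(self, cohort_and_folds):
        # each prediction's fold tag matches the assignment: train/test
        # disjointness holds by construction of the fold loop
        cohort, folds = cohort_and_folds
        preds = cross_validated_predictions(cohort, ModelSpec(family="LOGISTIC"), folds)
        assert all(folds.mapping[i] == f for i, f in zip(preds.ids, preds.fold))


class TestUnivariatePredictions:
    def test_clinical_stage_gives_at_most_three_values(self, small_cohort):
        folds = assign_folds(small_cohort, 5, 1)
        preds = univariate_predictions(small_cohort, "clinical_stage", folds)
        # 3 stage levels x 5 folds, but within a fold at most 3 values
        for f in range(1, 6):
            assert len(np.unique(preds.prob[preds.fold == f])) <= 3

    def test_clinical_stage_probabilities_in_narrow_band(self):
        # stage carries no signal in the generator, so a stage-only model
        # hovers near the 30% prevalence — the published narrow band
        cohort = sample_cohort(default_params(n=2000, seed=8))
        folds = assign_folds(cohort, 5, 8)
        preds = univariate_predictions(cohort, "clinical_stage", folds)
        assert preds.prob.min() > 0.20
        assert preds.prob.max() < 0.40
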