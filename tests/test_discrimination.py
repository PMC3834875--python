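"""Discrimination metrics against hand counts and pairwise oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stagebench import (
    ConfusionCounts,
    auc,
    basic_metrics,
    brier_score,
    confusion_at_threshold,
    discrimination_report,
    youden_threshold,
)

from .conftest import make_predictions


def pairwise_auc(prob, label):
    """Exhaustive Mann-Whitney oracle: mean over (pos, neg) pairs."""
    pos = [p for p, y in zip(prob, label) if y == 1]
    neg = [p for p, y in zip(prob, label) if y == 0]
    total = 0.0
    for a in pos:
        for b in neg:
            total += 1.0 if a > b else (0.5 if a == b else 0.0)
    return total / (len(pos) * len(neg))


class TestConfusion:
    def test_threshold_zero_predicts_all_positive(self):
        preds = make_predictions([0.1, 0.6, 0.4], [1, 0, 1])
        c = confusion_at_threshold(preds, 0.0)
        assert (c.tp, c.fp, c.tn, c.fn) == (2, 1, 0, 0)

    def test_threshold_above_max_predicts_none(self):
        preds = make_predictions([0.1, 0.6, 0.4], [1, 0, 1])
        c = confusion_at_threshold(preds, 0.99)
        assert (c.tp, c.fp) == (0, 0)
        assert c.n == 3

    def test_hand_counted_six_predictions(self):
        preds = make_predictions([0.9, 0.7, 0.5, 0.4, 0.2, 0.1], [1, 0, 1, 1, 0, 0])
        c = confusion_at_threshold(preds, 0.5)
        assert (c.tp, c.fp, c.tn, c.fn) == (2, 1, 2, 1)

    def test_ties_classify_positive(self):
        preds = make_predictions([0.5, 0.5], [1, 0])
        c = confusion_at_threshold(preds, 0.5)
        assert (c.tp, c.fp) == (1, 1)


class TestBasicMetrics:
    def test_youden_identity_exact(self):
        c = ConfusionCounts(tp=647, fn=353, tn=601, fp=399, threshold=0.3)
        m = basic_metrics(c)
        assert m["youden"] == m["sensitivity"] + m["specificity"] - 1.0
        assert m["youden"] == pytest.approx(0.248)

    def test_all_negative_classifier(self):
        c = ConfusionCounts(tp=0, fn=30, tn=70, fp=0, threshold=1.0)
        m = basic_metrics(c)
        assert (m["sensitivity"], m["specificity"], m["youden"]) == (0.0, 1.0, 0.0)
        assert math.isnan(m["ppv"])  # no predicted positives: flagged NA

    def test_perfect_classifier(self):
        m = basic_metrics(ConfusionCounts(tp=30, fn=0, tn=70, fp=0, threshold=0.5))
        assert all(m[k] == 1.0 for k in ("sensitivity", "specificity", "ppv", "npv"))
        assert m["youden"] == 1.0


class TestBrier:
    def test_constant_prevalence_prediction(self):
        label = np.r_[np.ones(30), np.zeros(70)].astype(int)
        preds = make_predictions(np.full(100, 0.3), label)
        assert brier_score(preds) == pytest.approx(0.21)

    def test_perfect_probabilities(self):
        preds = make_predictions([1.0, 0.0, 1.0], [1, 0, 1])
        assert brier_score(preds) == 0.0

    def test_direct_arithmetic(self):
        preds = make_predictions([0.8, 0.2], [1, 0])
        assert brier_score(preds) == pytest.approx(0.04)

    @pytest.mark.parametrize("pi", [0.1, 0.3, 0.5, 0.9])
    def test_constant_predictor_equals_pi_times_one_minus_pi(self, pi):
        n = 1000
        k = int(round(pi * n))
        label = np.r_[np.ones(k), np.zeros(n - k)].astype(int)
        preds = make_predictions(np.full(n, k / n), label)
        assert brier_score(preds) == pytest.approx((k / n) * (1 - k / n))


class TestAuc:
    def test_perfect_separation(self):
        preds = make_predictions([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert auc(preds) == 1.0

    def test_all_ties(self):
        preds = make_predictions([0.4] * 6, [1, 0, 1, 0, 1, 0])
        assert auc(preds) == 0.5

    def test_eight_point_hand_example(self):
        prob = [0.9, 0.8, 0.8, 0.6, 0.5, 0.4, 0.3, 0.1]
        label = [1, 1, 0, 1, 0, 0, 1, 0]
        preds = make_predictions(prob, label)
        assert auc(preds) == pytest.approx(pairwise_auc(prob, label))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auc(make_predictions([0.2, 0.4], [1, 1]))

    @settings(derandomize=True, max_examples=40)
    @given(
        st.lists(st.floats(0, 1, width=32), min_size=4, max_size=50),
        st.randoms(use_true_random=False),
    )
    def test_matches_pairwise_oracle_on_random_instances(self, prob, rnd):
        label = [rnd.randint(0, 1) for _ in prob]
        label[0], label[1] = 0, 1
        preds = make_predictions(prob, label)
        assert auc(preds) == pytest.approx(pairwise_auc(prob, label), abs=1e-12)

    def test_matches_sklearn_and_monotone_invariance(self, random_predictions):
        from sklearn.metrics import roc_auc_score

        preds = random_predictions(200, seed=3)
        expected = roc_auc_score(preds.label, preds.prob)
        assert auc(preds) == pytest.approx(expected, abs=1e-12)
        transformed = make_predictions(preds.prob**3, preds.label)  # strictly increasing
        assert auc(transformed) == pytest.approx(expected, abs=1e-12)


class TestReport:
    def test_sensitivity_monotone_in_threshold(self, random_predictions):
        preds = random_predictions(300, seed=11)
        sens, spec = [], []
        for t in np.linspace(0, 1, 51):
            m = basic_metrics(confusion_at_threshold(preds, t))
            sens.append(m["sensitivity"])
            spec.append(m["specificity"])
        assert all(a >= b - 1e-12 for a, b in zip(sens, sens[1:]))
        assert all(a <= b + 1e-12 for a, b in zip(spec, spec[1:]))

    def test_youden_threshold_maximises(self, random_predictions):
        preds = random_predictions(150, seed=2)
        t_star = youden_threshold(preds)
        j_star = basic_metrics(confusion_at_threshold(preds, t_star))["youden"]
        for t in np.unique(preds.prob):
            j = basic_metrics(confusion_at_threshold(preds, float(t)))["youden"]
            assert j <= j_star + 1e-12

    def test_report_internally_consistent(self, random_predictions):
        preds = random_predictions(400, seed=9)
        rep = discrimination_report(preds)
        assert rep.youden == rep.sensitivity + rep.specificity - 1.0
        assert rep.auc == pytest.approx(pairwise_auc(list(preds.prob), list(preds.label)))

    def test_null_predictions_give_null_metrics(self, random_predictions):
        preds = random_predictions(5000, seed=17)
        rep = discrimination_report(preds, threshold_rule="fixed", fixed_threshold=0.5)
        assert abs(rep.auc - 0.5) < 0.03

    def test_threshold_rules(self, random_predictions):
        preds = random_predictions(100, seed=4)
        assert discrimination_report(preds, "fixed", 0.7).threshold == 0.7
        assert discrimination_report(preds, "prevalence").threshold == preds.prevalence
        with pytest.raises(ValueError):
            discrimination_report(preds, "magic")
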