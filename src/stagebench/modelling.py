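"""Cross-validated staging classifiers.

Each model predicts the probability of non-organ-confined (NOC) disease from
pre-operative PSA, DRE-based clinical stage and biopsy Gleason score under a
5-fold cross-validation design: the cohort is randomly split into five
near-equal folds, each fold is scored by a model trained on the other four,
and the out-of-fold probabilities are pooled so that no patient is ever used
to both develop and test the model that scores them.

Three multivariable families are supported — unpenalised logistic regression,
random forests and k-nearest-neighbours (on standardised features) — plus
single-covariate logistic fits for evaluating each clinical variable in
isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler

from .cohort import BIOPSY_GS_LEVELS, CLINICAL_STAGE_LEVELS, noc_labels

__all__ = [
    "ALL_PREDICTORS",
    "FoldAssignment",
    "ModelSpec",
    "PredictionSet",
    "assign_folds",
    "cross_validated_predictions",
    "encode_features",
    "read_predictions",
    "univariate_predictions",
    "write_predictions",
]

ALL_PREDICTORS = ("psa", "clinical_stage", "biopsy_gs")
FAMILIES = ("LOGISTIC", "RANDOM_FOREST", "KNN", "UNIVARIATE")
_FAMILY_OFFSET = {f: i for i, f in enumerate(FAMILIES)}


@dataclass(frozen=True)
class FoldAssignment:
    """Random balanced partition of patient ids into folds 1..k."""

    mapping: dict[str, int]
    k: int
    seed: int

    def fold_of(self, ids) -> np.ndarray:
        return np.array([self.mapping[i] for i in ids], dtype=int)


@dataclass(frozen=True)
class ModelSpec:
    """A classifier family, its predictors and hyperparameters.

    Unstated-by-design defaults: random forest with 500 trees and sqrt
    feature subsampling; kNN with k=25 neighbours on standardised features,
    probability = fraction of NOC neighbours; logistic regression without
    penalty. All overridable through ``hyperparameters``.
    """

    family: str
    predictors: tuple[str, ...] = ALL_PREDICTORS
    hyperparameters: dict = field(default_factory=dict)
    name: str | None = None

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; expected one of {FAMILIES}")
        unknown = set(self.predictors) - set(ALL_PREDICTORS)
        if unknown:
            raise ValueError(f"unknown predictors {sorted(unknown)}")
        if self.family == "UNIVARIATE" and len(self.predictors) != 1:
            raise ValueError("UNIVARIATE models use exactly one predictor")
        if self.family != "UNIVARIATE" and set(self.predictors) != set(ALL_PREDICTORS):
            raise ValueError("multivariable models use all three predictors")

    @property
    def identifier(self) -> str:
        if self.name:
            return self.name
        if self.family == "UNIVARIATE":
            return f"univariate_{self.predictors[0]}"
        return self.family.lower()


@dataclass
class PredictionSet:
    """Pooled out-of-fold NOC probabilities with true labels."""

    ids: np.ndarray
    prob: np.ndarray
    label: np.ndarray
    fold: np.ndarray
    model: str

    def __post_init__(self):
        self.ids = np.asarray(self.ids, dtype=object)
        self.prob = np.asarray(self.prob, dtype=float)
        self.label = np.asarray(self.label, dtype=int)
        self.fold = np.asarray(self.fold, dtype=int)
        n = len(self.ids)
        if not (len(self.prob) == len(self.label) == len(self.fold) == n):
            raise ValueError("prediction-set fields must have equal length")
        if n and (self.prob.min() < 0 or self.prob.max() > 1):
            raise ValueError("predicted probabilities must lie in [0, 1]")
        if len(np.unique(self.ids)) != n:
            raise ValueError("duplicate patient ids in prediction set")

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def prevalence(self) -> float:
        return float(self.label.mean())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": self.ids,
                "prob": self.prob,
                "label": self.label,
                "fold": self.fold,
                "model": self.model,
            }
        )


def write_predictions(preds: PredictionSet, destination) -> None:
    preds.to_frame().to_csv(destination, index=False)


def read_predictions(source) -> PredictionSet:
    df = pd.read_csv(source, dtype={"id": str})
    models = df["model"].unique()
    if len(models) != 1:
        raise ValueError(f"expected a single model per file, found {list(models)}")
    return PredictionSet(
        ids=df["id"].to_numpy(),
        prob=df["prob"].to_numpy(),
        label=df["label"].to_numpy(),
        fold=df["fold"].to_numpy(),
        model=str(models[0]),
    )


def assign_folds(cohort: pd.DataFrame, k: int = 5, seed: int = 0) -> FoldAssignment:
    """Uniform random partition into k folds whose sizes differ by <= 1."""
    if k < 2:
        raise ValueError(f"k must be at least 2, got {k}")
    n = len(cohort)
    if n < k:
        raise ValueError(f"cohort size {n} smaller than fold count {k}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    # first (n mod k) folds get the extra patient
    sizes = np.full(k, n // k)
    sizes[: n % k] += 1
    folds = np.repeat(np.arange(1, k + 1), sizes)
    assignment = np.empty(n, dtype=int)
    assignment[order] = folds
    ids = cohort["id"].tolist()
    return FoldAssignment(mapping=dict(zip(ids, assignment.tolist())), k=k, seed=seed)


def encode_features(cohort: pd.DataFrame, predictors=ALL_PREDICTORS):
    """Design matrix under reference (treatment) coding.

    Encoding order is fixed: PSA first as one continuous column; clinical
    stage as indicators for T2a and NOT_REPORTED (reference T1c); biopsy
    Gleason score as indicators for its five non-reference categories
    (reference "<=5"). With all three predictors the dimension is
    1 + 2 + 5 = 8. Returns ``(X, feature_names)``.
    """
    unknown = set(predictors) - set(ALL_PREDICTORS)
    if unknown:
        raise ValueError(f"unknown predictors {sorted(unknown)}")
    columns: list[np.ndarray] = []
    names: list[str] = []
    if "psa" in predictors:
        columns.append(cohort["psa"].to_numpy(dtype=float))
        names.append("psa")
    if "clinical_stage" in predictors:
        for level in CLINICAL_STAGE_LEVELS[1:]:
            columns.append((cohort["clinical_stage"] == level).to_numpy(dtype=float))
            names.append(f"clinical_stage[{level}]")
    if "biopsy_gs" in predictors:
        for level in BIOPSY_GS_LEVELS[1:]:
            columns.append((cohort["biopsy_gs"] == level).to_numpy(dtype=float))
            names.append(f"biopsy_gs[{level}]")
    if not columns:
        raise ValueError("at least one predictor is required")
    return np.column_stack(columns), names


def derived_seed(spec: ModelSpec, fold_seed: int, fold_index: int) -> int:
    """Deterministic per-(model, fold) seed: documented fan-out from the
    fold seed so forest bootstraps and tie-breaks are reproducible."""
    return (fold_seed * 6151 + _FAMILY_OFFSET[spec.family] * 769 + fold_index) % (2**31 - 1)


def _build_estimator(spec: ModelSpec, seed: int):
    hp = spec.hyperparameters
    if spec.family in ("LOGISTIC", "UNIVARIATE"):
        # C=inf with the default l2 penalty is an unpenalised fit
        return LogisticRegression(
            C=np.inf, solver="lbfgs", max_iter=hp.get("max_iter", 2000)
        )
    if spec.family == "RANDOM_FOREST":
        return RandomForestClassifier(
            n_estimators=hp.get("n_estimators", 500),
            max_features=hp.get("max_features", "sqrt"),
            random_state=seed,
            n_jobs=1,
        )
    if spec.family == "KNN":
        return make_pipeline(
            StandardScaler(),
            KNeighborsClassifier(n_neighbors=hp.get("n_neighbors", 25)),
        )
    raise AssertionError(spec.family)


def cross_validated_predictions(
    cohort: pd.DataFrame, spec: ModelSpec, folds: FoldAssignment
) -> PredictionSet:
    """Pooled out-of-fold probabilities for one model.

    For each fold f, the model is fitted on every patient outside f and
    scores the patients in f; a training fold with only one outcome class
    aborts with an error. The whole run is deterministic given
    (cohort, spec, folds): model-internal randomness is seeded by
    :func:`derived_seed`.
    """
    ids = cohort["id"].to_numpy()
    missing = [i for i in ids if i not in folds.mapping]
    if missing:
        raise ValueError(f"fold assignment does not cover ids {missing[:5]}")
    fold_of = folds.fold_of(ids)
    y = noc_labels(cohort)
    X, _ = encode_features(cohort, spec.predictors)

    prob = np.empty(len(cohort), dtype=float)
    for f in range(1, folds.k + 1):
        test = fold_of == f
        train = ~test
        if not test.any():
            continue
        if len(np.unique(y[train])) < 2:
            raise ValueError(
                f"training data for fold {f} contains a single outcome class; "
                "cannot fit a classifier"
            )
        est = _build_estimator(spec, derived_seed(spec, folds.seed, f))
        est.fit(X[train], y[train])
        positive = list(est.classes_).index(1)
        prob[test] = est.predict_proba(X[test])[:, positive]
    return PredictionSet(
        ids=ids, prob=np.clip(prob, 0.0, 1.0), label=y, fold=fold_of, model=spec.identifier
    )


def univariate_predictions(
    cohort: pd.DataFrame, predictor: str, folds: FoldAssignment
) -> PredictionSet:
    """Out-of-fold probabilities from a single-covariate logistic fit."""
    spec = ModelSpec(family="UNIVARIATE", predictors=(predictor,))
    return cross_validated_predictions(cohort, spec, folds)
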