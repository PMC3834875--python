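"""Fit the three staging classifiers under 5-fold cross-validation and
compare their discrimination.

Each model predicts the probability of non-organ-confined disease from
PSA, clinical stage and biopsy Gleason score; metrics are computed on the
pooled out-of-fold predictions at the Youden-optimal threshold.
"""

import pandas as pd

from stagebench import (
    ModelSpec,
    assign_folds,
    cross_validated_predictions,
    default_params,
    discrimination_report,
    sample_cohort,
    univariate_predictions,
)

cohort = sample_cohort(default_params(n=603, seed=1))
folds = assign_folds(cohort, k=5, seed=2)

reports = []
for family in ("LOGISTIC", "RANDOM_FOREST", "KNN"):
    preds = cross_validated_predictions(cohort, ModelSpec(family=family), folds)
    reports.append(discrimination_report(preds))
for predictor in ("biopsy_gs", "psa", "clinical_stage"):
    preds = univariate_predictions(cohort, predictor, folds)
    reports.append(discrimination_report(preds))

table = pd.DataFrame({r.model: r.as_dict() for r in reports}).round(3)
print(table.to_string())
# AUC is the probability the model ranks a random NOC patient above a
# random OC patient; 0.5 is chance. Youden = sensitivity + specificity - 1.
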