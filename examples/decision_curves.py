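"""Decision curve analysis for the cross-validated logistic model.

Net benefit (true positives per patient, penalising false positives by the
odds of the threshold probability) is compared against treating everyone
and treating no one across threshold probabilities 1%-50%.
"""

from stagebench import (
    ModelSpec,
    assign_folds,
    best_model_at,
    cross_validated_predictions,
    decision_curve,
    default_params,
    sample_cohort,
)

cohort = sample_cohort(default_params(n=603, seed=1))
folds = assign_folds(cohort, k=5, seed=2)
preds = cross_validated_predictions(cohort, ModelSpec(family="LOGISTIC"), folds)

curve = decision_curve(preds)
for pt in (0.10, 0.20, 0.30, 0.40):
    i = list(curve.grid).index(pt)
    best = best_model_at([curve], pt)
    print(
        f"pt={pt:.2f}: model net benefit {curve.model_nb[i]:+.3f}, "
        f"treat-all {curve.treat_all[i]:+.3f}, best strategy: {best}"
    )
# above the ~30% prevalence, treat-all goes negative and a model only has
# value if it keeps a positive net benefit there
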