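"""Loess calibration curve for the cross-validated logistic model.

Prints the largest deviation of the smoothed observed probability from the
ideal 45-degree line, plus the binned observed fractions with Wilson 95%
intervals — the error bars of a calibration plot.
"""

import numpy as np

from stagebench import (
    ModelSpec,
    assign_folds,
    cross_validated_predictions,
    default_params,
    loess_calibration,
    sample_cohort,
)

cohort = sample_cohort(default_params(n=603, seed=1))
folds = assign_folds(cohort, k=5, seed=2)
preds = cross_validated_predictions(cohort, ModelSpec(family="LOGISTIC"), folds)

curve = loess_calibration(preds, span=0.75, degree=2)
print(f"model: {curve.model}")
print(f"prediction range: {curve.grid[0]:.3f} - {curve.grid[-1]:.3f}")
# 0 would be perfect calibration; small values mean predicted probabilities
# can be read as actual risks. The full-range maximum is dominated by the
# sparse extreme tail, where loess extrapolates from few patients, so the
# central band is the better summary.
lo, hi = np.quantile(preds.prob, [0.05, 0.95])
central = (curve.grid >= lo) & (curve.grid <= hi)
dev = abs(curve.smoothed - curve.grid)
print(f"max |smoothed observed - predicted|: {dev.max():.3f} (full range)")
print(f"max |smoothed observed - predicted|: {dev[central].max():.3f} (central 90% of predictions)")
print(curve.bins.round(3).to_string(index=False))
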