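# stagebench

Evaluation framework for clinical prediction models of prostate-cancer stage
at radical prostatectomy (RP).

Before surgery, a clinician knows a patient's serum PSA, DRE-based clinical
stage (T1c or T2a) and biopsy Gleason score (GS); pathology after surgery
reveals whether the tumour was organ-confined (OC) or non-organ-confined
(NOC: extracapsular extension, seminal-vesicle invasion or lymph-node
involvement). `stagebench` is for biostatisticians who want to fit staging
classifiers to such data and — more importantly — evaluate them the way
modern model-evaluation practice demands: with discrimination, calibration
*and* clinical utility, not AUC alone.

The package provides:

* **A synthetic cohort generator** calibrated to the published structure of a
  603-patient RP cohort: 30% NOC prevalence split 63/27/10 over ECE/SVI/LNI,
  stage-conditional log-normal PSA (means 7.6 / 8.6 ng/ml), stage-conditional
  biopsy GS distributions, a 31.8% "not reported" clinical-stage level, and a
  biopsy→prostatectomy GS transition structure with ≈53% concordance, ≈34%
  upgrading and ≈13% downgrading.
* **Descriptives**: cohort summary tables with OC-vs-NOC comparisons
  (t-test / Mann-Whitney U chosen by a Shapiro-Wilk check; chi-square for
  categoricals) and the Gleason upgrade/downgrade concordance table.
* **5-fold cross-validated models**: unpenalised logistic regression, random
  forests and k-nearest-neighbours on (PSA, clinical stage, biopsy GS), plus
  each variable in isolation; metrics are always computed on pooled
  out-of-fold predictions, so no patient is scored by a model that saw them.
* **Discrimination**: sensitivity, specificity, Youden index
  (J = sens + spec − 1), PPV, NPV, Brier score and Mann-Whitney AUC.
* **Calibration**: loess-smoothed (tricube local quadratic) observed-vs-
  predicted curves with quantile-binned Wilson 95% error bars.
* **Decision curve analysis**: net benefit
  NB(Pt) = TP/n − (FP/n)·Pt/(1−Pt) over a threshold-probability grid, with
  treat-all and treat-none reference strategies.
* **A Partin-style lookup-table comparator**: load a published
  (stage, PSA band, GS) → stage-probability table from CSV and evaluate its
  predictions with the same machinery.

## Worked example

```python
from stagebench import (ModelSpec, assign_folds, cross_validated_predictions,
                        default_params, discrimination_report, sample_cohort)

cohort = sample_cohort(default_params(n=603, seed=1))
folds = assign_folds(cohort, k=5, seed=2)
preds = cross_validated_predictions(cohort, ModelSpec(family="LOGISTIC"), folds)
print(discrimination_report(preds))
```

Running `examples/evaluate_models.py` (which does the above for every model)
prints:

```
             logistic  random_forest    knn  univariate_biopsy_gs  univariate_psa  univariate_clinical_stage
threshold       0.356          0.038  0.320                 0.294           0.339                      0.321
sensitivity     0.375          0.810  0.543                 0.560           0.245                      0.364
specificity     0.840          0.305  0.637                 0.654           0.854                      0.680
youden          0.215          0.115  0.181                 0.214           0.099                      0.044
ppv             0.507          0.339  0.397                 0.415           0.425                      0.333
npv             0.754          0.785  0.761                 0.772           0.720                      0.709
brier           0.205          0.272  0.206                 0.204           0.212                      0.214
auc             0.622          0.572  0.611                 0.610           0.525                      0.476
```

Read this as: on a fresh synthetic cohort the logistic model separates NOC
from OC patients best (AUC 0.622 — the probability it ranks a random NOC
patient above a random OC patient), biopsy GS is nearly as good alone, and
clinical stage alone is uninformative (AUC ≈ 0.5, probabilities squeezed
into a narrow band around the 30% prevalence). The threshold row is the
Youden-optimal cut chosen on the pooled out-of-fold predictions.

The other scripts in `examples/` demonstrate one capability each: cohort
generation and descriptives, calibration curves, decision curves, the
Partin-table comparator, and the end-to-end pipeline
(`stagebench run --n 300 --seed 7 --out pipeline_out` from the shell).

## Layout

`src/stagebench/` — `cohort` (generator + CSV IO), `descriptives`,
`modelling` (CV design), `discrimination`, `calibration`, `decision`,
`partin`, `pipeline` + `cli`. Methodological details and design rationale
are in `docs/methods.md`.
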