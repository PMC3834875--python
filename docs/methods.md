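# Methods

## The evaluation problem

A staging classifier maps a patient's pre-operative variables — serum PSA
(ng/ml), clinical stage from digital rectal examination (T1c, T2a, or not
reported) and biopsy Gleason score — to a probability that disease is
non-organ-confined (NOC) at radical prostatectomy. `stagebench` evaluates
such classifiers on three axes:

1. **Discrimination** — can the model rank NOC patients above OC patients?
   (sensitivity, specificity, Youden index, PPV, NPV, Brier score, AUC.)
2. **Calibration** — when the model says 30%, do 30% of such patients have
   NOC disease? (loess-smoothed observed-vs-predicted curves.)
3. **Clinical utility** — does acting on the model beat treating everyone
   or no one? (decision curve analysis / net benefit.)

## Synthetic cohort generator

No patient-level data ships with the package; the generator emulates the
published marginal and conditional structure of a 603-patient RP cohort so
the whole pipeline is exercisable and testable offline.

Sampling order: pathological stage first — Bernoulli(0.30) for NOC, then a
(0.63, 0.27, 0.10) split over ECE/SVI/LNI — then stage-conditional
covariates, then the prostatectomy grade, then stage-independent variables.

* **PSA** is log-normal per stage group: PSA is right-skewed with mean >
  median, and a log-normal is the standard parsimonious choice. The
  log-scale parameters are solved in closed form from the target
  mean/median pairs (7.6/6.7 ng/ml for OC, 8.6/7.5 for NOC) via
  μ = log(median), σ² = 2·log(mean/median). Samples are clipped to the
  observed 0.7–40 ng/ml range (the clip removes < 0.1% of mass). The
  implied overall mean is 0.7·7.6 + 0.3·8.6 = 7.90 ng/ml; the published
  overall mean of 7.96 differs from its own conditional means by printed
  rounding, and tests allow for that 0.06 discrepancy explicitly.
* **Age** is a truncated normal (means 60.7 / 62.2 y by stage, sd 6.5 y,
  truncated at the observed 42–74 range, rounded to integer years). The sd
  is not published; 6.5 y makes the printed range plausible at n ≈ 600.
  Truncation pulls the realised means ≈ 0.3 y below the location
  parameters; age is reported descriptively and never used as a predictor,
  so no compensation is applied.
* **Biopsy Gleason score** uses six ordered categories (≤5, 6, 3+4, 4+3, 8,
  9) with stage-conditional probabilities normalised from the published
  per-stage counts (which cover 552 of 603 patients — the remainder lacked
  a recorded grade; the generator itself emits no missing values).
* **Prostatectomy Gleason score** is drawn from the biopsy grade through
  per-category (downgrade, concordant, upgrade) triples taken from the
  published concordance table. Moves act on the five *reporting* groups
  (≤6, 3+4, 4+3, 8, 9–10), one group up or down, clamped at the ends; a
  move within the ≤6 group (e.g. ≤5 → 6) would be invisible to
  grade-change reporting, so group-scale moves are what makes the
  configured triples recoverable from the generated data. Concordant
  patients keep their exact six-level category; a move lands on the target
  group's representative category. The implied marginal triple is
  ≈ (13%, 53%, 34%).
* **Clinical stage** is sampled independently of pathological stage with
  probabilities (0.443, 0.239, 0.318) over (T1c, T2a, not reported) — the
  published group comparison is null — and "not reported" is a legitimate
  level, not missingness: such patients stay in the cohort and form their
  own indicator level in models.
* **Family history** is independent of stage (published p = 0.70) with
  probabilities (0.549, 0.201, 0.250) over (none, other cancer, prostate
  cancer). The published per-stage family-history counts are internally
  inconsistent (the NOC column does not sum to the NOC total), so no
  attempt is made to match them conditionally.

One master seed in `GeneratorParams` drives all sampling via a single
`numpy` Generator; two calls with identical parameters are identical.

**What the generator does not emulate:** correlations beyond those induced
by pathological stage (e.g. PSA and Gleason grade are conditionally
independent given stage, which is optimistic), inter-hospital pathology
variation, BPH exclusions, and T2 sub-stratification. Consequently passing
tests show the *machinery* is correct and recovers the published marginal
structure; they do not certify model performance on real cohorts, where
predictor correlations differ.

## Descriptive statistics

Continuous variables: mean, median, range and normal-approximation 95% CI,
split overall / OC / NOC. Group comparison uses the two-sample t-test when
both groups pass Shapiro-Wilk at α = 0.05 (D'Agostino above n = 5000, where
Shapiro-Wilk is unreliable), else Mann-Whitney U. Categorical variables:
counts and percentages (rounded half-away-from-zero to one decimal, the
convention of the published tables) compared by chi-square on the full
contingency table without continuity correction; expected counts below 5
log a warning rather than triggering an exact test. Groups with fewer than
two members suppress testing and are flagged.

The Gleason transition table classifies each patient by the sign of
(prostatectomy group index − biopsy group index) over the five reporting
groups; records missing either grade are excluded and counted.

## Cross-validation design

`assign_folds` draws a uniform random balanced partition (sizes differ by
at most one; e.g. 603 patients split 121/121/121/120/120). For each fold
the model trains on the complement and scores the fold; predictions are
pooled and every metric is computed once on the pooled set — matching a
single-number-per-model reporting style — rather than averaging per-fold
metrics. Feature encoding is fixed: PSA untransformed (no transform is
published; kNN standardises internally), clinical stage and biopsy GS as
reference-coded indicators (references T1c and ≤5), giving a
1 + 2 + 5 = 8-dimensional design.

Model defaults where no published values exist: random forest 500 trees
with sqrt feature subsampling; kNN k = 25 with probability = fraction of
NOC neighbours, distances on standardised features; logistic regression
unpenalised. Every model-internal random state is derived
deterministically from (model family, fold seed, fold index).

## Discrimination

Classification is at probability ≥ t (ties positive). No single threshold
is canonical for reporting sens/spec/PPV/NPV, so the default rule picks the
threshold maximising the Youden index on the pooled out-of-fold predictions
(smallest on ties); fixed and prevalence rules are available. Undefined
ratios (zero denominator) are NaN, flagged not-available. AUC is the
tie-corrected rank (Mann-Whitney) estimator, equal to the exhaustive
pairwise count and the trapezoidal ROC area; tests verify all three routes
agree.

## Calibration

The observed probability is estimated by loess: tricube-weighted local
polynomial regression of the binary outcome on the predicted probability,
span 0.75 and degree 2 by default, evaluated on a 101-point grid over the
*observed* prediction range (not [0,1] — a nearly constant model occupies a
narrow band) and clamped to [0,1]. The smoother is implemented in-package:
widely available lowess routines fit local lines only, and a local
quadratic tracks curvature without end-flattening; it is cross-checked
against `statsmodels.nonparametric.lowess` at degree 1. Loess extrapolates
poorly where predictions are sparse, so deviations at the extreme tail of
the range should be read alongside the binned summaries. Fewer than 10
distinct predicted values raise a diagnostic instead of a curve. Error
bars come from quantile bins (default 10) with Wilson 95% intervals;
empty bins created by ties are merged and logged.

## Decision curve analysis

Net benefit at threshold probability Pt classifies positive at
probability ≥ Pt and is TP/n − (FP/n)·Pt/(1−Pt), in units of net true
positives per patient. The default grid is 0.01–0.50 in steps of 0.005,
the range over which a 30%-prevalence staging decision is plausibly
contested. Treat-all and treat-none curves are computed from the same
labels; treat-all crosses zero exactly at the prevalence. `best_model_at`
includes both references as candidate strategies and breaks ties by
declared order.

## Partin-style lookup table

The comparator applies a published (clinical stage, PSA band, biopsy GS) →
stage-probability table, transcribed by the user into a documented CSV
layout (probabilities on the percent scale; PSA bands half-open
upper-inclusive, tiling (0, ∞)). The published probability values are not
redistributed; the test fixture is synthetic and labelled as such.
Evaluation is stratified by clinical stage, since each published sub-table
conditions on stage; patients whose stage the table does not cover
("not reported") are excluded and counted. Cells whose probabilities sum
outside 100 ± 3 points are flagged (published cells are rounded), while
band gaps or overlaps are hard errors. The ECE comparison labels ECE
against all other stages; any of the four outcomes can be requested.

## Pipeline

`run_pipeline` chains every stage and writes numeric CSVs, JSON summaries,
best-effort PNG plots and a manifest (config echo, derived seeds, library
versions, SHA-256 per numeric output). The master seed fans out to the
generator (seed itself) and fold assignment (seed·7919 + 1 mod 2³¹);
reruns with the same config reproduce every numeric file hash. Plots are
presentation artifacts; the CSVs are the contract surface.

## Problem sizes

Default cohorts are 603 patients (the emulated cohort's size); calibration
checks of the generator use 10,000 patients, where binomial sampling error
on the NOC percentage is ±0.46 points (1 SE). Property tests run at a few
hundred to a few thousand records, sizes at which every oracle comparison
is exact or within stated sampling tolerances.
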