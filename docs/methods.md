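# Methods

## Scope and setting

`vitalalert` implements the analysis core of a remote-monitoring alerting
system for noncritical, ambulatory patients: single-time-point vital-sign
records are scored on the NEWS2 chart, classified by a trained binary risk
model, checked against a resting-heart-rate band, and the three indicators
are fused into a four-level urgency colour. Mobile/web delivery, sensor
ingestion and ECG analysis are out of scope; the package is the computation
and its validation harness.

## NEWS2 scoring

Each of five measured parameters maps to an integer band score in
{0, 1, 2, 3}; the aggregate is their sum (range 0–15 here). Consciousness
and supplemental oxygen — the chart's other two rows — are fixed to their
zero-scoring values (*alert*, *room air*) because the system targets
noncritical patients; inputs stating anything else are rejected rather than
mis-scored.

Numerical conventions:

- **Rounding.** Chart bands are printed at integer precision (rates,
  pressures, SpO₂) and 0.1 °C (temperature). Inputs are rounded to that
  precision with ties away from zero before lookup, which makes the printed
  bands exhaustive and non-overlapping over the reals. Ties are evaluated in
  binary floating point, so a value stored just below an exact decimal tie
  (e.g. 36.15 is stored as 36.1499…) rounds down; this affects only exact
  printed ties and is irrelevant to measured data.
- **SpO₂ scale 2 above 92%.** The chart's scale-2 bands stop at "88–92"
  (score 0). For a patient breathing room air, 93% and above also scores 0
  (the elevated-saturation penalties apply only on supplemental oxygen);
  this is exposed as the documented constant
  `SPO2_SCALE2_ON_AIR_HIGH_SCORE`.
- **Temperature top band.** The ≥39.1 °C band scores 2 (the chart has no
  score-3 band for fever), so the maximum aggregate over the five scored
  parameters is 15 only because every *other* parameter reaches 3.
- **Risk tiers.** Aggregate ≥7 → high; 5–6 → medium; ≤4 with any single
  component equal to 3 → low-medium; otherwise low. The tiers are ordered by
  severity and the classification is monotone: raising any component never
  lowers the tier.
- **Physical ranges.** Values outside plausible physiology (e.g. SpO₂ > 100,
  temperature < 25 °C) are measurement errors and raise rather than score.

## Alert fusion

Three binary indicators each contribute 0 or 1:

1. classifier predicts *abnormal*;
2. NEWS2 aggregate exceeds the threshold — default strictly greater than 7
   (`news2_strict=True`); the ≥7 variant, matching the high-clinical-risk
   boundary, is a configuration switch;
3. resting heart rate outside [60, 100] bpm (both bounds normal).

The score (0–3) maps one-to-one to green/yellow/orange/red and an alert is
raised at orange or red, i.e. when at least two independent indicators
agree. Requiring agreement is the alarm-fatigue defence: one borderline
signal never pages anyone. The low-medium NEWS2 tier (single component of 3)
does not enter the fusion; only the aggregate does.

## Risk classifiers

Six families with fixed study configurations (registry defaults):
random forest (depth 3, 100 trees), logistic regression (C=1.0,
max_iter=100), decision tree (min_samples_leaf=2), KNN (k=5, uniform),
linear SVM (C=1.0, max_iter=100), XGBoost (depth 3, η=0.1, 100 rounds).
The estimators are scikit-learn/xgboost; this package owns the splitting,
metrics, cross-validation and benchmarking.

- **No feature normalization.** The deployed model scores manually entered
  vitals directly, so features are used on their natural scales. A known
  consequence: the linear SVM does not converge within its 100-iteration cap
  on these scales and can score below the majority-class rate — retained
  as-is because the cap is part of the configuration under study, and noted
  wherever a test would otherwise read it as a harness bug.
- **Decision-tree pruning.** The configured "pruning confidence 0.25" is a
  C4.5-style control with no scikit-learn equivalent; it is carried in the
  registry for configuration fidelity while the effective pruning knobs are
  `min_samples_leaf` (2) and the exposed `ccp_alpha` (default 0).
- **Splitting.** Train size is `round_half_away(fraction × N)`: 1,177
  records at 70% give 824/353. Shuffling, folds and tree seeds all derive
  from the caller's seed; identical seeds reproduce splits, folds and fitted
  predictions exactly.
- **Metrics.** From the confusion matrix with *abnormal* positive:
  accuracy, precision, recall, F1; MAE and RMSE are computed on hard 0/1
  predictions, so MAE = 1 − accuracy and RMSE = √MAE identically. Undefined
  ratios (empty denominator) are reported as 0. K-fold (default K=10) mean
  accuracy is the unweighted mean over folds.
- **Benchmark winner.** Highest hold-out accuracy, ties broken by recall,
  then lower MAE, then lower RMSE — accuracy and recall first because the
  system's goal is finding true positives without flooding clinicians.

## Synthetic cohorts

The generator emulates the published marginal summary statistics of the
1,177-record clinical extract (per-variable mean, std, min, max for age,
BMI, heart rate, systolic BP, respiration rate, temperature, SpO₂, blood
sugar).

- **Moment-matched truncated normals.** Each variable is a truncated normal
  on the published [min, max]; the parent location and scale are solved
  numerically (Powell hybrid root-finding on the truncated mean/std) so the
  *truncated* distribution hits the published mean and std. Naive
  `loc=mean` parents would be biased — e.g. the age ceiling at 99 would pull
  the sample mean ≈1 year below target, far outside Monte-Carlo error at
  n=100,000. Infeasible (mean, std, support) combinations raise. Quartiles
  are not enforced; the published quartiles are near-symmetric, so the
  family is adequate for means/spreads but not guaranteed at the quartile
  level.
- **Independence.** No covariance structure is published, so variables are
  independent by default. A correlation-matrix hook couples them through a
  Gaussian copula (correlated normals → uniforms → marginal quantiles)
  without changing the marginals.
- **Labels.** The clinical extract's normal/abnormal definition is not
  public, so the rule is explicit: `latent_news2` (default) sets
  p(abnormal) = logistic(a·(NEWS2 − b)), a=1.5, b=4, reusing the production
  scorer — labels are then a noisy monotone function of true deterioration,
  with prevalence ≈0.3 under the default marginals; `logistic_linear` uses a
  known linear-logistic model on standardized features, enabling
  parameter-recovery validation. Optional label noise flips labels with the
  configured probability. When sampling labels separately from features, use
  an independent seed: truncated-normal sampling inverts uniforms, so
  reusing one integer seed for both stages correlates the label thresholds
  with the features (`generate_cohort` avoids this internally by advancing
  one shared stream).
- **Missingness and imputation.** Cells are blanked completely at random at
  the configured rate, then each missing cell is replaced by the mean of the
  observed values in the same label class (whole cohort when no labels),
  matching the extract's preprocessing. Observed cells are never modified; a
  variable entirely missing within a group raises.
- **What the generator does not emulate.** Real vital signs are correlated
  (default), longitudinal, heteroskedastic across age and diagnosis strata,
  and their abnormality label encodes clinician judgement. Passing tests on
  these cohorts therefore validate the *machinery* — scoring, fusion,
  splitting, metrics, reproducibility, learnability of a feature-driven
  label — not clinical performance. Published classifier accuracies from the
  restricted extract are not reproduction targets here.

## Records, pipeline, CLI

Records are validated on read (ranges for height, weight, age, SpO₂ and the
vitals; non-empty unique ids): invalid rows are rejected with a per-row
reason and the rest kept, or the read aborts on the first error in strict
mode. BMI is weight/height² (kg/m², 4 significant figures), computed rather
than entered. The batch pipeline composes NEWS2 → batch classifier
prediction → HR flag → fusion per record, collecting per-level counts and a
rejects report. CLI runs log the seed, config hash and input checksum so
alarm behaviour is auditable; `--strict` makes any rejected record a nonzero
exit.

## Problem sizes in the shipped checks

The test suite and acceptance script use: 10,000-point grids per parameter
for chart agreement; 10⁴ random confusion matrices for metric identities;
n=5,000 for logistic parameter recovery (±3 SE, with standard errors from an
independent maximum-likelihood fit); n=500, K=10 for the label-shuffle
leakage guard across all six models; n=100,000 for marginal fidelity (3
Monte-Carlo SE); and study-sized cohorts (n=1,177) for the benchmark runs.
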