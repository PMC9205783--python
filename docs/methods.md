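# Methods

This note documents the models and procedures `aldpanel` implements, the
defaults it ships, the design decisions taken where the workflow was
genuinely open, and what the synthetic cohort does and does not emulate.

## Synthetic cohort generator

The generator (`aldpanel.cohort`) produces the study conditions the
analysis modules assume. Defaults describe a derivation-type ALD cohort:

- **Cohort composition.** 459 patients, of whom 360 are biopsied with the
  fibrosis-stage distribution 36/124/106/27/67 (F0–F4), assigned as exact
  counts so the ≥F2 endpoint yields exactly 200 cases and 160 controls.
  Unbiopsied patients model the low-liver-stiffness subset: histology
  missing, latent stage drawn from {0, 1}.
- **Histology coupling.** Inflammatory activity (I, 0–5) and steatosis
  (S, 0–3) are drawn from a Gaussian copula rank-coupled to fibrosis with
  correlations 0.6 and 0.3. These are free parameters chosen to reproduce
  the strong overlap between fibrosis and inflammation hit lists seen in
  real cohorts; the activity score is decomposed into lobular inflammation
  (0–3) plus ballooning (0–2) uniformly over feasible pairs.
- **Covariates.** Age ~ N(57, 9.6²) years clipped to 18–75; BMI lognormal
  with median 27.4 kg/m²; sex Bernoulli(0.76 male); abstinence
  Bernoulli(0.42) — locations matching typical ALD cohort medians.
- **Proteome.** Per-protein log2 baselines uniform over a 12-log2-unit
  dynamic range (18–30; the true dynamic range of plasma DIA matrices is
  not published, so this is a stated free choice). Planted markers (default
  9 per lesion axis, disjoint) add ±0.5 log2 units per stage step, with
  residual noise SD 0.5 log2 — effect sizes at which recovery should be
  essentially complete, used as the reference recovery condition. Planted
  markers are drawn from the reliably quantified abundance range
  (baseline ≥ dropout midpoint + 2), since a marker below the
  quantification limit is not a meaningful planting for recovery studies.
- **MNAR dropout.** Each log2 cell is removed with probability
  logistic(−steepness·(x − midpoint)), defaults midpoint 19, steepness 1,
  giving ≈10% overall missingness and ≈94–96% completeness after the 60%
  valid-value filter — the regime that motivates downshifted imputation.
- **Comparator tests.** Noisy monotone transforms of the relevant score on
  test-specific scales (kPa-like for elastography, index-like for serum
  scores), with per-patient availability drawn from five missingness
  patterns. These exercise fixed-cutoff benchmarking and
  missingness-pattern stratification without claiming clinical realism.
- **Outcomes.** Exponential event times with rate
  hazard_base·exp(log_hr·stage) (defaults 4·10⁻⁴/month and 0.6/stage for
  liver-related events; the all-cause-mortality coefficient is attenuated
  by 0.5), administratively censored at 60 months. Follow-up ends at death
  or censoring; events are only observed within follow-up.
- **QC replicates.** 13 columns of one fixed profile with multiplicative
  lognormal noise targeting a 19% per-protein CV.

All randomness flows from one seed through named substreams (histology,
covariates, proteome, dropout, liver, comparators, outcomes, qc), so any
component can be regenerated independently and outputs are byte-for-byte
reproducible.

**What the generator does not emulate:** peptide-level structure, batch
effects and instrument drift, non-monotone comparator physiology, competing
risks, and informative (outcome-dependent) censoring. Passing recovery
tests therefore demonstrates the pipeline's correctness and calibration
under its stated assumptions, not clinical performance on real cohorts.

## Preprocessing

Fixed order: minimum-proteins sample filter (≥200) → valid-values protein
filter (≥60% across all samples pooled) → log2 transform → QC-CV filter
(≤30%) → downshifted-normal imputation. Boundary semantics are inclusive
(exactly 200 proteins, exactly 60%, exactly 30% all pass). Decisions where
the workflow is underdetermined:

- QC CV is computed on linear intensities (the conventional definition);
  proteins with fewer than two observed QC values cannot be assessed and
  are removed and reported rather than silently kept.
- Imputation parameters (per-sample mean and SD) come from observed values
  only, with no iterative refinement; the SD uses the n−1 denominator.
- Whether the sample filter precedes the protein filter is not documented
  in the workflows this mirrors; the order above is fixed and tested.

## Differential screens

ANCOVA is an OLS partial F-test: log2 intensity ~ stage (categorical, one
indicator per level above baseline) + covariates, against the
covariates-only model. The factor of interest is categorical to keep
stage-shape flexibility; ordinal covariates enter as numeric scores.
Covariate sets: age, BMI, sex, abstinence for every factor; fibrosis and
inflammation screens additionally adjust for steatosis and the steatosis
screen for fibrosis (configurable — the real protocol's "vice versa" is
ambiguous about whether steatosis was adjusted for fibrosis, inflammation
or both). Stage levels with fewer than two samples are merged into their
nearest neighbor with a warning. The F denominator is floored at round-off
scale so a protein fit exactly by the covariates yields F = 0 rather than
0/0 noise. Since all proteins share one design matrix, the fits are
vectorized; tests cross-check single proteins against pingouin's ANCOVA.

Spearman partial correlation rank-transforms intensity, score and
covariates (average ranks), residualizes intensity and score ranks on the
covariate ranks, and reports the Pearson correlation of the residuals with
a t-based p-value on n − 2 − k degrees of freedom. Significance gate:
q < 0.05 and |r| ≥ 0.3.

## Panel selection and evaluation

- **mRMR** is the F-statistic/|Pearson| quotient variant: relevance is the
  one-way ANOVA F against the class, redundancy the mean absolute Pearson
  correlation with already-selected features floored at 0.001. This is
  stated explicitly because "mRMR" also names mutual-information variants.
  Ties break on lexicographic feature id; constant features have zero
  relevance.
- **Cross-validation** is five folds × ten repeats, stratified jointly on
  class label and the pattern-of-missingness key over the comparator
  variables; joint combinations rarer than the fold count are pooled within
  their class. To keep CV honest, the mRMR ranking is recomputed inside
  each training fold; ranking once on all data before CV (a common but
  leakage-prone shortcut) is available as `legacy_global_ranking`. A
  label-permutation audit (mean CV AUC within [0.45, 0.55]) is part of the
  test suite.
- **Logistic panels** are L2-penalized (inverse strength C = 1, intercept
  unpenalized) on internally standardized features, fitted to tight
  tolerance; the scaler travels with the frozen model. Classification uses
  a 0.5 probability cutoff with ties-at-cutoff classified as cases
  (≥ convention). Panel size is the smallest k attaining the maximal mean
  F1. The final model comes from one stratified 80/20 split and is frozen
  for benchmarking, rule-out and prognosis.
- **CV aggregates** use the normal approximation, CI = mean ± 1.96·SD/√50.

## Benchmarking

Comparators are evaluated both at fixed clinical cutoffs (boundary value =
case, in the direction the test indicates disease) and, through the same
logistic machinery, as single-variable models. DeLong's test uses midrank
placement values (probabilities from small panels tie frequently); two
identical predictors return z = 0, p = 1 rather than an error. NRI is the
class-based form computed from binary calls; with no events (or nonevents)
the affected component and the total are reported missing. Rule-out
accuracy carries a Clopper–Pearson 95% CI.

## Prognosis

The frozen diagnostic model's probability is the risk score; nothing is
refitted on outcomes. Harrell's C counts pairs where the smaller observed
time belongs to an event; pairs tied in time are non-comparable unless
exactly one is an event; risk ties get half credit. Horizon AUC uses the
simple exclusion rule (cases = events at or before the horizon; controls =
records observed event-free through the horizon, including follow-up ending
exactly at an administrative boundary; censored earlier without an event
excluded) rather than IPCW weighting — the choice is isolated so an IPCW
variant can be added. The composite liver-related-event list (ten named
outcomes) is configurable.

## Numerical and degenerate-input conventions

- Missingness is explicit (NaN); ordinal scores are nullable integers, so
  a missing biopsy score can never enter arithmetic as a sentinel.
- Matrix writes use full-precision decimal repr, making read∘write the
  identity and every result file byte-reproducible from (inputs, config,
  seed).
- Single-class truth vectors: ROC-AUC is reported missing, other metrics
  computed; empty-denominator rates are 0.
- Samples with fewer than two observed values cannot be imputed (SD
  undefined) and are a hard error.

## Problem sizes

The bundled tests and the acceptance script use the cohort's natural scale
(360 biopsied patients × 500 proteins), 5–10 generator seeds per stochastic
claim, 2,000 replicates for the DeLong type-I simulation, and 10,000
imputed cells for moment checks — sizes at which the Monte-Carlo error of
each check is well below its asserted tolerance.

## Known limitations

- The ANCOVA is unmoderated OLS (no empirical-Bayes variance shrinkage), by
  design.
- The horizon AUC is not IPCW-corrected; with heavy early censoring it is
  biased relative to the cumulative/dynamic estimand.
- Comparator simulation is a monotone-transform caricature; NRI and DeLong
  results on synthetic data validate the arithmetic, not clinical claims.
- No hyperparameter search and no comparison of classifier families:
  logistic regression is adopted as a premise.
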