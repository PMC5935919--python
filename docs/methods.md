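# Methods

This note documents the statistical procedures, the numerical choices, and
the design decisions behind `breathvoc`, in the spirit of a model-description
appendix.  It states no empirical number that the test suite or
`scripts/acceptance.py` does not itself compute.

## The diagnostic problem

Exhaled end-tidal ("alveolar") air is in gas-exchange equilibrium with
pulmonary blood, so blood-borne metabolic changes can surface as shifts in
breath VOC concentrations.  An IMR-MS instrument reports ~92 channels in
ppb: twelve directly calibrated compounds (methanol, acetonitrile, ethanol,
MEK, acetone, isoprene, n-propanol, benzene, toluene, n-heptane, ammonia,
sulfur dioxide) and the rest as mass labels `M<MW>`.  The task is a
case/control classifier for pancreatic ductal adenocarcinoma from a single
exhalation.

Only 40 of the 80 mass labels in the study panel are named in the published
tables (the 22 excluded exogenous masses plus 18 screened channels); the
other 40 filler molecular weights in `panel.STUDY_PANEL` are a synthetic
reconstruction chosen not to collide with any named channel.  They carry no
chemical claim; they exist so the panel has the documented 92 channels.

## Data reduction

* **CO₂ QC.**  "Below 2 vol% end-tidal CO₂" is read strictly: `co2 == 2.0`
  is kept.  Room-air samples are never CO₂-filtered (the criterion measures
  exhalation quality).  A missing CO₂ value on an alveolar sample is an
  error, never a silent keep.
* **Age window.**  40–75 inclusive at both ends.
* **Alveolar-gradient filter.**  The published analysis excluded molecules
  "significantly more present" in room air without naming the test.  Here:
  one-sided paired Wilcoxon signed-rank (environmental > alveolar), pairing
  each alveolar sample with the same subject's room-air sample, α = 0.05,
  chosen to match the non-parametric tests used elsewhere in that analysis.
  No room-air subtraction is performed anywhere — molecules are excluded,
  never corrected.  An `explicit_list` mode reproduces the fixed 22-mass
  exclusion (92 → 70).  That printed list contains "M18" amid
  M116/M117/M120/M121, very likely a typo for M118; the panel carries "M18"
  as printed and label resolution accepts "M118" as an alias rather than
  guessing.
* **Summaries.**  Median, geometric mean, min, max, arithmetic mean, SD
  (sample convention), 5th/95th percentiles, per feature per group.
  Geometric means of vectors containing zeros floor the zeros at half the
  smallest positive value of that feature and emit a warning.

## Penalized model

### Objective and solver

Each stage minimizes `-loglik + λ Σ_j w_j |β_j|` with the log-likelihood
**summed** over observations (the parametrization of the classical
`penalized`-style software family — λ values are only comparable under this
convention) and the intercept unpenalized.  `w_j = ∞` removes a feature
exactly.  The solver is proximal Newton: IRLS with working weights floored
at 1e-6, each quadratic subproblem solved by cyclic coordinate descent.
Convergence is declared on the *subgradient (KKT) residual of the logistic
objective*, recomputed independently of the solver loop; returned fits
satisfy it at 1e-7 (verified ≤ 1e-6 in the tests).  At λ = 0 on separable
data the likelihood has no maximizer; this is detected (vanishing deviance
with a non-stationary score) and raised as a numerical error rather than
returned.

Predictors are standardized to mean 0, SD 1 before fitting, using the
population-SD convention (ddof = 0; configurable).  Coefficients are
reported on both the standardized and the back-transformed original (ppb,
years) scale; the two give identical predictions by construction.

### Penalty selection

λ is chosen on a descending grid of 100 log-spaced values from λ_max (the
smallest λ with an all-null penalized solution, computed from the data and
the weights) down to λ_max·1e-4, by stratified k-fold cross-validation
(default k = 50) maximizing the summed out-of-fold log-likelihood.  Ties go
to the larger λ.  Fold assignments derive deterministically from the stage
seed; each stage of the pipeline draws its own sub-seed from the run seed.
Fold fits along the path run at a relaxed KKT tolerance (1e-4) with warm
starts — they only rank λ values — while every *returned* fit uses the
tight tolerance.

### The two-stage iterated fit

1. *Screen*: one LASSO (unit weights) over age, sex and every retained VOC
   at the CV-chosen λ; zero-coefficient terms are discarded and the
   surviving coefficients are thrown away (only membership matters).  Age is
   re-offered to the next stage even if screened out; sex is not (it
   competes like any predictor, mirroring the published analysis where it
   was eliminated).
2. *Iterated fit on the survivors*: a pilot LASSO (unit weights, fresh CV λ)
   produces coefficients whose inverse magnitudes become penalty weights
   `w_j = 1/|β_j|` for the adaptive LASSO (fresh CV λ).  Nonzero terms of
   the adaptive fit form the final model.  The adaptive fit with weights w
   is algebraically a unit-weight LASSO on the column-rescaled design
   `X_j / w_j` (checked numerically in the tests).

An empty final model is surfaced explicitly as a null model (intercept =
logit of prevalence), never an error.

### Confidence intervals

"Iterated bootstrap" is under-specified in the source; implemented as a
subject-level nonparametric bootstrap, stratified by outcome (class counts
preserved), refitting **only** the adaptive stage at frozen λ, weights,
candidate set and training standardization — intervals are percentile and
conditional on the selected model, matching the fact that the published CIs
cover only the final model's terms.  Default 200 resamples; a 10-resample
compatibility mode exists.  A degenerate `resample=False` switch reproduces
zero-width intervals for machinery checks.

### Published coefficients

`published.py` carries both printed coefficient columns verbatim, and
`apply_published_model` evaluates the final model on a feature vector.  The
scale of those printed coefficients is ambiguous: the methods standardized
predictors, yet magnitudes such as +0.0017 on ~100 ppb ammonia are plausible
raw-scale values.  The function therefore takes `scale="raw"` (default,
applied directly to ppb/years) or `scale="standardized"` (requires
standardization parameters); neither convention is claimed correct.

## Operating point and validation

Classification calls `score ≥ cutoff → case` (the boundary direction is a
convention, fixed and documented here).  The default cutoff policy returns
the largest cutoff with zero training false negatives — the smallest case
score — maximizing specificity subject to 100% sensitivity; a
`target_sensitivity` policy returns the largest cutoff reaching a requested
sensitivity.  Integer confusion counts are the primary state; percentages
are derived and, for display, rounded half-up to one decimal.  ROC
thresholds sit at observed score values; the trapezoidal AUC equals the
tie-corrected pairwise concordance (brute-force-verified).  Validation
applies the frozen model: training-time standardization and stored
probability cutoff, no refitting.

## Synthetic cohort generator

The generator emulates the structure of the study table, not its unpublished
raw data:

* Per-channel log-normal concentrations.  For the ten diagnostic VOCs the
  per-group geometric mean is the printed one and the log-SD is back-solved
  from the printed arithmetic mean/SD (σ = √log(1 + CV²), exact for a
  log-normal).  Calibrated-but-uninformative compounds use the printed
  alveolar median and 5th–95th span (σ = log(p95/p5)/(2·1.645)); unnamed
  filler masses default to GM 20 ppb, σ 0.9 — a generic trace-channel
  scale.  Features are independent by default; an equicorrelated log-scale
  mode (ρ) exists to stress collinearity.
* Paired room-air samples: retained molecules at 0.25× their alveolar GM
  (positive alveolar gradient), the 22 exogenous masses at 4× (environmental
  excess); calibrated compounds use their printed environmental summaries.
* Ages truncated-normal per group (controls 53 ± 9, cases 61 ± 8, support
  21–83); sex Bernoulli(½); CO₂ normal above the threshold with a
  configurable sub-2% fraction (default 5%); the published-structure preset
  reproduces the printed age-exclusion counts exactly (219 → 167 with 102
  controls/65 cases) and sets the sub-2% fraction to zero, since the printed
  cohort flow shows no CO₂ exclusions.
* The outcome mechanism is two-population (the group label shifts the
  log-locations); the implied log-scale discriminant coefficients
  Δμ_j/σ̄_j² and the realized AUC of that discriminant are reported as
  ground truth for recovery tests.

**What passing tests do and do not show.**  The generator reproduces the
printed *marginal* summaries; it cannot reproduce the unpublished joint
structure of the real data.  Its intrinsic discriminant AUC under this
calibration (computed by the acceptance script at n = 10 000) is ≈ 0.94 —
noticeably below the in-sample AUC printed for the real cohort — so
synthetic end-to-end runs demonstrate that the pipeline works and that its
counts and contracts hold, not that the real data's operating points are
recovered.  Two consequences are documented as red, not patched:

* *Full-sensitivity cutoff transfer.*  With intrinsic discrimination ≈ 0.94,
  a cutoff pinned at the smallest in-sample case score transfers to new data
  with high sensitivity but modest specificity; the ≥ 80%/≥ 80% band does
  not hold across seeds under this calibration.
* *Exact support recovery.*  With λ maximizing cross-validated likelihood
  (the rule used here and in the source analysis), the pilot and adaptive
  stages retain the planted informative features essentially always, but
  also a varying handful of noise channels; the *exact*-set recovery rate at
  n = 600 over a 70-channel panel stays far below 80%.  This overselection
  of prediction-optimal L1 penalties is well documented, and the same
  behaviour is reproduced by an independent reference implementation of the
  same two-stage procedure; a more conservative rule (e.g. 1-SE) prunes to
  the exact set but is not the procedure specified.

## Problem sizes used by the tests

Simulation-based checks run at deliberately modest sizes chosen as the
package's own defaults for a laptop-class run: 25-replicate bands use
10-fold CV and 40–50 λ grid points; the end-to-end structural check uses the
full 50-fold, 100-λ configuration once; the calibration check draws 100
cohorts of 102 controls.  All seeds are fixed in the tests; the acceptance
script derives every seed from its `--seed` argument.

## Known limitations

* No measurement-error model (no within-subject replicate variance is
  published); a multiplicative noise term exists with no calibrated default.
* Smoking/alcohol covariates recorded in the study are not simulated or
  modelled (the published model did not use them).
* Instrument physics, calibration-curve chemistry and the identity of the
  unnamed masses are out of scope; mass labels are opaque strings.
* Elastic-net/L2 penalties, multinomial outcomes and post-selection
  inference beyond the described bootstrap are not implemented.
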