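# breathvoc

Case/control diagnostics from exhaled-breath volatile organic compounds
(VOCs), built around the study design used for pancreatic ductal
adenocarcinoma (PDA) screening: end-tidal (alveolar) air is sampled together
with a paired room-air sample, an ion-molecule-reaction mass spectrometer
reports ~92 channels in ppb (12 directly calibrated compounds, the rest as
`M<MW>` mass labels), and a penalized logistic model turns the VOC profile
into a disease probability.

The package implements the full analysis pipeline:

1. **Sample QC** — an alveolar sample with end-tidal CO₂ < 2 vol% was not a
   proper end-tidal collection and is discarded; ages are restricted to a
   common 40–75 window so age cannot proxy for recruitment source.
2. **Alveolar-gradient filter** — a molecule significantly more concentrated
   in room air than in breath (one-sided paired Wilcoxon, α = 0.05) is of
   exogenous origin and leaves the candidate panel; the study's fixed
   22-mass exclusion list is available as an explicit mode (92 → 70
   channels).
3. **Iterated LASSO / adaptive LASSO logistic regression** — with outcome
   y ∈ {0, 1}, standardized predictors x and penalty weights w ≥ 0, each
   stage solves

   min over (β₀, β) of  −ℓ(β₀, β) + λ Σⱼ wⱼ |βⱼ| ,

   ℓ the summed Bernoulli log-likelihood, the intercept unpenalized, λ
   chosen to maximize the stratified k-fold (default 50) out-of-fold
   log-likelihood.  A screening LASSO (unit weights, all channels + age +
   sex) discards zero-coefficient terms; a pilot LASSO on the survivors
   yields weights wⱼ = 1/|βⱼ| (zero → ∞, i.e. eliminated) for the final
   adaptive LASSO.  The solver is coordinate descent inside IRLS with an
   independently verified KKT residual ≤ 1e-6.
4. **Operating point and validation** — bootstrap percentile CIs per
   coefficient (subject-level, stratified by outcome, selection frozen), a
   probability cutoff maximizing specificity subject to 100% training
   sensitivity, and frozen-model scoring of an independent cohort (training
   standardization and cutoff applied as-is).

Because the original per-subject table is not publicly depositable, the
package ships a seeded synthetic cohort generator calibrated to the study's
printed per-group summary statistics (log-normal concentrations; geometric
means and spreads of the ten diagnostic VOCs per group; age structure;
paired room-air samples; CO₂ values straddling the QC threshold).  Every
pipeline stage, the test suite and the acceptance script run end-to-end on
that generator.

## Worked example

```bash
breathvoc simulate --preset published-like --seed 0 --out training.csv
breathvoc fit training.csv --seed 0 --published-list --out-dir fit_out
breathvoc validate fit_out/model.json training_validation.csv
```

or equivalently the numbered drivers under `analysis/`
(`01_simulate_cohorts.py`, `02_qc_and_filter.py`, `03_fit_model.py`,
`04_validate.py`).  On the seed-0 synthetic cohorts the reduction stages
print

```
CO2 QC: 0 of 438 samples rejected
age restriction 40-75: 219 -> 167 subjects (52 excluded)
gradient filter (paired Wilcoxon): 67 retained, 25 excluded
gradient filter (fixed 22-mass list): 70 retained
control ammonia median: 87.7 ppb (printed study value 91.0 ppb)
```

— 219 enrolled subjects reduce to the 167 modelled ones (102 controls, 65
cases); the paired Wilcoxon filter finds all 22 designed-in exogenous masses
plus 3 false positives (≈ 70 × α expected).  The fit then reports

```
VOC panel: 92 -> 70 after gradient filter
screen stage retained 16 VOCs; final model: 14 VOCs plus age
AUC = 0.9722
training sensitivity = 100.0% (0/65 false negatives)
training specificity = 49.0% (52/102 false positives)
```

and frozen-model validation on the independent 50-subject cohort prints

```
confusion: TP=23 FN=1 TN=9 FP=17
sensitivity 95.8%  specificity 34.6%
```

The in-sample AUC (here 0.97) flatters the model: the generator's intrinsic
(log-scale discriminant) AUC under the printed-summary calibration is
≈ 0.94, which is why the full-sensitivity cutoff — pinned to the smallest
in-sample case score — transfers with high sensitivity but modest
specificity.  See `docs/methods.md` for what the synthetic cohorts do and do
not emulate.

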