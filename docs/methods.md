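# Methods

## The problem

Self-reported dietary intake (food frequency questionnaires, food
records, dietary recalls) carries systematic and random error that
attenuates and distorts diet–disease associations. Recovery biomarkers —
doubly labeled water for energy expenditure and urinary nitrogen for
protein — are assumed to measure true usual intake with *classical*
error: unbiased and independent of both the true value and participant
traits. Regression calibration uses a biomarker substudy to build an
equation predicting true intake from self-report and participant
characteristics; the fraction of biomarker variance the equation explains
(R²) measures its usefulness, and psychosocial traits (social
desirability, body image discordance, eating-behavior scales, share of
meals eaten at home) are candidate predictors of reporting error.

`dietcalib` implements this analysis for a cohort shaped like a
postmenopausal women's biomarker substudy: n = 450 with oversampled
race/ethnicity, age and BMI strata and a 19.6% reliability subsample that
repeats the biomarker protocol.

## Measurement models

All intakes are analyzed on the log scale.

Biomarker (classical):

    W = Z + e,            W₂ = Z + e₂  (reliability subsample)

with `Z` the latent log usual intake, `e` independent of `Z` and of all
covariates, and `ρ = corr(e₁, e₂)` the (not identifiable) correlation of
replicate errors.

Self-report (expanded):

    Q = S₀ + S₁ Z + S₂ V + S₃ V·Z + r + u

with `V` participant characteristics (centered BMI and age, race
dummies, and Medium/High dummies for six categorized psychosocial /
diet-behavior factors), `r` a person-specific bias and `u` occasion
noise, all independent of `Z`, `V` and `e`.

## Pipeline

1. **Scoring** (`instrument_scoring`): Crowne–Marlowe social desirability
   is the count of the 33 keyed true/false items; TFEQ-R18 sums its 18
   four-point items into cognitive restraint (6 items), uncontrolled
   eating (9) and emotional eating (3); body-image discordance is
   perceived minus ideal-for-self silhouette (9-figure scale); meals at
   home is the percent of recorded meals eaten at home (4-day food
   record by default). Each factor is cut into Low/Medium/High; the
   default cut-offs are the study's printed ones (e.g. ≤19 / 20–24 / >24
   for social desirability, <1 / 1–2 / ≥3 for body image), with
   recomputed empirical tertiles available (`--cutoffs tertile`).
2. **Preprocessing** (`preprocess`): protein density = 100 · 4 kcal/g ·
   protein / energy; values outside Q1 − 3·IQR … Q3 + 3·IQR (per
   log-scale variable, single pass, per model) are excluded; BMI, age and
   log self-reports are mean-centered; the design has the fixed group
   order self-report(s) → BMI → age → race → meals at home → body image →
   restraint → uncontrolled → emotional → social desirability.
3. **Bias regressions** (`calibration_core.fit_bias_model`): OLS of
   (log Q − log W) on the 17 covariate columns (18 coefficient rows with
   the intercept), per instrument and nutrient.
4. **Calibration regressions** (`fit_calibration`): OLS of log W on
   centered log Q (one column per included instrument) plus covariates,
   with per-group sequential (type-I) R² contributions and total R².
5. **Adjusted R²** (`variance_adjustment`): R² divided by
   `corr(W₁,W₂) − 0.5·ρ·var(W₁−W₂) / ((1−ρ)·var(W₁))`, which under the
   classical model equals var(Z)/var(W) when the assumed ρ matches the
   generating one; since ρ is not estimable, results are reported on the
   grid ρ ∈ {0, −0.1, −0.2}.
6. **Bootstrap comparison** (`resampling_inference`): participants are
   resampled with replacement (default B = 5000), both nested calibration
   models refit per resample, SE(ΔR²) = bootstrap SD, and the p-value is
   a two-sided normal (Wald) approximation on ΔR²_observed / SE; a
   percentile alternative is available behind `method="percentile"`.

## Synthetic cohort

The generator (`synthetic_cohort`) emulates the study design so every
stage can be tested against known ground truth.

* **Strata.** Race is multinomial over the published strata proportions
  (Non-Hispanic White 64.0%, Black 18.7%, Hispanic 14.2%, Asian/Pacific
  Islander 1.8%, Other 1.3%); BMI and age are mixtures of uniforms over
  the published bands. BMI is drawn through a Gaussian latent and a
  piecewise-linear inverse CDF so later stages can recover an exactly
  standard-normal BMI latent.
* **Psychosocial factors.** A six-dimensional latent Gaussian with the
  published inter-correlations (uncontrolled–emotional 0.60,
  restraint–uncontrolled 0.15, …), conditioned on the BMI latent to
  reproduce the published BMI couplings (emotional −0.40, uncontrolled
  −0.27, restraint 0.06), is mapped onto each instrument's bounded,
  mostly integer support. The latent location/scale per factor are
  moment-matched (root-finding on the clipped/rounded normal's first two
  moments) so the discretized scores hit the published means and SDs
  (e.g. uncontrolled eating 25.66 (3.47), social desirability 21.07
  (5.35)) rather than the attenuated values naive clipping would give.
* **Latent intake.** Bivariate log-normal: z_energy and z_protein have
  linear predictors in BMI and age (defaults 0.0136 and −0.0089 per unit
  for energy — the direction and size of the biomarker regressions in
  this population), correlated residuals (0.5), and an enforced
  consistency constraint 4·protein < energy by redrawing violators.
  Means log(2080 kcal/d) and log(70 g/d) give a protein density of
  ~13.5%. Optional `factor_coefs` let Z depend on standardized
  psychosocial scores (used by the power simulations).
* **Biomarkers.** W₁ = Z + e₁ for everyone; W₂ = Z + e₂ for the flagged
  19.6%; error SDs 0.09 (energy) and 0.17 (protein) give
  var(Z)/var(W) ≈ 0.67 and 0.58, in the range implied by published
  adjusted-R² values for such cohorts. The protein-density biomarker is
  derived: log PD = log 400 + W_protein − W_energy.
* **Self-reports.** Per instrument × nutrient cells of model (B). Default
  slopes (FFQ 0.60–0.65, records/recalls 0.80–0.85), mean log biases
  (−0.20 FFQ energy down to −0.03 for the food record) and noise
  variances are set so the implied self-report–biomarker correlations
  match the weak values such studies report (FFQ energy ≈ 0.15–0.2,
  record protein ≈ 0.45). The FFQ cells carry the two systematic biases
  the cohort showed: −0.1744 (energy) / −0.1423 (protein) for high social
  desirability and +0.1814 / +0.1268 for a high share of meals at home.
  The person effect r is one standard normal per participant × nutrient,
  shared across instruments and scaled by each cell's √var_r
  (configurable off); protein-density self-reports are derived from
  energy and protein.
* **Seeding.** One master seed; each stage derives a child
  `SeedSequence` from (seed, CRC32(stage name)), so stages are
  independently replayable and the whole simulation is byte-reproducible.

What the generator does *not* emulate: item-level questionnaire
responses (factor scores are generated directly), food-composition
coding, seasonal/period structure in the reliability replicate beyond ρ,
energy-balance physiology, and missing data. Passing tests therefore
demonstrate correctness of the estimators under the stated measurement
models, not robustness to violations real cohorts may show.

## Numerical choices

* Quantiles (tertiles, outlier fences) use linear-interpolation sample
  quantiles; category intervals are closed on the right of the lower
  category (score ≤ low_max → L), matching the printed "≤" convention.
* The outlier fence is computed once per variable on the full analysis
  sample (not iterated); an exclusion for one nutrient's model leaves the
  participant eligible for others.
* Sequential R² is computed by nested least-squares fits on cumulative
  column blocks, so contributions telescope to the total exactly
  (conservation is asserted to 1e-10). Sequential (type-I) order is the
  fixed design order above; it is the only decomposition whose
  contributions provably sum to the total, which is why it is the
  default.
* The adjusted-R² formula groups the subtracted term as
  0.5·ρ·var(W₁−W₂) / ((1−ρ)·var(W)); this is the only grouping under
  which the denominator equals var(Z)/var(W) under the classical model,
  and that identity is enforced as a test. corr(W₁,W₂) and var(W₁−W₂)
  use the replicate subsample while var(W) uses the full primary sample
  (all available information).
* An adjusted R² above 100% is flagged, never clamped; a non-positive
  denominator raises.
* Bootstrap resamples reuse the observed outlier exclusions and category
  cut-offs; resamples with an empty dummy level are refit via the
  minimum-norm least-squares solution (identical fitted values to
  dropping the empty column) and counted; rank deficiency beyond empty
  levels in more than 1% of resamples aborts.
* Conventional OLS SEs everywhere except the bootstrap ΔR² SE;
  significance is flagged at 0.05 with no multiplicity correction.

## Known limitations

* The Wald construction z = ΔR²/SE for the bootstrap comparison is
  anticonservative under the null: ΔR² of nested OLS models is
  non-negative with mean ≈ k(1−R²)/n, so the test statistic is centered
  away from zero. At the default design (12 inert extra columns,
  n = 450) the measured type-I error at α = 0.05 is ≈ 0.10. The
  percentile variant is no remedy (resampled ΔR² is almost surely
  positive). The construction is retained because it is the conventional
  one for this analysis; treat borderline p-values accordingly.
* Interaction terms S₃V·Z are supported in the generator but omitted
  from the default fitted designs, which contain no interaction rows.
* The oversampling design is represented by strata weights only; all
  regressions are unweighted, as in the source analysis.
* Whether person-specific biases r correlate across instruments is not
  identifiable from published results; the generator defaults to shared
  r (configurable off) so tests can probe correlated-error consequences.

## Problem sizes used in the test suite

Law-of-large-numbers checks use cohorts of 10,000; closed-form
measurement-model identities use 10⁴–10⁶ replicate pairs; parameter
recovery averages 200 cohorts of n = 450; bootstrap operating
characteristics use 300 cohorts × B = 500 per arm; the population-R²
oracle uses a single 200,000-row cohort. These sizes put Monte-Carlo
error comfortably inside the asserted tolerances.
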