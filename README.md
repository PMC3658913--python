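# dietcalib

Regression calibration of self-reported dietary intake against recovery
biomarkers, with psychosocial and diet-behavior covariates.

Self-reported diet (food frequency questionnaires, food records, 24-hour
recalls) measures true intake with both systematic and random error.
Recovery biomarkers — doubly labeled water for energy, urinary nitrogen
for protein — are taken to follow a classical measurement model, and a
calibration equation predicting log biomarker from log self-report and
participant characteristics can correct diet–disease association
estimates. `dietcalib` is for biostatisticians and nutritional
epidemiologists who want to build, dissect and stress-test such
equations: it scores the psychosocial instruments (Crowne–Marlowe social
desirability, TFEQ-R18 eating scales, body-silhouette discordance,
percent of meals at home), fits the bias and calibration regressions
with a per-group R² decomposition, converts R² to the latent-intake
scale using a reliability replicate, and tests covariate blocks by
bootstrap — all driven by a synthetic cohort generator with known ground
truth, since cohort data of this kind are not public.

## Model

On the log scale, with `Z` latent usual intake:

```
biomarker:    W  = Z + e          W₂ = Z + e₂   (reliability subsample)
self-report:  Q  = S₀ + S₁Z + S₂V + S₃V·Z + r + u
```

`V` holds centered BMI and age, race dummies, and Low/Medium/High
dummies for six psychosocial / diet-behavior factors. The package fits

* **bias regressions** `Q − W ~ V` (which traits predict mis-reporting),
* **calibration regressions** `W ~ Q + V` with sequential (type-I) R²
  per predictor group, summing exactly to the total,
* **adjusted R²** `R² / [corr(W₁,W₂) − ½ρ·var(W₁−W₂)/((1−ρ)var(W))]`,
  the fraction of *latent-intake* variance explained, over a grid of
  assumed replicate-error correlations ρ,
* **bootstrap ΔR²** comparing nested equations with and without the
  psychosocial block (B = 5000, Wald p from the bootstrap SE).

## Worked example

```python
import dietcalib as dc

tables = dc.simulate_cohort(seed=1)          # 450 women, 88 replicates
an     = dc.build_analysis_table(tables)

bias = dc.fit_bias_model(an, "FFQ", "energy")
print(bias.table.loc[["social_desirability_H", "meals_home_H"], ["beta", "se"]])

fit = dc.fit_calibration(an, ("FFQ", "4DFR", "24HR"), "energy")
print(f"total R2 = {fit.total_r2:.1f}%")

stats = dc.reliability_stats(tables["biomarkers"], "energy")
adj   = dc.adjusted_r2(fit.total_r2, stats, rho=-0.1)
print(f"adjusted R2 at rho=-0.1: {adj.adjusted_r2:.1f}%")
```

prints

```
                           beta        se
social_desirability_H -0.168635  0.054697
meals_home_H           0.209731  0.051041
total R2 = 51.7%
adjusted R2 at rho=-0.1: 71.8%
```

The first block is the fitted FFQ energy bias table: women in the high
social-desirability tertile under-report energy by ≈ 17% (log scale
−0.169) relative to the low tertile, while women eating most meals at
home under-report least — both recovering the effects built into the
generator's defaults. The calibration equation combining all three
instruments with BMI, age, race and the six factors explains 51.7% of
biomarker variance; dividing by the reliability-based estimate of
var(Z)/var(W) says it explains ≈ 72% of the variance of latent intake
itself when replicate errors are assumed to correlate at −0.1.

The same pipeline runs end to end from the shell:

```
dietcalib run --out results/ --seed 1          # simulate + fit everything
dietcalib defaults                             # print every default
dietcalib simulate --out cohort/ --seed 2
dietcalib score --responses raw.csv --meals meals.csv --out scored/
dietcalib compare --table results/analysis_table.csv --nutrient protein_density --B 5000 --seed 1 --out cmp.csv
```

`run` writes descriptives, factor inter-correlations, three bias tables,
twelve calibration tables, the adjusted-R² sensitivity grid, the
bootstrap comparisons and a manifest that makes the run byte-for-byte
reproducible.

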