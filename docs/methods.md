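# Methods

This note documents the statistical model behind `climdebt`, the choices made
where several defensible options exist, and the package's known limitations.

## 1. Problem statement

Plant communities integrate climate: which species co-occur at a site reflects
the temperature the vegetation has equilibrated to. When the climate warms
faster than communities reorganize, the temperature *indicated by the flora*
(FrT, "floristically reconstructed temperature") lags behind the temperature
*measured by instruments* (CrT, "climatically reconstructed temperature").
The gap

```
dT = CrT − FrT
```

is the **climatic debt**: positive values mean the community still resembles
one adapted to a cooler climate. The package (i) reconstructs FrT from species
lists via transfer functions, (ii) computes per-species and per-survey
ecological covariates, and (iii) regresses dT on those covariates with a
bootstrapped, spatially thinned, weighted partial-least-squares (PLS) model to
ask *what constrains climate tracking*.

A synthetic generator plants a known debt — a fraction `lag_lambda` (λ) of the
applied warming is withheld from the temperature that shapes community
composition — so every stage can be validated against ground truth.

## 2. Synthetic study system

* **Landscape.** An `nx × ny` grid of 1-km cells with a south–north
  temperature gradient plus smooth relief, an east–west precipitation
  gradient, static soil pH and C:N fields, a smoothed random forest mask, and
  a 4× finer temperature subgrid for local heterogeneity (THET). Two
  periods: a stable baseline (default 1965–1986) and a warmed study period
  (1987–2008); warming follows a linear ramp or a step.
* **Species pool.** Gaussian niches in temperature, precipitation, pH and
  C:N. Thermal optima are drawn `niche_optimum_margin` (2.5 °C) beyond the
  landscape's realized range, because real regional pools are not truncated at
  the borders of one territory; without this margin the warm end of the
  gradient would have artificially few species.
* **Surveys.** Poisson-cluster placement on forest cells (parents +
  Gaussian offspring), geometric year allocation (survey effort is uneven
  across years, as in real forest inventories), presence/absence by Bernoulli
  draws from niche suitability.
* **Planted debt.** Communities in a study year experience
  `T_eff = T_baseline + (1 − λ)·ΔT(year)`, so the true debt is
  `λ·ΔT(year)`. λ may be a constant or a function of baseline temperature.

## 3. Bioindication (transfer functions)

FrT is reconstructed with a hybrid model calibrated on baseline surveys:

1. **WA-PLS.** Weighted-averaging partial least squares on the
  presence/absence matrix. Component 1 is classical weighted averaging
  (species optima = occurrence-weighted response means; site scores =
  richness-weighted optimum means) with a linear deshrinking regression;
  further components are built by richness-weighted Gram–Schmidt
  orthogonalization of the score space.
2. **Residual learner.** A random forest on the same presence columns fits
  the WA-PLS residuals, capturing non-linear composition–climate structure.
3. **Classical recalibration.** Both stages estimate E[temperature |
  composition], which attenuates predictions toward the calibration mean by
  the unexplained-variance fraction. Applied to a warm-shifted study period
  this attenuation masquerades as debt. The final step therefore regresses
  **out-of-fold** (5-fold) hybrid predictions on the observed response and
  inverts that line at prediction time. Out-of-fold estimation matters: the
  forest overfits in-sample, so an in-sample slope would be ≈ 1 and the
  correction would vanish. Recalibration is skipped below 30 calibration
  surveys and refuses slopes < 0.2.

**Number of components.** `bioindicate` uses a fixed H = 3 rather than the
cross-validated minimum. Cross-validation scores interpolation error *inside*
the calibration climate window, while the debt application evaluates the model
on a distribution shifted toward the warm edge, where low-component weighted
averaging compresses reconstructions toward the calibration mean. The two
criteria are misaligned; fixed H = 3 keeps enough components to undo edge
compression. CV selection remains available (`n_components="cv"`).

**Applicability screen.** Species optima cannot be estimated outside the
calibration response range, so reconstructions are censored at the sampled
gradient ends. Each survey gets a `supported` flag — it must share at least
one species with the model *and* its observed climate must lie inside the
calibration response range. Debt averages and the regression stage use
supported surveys only; no-analogue surveys get FrT = NaN rather than an
error.

**Soil covariates.** pH and C:N are reconstructed with the same hybrid model
but *without* recalibration: soils are static across periods, so the soil
models are applied in-distribution and the recalibration would only amplify
prediction noise by 1/slope (enough to push C:N outside its physical range).
Nitrogen is taken as N = 1/C:N.

Temperature reconstruction skill is reported on a 30% held-out baseline
subset, and the baseline-period mean dT (which should be ≈ 0 at equilibrium)
is reported as a check.

## 4. Species-level metrics

* **Tolerances** TO_T / TO_W: range of baseline temperatures /
  precipitations over a species' occurrences.
* **Distribution conservatism (DC)** and **niche conservatism (NC)**:
  Schoener's D ratios D_obs/D_ref comparing a species' current occupancy
  histogram against the histogram expected if it had kept its former
  distribution (DC) or tracked its former thermal niche (NC). Ratios use
  histogram-matched subsampling: the reference sample is subsampled to match
  the observed sample size (strict matching when possible, best-effort
  otherwise), replicated and averaged, so D_obs and D_ref share sampling
  noise. Both need ≥ 3 occurrences per period, are clipped to [0, 1], and
  are undefined when the matching background cannot populate the reference
  niche.
* **Competition** C_W / C_N: community means of pairwise niche
  differentiation (1 − D) along the precipitation and bioindicated C:N
  gradients; a null model draws random communities from the 10-km regional
  pool with p = (r + 1)/(n + 1) randomization p-values.
* **Habitat**: past potential-habitat proximity (HP = 1/(distance +
  cell size)) and the change in habitat aggregation (dHA, from the
  shared-edge aggregation index AI = e/e_max).

## 5. Inference (weighted PLS)

Per bootstrap draw: greedy spatial thinning (default 10 km minimum distance,
random visiting order), observation weights 1/count(year) so each year
contributes equally, weighted standardization, weighted NIPALS PLS,
Bonferroni-corrected t-tests on component score slopes to retain components,
coefficients back-transformed to standardized units, and a variance partition
share_j = Σ_h Rd_h · w*²_jh that sums exactly to R². Effects are declared
significant when ≥ 99% of draws agree in sign. Variants PLS0–PLS4 refit on
survey subsets (all; late period; adding buffer covariates; managed;
unmanaged). Measurement error in bioindicated covariates can be propagated by
re-noising predictors across draws.

## 6. Diagnostics

Moran's I per distance class (default 0–150 km in 10-km classes), with
E[I] = −1/(n−1) under independence, permutation p-values, bootstrap
confidence bands, and a fixed |I| > 0.05 practical threshold; applied to raw
dT and to regression residuals.

## 7. Verification strategy

Every numerical component is tested against a hand-computable oracle or a
planted truth (see `tests/test_acceptance.py`):

* 1-component WA-PLS ≡ classical weighted averaging (10⁻⁸);
* full-component equal-weight PLS ≡ weighted OLS (10⁻⁸);
* variance shares sum to R² (10⁻⁸) across bootstrap draws;
* closed-form Schoener's D, DC/NC = 1 for conserved species, AI identities;
* planted debt λ·ΔT recovered within ±0.15 °C;
* planted standardized regression effects recovered within ±0.1 with correct
  sign calls;
* null model rejects at ≈ the nominal rate, Moran's I matches its
  independence expectation, thinning respects its minimum distance.

## 8. Limitations

* The generator plants debt through a community-wide lag factor; it does not
  model species-specific migration, demography, or dispersal limitation, so
  the recovered covariate effects on synthetic data reflect planted structure
  only.
* The applicability screen discards (rather than corrects) surveys outside
  the calibration climate range; in strongly warmed scenarios this loses the
  warmest surveys and can bias spatial coverage.
* Classical recalibration trades variance for bias: reconstruction RMSD
  rises by ≈ 1/slope while the distribution-shift bias falls. For weak
  calibrations (slope near the 0.2 floor) predictions become noisy; the
  slope floor is a guard, not a tuned constant.
* DC/NC depend on histogram bin width and on the matched-subsampling
  replicate count; defaults (1 °C bins, 100 replicates) follow the histogram
  scale of the synthetic gradient.
* Everything runs single-threaded by design (reproducibility over speed).
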