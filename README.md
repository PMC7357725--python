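# fertmeta

Meta-analysis of maize **fertilizer response (FR)** and **agronomic
nitrogen use efficiency (N-AE)** across smallholder on-farm trials in
sub-Saharan Africa, as a tested, reproducible pipeline.

On-farm fertilizer trials report a fertilized mean yield x̄_t and an
unfertilized control mean x̄_c per treatment–control pair, alongside soil
properties (pH, total C/N, extractable P, exchangeable cations, texture),
rainfall, altitude and management factors. Agronomists use such
collections to ask which soils respond to mineral N, which are
*non-responsive*, and which environmental factors drive the variation —
the evidence base for refining blanket fertilizer recommendations. This
package is for researchers who need that analysis chain end-to-end:
harmonization of heterogeneous literature data, missing-data imputation,
effect sizes, random-effects pooling, publication-bias diagnostics,
subgroup comparison and variable-importance ranking.

## The statistics at the core

* **Effect size** — log response ratio `ln FR = ln(x̄_t / x̄_c)` with
  delta-method sampling variance
  `v = sd_t²/(n_t·x̄_t²) + sd_c²/(n_c·x̄_c²)`.
* **Efficiency** — `N-AE = (x̄_t − x̄_c)/FN` in kg dry weight per kg
  applied N (descriptive; it has no sampling variance and is not pooled).
* **Responsiveness classes** — FR > 1 responsive; FR ≤ 1 split by control
  yield into *fertile* (> 1125 kg ha⁻¹) and *poor* non-responsive soils.
* **Random-effects model** — `y_i ~ N(μ, v_i + τ²)` with τ² estimated by
  REML; Cochran's Q_T with χ²(k−1) tests homogeneity.
* **Subgroups** — inverse-variance weighted mean `ln FR_w = Σw_i·lnFR_i /
  Σw_i`, `w_i = 1/v_i`, with normal 95% CIs; groups differ from no effect
  when the CI excludes ln FR = 0, and from each other when CIs are
  disjoint.
* **Publication bias** — weighted regression of effect on its standard
  error (funnel asymmetry z-test) and Duval–Tweedie trim-and-fill (L0
  estimator).
* **Drivers** — OLS on log-transformed, sd-standardized soil/climate
  predictors, ranked by PLS **VIP** scores (`Σ VIP² = p`; VIP > 1 marks
  important predictors), plus the power law `FR = a·(control yield)^b`
  fit on the log-log scale.

Because observation-level trial databases of this kind are rarely
published, the package ships a first-class synthetic generator
(`fertmeta.synthetic_data`) that emulates the schema and statistical
structure — study-level heterogeneity, covariate-linked effects,
sd/se/cv reporting styles, one extractable-P assay per study,
missingness, optional small-effect suppression — with a ground-truth
sidecar for parameter-recovery scoring.

## Worked example

```bash
$ fertmeta simulate --seed 7 --out trials.csv
wrote 487 observations to trials.csv
$ fertmeta run --input trials.csv --outdir bundle --seed 7
analyzed 487 observations; bundle in bundle
$ fertmeta report --outdir bundle
kenya: FR = 1.61 (ln FR 0.478 ± 0.032), tau2 = 0.221, Q_T = 4153.1 (df 228, p 0), k = 229
pooled: FR = 1.71 (ln FR 0.535 ± 0.024), tau2 = 0.246, Q_T = 9743.4 (df 486, p 0), k = 487
ssa_other: FR = 1.80 (ln FR 0.587 ± 0.034), tau2 = 0.267, Q_T = 5479.1 (df 257, p 0), k = 258
funnel regression test: z = 1.44, p = 0.15
trim-and-fill: k0 = 117 (left), adjusted mu = 0.316
power law [kenya]: FR = 68·yield^-0.50 (R² 0.36, p 7.73e-24)
power law [ssa_other]: FR = 89·yield^-0.55 (R² 0.33, p 2.02e-24)
```

Reading the output: fertilization raised yields by ~71% on average
(pooled FR 1.71); the enormous Q_T relative to its degrees of freedom
says the trials are strongly heterogeneous (τ² ≈ 0.25 on the log scale),
so moderators matter; the funnel regression test finds no significant
small-study asymmetry at α = 0.05; and the fitted power laws reproduce
the characteristic decline of FR with control-plot yield (exponent ≈
−0.5, the generator's configured coupling). The bundle directory
contains the underlying tables: `effects.csv`, `subgroups.csv`,
`glm_coefficients.csv`, `vip.csv`, `funnel.csv`, `pooled_fit.json`,
`bias.json`, `power_law.json`, `nae_descriptives.csv` and a
`manifest.json` with every setting and seed; re-running with the same
seed reproduces the bundle byte for byte.

The same pipeline runs on your own data: a CSV in the schema documented
in `src/fertmeta/schema.yaml` (one row per treatment–control pair,
comma-separated, `.` decimal, empty cell = missing), via
`fertmeta run --input your_trials.csv --outdir out`.

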