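# Methods

This note documents the statistical models, the defaults and why they
were chosen, the numerical choices, and what the synthetic-data tests do
and do not demonstrate about real trial databases.

## Data model and harmonization

One record is a treatment–control pair of maize plots: mean yields (kg
ha⁻¹), a dispersion statistic per arm (sd, se or CV), replicate counts,
the N application rate FN (kg N ha⁻¹), soil properties, rainfall per
growing season, altitude, and categorical factors (soil group, USDA
texture class, agro-ecological zone, nutrient combination, manager).
The CSV dialect is fixed — UTF-8, comma separator, `.` decimal, empty
string for missing — so fixture files are unambiguous across platforms.

Unit conversion is declarative: the current unit of a column is declared
(`df.attrs["units"]` or pipeline config) and `harmonize` applies the
matching multiplicative rule, then marks the column canonical, which
makes the operation idempotent. Two conversions are built-in constants
rather than configuration, because they are fixed published calibrations
between extractable-P assays: P-Olsen = 0.44·P-Bray-1 and
P-Olsen = 0.79·P-Bray-2. A converted value is always flagged and exactly
equal to factor × its retained source value. Measured P-Olsen always
beats a derived value; soil-group labels are free strings relabeled only
through a user-supplied mapping (literature databases mix WRB and legacy
taxonomy, and we preserve labels rather than guess corrections).

## Missing-data cascade

The order is fixed and each step narrows the work of the next:

1. **sd recovery**: reported sd wins; else sd = se·√n; else sd =
   CV·mean/100.
2. **1.5×-mean fallback**: remaining missing sds are set to 1.5 times
   the mean of all reported sds, both arms pooled. This is a
   deliberately conservative convention for variance-less studies, not
   an unbiased estimate; affected rows are flagged.
3. **Correlation-gated linear imputation**: soil-property pairs with
   Pearson r > 0.8 (pairwise-complete, ≥ 3 pairs) are collapsed. The
   gate applies to signed r by default — a `use_abs_r` switch admits
   strong negative pairs — pairs are taken greedily by descending |r|,
   each variable joins at most one pair, and within a pair the member
   with more missing values is dropped after an OLS line (fit on
   complete pairs) fills gaps in the kept member. Equal missing counts
   drop the variable later in the configured ordering, for determinism.
   Dropped variables are excluded from all later analysis.
4. **Predictive mean matching** (chained equations) fills the rest:
   regress the target on the other configured variables, draw the
   coefficients from their estimated sampling distribution, and give
   each missing case the observed value of one of the k nearest
   predicted-mean donors, chosen uniformly. Defaults k = 5 donors and
   10 iterations with a single completed dataset (m = 1) are the common
   PMM defaults; the analysis consumes one completed table, so multiple
   imputation with pooling is out of scope. PMM guarantees imputations
   stay inside the observed support and preserve marginal shape.

Re-running the cascade on its own output is a no-op, and every imputed
cell carries a `*_imputed` flag in the emitted tables.

## Effect sizes and responsiveness

ln FR = ln(x̄_t/x̄_c) is the unit of analysis; its delta-method variance
v = sd_t²/(n_t x̄_t²) + sd_c²/(n_c x̄_c²) is used as the known sampling
variance. N-AE = (x̄_t − x̄_c)/FN is computed only where FN > 0
(controls are not efficiency-scored) and may be negative. FR ≤ 1 —
boundary included — is non-responsive, subdivided at a control yield of
1125 kg ha⁻¹ (a benchmark for fertile smallholder plots in SSA;
configurable because other regions may warrant a different cut).

## Random-effects meta-analysis

The intercept-only model y_i ~ N(μ, v_i + τ²) treats every observation
as an independent record, accepting multiple entries per experiment;
this raises precision but understates standard errors where entries
share an experiment — a known limitation, stated rather than corrected.
τ² maximizes the restricted likelihood; since the model is
intercept-only the profile is one-dimensional and τ̂² is found by
bounded scalar search on [0, 10·var(y)] with tolerance 1e-8, the
boundary τ² = 0 checked explicitly. Q_T = Σw_i(y_i − ȳ_w)² with
w_i = 1/v_i is referred to χ²(k−1).

Subgroup means use fixed-effect weights 1/v_i exactly (a random-effects
weighting 1/(v_i + τ²) is available behind a switch), normal-quantile
95% CIs (z = 1.959964, no t-adjustment), and the CI decision rules:
a level differs from no effect iff its CI excludes 0; two levels differ
iff their CIs are disjoint. N-rate subgroups default to bin edges
0/30/60/90/120/150 kg N ha⁻¹.

The funnel-asymmetry test regresses y_i on √v_i with weights 1/v_i and
refers slope/se to the standard normal. Trim-and-fill uses the L0
estimator: with suppression assumed on one side (auto-detected from the
skewness of effects about the fixed-effect center; positive skew means
a long right tail, hence missing left), rank the absolute deviations,
compute L0 = (4T − n(n+1))/(2n−1) from the sum T of ranks of positive
deviations, trim the k0 most extreme effects, re-center, and iterate to
stabilization (cap 100 rounds); filled pseudo-records are mirror images
about the final center and the adjusted μ is the fixed-effect mean of
observed + filled.

## Regression and variable importance

Predictors with right-skewed marginals — total C, P-Olsen, N rate,
exchangeable K, silt, rainfall — are log-transformed; soil pH and clay
enter untransformed. (Sources conflict on logging pH; the fitted-model
record we follow leaves it raw, and `log_ph` flips it.) Columns are then
divided by their sample sd *without centering* so every factor has equal
representation; scale-only standardization leaves slope t-statistics and
p-values identical to the raw fit, so inference is unaffected while
coefficients become comparable. The N-AE model excludes the N rate,
which already sits in the response's denominator. No multiple-testing
correction is applied across coefficients; raw significance codes are
reported.

VIP scores come from a PLS decomposition of the same standardized (X, y):
VIP_j = √(p·Σ_a SS_a(w_aj/‖w_a‖)²/Σ_a SS_a) with SS_a the response
variance captured by component a. Σ_j VIP_j² = p identically, and
VIP > 1 is the conventional importance cut. The component count is
chosen by leave-one-out cross-validated squared prediction error, capped
at min(p, 10), since no principled fixed value exists for these designs.

The FR–control-yield relation is summarized by FR = a·(control yield)^b
fit as OLS of ln FR on ln yield (a multiplicative-error model consistent
with the log-scale analysis; nonlinear least squares on the original
scale would weight large yields differently and is not the default).

## Synthetic generator

The generator draws studies (region, P assay, variance-reporting style,
soil group), then observations with covariates anchored to published
on-farm maize trials in SSA: soil pH ≈ N(5.2, 0.7), total C log-normal
around 14 g kg⁻¹ with total N ≈ C/10 (giving the strongly correlated
pair the linear-imputation stage expects), P-Olsen log-normal around
6 mg kg⁻¹, Dirichlet texture, rainfall ≈ 850 mm per season, N rates
uniform on 15–150 kg N ha⁻¹, control yields log-normal around 1.6 t ha⁻¹
in Kenya and 1.1 t ha⁻¹ elsewhere. Within-plot sds are proportional to
means (CV log-normal around 15%), so the sd/se/CV recovery paths are all
exercised; replicate counts are 3–4.

True effects follow ln FR_i = μ + Σβ_j z_ij + b·(ln y_c,i − m) + u_study
with defaults μ = 0.56, coupling b = −0.5 (the power-law decline of FR
with control yield), and small moderator loadings on pH, log exch. K,
log P-Olsen and log rainfall. Two design choices matter:

* **τ² is the total heterogeneity.** The configured τ² is the marginal
  between-observation variance of true ln FR; the study effect receives
  τ² minus the systematic variance, and a configuration whose systematic
  part alone exceeds τ² raises as infeasible. Intercept-only REML
  therefore estimates the configured τ² directly.
* **Population-moment standardization.** Covariate loadings are
  standardized against reference moments from one large fixed-seed draw
  of the same covariate recipe, not per-dataset sample moments.
  Sample-moment centering would pin the systematic part's sample mean
  at exactly zero in every replicate, deleting its contribution to the
  variability of the pooled estimate and producing materially
  over-conservative CIs (~99% realized coverage for a nominal 95%);
  with population centering the recovery experiments attain nominal
  coverage.

Fertile non-responsive soils are a small mixture (5%) of
high-control-yield observations with near-zero response — the minimal
mechanism for the leveling of FR at high control yields — rather than a
separate latent class. Missingness (default ≈ 10–35% per soil variable,
MCAR; a MAR-on-region variant scales rates 0.6×/1.4× by region) and
optional publication bias are applied last; suppression probability is
`strength · Φ(−z_i)` with z_i the standardized observed effect, so small
and imprecise effects vanish first. A ground-truth sidecar records every
latent quantity.

**Recovery experiments** (`recovery_config`) disable the mixture,
missingness and bias, report sds directly, and use one observation per
study so records are independent: they isolate estimator performance
from the deliberately conservative 1.5× sd convention and from
within-study correlation, which the default conditions include. The
residual discrepancy they tolerate is Monte-Carlo error only. What
passing recovery does *not* show: robustness to the clustering of real
multi-treatment experiments (the pipeline deliberately ignores it, as
stated above), to informative missingness beyond MAR-on-region, or to
real soil covariance structures (covariates are drawn independently
apart from the C–N link; no spatial correlation, no weather series).

The publication-bias power simulation uses a small true effect
(μ = 0.15) with heterogeneity well below sampling variance
(τ² = 0.01, CV 0.25): selection acts on z = lnFR/se, so detectable
funnel asymmetry requires the suppression region to be populated and
the funnel to be sampling-error-dominated. Under the default μ = 0.56
almost every observation is individually significant, suppression
removes ~4% of records, and no asymmetry test has power — itself an
informative property of this design space.

## Numerical choices and degenerate inputs

REML: bounded Brent search, xatol 1e-8, explicit τ² = 0 comparison;
homogeneous inputs return exactly 0. Q_T with k = 1 returns df 0 and an
undefined p. Subgroup levels with zero records are an error; missing
levels are excluded and counted. The funnel regression refuses
all-equal standard errors (degenerate design). Trim-and-fill trims at
most k − 2 records. PMM requires ≥ k observed values per variable,
uses least-squares with a pseudo-inverse for near-collinear designs,
and is deterministic under a fixed seed. Standardization refuses
constant columns; log transforms refuse non-positive values (a drop
mode exists for pipeline use). Power-law fits refuse all-equal control
yields. Pipeline stages that lack enough rows (small regions, sparse
levels) are skipped and logged rather than failing the run.

## Problem sizes used in checks

The shipped test-suite and acceptance-script problem sizes — ~440–500
observations per synthetic database (mirroring the scale of extracted
literature databases of this kind), 60–200 recovery replicates, 500–1000
Monte-Carlo calibration draws — were chosen so each statistical check
has adequate power while the whole suite stays comfortably
interactive-scale on one CPU.
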