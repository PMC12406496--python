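# Methods

This note documents the statistical models implemented in `tbiharm`, the
parameter choices that matter, what the synthetic cohort generator does and
does not emulate, and the numerical conventions fixed by the package.

## Sham-referenced volumetry

Each scan is compared voxel-wise against a sham reference built from `n ≥ 2`
sham scans: `m̂` and `ŝ` are the per-voxel sample mean and SD (denominator
`n − 1`). Voxels with `ŝ < 10⁻⁶` (native units) are marked invalid rather
than clamped — a floor would fabricate extreme z values at near-constant
voxels (masked-edge voxels routinely have constant values and are simply
excluded). The subject statistic is `z = (x − m̂)/ŝ`; `Scalar_LOW` counts
voxels with `z < −z_c` strictly, `Scalar_HIGH` voxels with `z > +z_c`
strictly (a voxel exactly at the threshold is not counted; one convention
had to be fixed for exact tests). Volumes in mm³ are counts times the voxel
volume.

### Distribution-corrected thresholds

A nominal cutoff `z₀` (default 3.1) is stated on the standard normal scale,
with two-sided tail mass `p₀ = 2(1 − Φ(z₀)) ≈ 0.00194`. Because the
reference mean and SD come from a small sample, the achieved tail mass at
`±z₀` differs from `p₀`, in opposite directions for the two kinds of test
subject:

- **Out-of-group** (injured animal, not part of the reference):
  `x − m̂ ~ N(0, σ²(n+1)/n)` independent of `ŝ`, so `z` is `√((n+1)/n)`
  times a t variate with `n − 1` df. The corrected threshold is
  `z_c = t⁻¹(1 − p₀/2; n − 1) · √((n+1)/n)`, always above `z₀`
  (e.g. 5.11 at `n = 8`, 3.81 at `n = 17`), and it returns to `z₀` as
  `n → ∞`.
- **In-group** (sham animal, included in its own reference): the leave-in
  statistic `(x_i − m̂)/ŝ` is bounded by `(n−1)/√n` and its cutoff deflates
  below `z₀` (2.24 at `n = 8`, 2.70 at `n = 17`). The default calibration
  is Monte Carlo — simulate reference cohorts, take the `1 − p₀` quantile
  of the leave-in statistic — with an error gate (twice the quantile
  standard error, estimated from the local density) that raises rather
  than silently under-delivering precision. A closed form via the
  internally-studentized-residual identity
  `T = z√(n(n−2))/√((n−1)² − nz²) ~ t_{n−2}` is available both as a cheap
  alternative for large `n` and as an independent cross-check of the
  Monte-Carlo path.

A `p₀` convention had to be chosen: `z₀ = 3.1` is often glossed as
"p < 0.001", which is the one-sided mass; the two-sided convention is the
default here and the one-sided variant is selectable. An override-table
mode accepts externally supplied (injured, sham) threshold pairs keyed by
site/day for replication runs against published values.

### Detection rule and frequency maps

An injured subject is "detected" when its volume of pathology exceeds the
sham mean by `k` sham SDs (`k = 2` by default, exposed in the pipeline
config). Frequency maps count, per voxel, the subjects whose two-sided
normal p from the z-map survives `α` after per-subject Benjamini–Hochberg
correction across that subject's valid voxels; whether FDR should run
within subject or across subjects is ambiguous in general, and
within-subject was chosen (each animal's map is corrected as its own
family).

## Continuous harmonization (empirical-Bayes location/scale)

The model for feature `v`, sample `j` in batch (site) `i` is

    y_ijv = α_v + X_ij β_v + γ_iv + δ_iv ε_ijv,   ε ~ N(0, 1),

with covariates `X` (group and sex one-hot with first level dropped;
atrophy and day standardized internally and back-transformed in reports —
conditioning stability matters on small cohorts). Feature-wise least
squares with one indicator per batch gives batch intercepts; the grand
intercept is their sample-size-weighted mean, which enforces
`Σᵢ nᵢ γ̂_iv = 0` exactly. The pooled residual variance `σ̂²_v` uses
denominator `N` (total samples), and the per-batch scale estimates
`δ̂²_iv` use the matching population (denominator `nᵢ`) convention — one
convention had to be fixed for exact tests, and this pair makes the
single-batch case an exact identity.

With EB enabled (the default), priors `γ_iv ~ N(γ̄_i, τ̄²_i)` and
`δ²_iv ~ InverseGamma(λ_i, θ_i)` are estimated by method of moments across
features (`λ = (m̄² + 2s²)/s²`, `θ = (m̄s² + m̄³)/s²` with `m̄, s²` the mean
and variance of the `δ̂²`), and the two conditional posterior means are
iterated to convergence (max relative change `< 10⁻⁴`, cap 200
iterations). Harmonized values are
`y* = σ̂/δ* · (z − γ*) + α̂ + X β̂`. Zero- and near-zero-variance features
(SD `< 10⁻¹²`) pass through unchanged with a logged warning. There is no
reference-batch mode and no non-parametric EB. Only the ratio of batch
scale to pooled scale is identifiable, which is why the parameter-recovery
simulation (`simulate_location_scale`) draws true `γ` satisfying the
zero-sum constraint and normalizes true `δ²` to pooled variance 1 per
feature.

## Count harmonization (negative binomial)

Volumes of pathology are counts, and the location/scale model does not
respect integrality. Each feature is fitted by a log-link Poisson
regression on batch indicators plus covariates (the Poisson score equations
give consistent NB mean estimates); the per feature-batch dispersion `φ_gi`
(variance `μ + φμ²`) is then profiled by maximum likelihood at the fitted
means, with a method-of-moments fallback, and `φ = 0` (Poisson) is accepted
when ML runs to the boundary. The batch-free target keeps the covariate
structure but replaces the batch intercept with its weighted average and
pools dispersion as the sample-size-weighted mean of the `φ_gi`. No
empirical-Bayes shrinkage is applied to the count model.

Counts map through the mid-cumulative probability
`p = F(y − 1) + ½ f(y)` of the batch-specific distribution to the quantile
of the batch-free one. The midpoint rule is deterministic (no randomized
quantile residuals, so regression tests can be exact), monotone in `y` at
fixed parameters, free of the systematic inflation of mapping at `F(y)`,
and reduces to the exact identity when the two distributions coincide
(single batch). All-zero features are returned unchanged; features nonzero
in only one batch are adjusted by the model but flagged in the log. A
per-sample total-count offset is supported but off by default: pathology
volumes are not library-size data.

## Diagnostics

- **Outlier screen:** fraction of a site's values beyond
  `[Q1 − 1.5·IQR, Q3 + 1.5·IQR]` fences of the *other* sites' values,
  per voxel (default) or pooled; sites above 5% are flagged. Quartiles use
  linear interpolation (type 7) — fence values depend on the quartile rule,
  so it is fixed and recorded in the report. Under a Gaussian null the
  expected proportion is `2Φ(−2.698) ≈ 0.7%`.
- **Excess kurtosis:** fourth standardized moment minus 3,
  population-moment estimator by default (bias-corrected selectable).
- **Bland–Altman:** bias (mean paired difference, algebraically the
  difference of means) and limits of agreement `bias ± 1.96·SD(diff)`.
- **KS site tests:** two-sample Kolmogorov–Smirnov per unordered site pair
  with BH adjustment across pairs. Site samples are drawn as seeded random
  (scan, voxel) pairs — independent draws from each site's value
  distribution — because pooling whole lattices would correlate the
  samples through the shared anatomical baseline and miscalibrate the
  test. Note that with only a handful of subjects per site, subject-level
  random effects make site distributions genuinely differ under a "null"
  configuration; the calibration property holds when subject variance is
  absent, and rejections beyond nominal otherwise reflect real
  finite-subject variation.
- **Kruskal–Wallis:** tie-corrected H with the chi-square reference
  (`H = 0, p = 1` defined for all-identical values). The chi-square
  p-value approximates the exact permutation p at small n (e.g. 0.0087 vs
  2/252 = 0.0079 for {1..5} vs {6..10}); tests assert the H statistic
  exactly and the decision agreement, not fine p agreement.
- **Cohen's d** with the pooled-SD denominator; significance of d against
  0 by seeded bootstrap CI over subjects (a one-sample t on jackknife
  pseudo-values is the selectable literal alternative).
- **Variance heterogeneity** across sites by Fligner–Killeen — robust to
  the skewness of count-derived volumes, which is why it was chosen over
  Levene or Bartlett.

## Power maps

Voxel-wise power uses the noncentral-t form of the two-sided two-sample t
test: `ncp = d√(n₁n₂/(n₁+n₂))`, `df = n₁+n₂−2`,
`power = 1 − F_nct(t_crit) + F_nct(−t_crit)`. Power depends on |d| (signed
d is kept in the d-maps; the test is two-sided) and equals `α` at `d = 0`.
At extreme noncentrality where scipy's noncentral t loses accuracy the
normal approximation is substituted (power is 1 to numerical precision
there). Change maps are harmonized − original per voxel; power changes are
reported in percentage points on the ±100 scale, and across-site "pooled
average" maps are unweighted means of the per-site change maps.

## Synthetic cohort generator

The generator emulates the *statistical structure* of a four-site
preclinical TBI imaging study: per-site sham counts (17, 16, 14, 11) and
injured counts (33, 33, 35, 27), two imaging days (3 and 30), sex assigned
at random, and an atrophy covariate (mm³; ~N(40, 15²) truncated at 5 for
injured animals, near zero for shams) standing in for lesion severity. The
scalar field is a smooth ellipsoidal "brain" at ≈0.25 with a
high-anisotropy band reaching ≈0.6; site `i` observes
`b_i·(field + subject offset + lesion + noise) + a_i` with default offsets
(0, 0.04, −0.03, 0.06) and scales (1, 1.08, 0.94, 1.25) — moderate effects
of the order of within-tissue SD, enough to make every site pair differ
detectably before harmonization. Site effects are scan-wide scalars by
default with an optional smooth spatially varying field (the harmonization
model is per-feature, so both regimes are generatable). The lesion is a
Gaussian-tapered sphere on the configured hemisphere (left for sites 1–3,
right for site 4, with no automatic flipping) whose depth is
`slope × atrophy × day factor`; the day-30 factor is 0.95, reflecting a
chronic lesion of nearly the same burden as the acute one. Site 4 is by
default the outlier site: Student-t(3) noise (heavy tails, strongly
positive excess kurtosis) plus a reduced-coverage mask (ventral slices
zeroed), which drives its 1.5×IQR outlier proportion far above the 5% flag
threshold while clean sites stay below ~1%.

One root seed feeds independent substreams (covariates, subject effects,
scan noise, dropout), so enabling dropout or changing the lesion does not
shift unrelated draws; identical config and seed give bit-identical
output. The per-scan dropout probability (default 0, so scan counts are
exact at `2 × 186 = 372`) emulates missing datasets.

What the generator does **not** emulate: diffusion-tensor physics, k-space
acquisition, registration error, anatomically realistic lesion shapes or
tissue classes, spatial noise correlation, or longitudinal within-subject
trajectories beyond the day factor. Passing tests therefore demonstrate
that the *analysis machinery* behaves as specified under the assumed
statistical structure — batch effects removed, group effects and counts
preserved, thresholds and power calibrated — not that real multi-site data
meet those assumptions.

The count generator draws NB counts with per-feature lognormal base means,
known site multipliers and a group fold change, providing ground truth for
the count-harmonization recovery checks (`dispersion → 0` recovers
Poisson).

## Pipeline conventions

The orchestrated run makes the analysis order explicit: outlier screen
first (flagged sites excluded before any harmonization by default, and the
exclusion is configurable), then the sham reference at the configured
scope (pooled by default; site-specific selectable), corrected thresholds
from the reference sizes per day, volumetry before harmonization,
univariate count harmonization (the count engine is the univariate
default; the continuous engine is selectable for comparison) and/or
voxel-level continuous harmonization, volumetry after, diagnostics, and
voxel stat maps. α levels default to 0.05 for univariate statistics and
0.01 for voxel-level statistics. Every artifact is written with a SHA-256
checksum into a manifest; a failed stage leaves a `FAILED` marker naming
the stage.

## Problem sizes used in the shipped checks

The shipped tests and the acceptance script run at desk scale, chosen so
the full suite completes in well under a minute of compute per component:
the default cohort grid is 32×24×48 voxels (≈21k in-mask), EB recovery
uses 200 features × 2 batches × 20 samples, count recovery 500 features ×
100 samples, the threshold oracle 10⁷ Monte-Carlo draws, and the power
oracle 10⁵ simulated t tests per grid point. These sizes estimate the same
quantities as larger runs with comfortable margin relative to the asserted
tolerances.

## Known limitations

- New-sample `transform` standardizes continuous covariates with the new
  sample's own center/scale; for heavily unbalanced transfer data the
  covariate projection can shift slightly.
- The count engine fits one Poisson mean model per feature in a Python
  loop; it is sized for univariate volume tables (a few features), not
  for voxel-scale count matrices.
- Kurtosis of Student-t(3) noise has no finite population value; the
  generator's outlier site is characterized by its empirical kurtosis and
  outlier proportion, which are seed-dependent.
- No spatial smoothing or regularization is applied after harmonization,
  matching the analysis the pipeline reproduces; spatially correlated
  residual site effects would not be captured by the per-voxel model.
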