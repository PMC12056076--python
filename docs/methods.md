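# Methods

This note documents the statistical models in `dtiharm`, the choices made
where the design was genuinely open, and what the synthetic-data tests do
and do not establish about real data.

## Location-scale harmonization (ComBat family)

The observation model for site *i*, subject *j*, feature (ROI) *v* is

    y_ijv = f_v(X_ij) + gamma_iv + delta_iv * e_ijv,     e_ijv ~ N(0, sigma_v^2)

- **Covariate surface** `f_v`: in linear mode an intercept plus linear age
  and sex terms; in GAM mode a penalized cubic B-spline over age (10 basis
  functions, second-order difference penalty, smoothing weight by GCV per
  feature) plus a linear sex term. Extra numeric covariates (e.g.
  sex-normalized ICV) enter linearly in both modes.
- **Identifiability**: batch indicator columns are fitted jointly with the
  surface; the grand mean is the site-size-weighted average of the batch
  intercepts, so the site offsets satisfy `sum_i n_i * gamma_iv = 0`. In GAM
  mode the age smooth carries an mgcv-style sum-to-zero constraint so its
  level cannot trade off against batch intercepts; fitting the smooth and
  the batch dummies jointly prevents the smooth from absorbing site offsets
  when age ranges are confounded with site.
- **Standardization**: `sigma_v` is the pooled residual SD after removing
  the surface and the constrained batch offsets (1/n convention). Raw site
  effects are the per-site mean (`gamma_hat`) and population SD
  (`delta_hat`, ddof = 0) of the standardized residuals. The ddof = 0
  convention makes the moment identities exact: two identical batches give
  `delta_hat = 1` to machine precision, and non-EB adjustment equalizes
  per-site (population) residual moments exactly.
- **Empirical Bayes**: per site, a normal prior on location and an
  inverse-gamma prior on the squared scale, hyperparameters by method of
  moments across features, and iterated conditional posterior means
  (relative-change tolerance 1e-4, cap 100 iterations; non-convergence
  raises an error carrying the last iterate). Degenerate priors (zero
  between-feature variance) fall back to the raw estimates, as does a
  single-feature table. With EB disabled the raw estimates pass through
  unchanged.
- **Adjustment**: `y* = sigma_v * (Z - gamma*) / delta* + f_v(X)`.

What ComBat identifies is *relative*: site shifts centered by the
size-weighted mean and site scales normalized by the pooled residual SD.
Parameter-recovery tests therefore compare against these estimands, not the
raw generating values.

### CovBat

CovBat runs linear-mode ComBat, then a PCA of the pooled adjusted residuals
(population covariance; at most `min(n-1, V)` components). For the leading
K components — the smallest K whose cumulative explained variance reaches
`pct_var` — per-site score means and SDs are removed and the scores
rescaled to the pooled per-component SD, so total variance is conserved
rather than forced to unity; trailing components pass through, and the
covariate surface is re-added. The pooled-SD rescaling follows the behavior
of the reference implementation of the method; the bare score-standardizing
formula alone leaves the output scale ambiguous. All score moments use
ddof = 0 so that sites with identical residual structure are a no-op.

## Penalized splines and quantile curves

One basis serves the ComBat-GAM surface, the mean curve, the SD curve, and
the centile curves: cubic B-splines, 10 basis functions on equally spaced
knots over the age span, second-order difference penalty. The smoothing
weight minimizes GCV on a 25-point log grid (1e-6 to 1e6); among weights
whose GCV is within 0.1% of the minimum the largest is taken, which
stabilizes near-flat signals (GCV is flat to O(edf/n) there) without
affecting genuinely curved fits. Evaluation outside the fitted span clamps
to the endpoints — spline extrapolation is not trusted anywhere in the
package.

Centile curves minimize a smoothed pinball loss
`rho_eps(r) = (tau - 1) r + eps log(1 + exp(r / eps))` with
`eps = 0.02 x` a robust residual scale, optimized by L-BFGS with an
analytic gradient and warm-started at the mean fit. The pinball data term
has per-observation curvature roughly equal to the residual density at the
target quantile (versus 1 for least squares), so the LS-chosen smoothing
weight is rescaled by the mean local curvature to give the quantile fit a
comparable effective degrees of freedom. Centiles are fitted independently
per tau and sorted pointwise across tau; the number of reordered grid
points is recorded, and a warning is emitted when sorting was needed.

Known approximation limits: with 10 basis functions over ages 3-95 the
steep developmental limb (ages 3-10) carries ~2-3e-3 FA of representation
bias in any fit, and the linear null-space component of the penalty leaves
~3e-4 of slope noise at the range boundaries at n = 20,000. Coverage of the
fitted centiles is nevertheless calibrated to within +/-0.005 at tau = 0.5
and 0.9 (checked at n = 20,000).

## Reference building by iterative subsampling

Sample-size weighting would let one very large cohort dominate a pooled
ComBat fit. The builder therefore harmonizes 25 subsamples of up to 200
subjects per dataset (defaults; both configurable): datasets with
`n >= iterations x per_iteration_n` are partitioned into disjoint blocks
(every row used exactly once), smaller datasets are re-drawn each iteration
without replacement within the iteration. Each subsample is harmonized with
ComBat-GAM (the smooth is refit per iteration), outputs are pooled with
iteration labels, and subjects appearing in several iterations are *not*
deduplicated before curve fitting — the pooled outputs are what the curves
summarize. Per (ROI, sex) the builder stores a mean curve, an SD curve
(square root of a GCV smooth of squared residuals, floored at 1e-4), and
the centile curves, on a 0.1-year grid. The default centile grid is tau =
0.01, ..., 0.99; coarser grids are accepted wherever speed matters.

The bundle is versioned (semantic version string required), carries its
creation time, contributing dataset names, covariate spec and quantile
grid, and is validated on construction and on read: strictly increasing
grids, positive SD curves, non-crossing centiles, and the median centile
within 3 reference SDs of the mean curve.

## Harmonizing a new site to a reference

Controls are standardized per subject against the bundle,
`Z_jv = (y_jv - mu_ref,v(age_j, sex_j)) / sigma_ref,v(age_j, sex_j)`; the
site's per-ROI shift and scale on Z are shrunk by the same EB machinery
(the site is a single batch pooling across ROIs; disable-able); all rows —
cases included — are transformed back. Case rows never influence the fit
(verified exactly), and applying a stored model is a pure function of
(model, bundle, age, sex, value), so re-application is bit-identical.

`sigma_ref` is age- and sex-dependent by default because residual spread
varies over the lifespan. A `constant_reference_sd` flag replaces it with
its per-ROI mean: with a homoskedastic site this makes the transform affine
in y, which is the regime in which harmonization provably preserves
association statistics (used by the longitudinal strategy comparison).
Ages outside the bundle span are clamped with a logged count. The
statistical QC rule removes a subject entirely if any ROI lies more than
k = 5 sample SDs (ddof = 1) from its own site's per-ROI mean, computed on
raw values including the candidate outlier.

## Evaluation statistics

- **Peak age**: argmax of a curve on its 0.1-year grid, ties toward the
  younger age, reported both raw and rounded to integer years; a trajectory
  counts as concave-down only when the argmax is more than 1 year interior
  to both endpoints. An optional LOESS re-smoothing (span 0.1) behind the
  same interface serves as a robustness check on spline-driven peaks.
- **Fréchet distance**: discrete, by the standard dynamic-programming
  coupling recursion, on polylines whose age axis is min-max normalized to
  [0, 1] with FA values raw. This parameterization is recorded here because
  distances are comparable only within one convention.
- **Sex effects**: per ROI, OLS of z-scored FA on z-scored sex plus an
  unpenalized 10-function spline age basis (sum-to-zero constrained);
  "standardized beta" throughout means both outcome and predictor are
  z-scored. Age-by-sex interactions are F-tests of spline x sex columns.
  BH-FDR across ROIs.
- **Group effects** (e.g. allele count): per ROI OLS with age, sex,
  age x sex, age^2 covariates; interaction models only for nominally
  significant ROIs (p < 0.05).
- **Longitudinal comparison**: per strategy (raw / apply-baseline-params /
  fit-separately), per-ROI linear mixed models with a random intercept per
  subject (no random slope) and fixed effects age, sex, age x sex, age^2;
  the summary is the Pearson correlation across ROIs between each
  strategy's standardized age betas and the raw-data betas.
- **Acquisition correlations**: Pearson r of per-site shift and scale
  parameters against site-level acquisition values (e.g. voxel volume)
  across at least 4 sites.
- **Train-vs-test MAE**: per-subject |harmonized - mu_ref|, averaged to
  site-level MAEs per ROI; Welch t-tests train vs test per ROI, BH-FDR.
- The silver-standard peak table is configuration; the shipped placeholder
  (12 regions, all at 30 y, the midpoint of the expected 20-40 window) is
  synthetic and only supports range checks — substitute a published table
  for real benchmarking.

## Synthetic data generator

Lifespan trajectories use the unimodal gamma-shaped form
`f(age) = c0 + c1 (age/p)^k exp(k (1 - age/p))`, which peaks exactly at age
p with value c0 + c1 and declines gently thereafter — matching the
developmental rise, young-adult peak (defaults drawn in 22-38 y), and slow
senescent decline of white-matter FA. Defaults: 25 ROIs named after the
combined skeleton measures, per-ROI additive sex offsets (~0.005 FA),
residual SD 0.02 FA, ages uniform on 3-95, 48% male. Site effects default
to `y = delta (f + eps) + gamma` (scale on signal plus noise); the
`site_effect_on="residual"` option applies delta to the noise only, which
is exactly ComBat's decomposition and is what parameter-recovery tests use.
Longitudinal mode adds persistent subject random intercepts, fixed
inter-wave intervals (default 2.25 y), and a `slope_factor` that makes
within-subject change steeper than the cross-sectional curve — the regime
in which refitting harmonization per wave absorbs true change.

The generator produces Gaussian, uniformly age-sampled, missing-data-free
tables. Passing tests therefore demonstrate correctness of the estimators
under their own assumptions (and calibrated inference under Gaussian
noise); they do not establish robustness to skewed FA distributions,
age-density gaps, scanner drift within site, or non-multiplicative site
artifacts in real cohorts.

## Problem sizes used in checks

Recovery and calibration checks run at sizes chosen to make their
tolerances statistically meaningful on a single CPU: 100 replicates of
5 sites x 300 subjects for EB recovery; 20,000 subjects for centile
coverage; a 6,000-subject bundle behind site-recovery (n = 200) and
longitudinal (n = 500, two waves) checks; 200 replicates of 25 ROIs x 200
subjects for null-inference calibration. The longitudinal check uses a
variance split matching good FA test-retest reliability (subject SD 0.018,
residual SD 0.008, ICC ~ 0.84).

## Known limitations

- Nonparametric EB, longitudinal/random-effect ComBat variants, nested or
  Gaussian-mixture ComBat, and GAM-LSS (four-moment) centiles are out of
  scope.
- Centile fits share one smoothing weight (curvature-rescaled from the mean
  fit) per (ROI, sex) rather than per-tau selection.
- The bundle JSON schema is self-consistent but not guaranteed
  byte-compatible with any other tool's format.
- Harmonization nudges adjusted FA values slightly outside [0, 1] in
  extreme tails; values are left untruncated by design.
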