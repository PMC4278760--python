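# Methods

## The model

Each voxel's time series is modeled by the mass-univariate GLM
`y = Xβ + ε` with `X` a T×p design whose task columns are boxcar functions
convolved with a canonical double-gamma HRF (peak 6 s, undershoot 16 s,
undershoot amplitude 1/6 of the peak), sampled at the TR, plus nuisance
columns. The HRF kernel is normalised to unit sum so that a sustained
block's regressor plateaus at 1 and effect sizes read directly as plateau
percent-signal-change amplitudes.

Three contrast-variance estimators are implemented:

* **OLS** (`OLSGLM`): `Var(cᵀβ̂) = σ̂² cᵀ(XᵀX)⁻¹c`, dof T−p. Under
  autocorrelated noise with a low-frequency task regressor this
  underestimates the variance (measured 95% CI coverage ≈ 0.82 under AR(1)
  φ = 0.4); it is the baseline, not the default.
* **AR-prewhitened GLS** (`ARWhitenedGLM`): an AR(p) model (default p = 1)
  fitted to the OLS residuals by Yule–Walker, data and design conditionally
  whitened (first p samples dropped), then refit. A non-stationary AR fit
  is an error that points the user to the sandwich estimator. dof T−p−p_ar.
* **Replication-block sandwich** (`SandwichGLM`, the default): the run is
  cut into `q = ⌊√T⌋` blocks of length `⌊T/q⌋` (trailing remainder dropped
  from the end); coefficients solve the pooled normal equations
  `β̂ = B⁻¹ Σᵢ Xᵢᵀyᵢ`, `B = Σᵢ XᵢᵀXᵢ`, which is identical to fitting the
  across-block mean time course when all block designs agree and remains
  unbiased when sub-run blocks cut the task cycle (block designs need not
  be equal). The contrast variance is
  `cᵀB⁻¹(Σᵢ XᵢᵀΣ̂Xᵢ)B⁻¹c` with `Σ̂ = (q−1)⁻¹ Σₖ rₖrₖᵀ` built from block
  residuals, and the cross-voxel covariance replaces `Σ̂` by the
  cross-voxel residual covariance. Implementation note: writing
  `aᵢ = XᵢB⁻¹c`, variance and covariance reduce to sums of products of the
  scalar scores `aᵢᵀrₖ/√(q−1)`; one score matrix per contrast is retained
  per voxel, so whole-brain covariances against the comparison voxel are a
  single matrix product and every 2×2 voxel-pair covariance matrix is
  positive semi-definite by construction.

Choices where the design was genuinely open:

* `Σ̂` is normalised by q−1 (near-unbiasedness; Monte-Carlo check: the mean
  estimated variance matches the empirical variance of the estimates to
  within 1%, with a small ≈1% downward finite-sample bias from using fitted
  residuals).
* Sandwich degrees of freedom are q−1 (the replications are the effective
  sample); this is configurable (`dof=` parameter), since T−p is also
  arguable. All t→z conversions use the probability integral transform
  through the exact t CDF, evaluated on the matching tail for numerical
  stability; with q−1 ≈ 13 dof the transform compresses large t values
  noticeably (t = 8.5 → z ≈ 4.6), which matters when reasoning about
  thresholds.
* Voxels whose contrast variance is zero relative to machine precision
  (constant or noise-free series) are excluded from the analysis mask
  rather than yielding infinite t.

## Thresholding

Supra-threshold voxels (one-sided, positive z) are grouped by face
connectivity (4-connectivity in 2-D, 6 in 3-D; diagonal connectivity is an
option). Cluster-level p-values come from either

* **GRF**: the expected-cluster-count approximation for a smooth Gaussian
  field (Euler-characteristic density, Poisson clumping, exponential
  cluster-size tail), using per-axis FWHM estimated from standardized
  residual fields via the variance of spatial first differences
  (`FWHM = √(4 ln 2/λ̂)`, floored at 1 voxel); or
* **simulation** (`method="permutation"`, the default): a max-cluster-size
  null distribution from smooth Gaussian fields generated at the estimated
  smoothness (the smoothing kernel is chosen so the simulated fields'
  *estimated* FWHM matches the target, keeping generator and estimator
  consistent), with the standard (1+b)/(1+B) p-value. This is preferred for
  small 2-D maps where GRF asymptotics are dubious.

Measured family-wise error over 500 null smooth fields at α = 0.05: ≈ 4–5%.

## The in-limbo step

The comparison voxel is the significant voxel with minimal z (ties broken
by lexicographic index, with a warning). An alternative
`selection_rule="cluster_mean"` benchmarks against the mean contrast of the
least-significant cluster — pooled through the block scores, so its
variance is exact — but the least-significant-voxel rule is the default
because the resulting guarantee is the strongest: every "less" voxel is
significantly below *all* significant voxels.

Single-subject: one-sided t on the contrast difference with the pooled
variance `Var_r + Var_j − 2 Cov`, dof q−1. A pooled variance of exactly
zero (voxel identical to the comparison voxel) is a hard error, not NaN.
Group: per-subject differences (comparison minus voxel, so positive t means
"less activated") fitted by intercept-only WLS with weights 1/sd; the
residual scale uses n−1 dof; an all-zero difference vector yields t = 0 by
convention, a zero residual scale with a non-zero estimate is an error.
No multiple-comparisons correction is applied to the in-limbo p-values by
default — this labels the *minimum* number of voxels in limbo;
`correction="fdr"` (Benjamini–Hochberg) is available and can only enlarge
the in-limbo set. Group analyses re-select the comparison voxel at every
threshold; a threshold sweep therefore need not produce monotone in-limbo
volumes, since a different comparison voxel changes every test's covariance
term.

## The synthetic-data generator

`simulate` emulates a square 2-D brain (64×64, stored as single-slice 3-D
NIfTI) with two disc regions (radius 6): A at 3% and B at 1.5% signal
change over a baseline of 100, responding to 10 cycles of 20 s on / 20 s
off at TR 2 s (T = 200). Noise is stationary AR(1) (marginal SD `sigma`,
lag-1 coefficient 0.3, exact stationary initialization), optionally
spatially smoothed with the marginal SD preserved. Multi-subject mode
jitters each region's center (SD 2 voxels), radius (SD 0.5) and amplitude
(SD 0.5%) per subject, producing rings of partial overlap around the
group core; regions are re-drawn (up to 100 times) if jitter makes them
overlap. Randomness uses one root seed with per-subject, per-purpose
`SeedSequence` substreams (`spawn_key=(subject, purpose)`), so datasets are
byte-reproducible from (spec, seed) and adding subjects never perturbs
existing ones.

The noise default `sigma = 2.0` was set by a power calculation against the
regime the two-region scenario is meant to illustrate: at the demonstration
threshold z = 3.7 the strong region must sit well above threshold
(single-subject sandwich t ≈ 8.5 at sigma 2.0), the weak region mostly
below it (t ≈ 4.3), and the weak region must remain statistically
indistinguishable from the least-significant activated voxel. A much
smaller sigma makes the weak region genuinely separable (it then *is*
significantly less activated and the inconclusive state vanishes); a much
larger one destroys the strong region's detectability. The demonstration
threshold itself is stringent because the background "less" test compares
against a comparison voxel sitting at the primary threshold: its t is
roughly `t(z_thr)/√2`, which clears the one-sided dof-13 critical value
comfortably only for z_thr ≳ 3.5. The regime is intentionally tight — with
13 dof the t→z compression leaves only a narrow window in which the weak
region is simultaneously sub-threshold and within testing distance of the
comparison voxel, so a modest fraction of datasets will land on either
side (weak region partially significant, or partially rejected as less).
That variability is a property of the study conditions, not a failure of
the method.

What the generator does *not* emulate: physiological noise, motion, field
inhomogeneity, spatial heterogeneity of the HRF, non-Gaussian noise, and
realistic 3-D anatomy. Passing recovery tests therefore demonstrate the
statistical machinery under the stated noise model, not performance on real
scanner data.

## Numerical and interface choices

* Voxel indexing is 0-based array order; flattening over a mask is C-order;
  all NIfTI outputs carry the input affine unchanged; volumes are reported
  in cm³ from the affine's voxel dimensions.
* Events/designs are plain TSV; configurations and run summaries are JSON;
  a resolved-config sidecar is written next to every run's outputs.
* Exit codes of the CLI: 0 success, 2 "no significant voxels" (a defined
  outcome: without activated areas nothing can be in limbo), 1 otherwise.
* Known limitations: the group pipeline assumes subjects share a grid and
  analysis mask (voxels missing in any subject are background); GRF
  p-values ignore lower-order Euler-characteristic terms; the simulation
  null for cluster inference assumes stationary smoothness.
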