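# inlimbo

Three-class statistical parametric mapping for task fMRI: every voxel is
labeled **activated**, **significantly less activated**, or **in limbo**.

## Why

Conventional fMRI analysis thresholds a statistical map and splits the brain
into voxels that do or do not differ significantly across conditions. That
binary split invites a fallacy: "region A is significant and region B is not,
so A is selectively involved." The claim requires a *direct* test of A − B,
which standard pipelines never run. Region B may simply be noisier, or the
study underpowered.

`inlimbo` runs that missing test for the whole brain. After ordinary
cluster-based thresholding, it selects the **comparison voxel** — the
significantly activated voxel with the lowest surviving test statistic — and
tests every non-significant voxel's contrast against it. Voxels whose
contrast is significantly smaller are *less activated*; voxels that differ
neither from baseline nor from the comparison voxel are **in limbo**: the
measurement is inconclusive and no claim of selective activation is licensed.

## The statistics

For each voxel *j* the run is divided into `q = ⌊√T⌋` equal-length
replication blocks with designs `X_i` and data `y_i`. With bread
`B = Σ_i X_iᵀX_i` the GLM coefficients solve the pooled normal equations
`β̂_j = B⁻¹ Σ_i X_iᵀ y_i`, and for a contrast `c` the variance is the
replication-block sandwich

```
Var(cᵀβ̂_j) = cᵀ B⁻¹ (Σ_i X_iᵀ Σ̂_j X_i) B⁻¹ c ,    Σ̂_j = (q−1)⁻¹ Σ_k r_kj r_kjᵀ ,
```

with `r_kj` the residuals of block *k*. The same construction with
`Σ̂_jk = (q−1)⁻¹ Σ r_kj r_klᵀ` gives the cross-voxel covariance
`Cov(cᵀβ̂_j, cᵀβ̂_k)`, robust to both autocorrelation and HRF
misspecification — no AR model of the noise is required. The in-limbo test
against comparison voxel *r* is then the one-sided

```
t = (cᵀβ̂_r − cᵀβ̂_j) / √(Var_r + Var_j − 2·Cov_rj) ,   dof = q − 1 .
```

At the group level the per-subject differences `d_i = cᵀβ̂_r,i − cᵀβ̂_j,i`
are combined by weighted least squares on an intercept-only design with
weights `1/sd_i` from each subject's sandwich variance/covariance
(one-sided t with n − 1 dof). Cluster-level inference on the primary z map
uses either a Gaussian-random-field expected-cluster-count approximation or
a simulated max-cluster-size null matched to the map's estimated smoothness
(the default for small 2-D maps).

OLS and AR-prewhitened GLS fits are included as baselines; under
autocorrelated noise their confidence intervals under-cover, which is the
motivation for the sandwich estimator.

## Worked example

Generate a synthetic subject — a 64×64 "brain" with a strong region A (3%
signal change) and a weak region B (1.5%) responding to a blocked task, with
AR(1) noise — and run the full pipeline at a stringent primary threshold:

```bash
inlimbo simulate --out demo --seed 0
inlimbo run --bold demo/sub-00_bold.nii.gz --mask demo/mask.nii.gz \
            --design demo/design.tsv --out demo_out \
            --z-threshold 3.7 --seed 0
```

prints

```
{"background": 0, "less": 3874, "in_limbo": 95, "activated": 127}
```

and `demo_out/summary.json` records the comparison voxel and volumes:

```json
"comparison_voxel": [42, 41, 0],
"comparison_z": 3.706,
"counts": {"background": 0, "less": 3874, "in_limbo": 95, "activated": 127}
```

Reading: 127 voxels survive cluster thresholding (region A in full, plus a
handful of region-B voxels that crossed z = 3.7). The comparison voxel is
the weakest of these (z ≈ 3.71, barely above threshold). 95 voxels — almost
all of region B — are *in limbo*: not significant, but also not
significantly less activated than the comparison voxel, so concluding "A is
active and B is not" would be unwarranted. The remaining 3874 voxels are
significantly less activated than every significant voxel.

Other entry points: `inlimbo run-group` (multi-subject WLS analysis),
`inlimbo sweep` (volumes across several z thresholds, re-selecting the
comparison voxel at each), and the Python API (`inlimbo.analyze_subject`,
`inlimbo.analyze_group`, `inlimbo.SandwichGLM`, ...).

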