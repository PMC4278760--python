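"""Mass-univariate GLM fitting with robust replication-block variances.

Three estimators are provided, all operating on a T x V data matrix (V
voxels) and a shared design:

``OLSGLM``
    Ordinary least squares with the classical residual variance.  Its
    contrast variances are anti-conservative under temporally
    autocorrelated noise; it is included as the naive baseline.
``ARWhitenedGLM``
    Prewhitening baseline: an AR(order) model is fitted to the OLS
    residuals of each voxel and the data and design are conditionally
    whitened before refitting.
``SandwichGLM``
    The estimator of interest.  The run is divided into q equal-length
    replication blocks; coefficients come from the mean time course across
    blocks and the contrast variance from the sandwich (bread-meat-bread)
    formula with the meat built from the empirical block-residual
    covariance.  Cross-voxel covariances of contrast estimates come from
    the same construction with the cross-voxel residual covariance, which
    is what the in-limbo test downstream needs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator

from .design import DesignMatrix, ReplicationBlocks, make_blocks

__all__ = [
    "ContrastSpec",
    "GLMFit",
    "OLSGLM",
    "ARWhitenedGLM",
    "SandwichGLM",
    "fit_ols",
    "fit_gls_ar",
    "fit_sandwich",
    "sandwich_covariance",
    "t_to_z",
    "contrast_zmap",
]


@dataclass(frozen=True)
class ContrastSpec:
    """A length-p contrast weight vector c, testing c'beta > 0."""

    weights: np.ndarray

    def __post_init__(self) -> None:
        w = np.atleast_1d(np.asarray(self.weights, dtype=float))
        object.__setattr__(self, "weights", w)
        if w.ndim != 1:
            raise ValueError("contrast weights must be a vector")
        if not np.any(w != 0):
            raise ValueError("contrast weights must not all be zero")


def _as_contrast(contrast: ContrastSpec | np.ndarray) -> np.ndarray:
    if isinstance(contrast, ContrastSpec):
        return contrast.weights
    return ContrastSpec(np.asarray(contrast)).weights


@dataclass
class GLMFit:
    """Per-voxel contrast estimates with their variance estimator.

    ``block_scores`` (sandwich only) holds the q x V matrix of per-block
    residual projections a'r_i for the fitted contrast; variances are
    sums of squared scores and cross-voxel covariances are score
    cross-products, so everything the in-limbo test needs is retained in
    O(qV) memory.
    """

    beta: np.ndarray            # V x p
    contrast: np.ndarray        # V
    variance: np.ndarray        # V
    dof: float
    estimator: str              # {"ols", "gls_ar", "sandwich"}
    contrast_weights: np.ndarray
    residual_blocks: np.ndarray | None = None  # q x L x V
    block_scores: np.ndarray | None = None     # q x V

    @property
    def n_voxels(self) -> int:
        return self.contrast.shape[0]

    def t_values(self) -> np.ndarray:
        t = np.full(self.n_voxels, np.nan)
        ok = self.variance > 0
        t[ok] = self.contrast[ok] / np.sqrt(self.variance[ok])
        return t


def _check_xy(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, bool]:
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    single = y.ndim == 1
    if single:
        y = y[:, None]
    if y.shape[0] != X.shape[0]:
        raise ValueError("data and design must have the same number of time points")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix X'X is singular (rank-deficient design)")
    return X, y, single


class OLSGLM(BaseEstimator):
    """Ordinary least squares GLM, fitted jointly over all voxels.

    After ``fit(X, y)``: ``coef_`` (V x p), ``sigma2_`` (V), ``dof_``.
    """

    def fit(self, X: np.ndarray, y: np.ndarray) -> "OLSGLM":
        X, y, self._single = _check_xy(X, y)
        T, p = X.shape
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        self.coef_ = beta.T
        self.residuals_ = resid
        self.dof_ = T - p
        self.sigma2_ = (resid**2).sum(axis=0) / self.dof_
        self.xtx_inv_ = np.linalg.inv(X.T @ X)
        self.design_ = X
        return self

    def contrast_estimate(self, contrast) -> tuple[np.ndarray, np.ndarray]:
        c = _as_contrast(contrast)
        est = self.coef_ @ c
        var = self.sigma2_ * float(c @ self.xtx_inv_ @ c)
        return est, var

    def to_fit(self, contrast) -> GLMFit:
        c = _as_contrast(contrast)
        est, var = self.contrast_estimate(c)
        return GLMFit(
            beta=self.coef_, contrast=est, variance=var, dof=self.dof_,
            estimator="ols", contrast_weights=c,
        )


def _yule_walker(resid: np.ndarray, order: int) -> np.ndarray:
    """Vectorized Yule-Walker AR coefficient estimates, one voxel per column.

    Returns an (order, V) array of AR coefficients.
    """
    T, V = resid.shape
    r = resid - resid.mean(axis=0)
    denom = (r**2).sum(axis=0)
    acov = np.empty((order + 1, V))
    acov[0] = denom / T
    for k in range(1, order + 1):
        acov[k] = (r[k:] * r[:-k]).sum(axis=0) / T
    if order == 1:
        with np.errstate(invalid="ignore", divide="ignore"):
            phi = acov[1] / acov[0]
        return phi[None, :]
    # batch Toeplitz solve
    idx = np.abs(np.subtract.outer(np.arange(order), np.arange(order)))
    R = acov[idx].transpose(2, 0, 1)          # V x order x order
    rhs = acov[1:].T[:, :, None]              # V x order x 1
    phi = np.linalg.solve(R, rhs)[:, :, 0].T  # order x V
    return phi


def _ar_stationary(phi: np.ndarray) -> np.ndarray:
    """Boolean per voxel: are the fitted AR coefficients stationary?"""
    order, V = phi.shape
    if order == 1:
        return np.abs(phi[0]) < 1.0
    ok = np.empty(V, dtype=bool)
    for v in range(V):
        roots = np.roots(np.concatenate(([1.0], -phi[:, v])))
        ok[v] = np.all(np.abs(roots) < 1.0)
    return ok


class ARWhitenedGLM(BaseEstimator):
    """GLS via AR(order) prewhitening of OLS residuals.

    The first ``order`` observations are dropped (conditional whitening).
    Non-stationary AR fits raise, with a pointer to the sandwich
    estimator, which does not require an autocorrelation model.
    """

    def __init__(self, order: int = 1):
        self.order = order

    def fit(self, X: np.ndarray, y: np.ndarray) -> "ARWhitenedGLM":
        if self.order < 1:
            raise ValueError("AR order must be >= 1")
        X, y, self._single = _check_xy(X, y)
        T, p = X.shape
        V = y.shape[1]
        ols = OLSGLM().fit(X, y)
        phi = _yule_walker(ols.residuals_, self.order)
        ok = _ar_stationary(phi)
        if not np.all(ok):
            raise ValueError(
                f"non-stationary AR({self.order}) fit in {int((~ok).sum())} voxel(s); "
                "consider the sandwich estimator, which needs no autocorrelation model"
            )
        self.ar_coefficients_ = phi
        d = self.order
        yw = y[d:].copy()
        Xw = np.broadcast_to(X[d:], (V, T - d, p)).copy()
        for k in range(1, d + 1):
            yw -= phi[k - 1] * y[d - k : T - k]
            Xw -= phi[k - 1][:, None, None] * X[d - k : T - k]
        # per-voxel normal equations (design differs per voxel after whitening)
        xtx = np.einsum("vtp,vtq->vpq", Xw, Xw)
        xty = np.einsum("vtp,tv->vp", Xw, yw)
        beta = np.linalg.solve(xtx, xty[:, :, None])[:, :, 0]  # V x p
        resid = yw - np.einsum("vtp,vp->tv", Xw, beta)
        self.coef_ = beta
        self.dof_ = (T - d) - p
        self.sigma2_ = (resid**2).sum(axis=0) / self.dof_
        self.xtx_inv_ = np.linalg.inv(xtx)
        return self

    def contrast_estimate(self, contrast) -> tuple[np.ndarray, np.ndarray]:
        c = _as_contrast(contrast)
        est = self.coef_ @ c
        var = self.sigma2_ * np.einsum("p,vpq,q->v", c, self.xtx_inv_, c)
        return est, var

    def to_fit(self, contrast) -> GLMFit:
        c = _as_contrast(contrast)
        est, var = self.contrast_estimate(c)
        return GLMFit(
            beta=self.coef_, contrast=est, variance=var, dof=self.dof_,
            estimator="gls_ar", contrast_weights=c,
        )


class SandwichGLM(BaseEstimator):
    """Replication-block sandwich GLM.

    Parameters
    ----------
    q
        Number of replication blocks; defaults to floor(sqrt(T)).
    dof
        Degrees of freedom used for t tests and z conversion; defaults to
        q - 1 (the replications are the effective sample).

    Notes
    -----
    With block designs X_i (length L each) and bread B = sum_i X_i'X_i,
    the coefficients solve the pooled normal equations

        b = B^-1 sum_i X_i' y_i,

    which for identical block designs is exactly the OLS fit of the
    across-block mean time course (and stays unbiased when sub-run block
    designs differ, where the literal mean-course fit does not).  Block
    residuals r_i = y_i - X_i b give the residual covariance estimate
    Sigma = sum_k r_k r_k' / (q-1) and the sandwich variance

        Var(c'b) = c' B^-1 (sum_i X_i' Sigma X_i) B^-1 c
                 = sum_{i,k} (a_i' r_k)^2 / (q-1),   a_i = X_i B^-1 c.

    The scalar scores a_i' r_k (scaled by 1/sqrt(q-1)) are stored per
    voxel, so the variance is a plain sum of squares and the cross-voxel
    covariance of contrast estimates is the matching cross-product —
    which makes every 2x2 covariance matrix of voxel pairs positive
    semi-definite by construction.
    """

    def __init__(self, q: int | None = None, dof: float | None = None):
        self.q = q
        self.dof = dof

    def fit(self, X, y=None) -> "SandwichGLM":
        if isinstance(X, ReplicationBlocks):
            blocks = X
            if y is not None:
                raise ValueError("pass data inside ReplicationBlocks or as y, not both")
        else:
            if isinstance(X, DesignMatrix):
                X = X.values
            X = np.asarray(X, dtype=float)
            y = np.asarray(y, dtype=float)
            blocks = make_blocks(y, X, q=self.q)
        bd = blocks.block_design            # q x L x p
        data = blocks.block_data            # q x L (x V)
        self._single = data.ndim == 2
        if self._single:
            data = data[..., None]
        q, L, p = bd.shape
        for i in range(q):
            if np.linalg.matrix_rank(bd[i]) < min(L, p):
                raise ValueError(f"block {i} design is rank deficient")
        bread = np.einsum("qlp,qlr->pr", bd, bd)      # sum_i Xi'Xi
        try:
            bread_inv = np.linalg.inv(bread)
        except np.linalg.LinAlgError as err:
            raise ValueError("pooled block design is singular") from err
        xty = np.einsum("qlp,qlv->pv", bd, data)       # sum_i Xi'yi
        beta = bread_inv @ xty                         # p x V
        resid = data - np.einsum("qlp,pv->qlv", bd, beta)
        self.blocks_ = blocks
        self.q_ = q
        self.block_length_ = L
        self.coef_ = beta.T                            # V x p
        self.residual_blocks_ = resid                  # q x L x V
        self.bread_inv_ = bread_inv
        self.dof_ = float(self.dof) if self.dof is not None else float(q - 1)
        return self

    # -- contrast-level quantities -------------------------------------

    def block_scores(self, contrast) -> np.ndarray:
        """(q^2) x V score matrix for the given contrast.

        Row (i, k) holds a_i' r_k / sqrt(q - 1) with a_i = X_i B^-1 c, so
        Var(c'b) is the column-wise sum of squares and cross-voxel
        covariances are column cross-products.
        """
        c = _as_contrast(contrast)
        a = np.einsum("qlp,p->ql", self.blocks_.block_design,
                      self.bread_inv_ @ c)             # q x L
        s = np.einsum("il,klv->ikv", a, self.residual_blocks_)
        return s.reshape(self.q_**2, -1) / np.sqrt(self.q_ - 1)

    def contrast_estimate(self, contrast) -> tuple[np.ndarray, np.ndarray]:
        c = _as_contrast(contrast)
        est = self.coef_ @ c
        s = self.block_scores(c)
        var = (s**2).sum(axis=0)
        return est, var

    def covariance(self, contrast, j: int, k: int) -> float:
        """Cross-voxel covariance Cov(c'b_j, c'b_k) from block residuals."""
        s = self.block_scores(contrast)
        return float((s[:, j] * s[:, k]).sum())

    def to_fit(self, contrast) -> GLMFit:
        c = _as_contrast(contrast)
        est, var = self.contrast_estimate(c)
        return GLMFit(
            beta=self.coef_, contrast=est, variance=var, dof=self.dof_,
            estimator="sandwich", contrast_weights=c,
            residual_blocks=self.residual_blocks_,
            block_scores=self.block_scores(c),
        )


# -- thin functional wrappers over the estimators ----------------------

def fit_ols(y: np.ndarray, X: DesignMatrix | np.ndarray, contrast) -> GLMFit:
    """OLS fit; variance from the classical residual estimator, dof T-p."""
    Xv = X.values if isinstance(X, DesignMatrix) else X
    return OLSGLM().fit(Xv, y).to_fit(contrast)


def fit_gls_ar(y: np.ndarray, X: DesignMatrix | np.ndarray, contrast,
               ar_order: int = 1) -> GLMFit:
    """Prewhitened (AR) GLS fit, the comparison baseline."""
    Xv = X.values if isinstance(X, DesignMatrix) else X
    return ARWhitenedGLM(order=ar_order).fit(Xv, y).to_fit(contrast)


def fit_sandwich(blocks: ReplicationBlocks, contrast) -> GLMFit:
    """Replication-block sandwich fit (the default estimator)."""
    return SandwichGLM().fit(blocks, None).to_fit(contrast)


def sandwich_covariance(fit: GLMFit, voxel_j: int, voxel_k: int,
                        contrast=None) -> float:
    """Cross-voxel covariance of contrast estimates from a sandwich fit."""
    if fit.estimator != "sandwich" or fit.block_scores is None:
        raise ValueError("cross-voxel covariance requires a sandwich fit with retained residual blocks")
    if contrast is not None:
        c = _as_contrast(contrast)
        if not np.array_equal(c, fit.contrast_weights):
            raise ValueError("contrast differs from the one the fit was built with")
    s = fit.block_scores
    return float((s[:, voxel_j] * s[:, voxel_k]).sum())


def t_to_z(t: np.ndarray, dof: float) -> np.ndarray:
    """Map t values to standard-normal z via the probability integral transform.

    Evaluated through the survival function on the matching tail so large
    statistics stay finite and the map is odd-symmetric.
    """
    t = np.asarray(t, dtype=float)
    z = np.empty_like(t)
    pos = t >= 0
    z[pos] = stats.norm.isf(stats.t.sf(t[pos], dof))
    z[~pos] = stats.norm.ppf(stats.t.cdf(t[~pos], dof))
    return z


def contrast_zmap(fit: GLMFit, mask: np.ndarray | None = None,
                  affine: np.ndarray | None = None):
    """Convert a GLM fit into a z map over the analysis mask.

    Zero-variance voxels (constant or noise-free signal) are excluded
    from the mask; an all-zero-variance fit is an error.  "Zero" is
    assessed relative to the contrast scale, since an exact fit leaves
    rounding-level residuals rather than literal zeros.
    """
    from .threshold import ZMap  # local import to avoid a cycle

    scale = np.maximum(1.0, np.abs(fit.contrast))
    ok = np.sqrt(np.maximum(fit.variance, 0.0)) > 1e-12 * scale
    if not np.any(ok):
        raise ValueError("all voxels have zero variance; nothing to test")
    t = np.zeros(fit.n_voxels)
    t[ok] = fit.contrast[ok] / np.sqrt(fit.variance[ok])
    z_flat = np.zeros(fit.n_voxels)
    z_flat[ok] = t_to_z(t[ok], fit.dof)
    if mask is None:
        mask = np.ones(fit.n_voxels, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    z = np.zeros(mask.shape)
    valid = np.zeros(mask.shape, dtype=bool)
    z[mask] = z_flat
    valid[mask] = ok
    return ZMap(z=z, mask=valid, affine=affine, dof=fit.dof)
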