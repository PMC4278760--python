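"""Comparison-voxel selection and the three-class in-limbo labeling.

Every voxel that survives cluster thresholding is "activated".  Among the
remaining in-mask voxels, each is tested against the *comparison voxel* —
the least-significantly activated voxel — with a t statistic on the
difference of contrast estimates whose pooled variance includes both
voxel variances and their cross-voxel covariance.  Voxels whose contrast
is significantly smaller than the comparison voxel's are "less"; the rest
are "in limbo": they differ neither from baseline nor from the activated
regions, so their status is inconclusive.

Label codes used throughout: 0 background, 1 less, 2 in_limbo,
3 activated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .glm import GLMFit, SandwichGLM
from .threshold import ClusterResult, ZMap

__all__ = [
    "LABEL_BACKGROUND",
    "LABEL_LESS",
    "LABEL_IN_LIMBO",
    "LABEL_ACTIVATED",
    "EmptySignificantSetError",
    "ComparisonVoxel",
    "SubjectDifference",
    "LimboResult",
    "select_comparison_voxel",
    "limbo_test_single",
    "limbo_test_group",
    "classify_brain",
]

LABEL_BACKGROUND = 0
LABEL_LESS = 1
LABEL_IN_LIMBO = 2
LABEL_ACTIVATED = 3

LABEL_NAMES = {
    LABEL_BACKGROUND: "background",
    LABEL_LESS: "less",
    LABEL_IN_LIMBO: "in_limbo",
    LABEL_ACTIVATED: "activated",
}


class EmptySignificantSetError(RuntimeError):
    """No voxel survived thresholding.

    Without significantly activated areas there is no comparison voxel,
    and there can be no regions that are in limbo.
    """


@dataclass
class ComparisonVoxel:
    """The benchmark voxel all non-significant voxels are tested against."""

    index: tuple
    flat_index: int
    contrast: float
    variance: float
    t_value: float
    z_value: float
    selection_rule: str = "min_t_significant"
    block_scores: np.ndarray | None = None  # q-vector for the pooled test


@dataclass
class SubjectDifference:
    """Per-subject contrast differences (comparison minus voxel) and their
    standard deviations from the per-subject sandwich variance/covariance."""

    d: np.ndarray
    sd: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.atleast_1d(np.asarray(self.d, dtype=float))
        self.sd = np.atleast_1d(np.asarray(self.sd, dtype=float))
        if self.d.shape != self.sd.shape:
            raise ValueError("d and sd must have the same length")
        if self.d.shape[0] < 2:
            raise ValueError("need at least 2 subjects")
        if np.any(self.sd <= 0):
            raise ValueError("all subject-level standard deviations must be > 0")


@dataclass
class LimboResult:
    labels: np.ndarray
    t_limbo: np.ndarray
    p_limbo: np.ndarray
    alpha: float
    comparison: ComparisonVoxel
    corrected: str = "none"
    level: str = "subject"

    def volume(self, label: int, voxel_volume_cm3: float = 1.0) -> float:
        return float(np.sum(self.labels == label) * voxel_volume_cm3)

    def counts(self) -> dict[str, int]:
        return {name: int(np.sum(self.labels == code))
                for code, name in LABEL_NAMES.items()}


def _flat_indices_of_mask(mask: np.ndarray) -> np.ndarray:
    """Map grid positions to fit-array indices (C-order over the mask)."""
    flat = np.full(mask.shape, -1, dtype=int)
    flat[mask] = np.arange(int(mask.sum()))
    return flat


def select_comparison_voxel(zmap: ZMap, clusters: ClusterResult,
                            fit: GLMFit | None = None,
                            selection_rule: str = "min_t_significant") -> ComparisonVoxel:
    """Pick the least-significantly activated voxel.

    Ties on the minimum statistic are broken by lexicographic voxel index
    (deterministic) with a warning.  ``selection_rule="cluster_mean"``
    instead benchmarks against the mean contrast of the least-significant
    cluster (pooled through the block scores, so its variance is exact).
    """
    sig = clusters.significant & zmap.mask
    if not np.any(sig):
        raise EmptySignificantSetError(
            "no significantly activated areas survive thresholding; "
            "without them there can be no regions in limbo")
    coords = np.argwhere(sig)
    zvals = zmap.z[sig]
    zmin = zvals.min()
    ties = np.flatnonzero(zvals == zmin)
    if ties.size > 1:
        warnings.warn(
            f"{ties.size} significant voxels tie at the minimum statistic; "
            "choosing the lexicographically smallest index", stacklevel=2)
    order = np.lexsort(coords[ties].T[::-1])
    pick = tuple(coords[ties[order[0]]])

    flat = _flat_indices_of_mask(zmap.mask)
    flat_idx = int(flat[pick])
    contrast = variance = t_value = np.nan
    scores = None
    if fit is not None:
        contrast = float(fit.contrast[flat_idx])
        variance = float(fit.variance[flat_idx])
        t_value = float(fit.t_values()[flat_idx])
        if fit.block_scores is not None:
            scores = fit.block_scores[:, flat_idx].copy()

    if selection_rule == "cluster_mean":
        if fit is None or fit.block_scores is None:
            raise ValueError("cluster_mean selection needs a sandwich fit")
        labels = clusters.cluster_labels
        members = labels == labels[pick]
        member_idx = flat[members & zmap.mask]
        scores = fit.block_scores[:, member_idx].mean(axis=1)
        contrast = float(fit.contrast[member_idx].mean())
        variance = float((scores**2).sum())
        t_value = contrast / np.sqrt(variance) if variance > 0 else np.nan
    elif selection_rule != "min_t_significant":
        raise ValueError(f"unknown selection_rule {selection_rule!r}")

    return ComparisonVoxel(
        index=pick, flat_index=flat_idx, contrast=contrast, variance=variance,
        t_value=t_value, z_value=float(zmin), selection_rule=selection_rule,
        block_scores=scores)


def limbo_test_single(fit: GLMFit, comparison: ComparisonVoxel,
                      voxel: int, alpha: float = 0.05) -> tuple[float, float, str]:
    """One-sided test: is this voxel's contrast smaller than the comparison's?

    t = (c'b_comp - c'b_voxel) / sqrt(Var_comp + Var_voxel - 2 Cov); the
    pooled variance is computed from the block scores, which guarantees it
    is non-negative; an exactly zero pooled variance means the voxel pair
    is degenerate (identical residual blocks) and raises.
    """
    if fit.estimator != "sandwich" or fit.block_scores is None:
        raise ValueError("the in-limbo test requires a sandwich fit with residual blocks")
    s = fit.block_scores
    s_comp = comparison.block_scores if comparison.block_scores is not None \
        else s[:, comparison.flat_index]
    c_comp = comparison.contrast if np.isfinite(comparison.contrast) \
        else float(fit.contrast[comparison.flat_index])
    diff_scores = s_comp - s[:, voxel]
    pooled_var = float((diff_scores**2).sum())
    num = c_comp - float(fit.contrast[voxel])
    if pooled_var <= 0:
        raise ValueError(
            f"degenerate voxel pair (comparison {comparison.index}, voxel {voxel}): "
            "pooled variance of the contrast difference is zero")
    t = num / np.sqrt(pooled_var)
    p = float(stats.t.sf(t, fit.dof))
    label = "less" if p <= alpha else "in_limbo"
    return float(t), p, label


def limbo_test_group(diffs: SubjectDifference, alpha: float = 0.05
                     ) -> tuple[float, float, str]:
    """Group-level in-limbo test: weighted least squares on subject differences.

    The per-subject differences d (comparison minus voxel) are regressed
    on an intercept-only design with weights 1/sd; the residual scale uses
    n - 1 degrees of freedom, and the one-sided p tests whether the
    voxel's contrast is smaller than the comparison voxel's at the group
    level.
    """
    t, p = _wls_t(diffs.d[:, None], diffs.sd[:, None])
    t, p = float(t[0]), float(p[0])
    label = "less" if p <= alpha else "in_limbo"
    return t, p, label


def _wls_t(D: np.ndarray, SD: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized intercept-only WLS t tests, one column per voxel.

    Degenerate zero-residual columns: a zero estimate gives t = 0
    (p = 0.5); a non-zero estimate with zero residual scale raises.
    """
    n = D.shape[0]
    if n < 2:
        raise ValueError("need at least 2 subjects")
    if np.any(SD <= 0):
        raise ValueError("all subject-level standard deviations must be > 0")
    w = 1.0 / SD**2
    wsum = w.sum(axis=0)
    beta = (w * D).sum(axis=0) / wsum
    resid = D - beta
    scale = (w * resid**2).sum(axis=0) / (n - 1)
    var_beta = scale / wsum
    t = np.zeros(D.shape[1])
    ok = var_beta > 0
    bad = (~ok) & (beta != 0)
    if np.any(bad):
        raise ValueError("zero residual scale with a non-zero estimate: "
                         "degenerate subject differences")
    t[ok] = beta[ok] / np.sqrt(var_beta[ok])
    p = stats.t.sf(t, n - 1)
    return t, p


def classify_brain(zmap: ZMap, clusters: ClusterResult,
                   fit: GLMFit | SandwichGLM | None = None,
                   diffs: tuple[np.ndarray, np.ndarray] | None = None,
                   alpha: float = 0.05, correction: str = "none",
                   selection_rule: str = "min_t_significant",
                   comparison: ComparisonVoxel | None = None) -> LimboResult:
    """Label every in-mask voxel activated / in_limbo / less.

    Single-subject level: pass ``fit`` (a sandwich :class:`GLMFit` whose
    voxel order matches the C-order of ``zmap.mask``).  Group level: pass
    ``diffs`` = (D, SD), two n_subjects x V arrays of per-subject
    comparison-minus-voxel differences and their standard deviations.

    ``correction="fdr"`` applies Benjamini-Hochberg to the in-limbo
    p-values before labeling; the default (no correction) yields the
    minimum number of in-limbo voxels.
    """
    if isinstance(fit, SandwichGLM):
        raise TypeError("pass fit.to_fit(contrast), not the estimator itself")
    if correction not in ("none", "fdr"):
        raise ValueError(f"unknown correction {correction!r}")
    mask = zmap.mask
    V = int(mask.sum())
    activated = clusters.significant & mask
    tested = mask & ~activated

    flat = _flat_indices_of_mask(mask)
    tested_idx = flat[tested]

    level = "subject"
    if diffs is None:
        if fit is None:
            raise ValueError("pass either a sandwich fit or group differences")
        if fit.n_voxels != V:
            raise ValueError("fit voxel count does not match the z-map mask")
        if comparison is None:
            comparison = select_comparison_voxel(zmap, clusters, fit=fit,
                                                 selection_rule=selection_rule)
        s = fit.block_scores
        if fit.estimator != "sandwich" or s is None:
            raise ValueError("the in-limbo test requires a sandwich fit with residual blocks")
        s_comp = comparison.block_scores if comparison.block_scores is not None \
            else s[:, comparison.flat_index]
        diff_scores = s_comp[:, None] - s[:, tested_idx]
        pooled_var = (diff_scores**2).sum(axis=0)
        if np.any(pooled_var <= 0):
            bad = np.argwhere(tested)[pooled_var <= 0][0]
            raise ValueError(
                f"degenerate voxel pair (comparison {comparison.index}, voxel {tuple(bad)}): "
                "pooled variance of the contrast difference is zero")
        c_comp = comparison.contrast
        t_vals = (c_comp - fit.contrast[tested_idx]) / np.sqrt(pooled_var)
        p_vals = stats.t.sf(t_vals, fit.dof)
    else:
        level = "group"
        D, SD = diffs
        D = np.asarray(D, dtype=float)
        SD = np.asarray(SD, dtype=float)
        if D.shape[1] != V:
            raise ValueError("difference arrays must have one column per mask voxel")
        if comparison is None:
            comparison = select_comparison_voxel(zmap, clusters)
        # restrict to tested voxels: the comparison voxel's own column has
        # a degenerate zero difference and is never tested
        t_vals, p_vals = _wls_t(D[:, tested_idx], SD[:, tested_idx])

    if correction == "fdr" and p_vals.size:
        reject, *_ = multipletests(p_vals, alpha=alpha, method="fdr_bh")
    else:
        reject = p_vals <= alpha

    labels = np.full(mask.shape, LABEL_BACKGROUND, dtype=np.int16)
    labels[activated] = LABEL_ACTIVATED
    tested_coords = np.nonzero(tested)
    labels[tested_coords] = np.where(reject, LABEL_LESS, LABEL_IN_LIMBO)

    t_map = np.full(mask.shape, np.nan)
    p_map = np.full(mask.shape, np.nan)
    t_map[tested_coords] = t_vals
    p_map[tested_coords] = p_vals

    return LimboResult(labels=labels, t_limbo=t_map, p_limbo=p_map,
                       alpha=alpha, comparison=comparison,
                       corrected=correction, level=level)
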