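"""Design-matrix construction for block/event fMRI experiments.

Task regressors are boxcar functions (one per condition) convolved with a
canonical double-gamma haemodynamic response function and sampled at the
repetition time.  Nuisance regressors (drift, motion, ...) are appended
unchanged after the task columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "HRFModel",
    "DesignMatrix",
    "ReplicationBlocks",
    "double_gamma_hrf",
    "build_design",
    "make_blocks",
]


@dataclass(frozen=True)
class HRFModel:
    """Canonical double-gamma haemodynamic response kernel.

    Peak at ~6 s, undershoot at ~16 s, undershoot amplitude 1/6 of the peak
    (the conventional constants).  ``oversampling`` controls the internal
    sampling rate used for the convolution before decimating back to the TR
    grid.
    """

    kind: str = "canonical_double_gamma"
    oversampling: int = 16
    peak_delay: float = 6.0
    undershoot_delay: float = 16.0
    undershoot_ratio: float = 1.0 / 6.0
    duration: float = 32.0

    def __post_init__(self) -> None:
        if self.kind != "canonical_double_gamma":
            raise ValueError(f"unknown HRF kind {self.kind!r}")
        if self.oversampling < 1:
            raise ValueError("oversampling must be >= 1")


def double_gamma_hrf(hrf: HRFModel, dt: float) -> np.ndarray:
    """Sample the double-gamma kernel on a grid of spacing ``dt`` seconds.

    The kernel is normalised to unit (discrete) sum, so a sustained
    boxcar convolved with it plateaus at 1 and ``effect_size``
    parameters read directly as plateau signal amplitudes.
    """
    t = np.arange(0, hrf.duration + dt, dt)
    # gamma pdfs with shape a and scale 1: peak at (a - 1)
    peak = stats.gamma.pdf(t, hrf.peak_delay, scale=1.0)
    under = stats.gamma.pdf(t, hrf.undershoot_delay, scale=1.0)
    kernel = peak - hrf.undershoot_ratio * under
    kernel /= kernel.sum()
    return kernel


@dataclass(frozen=True)
class DesignMatrix:
    """A T x p design matrix with named columns and its repetition time."""

    values: np.ndarray
    regressor_names: list[str]
    tr: float

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 2:
            raise ValueError("design matrix must be 2-D (T x p)")
        T, p = values.shape
        if not (T > p >= 1):
            raise ValueError(f"need T > p >= 1, got T={T}, p={p}")
        if len(self.regressor_names) != p:
            raise ValueError("regressor_names length must match columns")
        if not np.all(np.isfinite(values)):
            raise ValueError("design matrix contains non-finite entries")
        if np.linalg.matrix_rank(values) < p:
            raise ValueError(
                "design matrix is rank deficient; collinear columns: "
                f"{_collinear_columns(values, self.regressor_names)}"
            )
        if self.tr <= 0:
            raise ValueError("tr must be positive")

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[0]

    @property
    def n_regressors(self) -> int:
        return self.values.shape[1]


def _collinear_columns(values: np.ndarray, names: list[str]) -> list[str]:
    """Name the columns involved in a rank deficiency (for error messages)."""
    _, r = np.linalg.qr(values)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(values.shape) * np.finfo(float).eps if diag.max() > 0 else 0.0
    bad = np.where(diag <= tol)[0]
    if bad.size == 0:
        return list(names)
    return [names[i] for i in bad]


def build_design(
    onsets: dict[str, list[float]],
    durations: dict[str, float] | float,
    n_timepoints: int,
    tr: float,
    hrf: HRFModel | None = None,
    nuisance: np.ndarray | None = None,
    nuisance_names: list[str] | None = None,
) -> DesignMatrix:
    """Build a design matrix from event onsets.

    Parameters
    ----------
    onsets
        Mapping condition name -> event onset times in seconds.
    durations
        Event duration in seconds, either one value per condition (dict) or
        a single value shared by all conditions.
    n_timepoints, tr
        Number of volumes and repetition time in seconds.
    hrf
        HRF model; the canonical double-gamma kernel by default.
    nuisance
        Optional T x k matrix appended after the task columns.
    """
    hrf = hrf or HRFModel()
    if n_timepoints < 2:
        raise ValueError("need at least 2 time points")
    run_length = n_timepoints * tr
    dt = tr / hrf.oversampling
    n_fine = int(round(run_length / dt))
    kernel = double_gamma_hrf(hrf, dt)

    columns: list[np.ndarray] = []
    names: list[str] = []
    for condition in onsets:
        dur = durations[condition] if isinstance(durations, dict) else durations
        if dur <= 0:
            raise ValueError(f"duration for {condition!r} must be > 0")
        boxcar = np.zeros(n_fine)
        for onset in onsets[condition]:
            if not (0 <= onset < run_length):
                raise ValueError(
                    f"onset {onset} s of condition {condition!r} outside [0, {run_length}) s"
                )
            start = int(round(onset / dt))
            stop = min(int(round((onset + dur) / dt)), n_fine)
            boxcar[start:stop] = 1.0
        fine = np.convolve(boxcar, kernel)[:n_fine]
        # decimate back to the TR grid
        columns.append(fine[:: hrf.oversampling][:n_timepoints])
        names.append(condition)

    if nuisance is not None:
        nuisance = np.atleast_2d(np.asarray(nuisance, dtype=float))
        if nuisance.shape[0] != n_timepoints:
            nuisance = nuisance.T
        if nuisance.shape[0] != n_timepoints:
            raise ValueError("nuisance matrix rows must equal n_timepoints")
        for k in range(nuisance.shape[1]):
            columns.append(nuisance[:, k])
            if nuisance_names is not None:
                names.append(nuisance_names[k])
            else:
                names.append(f"nuisance_{k}")

    if not columns:
        raise ValueError("design has no columns (no conditions and no nuisance)")
    values = np.column_stack(columns)
    return DesignMatrix(values=values, regressor_names=names, tr=tr)


@dataclass(frozen=True)
class ReplicationBlocks:
    """A run divided into q equal-length replication blocks.

    The blocks play the role of replications for the sandwich estimator:
    the design is split identically with the data, and block designs need
    not be equal to each other (a block may start mid-task-cycle).
    """

    block_design: np.ndarray  # q x L x p
    block_data: np.ndarray    # q x L x V (or q x L for a single voxel)
    tr: float = 1.0

    def __post_init__(self) -> None:
        bd = np.asarray(self.block_design, dtype=float)
        y = np.asarray(self.block_data, dtype=float)
        object.__setattr__(self, "block_design", bd)
        object.__setattr__(self, "block_data", y)
        if bd.ndim != 3:
            raise ValueError("block_design must be q x L x p")
        q, L, p = bd.shape
        if q < 2:
            raise ValueError(f"need at least 2 replication blocks, got {q}")
        if y.shape[:2] != (q, L):
            raise ValueError("block_data must share leading (q, L) shape with block_design")
        pooled = bd.reshape(q * L, p)
        if np.linalg.matrix_rank(pooled) < p:
            raise ValueError("pooled block design is rank deficient")

    @property
    def q(self) -> int:
        return self.block_design.shape[0]

    @property
    def block_length(self) -> int:
        return self.block_design.shape[1]


def default_n_blocks(n_timepoints: int) -> int:
    """Default block count: the (floored) square root of the run length."""
    return int(np.floor(np.sqrt(n_timepoints)))


def make_blocks(
    y: np.ndarray,
    X: DesignMatrix | np.ndarray,
    q: int | None = None,
    tr: float | None = None,
) -> ReplicationBlocks:
    """Divide a run into q equal-length replication blocks.

    Defaults to q = floor(sqrt(T)); the trailing T - q*floor(T/q) time
    points are discarded from the end of the run.
    """
    if isinstance(X, DesignMatrix):
        tr = X.tr if tr is None else tr
        X = X.values
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    T = X.shape[0]
    if T < 4:
        raise ValueError("need at least 4 time points to form replication blocks")
    if y.shape[0] != T:
        raise ValueError("data and design must have the same number of time points")
    if q is None:
        q = default_n_blocks(T)
    if q < 2:
        raise ValueError(f"number of blocks must be >= 2, got {q}")
    L = T // q
    if L < 1:
        raise ValueError(f"cannot split T={T} time points into q={q} blocks")
    used = q * L
    p = X.shape[1]
    block_design = X[:used].reshape(q, L, p)
    block_data = y[:used].reshape(q, L, *y.shape[1:])
    return ReplicationBlocks(block_design=block_design, block_data=block_data, tr=tr or 1.0)
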