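"""NIfTI-1 and tabular I/O helpers.

All spatial outputs carry the input affine unchanged.  2-D synthetic
brains are stored as single-slice 3-D volumes so every module shares one
I/O path.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "load_volume",
    "load_bold",
    "save_map",
    "read_events",
    "read_design_tsv",
    "write_cluster_table",
]


def load_volume(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Load a 3-D volume (e.g. a mask); returns (data, affine)."""
    img = nib.load(str(path))
    return np.asanyarray(img.dataobj), img.affine


def load_bold(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Load a 4-D BOLD series as (T, x, y, z) plus the affine.

    NIfTI stores time last; internally time comes first.
    """
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 4:
        raise ValueError(f"expected a 4-D BOLD image, got shape {data.shape}")
    return np.moveaxis(data, -1, 0).astype(float), img.affine


def save_map(data: np.ndarray, affine: np.ndarray | None, path: str | Path,
             dtype=np.float32) -> Path:
    """Write a spatial map as NIfTI-1, padding 2-D maps to a single slice."""
    data = np.asarray(data)
    if data.ndim == 2:
        data = data[:, :, None]
    if affine is None:
        affine = np.eye(4)
    img = nib.Nifti1Image(np.ascontiguousarray(data.astype(dtype)), affine)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(img, str(path))
    return path


def read_events(path: str | Path) -> tuple[dict[str, list[float]], dict[str, float]]:
    """Read an events table (TSV with onset, duration, condition columns)."""
    df = pd.read_csv(path, sep="\t")
    required = {"onset", "duration", "condition"}
    if not required.issubset(df.columns):
        raise ValueError(f"events file needs columns {sorted(required)}")
    onsets: dict[str, list[float]] = {}
    durations: dict[str, float] = {}
    for cond, sub in df.groupby("condition", sort=False):
        onsets[str(cond)] = sub["onset"].astype(float).tolist()
        durations[str(cond)] = float(sub["duration"].iloc[0])
    return onsets, durations


def read_design_tsv(path: str | Path) -> tuple[np.ndarray, list[str]]:
    """Read a pre-built numeric design matrix from delimited text."""
    df = pd.read_csv(path, sep="\t")
    return df.to_numpy(dtype=float), [str(c) for c in df.columns]


def write_cluster_table(clusters, path: str | Path) -> Path:
    rows = []
    for c in clusters:
        rows.append({
            "label": c.label,
            "size": c.size,
            "min_z": c.min_z,
            "max_z": c.max_z,
            "p_cluster": c.p_cluster,
            "significant": c.significant,
            "peak": "x".join(str(v) for v in c.peak),
        })
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    return path
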