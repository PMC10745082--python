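"""Voxel-level data preparation.

Reads 4D volumes and 3D masks, extracts masked voxel time series, truncates
runs to a common length, normalizes each voxel to zero mean / unit L2 norm,
spatially concatenates runs across tasks, and draws seeded uniform voxel
subsamples.  The inverse mapping back to 3D volumes is exact.

Voxel linearization
-------------------
Inside-mask voxels are ordered with the *first* spatial axis varying fastest
(Fortran order).  This ordering is a bijection between inside voxels and
``0..n-1`` and is used consistently by :func:`extract_masked_signals` and
:func:`map_to_volume`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "BrainMask",
    "VoxelSignalMatrix",
    "extract_masked_signals",
    "truncate_to_common_length",
    "normalize_voxels",
    "concat_tasks",
    "subsample_voxels",
    "map_to_volume",
    "load_volume4d",
    "save_volume4d",
    "load_mask",
    "save_mask",
    "read_design_tsv",
    "write_design_tsv",
]


@dataclass(frozen=True)
class BrainMask:
    """Boolean 3D brain mask with a declared voxel linearization."""

    inside: np.ndarray

    def __post_init__(self):
        inside = np.asarray(self.inside, dtype=bool)
        if inside.ndim != 3:
            raise ValueError(f"mask must be 3D, got ndim={inside.ndim}")
        object.__setattr__(self, "inside", inside)

    @property
    def grid_dims(self) -> tuple[int, int, int]:
        return self.inside.shape

    @property
    def n(self) -> int:
        return int(self.inside.sum())

    @property
    def linear_indices(self) -> np.ndarray:
        """F-order flat indices of inside voxels (first axis fastest)."""
        return np.flatnonzero(self.inside.ravel(order="F"))

    def coordinates(self) -> np.ndarray:
        """(n, 3) integer grid coordinates of inside voxels, mask order."""
        return np.column_stack(
            np.unravel_index(self.linear_indices, self.grid_dims, order="F")
        )


@dataclass
class VoxelSignalMatrix:
    """t x n matrix of voxel time series for one subject/task (or a
    task-concatenated block of them)."""

    data: np.ndarray
    subject_id: str | None = None
    task_id: str | None = None
    normalized: bool = False
    #: column indices flagged as degenerate (zero variance) by normalization
    excluded: tuple[int, ...] = ()
    #: per-column (task, voxel) labels after task concatenation
    col_task: np.ndarray | None = None
    col_voxel: np.ndarray | None = None

    def __post_init__(self):
        data = np.asarray(self.data, dtype=float)
        if data.ndim != 2:
            raise ValueError(f"signal matrix must be 2D, got ndim={data.ndim}")
        self.data = data

    @property
    def t(self) -> int:
        return self.data.shape[0]

    @property
    def n(self) -> int:
        return self.data.shape[1]


def extract_masked_signals(
    volume4d: np.ndarray,
    mask: BrainMask,
    *,
    subject_id: str | None = None,
    task_id: str | None = None,
) -> VoxelSignalMatrix:
    """Extract the t x n matrix of inside-mask voxel time series.

    Column ``j`` is the series of the j-th inside voxel under the mask's
    F-order linearization.
    """
    volume4d = np.asarray(volume4d, dtype=float)
    if volume4d.ndim != 4:
        raise ValueError(f"expected 4D volume, got ndim={volume4d.ndim}")
    if volume4d.shape[:3] != mask.grid_dims:
        raise ValueError(
            f"volume spatial dims {volume4d.shape[:3]} != mask {mask.grid_dims}"
        )
    if mask.n == 0:
        raise ValueError("mask has no inside voxels")
    n_grid = int(np.prod(mask.grid_dims))
    flat = volume4d.reshape((n_grid, volume4d.shape[3]), order="F")
    data = flat[mask.linear_indices, :].T
    return VoxelSignalMatrix(data, subject_id=subject_id, task_id=task_id)


def map_to_volume(component: np.ndarray, mask: BrainMask) -> np.ndarray:
    """Scatter an n-vector back to a 3D volume; outside voxels are zero."""
    component = np.asarray(component, dtype=float).ravel()
    if component.size != mask.n:
        raise ValueError(f"vector length {component.size} != mask n={mask.n}")
    flat = np.zeros(int(np.prod(mask.grid_dims)))
    flat[mask.linear_indices] = component
    return flat.reshape(mask.grid_dims, order="F")


def truncate_to_common_length(per_task: Mapping[str, VoxelSignalMatrix]):
    """Cut every task's matrix to the minimum frame count, keeping the
    *leading* frames (early blocks of every task survive truncation)."""
    if len(per_task) == 0:
        raise ValueError("need at least one task matrix")
    t_min = min(m.t for m in per_task.values())
    return {
        task: replace(m, data=m.data[:t_min].copy()) for task, m in per_task.items()
    }


def normalize_voxels(m: VoxelSignalMatrix, *, eps: float = 1e-12) -> VoxelSignalMatrix:
    """Mean-center then scale each voxel column to unit L2 norm.

    Zero-variance columns cannot be normalized; they are zeroed and their
    indices recorded in ``excluded`` so downstream voxel sets can drop them.
    """
    if m.t < 2:
        raise ValueError("need at least 2 frames to normalize")
    data = m.data - m.data.mean(axis=0, keepdims=True)
    norms = np.linalg.norm(data, axis=0)
    scale = max(1.0, float(np.abs(m.data).max()))
    degenerate = norms < eps * scale
    safe = np.where(degenerate, 1.0, norms)
    data = data / safe
    data[:, degenerate] = 0.0
    return replace(
        m,
        data=data,
        normalized=True,
        excluded=tuple(int(i) for i in np.flatnonzero(degenerate)),
    )


def concat_tasks(
    per_task: Mapping[str, VoxelSignalMatrix],
    task_order: Sequence[str],
) -> VoxelSignalMatrix:
    """Spatially concatenate one subject's per-task matrices, task-block-wise.

    Columns are ordered by ``task_order``; per-column (task, voxel) labels are
    recorded in ``col_task`` / ``col_voxel``.
    """
    if set(task_order) != set(per_task):
        raise ValueError("task_order must list exactly the provided tasks")
    mats = [per_task[t] for t in task_order]
    ts = {m.t for m in mats}
    if len(ts) != 1:
        raise ValueError(f"frame counts differ across tasks: {sorted(ts)}")
    data = np.hstack([m.data for m in mats])
    col_task = np.concatenate([np.repeat(t, per_task[t].n) for t in task_order])
    col_voxel = np.concatenate([np.arange(per_task[t].n) for t in task_order])
    excluded: list[int] = []
    offset = 0
    for t in task_order:
        excluded.extend(offset + i for i in per_task[t].excluded)
        offset += per_task[t].n
    subject_ids = {m.subject_id for m in mats}
    subject_id = subject_ids.pop() if len(subject_ids) == 1 else None
    return VoxelSignalMatrix(
        data,
        subject_id=subject_id,
        task_id=None,
        normalized=all(m.normalized for m in mats),
        excluded=tuple(excluded),
        col_task=col_task,
        col_voxel=col_voxel,
    )


def subsample_voxels(m: VoxelSignalMatrix, fraction: float, seed: int):
    """Seeded uniform voxel subsample via a Fisher-Yates permutation.

    Draws ``floor(fraction * n)`` distinct column indices (returned sorted)
    and the corresponding sub-matrix.  Identical seed => identical indices.
    """
    if not (0.0 < fraction <= 1.0):
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    k = math.floor(fraction * m.n)
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.permutation(m.n)[:k])
    sub = replace(m, data=m.data[:, idx].copy())
    sub.excluded = tuple(
        int(j) for j, orig in enumerate(idx) if int(orig) in set(m.excluded)
    )
    if m.col_task is not None:
        sub.col_task = m.col_task[idx]
        sub.col_voxel = m.col_voxel[idx]
    return idx, sub


# ---------------------------------------------------------------------------
# File formats (NIfTI volumes/masks, design TSV)
# ---------------------------------------------------------------------------


def save_volume4d(path, volume4d: np.ndarray, affine: np.ndarray | None = None):
    import nibabel as nib

    affine = np.eye(4) if affine is None else affine
    nib.save(nib.Nifti1Image(np.asarray(volume4d, dtype=np.float32), affine), str(path))


def load_volume4d(path) -> np.ndarray:
    import nibabel as nib

    return np.asarray(nib.load(str(path)).get_fdata(), dtype=float)


def save_mask(path, mask: BrainMask, affine: np.ndarray | None = None):
    import nibabel as nib

    affine = np.eye(4) if affine is None else affine
    nib.save(
        nib.Nifti1Image(mask.inside.astype(np.uint8), affine),
        str(path),
    )


def load_mask(path) -> BrainMask:
    import nibabel as nib

    data = np.asarray(nib.load(str(path)).get_fdata())
    return BrainMask(data > 0.5)


def write_design_tsv(path, design) -> None:
    """Write a block design as a TSV with columns onset, duration, condition."""
    import pandas as pd

    rows = [
        {"onset": b.onset, "duration": b.duration, "condition": b.condition}
        for b in design.blocks
    ]
    pd.DataFrame(rows, columns=["onset", "duration", "condition"]).to_csv(
        str(path), sep="\t", index=False
    )


def read_design_tsv(path, task_id: str, tr: float, n_frames: int):
    """Read a block-design TSV back into a TaskDesign."""
    import pandas as pd

    from .synth import make_block_design

    df = pd.read_csv(str(path), sep="\t")
    spec = [
        (float(r.onset), float(r.duration), str(r.condition)) for r in df.itertuples()
    ]
    return make_block_design(task_id, tr, n_frames, spec)
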