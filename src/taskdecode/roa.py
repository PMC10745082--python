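"""Ratio-of-activation (ROA) component ranking.

For each stage-2 component (row of the code matrix), count the nonzero
entries among columns belonging to each task; the ROA is the population
standard deviation of those per-task counts.  Components with high ROA have
task-dependent activation support and are the most discriminative; the
incremental experiment retrains the SVM on the top-m ranked components for
growing m.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .classify import feature_matrix, train_eval_svm
from .sparse import CodeMatrix2

__all__ = [
    "ROATable",
    "activation_counts",
    "roa_value",
    "rank_components",
    "incremental_accuracy",
]

#: coordinate descent returns exact zeros; the tolerance is a safety net
DEFAULT_NZ_TOL = 1e-8


@dataclass
class ROATable:
    """Per-component task activation counts, ROA values and descending ranks."""

    counts: np.ndarray  # (k2, T) int
    roa: np.ndarray  # (k2,)
    order: np.ndarray  # component indices, best first (ties -> lower index)
    rank: np.ndarray  # rank[j] = 1-based rank of component j
    task_order: tuple

    def to_frame(self):
        import pandas as pd

        df = pd.DataFrame(
            self.counts, columns=[f"N_{t}" for t in self.task_order]
        )
        df.insert(0, "component", np.arange(self.counts.shape[0]))
        df["roa"] = self.roa
        df["rank"] = self.rank
        return df


def _task_column_index(codes: CodeMatrix2):
    task_order = codes.tasks()
    idx = {t: i for i, t in enumerate(task_order)}
    col_task = np.array([idx[t] for _, t, _ in codes.column_labels])
    return task_order, col_task


def activation_counts(
    codes: CodeMatrix2, component: int, nz_tol: float = DEFAULT_NZ_TOL
) -> np.ndarray:
    """N_t: number of columns labeled task t where the component's entry is
    nonzero (|.| > nz_tol)."""
    if nz_tol < 0:
        raise ValueError("nz_tol must be >= 0")
    if not (0 <= component < codes.codes.shape[0]):
        raise ValueError(f"component {component} out of range")
    task_order, col_task = _task_column_index(codes)
    nz = np.abs(codes.codes[component]) > nz_tol
    return np.bincount(col_task[nz], minlength=len(task_order)).astype(int)


def roa_value(N: np.ndarray) -> float:
    """Population standard deviation of the per-task counts."""
    N = np.asarray(N, dtype=float).ravel()
    if N.size < 2:
        raise ValueError("need counts for >= 2 tasks")
    return float(np.sqrt(np.mean((N - N.mean()) ** 2)))


def rank_components(codes: CodeMatrix2, nz_tol: float = DEFAULT_NZ_TOL) -> ROATable:
    """ROA table with components ordered by descending ROA (stable ties)."""
    task_order, col_task = _task_column_index(codes)
    T = len(task_order)
    if T < 2:
        raise ValueError("need >= 2 tasks for ROA")
    k2 = codes.codes.shape[0]
    counts = np.zeros((k2, T), dtype=int)
    nz = np.abs(codes.codes) > nz_tol
    for t in range(T):
        counts[:, t] = nz[:, col_task == t].sum(axis=1)
    roa = np.sqrt(np.mean((counts - counts.mean(axis=1, keepdims=True)) ** 2, axis=1))
    order = np.argsort(-roa, kind="stable")
    rank = np.empty(k2, dtype=int)
    rank[order] = np.arange(1, k2 + 1)
    return ROATable(counts=counts, roa=roa, order=order, rank=rank, task_order=task_order)


def incremental_accuracy(
    ranked: ROATable,
    train_codes: CodeMatrix2,
    test_codes: CodeMatrix2,
    steps: Sequence[int],
    C: float = 1.0,
) -> list[tuple[int, float]]:
    """Test accuracy using only the top-m ranked components, for each m.

    Selected components are passed to the feature builder as a set (used in
    ascending index order), so m = k2 reproduces the full-feature
    classification exactly.
    """
    k2 = train_codes.codes.shape[0]
    steps = [int(m) for m in steps]
    if any(m < 1 or m > k2 for m in steps):
        raise ValueError(f"steps must lie in 1..{k2}")
    if sorted(steps) != steps:
        raise ValueError("steps must be increasing")
    curve = []
    for m in steps:
        comps = ranked.order[:m]
        Xtr, ytr, _ = feature_matrix(train_codes, components=comps)
        Xte, yte, _ = feature_matrix(test_codes, components=comps)
        _, acc, _ = train_eval_svm(Xtr, ytr, Xte, yte, C=C)
        curve.append((m, float(acc)))
    return curve
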