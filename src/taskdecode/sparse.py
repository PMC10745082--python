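"""Two-stage sparse representation.

Stage 1 codes each subject/task voxel-signal matrix on the group temporal
dictionary by column-wise L1-regularized least squares (LASSO).  Stage 2
aggregates the transposed stage-1 codes across subjects and tasks and learns
a group spatial dictionary (atoms constrained to the unit L2 ball) together
with sparse codes that serve as classification features.

The LASSO subproblem ``min_a 0.5 ||s - D a||^2 + lam ||a||_1`` is solved by
cyclic coordinate descent (scikit-learn's solver, with the penalty rescaled
to match this objective exactly).  Dictionary learning alternates full
coding passes with per-atom block-coordinate updates projected onto the unit
ball, which makes the objective non-increasing across alternations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import Lasso

__all__ = [
    "LoadingMatrix1",
    "SpatialDictionary",
    "CodeMatrix2",
    "lasso_code",
    "assemble_stage2_input",
    "disassemble_stage2_input",
    "learn_spatial_dictionary",
    "code_test_set",
    "reconstruction_error",
]


@dataclass
class LoadingMatrix1:
    """Stage-1 sparse codes (k1 x n) of one subject/task on the temporal
    dictionary."""

    codes: np.ndarray
    subject_id: str
    task_id: str
    layer: int = 1
    lambda1: float = 0.1

    def __post_init__(self):
        self.codes = np.asarray(self.codes, dtype=float)
        if self.codes.ndim != 2:
            raise ValueError("codes must be 2D (k1 x n)")


@dataclass
class SpatialDictionary:
    """Group spatial dictionary D2 (n x k2) with unit-ball atoms."""

    atoms: np.ndarray
    layer: int = 1
    lambda2: float = 0.05
    objective_history: list = field(default_factory=list)
    max_atom_norm_history: list = field(default_factory=list)

    def __post_init__(self):
        self.atoms = np.asarray(self.atoms, dtype=float)
        norms = np.linalg.norm(self.atoms, axis=0)
        if np.any(norms > 1.0 + 1e-8):
            raise ValueError("dictionary atoms must satisfy ||d||_2 <= 1")

    @property
    def k(self) -> int:
        return self.atoms.shape[1]


@dataclass
class CodeMatrix2:
    """Stage-2 sparse codes (k2 x m) with per-column (subject, task,
    component) labels."""

    codes: np.ndarray
    column_labels: list  # [(subject_id, task_id, component_index), ...]
    layer: int = 1

    def __post_init__(self):
        self.codes = np.asarray(self.codes, dtype=float)
        if self.codes.ndim != 2:
            raise ValueError("codes must be 2D (k2 x m)")
        if self.column_labels is not None and len(self.column_labels) != self.codes.shape[1]:
            raise ValueError("one label per column required")

    @property
    def k(self) -> int:
        return self.codes.shape[0]

    def tasks(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for _, t, _ in self.column_labels:
            seen.setdefault(t, None)
        return tuple(seen)

    def samples(self) -> list[tuple[str, str]]:
        """Unique (subject, task) pairs in first-appearance order."""
        seen: dict[tuple[str, str], None] = {}
        for s, t, _ in self.column_labels:
            seen.setdefault((s, t), None)
        return list(seen)


def lasso_code(
    signals: np.ndarray,
    dictionary: np.ndarray,
    lam: float,
    *,
    tol: float = 1e-10,
    max_iter: int = 100_000,
) -> np.ndarray:
    """Column-wise LASSO codes: each output column minimizes
    ``0.5 ||s_j - D a||_2^2 + lam ||a||_1``.

    ``lam = 0`` falls back to least squares.  Returns a (k x n) array.
    """
    D = np.asarray(dictionary, dtype=float)
    S = np.asarray(signals, dtype=float)
    if lam < 0:
        raise ValueError(f"lam must be >= 0, got {lam}")
    squeeze = S.ndim == 1
    if squeeze:
        S = S[:, None]
    if S.ndim != 2 or D.ndim != 2 or S.shape[0] != D.shape[0]:
        raise ValueError(
            f"shape mismatch: signals {S.shape} vs dictionary {D.shape}"
        )
    if not (np.all(np.isfinite(S)) and np.all(np.isfinite(D))):
        raise ValueError("NaN/inf in signals or dictionary")
    t = D.shape[0]
    if lam == 0:
        alpha, *_ = np.linalg.lstsq(D, S, rcond=None)
    else:
        # sklearn objective: 1/(2t) ||y - Xw||^2 + a ||w||_1  =>  a = lam / t
        model = Lasso(
            alpha=lam / t, fit_intercept=False, tol=tol, max_iter=max_iter
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            model.fit(D, S)
        coef = model.coef_  # (n_targets, k) or (k,) for a single target
        alpha = coef.T if coef.ndim == 2 else coef.reshape(-1, 1)
    return alpha[:, 0] if squeeze else alpha


def _lasso_objective(S, D, alpha, lam):
    resid = S - D @ alpha
    return 0.5 * float((resid**2).sum()) + lam * float(np.abs(alpha).sum())


def assemble_stage2_input(alpha1_set: Sequence[LoadingMatrix1]):
    """Aggregate stage-1 codes into the stage-2 input matrix.

    Columns are transposed rows of each subject/task code matrix, ordered
    subject-major, then task, then component; returns ``(S2, labels)`` where
    ``S2`` is (n x k1*T*p) and labels are (subject, task, component) tuples.
    Subject and task order follow first appearance in ``alpha1_set``.
    """
    if len(alpha1_set) == 0:
        raise ValueError("empty stage-1 code set")
    k1 = alpha1_set[0].codes.shape[0]
    n = alpha1_set[0].codes.shape[1]
    layer = alpha1_set[0].layer
    for a in alpha1_set:
        if a.codes.shape != (k1, n) or a.layer != layer:
            raise ValueError("all stage-1 codes must share (k1, n) and layer")
    subjects: dict[str, None] = {}
    tasks: dict[str, None] = {}
    for a in alpha1_set:
        subjects.setdefault(a.subject_id, None)
        tasks.setdefault(a.task_id, None)
    by_key = {(a.subject_id, a.task_id): a for a in alpha1_set}
    blocks, labels = [], []
    for s in subjects:
        for t in tasks:
            if (s, t) not in by_key:
                raise ValueError(f"missing stage-1 codes for ({s}, {t})")
            blocks.append(by_key[(s, t)].codes.T)  # n x k1
            labels.extend((s, t, c) for c in range(k1))
    return np.hstack(blocks), labels


def disassemble_stage2_input(S2: np.ndarray, labels) -> dict:
    """Inverse of :func:`assemble_stage2_input` (for round-trip checks)."""
    out: dict[tuple[str, str], list] = {}
    for col, (s, t, _c) in zip(S2.T, labels):
        out.setdefault((s, t), []).append(col)
    return {key: np.array(cols).reshape(len(cols), -1) for key, cols in out.items()}


def learn_spatial_dictionary(
    S2: np.ndarray,
    k2: int,
    lam2: float,
    n_iter: int = 30,
    seed: int = 0,
    *,
    labels=None,
    layer: int = 1,
    lasso_tol: float = 1e-8,
    lasso_max_iter: int = 10_000,
) -> tuple[SpatialDictionary, CodeMatrix2]:
    """Alternating sparse coding / dictionary update for
    ``min 0.5 ||S2 - D A||_F^2 + lam2 ||A||_1,1  s.t. ||d_j||_2 <= 1``.

    Atoms are initialized from ``k2`` randomly selected normalized columns of
    ``S2``; unused atoms (zero code row) are re-seeded from the currently
    worst-reconstructed column, which leaves the objective unchanged.  The
    recorded objective history (evaluated after each coding pass) is
    non-increasing.
    """
    S2 = np.asarray(S2, dtype=float)
    n, m = S2.shape
    if k2 > m:
        raise ValueError(f"k2 ({k2}) must be <= number of columns ({m})")
    if lam2 <= 0:
        raise ValueError("lam2 must be > 0")
    rng = np.random.default_rng(seed)
    picks = rng.permutation(m)[:k2]
    D = S2[:, picks].copy()
    norms = np.linalg.norm(D, axis=0)
    zero = norms < 1e-12
    if np.any(zero):
        D[:, zero] = rng.standard_normal((n, int(zero.sum())))
        norms = np.linalg.norm(D, axis=0)
    D /= np.maximum(norms, 1.0)  # project onto unit ball

    objective = []
    max_norms = []
    A = np.zeros((k2, m))
    for it in range(int(n_iter)):
        A = lasso_code(S2, D, lam2, tol=lasso_tol, max_iter=lasso_max_iter)
        objective.append(_lasso_objective(S2, D, A, lam2))
        # block-coordinate dictionary update (Mairal-style), unit-ball projection
        G = A @ A.T
        B = S2 @ A.T
        R = None
        for j in range(k2):
            if G[j, j] > 1e-12:
                d = D[:, j] + (B[:, j] - D @ G[:, j]) / G[j, j]
                D[:, j] = d / max(1.0, float(np.linalg.norm(d)))
            else:
                # unused atom: its code row is zero, so replacing the atom
                # does not change the current objective value
                if R is None:
                    R = ((S2 - D @ A) ** 2).sum(axis=0)
                worst = int(np.argmax(R))
                d = S2[:, worst]
                nrm = float(np.linalg.norm(d))
                D[:, j] = (
                    d / max(1.0, nrm)
                    if nrm > 1e-12
                    else rng.standard_normal(n) / np.sqrt(n)
                )
        max_norms.append(float(np.linalg.norm(D, axis=0).max()))
    A = lasso_code(S2, D, lam2, tol=lasso_tol, max_iter=lasso_max_iter)
    objective.append(_lasso_objective(S2, D, A, lam2))

    if labels is None:
        labels = [("-", "-", c) for c in range(m)]
    dictionary = SpatialDictionary(
        atoms=D,
        layer=layer,
        lambda2=lam2,
        objective_history=objective,
        max_atom_norm_history=max_norms,
    )
    return dictionary, CodeMatrix2(codes=A, column_labels=list(labels), layer=layer)


def code_test_set(
    signals: np.ndarray,
    D1: np.ndarray,
    lam1: float,
    D2: np.ndarray,
    lam2: float,
    *,
    subject_id: str = "test",
    task_id: str = "-",
    layer: int = 1,
    tol: float = 1e-8,
    max_iter: int = 10_000,
) -> CodeMatrix2:
    """Two-stage coding of held-out signals on trained dictionaries.

    ``alpha1 = lasso(signals, D1)`` then ``alpha2 = lasso(alpha1', D2)``;
    a pure function of its inputs (no training-data leakage), with the same
    regularization values as training.
    """
    D1 = np.asarray(D1, dtype=float)
    D2 = np.asarray(D2, dtype=float)
    alpha1 = lasso_code(signals, D1, lam1, tol=tol, max_iter=max_iter)
    if alpha1.T.shape[0] != D2.shape[0]:
        raise ValueError(
            f"stage-1 code width {alpha1.shape[1]} does not match D2 rows {D2.shape[0]}"
        )
    alpha2 = lasso_code(alpha1.T, D2, lam2, tol=tol, max_iter=max_iter)
    k1 = alpha1.shape[0]
    labels = [(subject_id, task_id, c) for c in range(k1)]
    return CodeMatrix2(codes=alpha2, column_labels=labels, layer=layer)


def reconstruction_error(
    signals: np.ndarray, D1: np.ndarray, D2: np.ndarray, alpha2: np.ndarray
) -> float:
    """Relative Frobenius error of the chained factorization
    ``S ~ D1 (D2 alpha2)'``."""
    S = np.asarray(signals, dtype=float)
    denom = float(np.linalg.norm(S))
    if denom == 0:
        raise ValueError("zero-norm signal matrix")
    recon = np.asarray(D1) @ (np.asarray(D2) @ np.asarray(alpha2)).T
    return float(np.linalg.norm(S - recon)) / denom
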