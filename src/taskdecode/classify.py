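"""Subject-level cross-validation and linear SVM task-state classification.

Each (subject, task) pair contributes one sample: the k2 x k1 block of the
stage-2 code matrix for that pair, flattened component-major (the per-
component k2-vectors concatenated in component order).  Classification uses
a linear-kernel one-vs-one multiclass SVM (C defaults to 1, mirroring the
LIBSVM defaults the method invokes without parameters).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.svm import SVC

from .sparse import CodeMatrix2

__all__ = [
    "FoldSplit",
    "ConfusionMatrix",
    "make_folds",
    "feature_matrix",
    "features_from_codes",
    "train_eval_svm",
    "crossval_report",
]


@dataclass(frozen=True)
class FoldSplit:
    """Disjoint subject-to-fold assignment (fold sizes differ by <= 1)."""

    k: int
    assignments: dict  # subject_id -> fold index
    seed: int

    def fold(self, i: int) -> tuple:
        return tuple(s for s, f in self.assignments.items() if f == i)

    def train_test(self, i: int) -> tuple[tuple, tuple]:
        test = self.fold(i)
        train = tuple(s for s, f in self.assignments.items() if f != i)
        return train, test


@dataclass
class ConfusionMatrix:
    """Row = true task, column = predicted task."""

    counts: np.ndarray
    task_order: tuple

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.shape != (len(self.task_order), len(self.task_order)):
            raise ValueError("counts must be T x T")
        if np.any(self.counts < 0):
            raise ValueError("counts must be >= 0")

    @property
    def accuracy(self) -> float:
        total = self.counts.sum()
        return float(np.trace(self.counts) / total) if total else float("nan")

    def specificity(self) -> dict:
        """Per-task TN / (TN + FP) from the confusion counts."""
        total = self.counts.sum()
        out = {}
        for i, task in enumerate(self.task_order):
            tp = self.counts[i, i]
            fp = self.counts[:, i].sum() - tp
            tn = total - self.counts[i, :].sum() - self.counts[:, i].sum() + tp
            out[task] = float(tn / (tn + fp)) if (tn + fp) else float("nan")
        return out


def make_folds(subject_ids: Sequence[str], k: int, seed: int) -> FoldSplit:
    """Seeded uniform shuffle followed by contiguous chunking into k folds."""
    subject_ids = list(subject_ids)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > len(subject_ids):
        raise ValueError(f"k ({k}) exceeds number of subjects ({len(subject_ids)})")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(subject_ids))
    chunks = np.array_split(order, k)
    assignments = {}
    for f, chunk in enumerate(chunks):
        for idx in chunk:
            assignments[subject_ids[int(idx)]] = f
    return FoldSplit(k=k, assignments=assignments, seed=seed)


def feature_matrix(
    codes: CodeMatrix2,
    components: Sequence[int] | None = None,
) -> tuple[np.ndarray, np.ndarray, list]:
    """(X, y, samples): one row per (subject, task) sample.

    ``components`` optionally restricts to a subset of stage-2 components
    (rows of the code matrix); they are used in ascending index order so a
    full subset reproduces the full feature matrix exactly.
    """
    if components is None:
        comps = np.arange(codes.codes.shape[0])
    else:
        comps = np.array(sorted(int(c) for c in components))
        if comps.size and (comps.min() < 0 or comps.max() >= codes.codes.shape[0]):
            raise ValueError("component index out of range")
    samples = codes.samples()
    cols_by_sample: dict[tuple[str, str], dict[int, int]] = {s: {} for s in samples}
    for j, (s, t, c) in enumerate(codes.column_labels):
        cols_by_sample[(s, t)][c] = j
    X = np.empty((len(samples), comps.size * len(cols_by_sample[samples[0]])))
    y = np.empty(len(samples), dtype=object)
    for i, key in enumerate(samples):
        col_idx = [cols_by_sample[key][c] for c in sorted(cols_by_sample[key])]
        block = codes.codes[np.ix_(comps, col_idx)]  # (m, k1)
        X[i] = block.T.ravel()  # component-major: per-component vectors in order
        y[i] = key[1]
    return X, np.array([str(v) for v in y]), samples


def features_from_codes(codes: CodeMatrix2, subject_id: str, task_id: str) -> np.ndarray:
    """Flattened k2 x k1 feature vector for one (subject, task) sample."""
    X, _, samples = feature_matrix(codes)
    try:
        i = samples.index((subject_id, task_id))
    except ValueError:
        raise KeyError(f"no codes labeled ({subject_id!r}, {task_id!r})") from None
    return X[i]


def train_eval_svm(
    train_features: np.ndarray,
    train_labels: Sequence[str],
    test_features: np.ndarray,
    test_labels: Sequence[str],
    C: float = 1.0,
) -> tuple[ConfusionMatrix, float, dict]:
    """Linear one-vs-one multiclass SVM; returns (confusion, accuracy,
    per-task specificity)."""
    train_labels = np.asarray(train_labels)
    test_labels = np.asarray(test_labels)
    classes = sorted(set(train_labels))
    if len(classes) < 2:
        raise ValueError("need >= 2 classes in training labels")
    if train_features.shape[1] != test_features.shape[1]:
        raise ValueError("train/test feature dimensions differ")
    clf = SVC(kernel="linear", C=C, decision_function_shape="ovo")
    clf.fit(train_features, train_labels)
    pred = clf.predict(test_features)
    task_order = tuple(sorted(set(classes) | set(test_labels)))
    index = {t: i for i, t in enumerate(task_order)}
    counts = np.zeros((len(task_order), len(task_order)), dtype=int)
    for yt, yp in zip(test_labels, pred):
        counts[index[yt], index[yp]] += 1
    cm = ConfusionMatrix(counts=counts, task_order=task_order)
    return cm, cm.accuracy, cm.specificity()


def crossval_report(fold_results: Sequence[tuple]) -> dict:
    """Aggregate per-fold (ConfusionMatrix, accuracy, specificity) triples.

    Returns mean accuracy with the *sample* standard deviation across folds,
    macro specificity (mean over tasks, then over folds), the mean confusion
    matrix and all per-fold values.
    """
    if any(fr is None for fr in fold_results) or len(fold_results) == 0:
        raise ValueError("missing fold result")
    accs = np.array([a for _, a, _ in fold_results], dtype=float)
    macro_spec = np.array(
        [float(np.mean(list(spec.values()))) for _, _, spec in fold_results]
    )
    task_order = fold_results[0][0].task_order
    for cm, _, _ in fold_results:
        if cm.task_order != task_order:
            raise ValueError("inconsistent task order across folds")
    mean_conf = np.mean([cm.counts for cm, _, _ in fold_results], axis=0)
    return {
        "mean_accuracy": float(accs.mean()),
        "sd_accuracy": float(accs.std(ddof=1)) if accs.size > 1 else 0.0,
        "mean_specificity": float(macro_spec.mean()),
        "mean_confusion": mean_conf,
        "task_order": task_order,
        "fold_accuracies": accs.tolist(),
        "fold_specificities": [spec for _, _, spec in fold_results],
    }
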