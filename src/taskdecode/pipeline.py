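"""End-to-end orchestration: preprocess, per-fold training/coding, SVM
classification, matching metrics and ROA analysis.

All randomness is derived from the single config seed via
``_utils.derive_rng(seed, stage, fold, layer, ...)``, so a whole run is
reproducible bit-for-bit.  Training artifacts (DBN, temporal and spatial
dictionaries) are functions of the training fold only; test subjects are
coded independently with the trained dictionaries.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from ._utils import derive_rng, derive_seed
from .classify import (
    FoldSplit,
    crossval_report,
    feature_matrix,
    make_folds,
    train_eval_svm,
)
from .dbn import multilevel_temporal_features, normalize_dictionary, train_dbn
from .metrics import spatial_match, temporal_match
from .preproc import (
    VoxelSignalMatrix,
    concat_tasks,
    normalize_voxels,
    subsample_voxels,
    truncate_to_common_length,
)
from .roa import incremental_accuracy, rank_components
from .sparse import (
    CodeMatrix2,
    LoadingMatrix1,
    assemble_stage2_input,
    code_test_set,
    lasso_code,
    learn_spatial_dictionary,
)
from .synth import Cohort, canonical_hrf, convolve_design, task_templates

logger = logging.getLogger("taskdecode")

__all__ = [
    "RunConfig",
    "PreprocessedCohort",
    "preprocess_cohort",
    "design_regressors",
    "train_fold",
    "code_fold",
    "classify_fold",
    "roa_fold",
    "run_fold",
    "run_all",
]


@dataclass
class RunConfig:
    """Hyperparameters of a full run.

    Defaults mirror the full-scale method configuration (4 layers x 128
    neurons, lambda1 = 0.1, lambda2 = 0.05, fivefold CV, 10% voxel
    subsample); ``desk_scale()`` returns a small configuration suitable for
    laptop-sized synthetic cohorts.
    """

    layers: int = 4
    k1: int = 128
    k2: int = 128
    lambda1: float = 0.1
    lambda2: float = 0.05
    folds: int = 5
    voxel_fraction: float = 0.1
    seed: int = 0
    svm_c: float = 1.0
    dict_iters: int = 20
    rbm_hyper: dict = field(default_factory=dict)
    lasso_tol: float = 1e-6
    lasso_max_iter: int = 5000
    roa_steps: tuple = ()  # empty: 1..k2
    desk: bool = False

    def __post_init__(self):
        if self.lambda1 <= 0 or self.lambda2 <= 0:
            raise ValueError("lambda1 and lambda2 must be > 0")
        if not (0 < self.voxel_fraction <= 1):
            raise ValueError("voxel_fraction must be in (0, 1]")
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if self.layers < 1 or self.k1 < 1 or self.k2 < 1:
            raise ValueError("layers, k1 and k2 must be >= 1")

    @classmethod
    def desk_scale(cls, **overrides) -> "RunConfig":
        base = dict(
            layers=2,
            k1=16,
            k2=16,
            voxel_fraction=0.2,
            dict_iters=15,
            rbm_hyper={"epochs": 30, "batch": 32},
            desk=True,
        )
        base.update(overrides)
        return cls(**base)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["roa_steps"] = list(d["roa_steps"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        d["roa_steps"] = tuple(d.get("roa_steps", ()))
        return cls(**d)

    def to_yaml(self, path) -> None:
        import yaml

        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass
class PreprocessedCohort:
    """Truncated, normalized per-subject/task matrices over a common voxel set."""

    subject_mats: dict  # subject_id -> {task_id -> VoxelSignalMatrix}
    task_order: tuple
    kept_voxels: np.ndarray  # original voxel indices retained cohort-wide
    t: int

    @property
    def subject_ids(self) -> tuple:
        return tuple(self.subject_mats)

    @property
    def n(self) -> int:
        return int(self.kept_voxels.size)


def preprocess_cohort(cohort: Cohort) -> PreprocessedCohort:
    """Truncate all runs to the common frame count, normalize voxels, and
    drop voxels that are degenerate (zero variance) in any run."""
    task_order = cohort.task_ids
    normalized: dict = {}
    excluded: set[int] = set()
    t_common = None
    for sid, runs in cohort.subjects.items():
        trunc = truncate_to_common_length(runs)
        t_common = next(iter(trunc.values())).t
        normed = {t: normalize_voxels(m) for t, m in trunc.items()}
        for m in normed.values():
            excluded.update(m.excluded)
        normalized[sid] = normed
    n = next(iter(next(iter(normalized.values())).values())).n
    kept = np.array([j for j in range(n) if j not in excluded], dtype=int)
    out: dict = {}
    for sid, runs in normalized.items():
        out[sid] = {
            t: replace(m, data=m.data[:, kept].copy(), excluded=())
            for t, m in runs.items()
        }
    return PreprocessedCohort(
        subject_mats=out, task_order=task_order, kept_voxels=kept, t=t_common
    )


def design_regressors(cohort: Cohort, t: int) -> dict:
    """HRF-convolved (task, condition) regressors truncated to t frames."""
    out = {}
    for task, design in cohort.designs.items():
        kern = canonical_hrf(design.tr)
        for cond in design.conditions:
            out[(task, cond)] = convolve_design(design, kern, cond)[:t]
    return out


def _group_training_matrix(
    pre: PreprocessedCohort, train_subjects: Sequence[str], config: RunConfig
) -> np.ndarray:
    """Stack subsampled voxel series of all training subjects: samples x t."""
    blocks = []
    for sid in train_subjects:
        concat = concat_tasks(pre.subject_mats[sid], pre.task_order)
        sub_seed = derive_seed(config.seed, "subsample", sid)
        _, sub = subsample_voxels(
            concat, config.voxel_fraction, np.random.default_rng(sub_seed).integers(2**32)
        )
        blocks.append(sub.data.T)
    return np.vstack(blocks)


def train_fold(
    pre: PreprocessedCohort,
    split: FoldSplit,
    fold: int,
    config: RunConfig,
) -> dict:
    """Train DBN + both sparse stages on the training subjects of one fold.

    Returns per-layer artifacts: temporal dictionary, spatial dictionary and
    labeled training codes, plus the DBN model and timings.
    """
    train_subjects, _ = split.train_test(fold)
    t0 = time.time()
    group = _group_training_matrix(pre, train_subjects, config)
    layer_sizes = (pre.t,) + (config.k1,) * config.layers
    dbn_seed = derive_seed(config.seed, "dbn", fold)
    model = train_dbn(group, layer_sizes, hyper=config.rbm_hyper, seed=dbn_seed)
    Ws = multilevel_temporal_features(model)
    logger.info(
        "fold %d: DBN trained on %s samples in %.1fs", fold, group.shape[0],
        time.time() - t0,
    )

    layers = []
    for l, W in enumerate(Ws, start=1):
        t1 = time.time()
        D1 = normalize_dictionary(W, layer=l)
        alpha1 = []
        for sid in train_subjects:
            for task in pre.task_order:
                codes = lasso_code(
                    pre.subject_mats[sid][task].data,
                    D1.atoms,
                    config.lambda1,
                    tol=config.lasso_tol,
                    max_iter=config.lasso_max_iter,
                )
                alpha1.append(
                    LoadingMatrix1(
                        codes, subject_id=sid, task_id=task, layer=l,
                        lambda1=config.lambda1,
                    )
                )
        S2, labels = assemble_stage2_input(alpha1)
        dict_seed = derive_rng(config.seed, "dict", fold, l).integers(2**32)
        D2, A2 = learn_spatial_dictionary(
            S2,
            config.k2,
            config.lambda2,
            n_iter=config.dict_iters,
            seed=int(dict_seed),
            labels=labels,
            layer=l,
            lasso_tol=config.lasso_tol,
            lasso_max_iter=config.lasso_max_iter,
        )
        logger.info(
            "fold %d layer %d: stage-1+2 trained in %.1fs (objective %.4g)",
            fold, l, time.time() - t1, D2.objective_history[-1],
        )
        layers.append({"D1": D1, "D2": D2, "train_codes": A2})
    return {"model": model, "layers": layers, "train_subjects": train_subjects}

def code_fold(
    pre: PreprocessedCohort,
    trained: dict,
    split: FoldSplit,
    fold: int,
    config: RunConfig,
) -> list[CodeMatrix2]:
    """Two-stage coding of the fold's test subjects, one CodeMatrix2 per layer."""
    _, test_subjects = split.train_test(fold)
    per_layer = []
    for l, art in enumerate(trained["layers"], start=1):
        blocks, labels = [], []
        for sid in test_subjects:
            for task in pre.task_order:
                cm = code_test_set(
                    pre.subject_mats[sid][task].data,
                    art["D1"].atoms,
                    config.lambda1,
                    art["D2"].atoms,
                    config.lambda2,
                    subject_id=sid,
                    task_id=task,
                    layer=l,
                    tol=config.lasso_tol,
                    max_iter=config.lasso_max_iter,
                )
                blocks.append(cm.codes)
                labels.extend(cm.column_labels)
        per_layer.append(
            CodeMatrix2(codes=np.hstack(blocks), column_labels=labels, layer=l)
        )
    return per_layer


def classify_fold(trained: dict, test_codes: list, config: RunConfig) -> list[tuple]:
    """Per-layer (ConfusionMatrix, accuracy, specificity) on the test fold."""
    results = []
    for art, codes in zip(trained["layers"], test_codes):
        Xtr, ytr, _ = feature_matrix(art["train_codes"])
        Xte, yte, _ = feature_matrix(codes)
        results.append(train_eval_svm(Xtr, ytr, Xte, yte, C=config.svm_c))
    return results


def roa_fold(trained: dict, test_codes: list, config: RunConfig) -> list[dict]:
    """Per-layer ROA table and incremental top-m accuracy curve."""
    out = []
    for art, codes in zip(trained["layers"], test_codes):
        table = rank_components(art["train_codes"])
        steps = list(config.roa_steps) or list(range(1, config.k2 + 1))
        curve = incremental_accuracy(
            table, art["train_codes"], codes, steps, C=config.svm_c
        )
        out.append({"table": table, "curve": curve})
    return out


def metrics_fold(
    trained: dict,
    regressors: dict,
    templates: np.ndarray | None,
    task_order: Sequence[str],
) -> list[dict]:
    """Per-layer temporal (and, when templates are given, spatial) matching."""
    out = []
    for art in trained["layers"]:
        entry = {"temporal": temporal_match(art["D1"], regressors)}
        if templates is not None:
            entry["spatial"] = spatial_match(
                art["D2"], {t: templates[:, i] for i, t in enumerate(task_order)}
            )
        out.append(entry)
    return out


def run_fold(
    cohort: Cohort,
    fold: int,
    config: RunConfig,
    *,
    pre: PreprocessedCohort | None = None,
    split: FoldSplit | None = None,
    with_roa: bool = True,
) -> dict:
    """Full train/code/classify/ROA flow for one fold."""
    pre = pre if pre is not None else preprocess_cohort(cohort)
    split = split if split is not None else make_folds(
        pre.subject_ids, config.folds, config.seed
    )
    trained = train_fold(pre, split, fold, config)
    test_codes = code_fold(pre, trained, split, fold, config)
    classification = classify_fold(trained, test_codes, config)
    regressors = design_regressors(cohort, pre.t)
    templates = None
    if cohort.truth:
        truth = next(iter(cohort.truth.values()))
        templates = task_templates(truth, pre.task_order)[pre.kept_voxels]
    matches = metrics_fold(trained, regressors, templates, pre.task_order)
    result = {
        "fold": fold,
        "trained": trained,
        "test_codes": test_codes,
        "classification": classification,
        "matches": matches,
    }
    if with_roa:
        result["roa"] = roa_fold(trained, test_codes, config)
    return result


def run_all(cohort: Cohort, config: RunConfig, *, with_roa: bool = False) -> dict:
    """Run every fold and aggregate per-layer accuracy/specificity."""
    pre = preprocess_cohort(cohort)
    split = make_folds(pre.subject_ids, config.folds, config.seed)
    fold_results = [
        run_fold(cohort, f, config, pre=pre, split=split, with_roa=with_roa)
        for f in range(config.folds)
    ]
    per_layer = []
    for l in range(config.layers):
        agg = crossval_report([fr["classification"][l] for fr in fold_results])
        per_layer.append(agg)
    return {
        "config": config.to_dict(),
        "split": split,
        "per_layer": per_layer,
        "folds": fold_results,
    }


def report_to_json(report: dict) -> str:
    """Serializable summary of a run_all report (drops bulky artifacts)."""

    def _clean(layer_idx, agg):
        return {
            "layer": layer_idx + 1,
            "mean_accuracy": agg["mean_accuracy"],
            "sd_accuracy": agg["sd_accuracy"],
            "mean_specificity": agg["mean_specificity"],
            "task_order": list(agg["task_order"]),
            "mean_confusion": np.asarray(agg["mean_confusion"]).tolist(),
            "fold_accuracies": agg["fold_accuracies"],
        }

    payload = {
        "config": report["config"],
        "layers": [_clean(i, a) for i, a in enumerate(report["per_layer"])],
    }
    return json.dumps(payload, indent=2)
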