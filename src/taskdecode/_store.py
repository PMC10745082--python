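"""Run-directory persistence for the CLI stages.

Artifacts are stored as ``.npz`` arrays plus JSON sidecars inside a run
directory so the pipeline stages (simulate, preprocess, train, code,
classify, roa, report) can execute as separate processes.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .preproc import BrainMask, VoxelSignalMatrix
from .sparse import CodeMatrix2
from .synth import Cohort, GroundTruth, make_block_design


def save_cohort(cohort: Cohort, run_dir) -> None:
    run_dir = Path(run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    arrays = {"mask": cohort.mask.inside}
    for sid, runs in cohort.subjects.items():
        for task, m in runs.items():
            arrays[f"sig__{sid}__{task}"] = m.data
    truth0 = next(iter(cohort.truth.values())) if cohort.truth else None
    if truth0 is not None:
        arrays["spatial_maps"] = truth0.spatial_maps
        arrays["artifact_maps"] = truth0.artifact_maps
    np.savez_compressed(run_dir / "cohort.npz", **arrays)
    meta = {
        "subjects": list(cohort.subject_ids),
        "tasks": list(cohort.task_ids),
        "designs": {
            t: {
                "tr": d.tr,
                "n_frames": d.n_frames,
                "blocks": [[b.onset, b.duration, b.condition] for b in d.blocks],
            }
            for t, d in cohort.designs.items()
        },
        "network_tasks": list(truth0.network_tasks) if truth0 else [],
        "network_conditions": list(truth0.network_conditions) if truth0 else [],
        "noise_sigma": truth0.noise_sigma if truth0 else 0.0,
        "seed": truth0.seed if truth0 else 0,
    }
    (run_dir / "cohort.json").write_text(json.dumps(meta, indent=2))


def load_cohort(run_dir) -> Cohort:
    run_dir = Path(run_dir)
    meta = json.loads((run_dir / "cohort.json").read_text())
    with np.load(run_dir / "cohort.npz") as z:
        mask = BrainMask(z["mask"])
        designs = {
            t: make_block_design(
                t, d["tr"], d["n_frames"], [tuple(b) for b in d["blocks"]]
            )
            for t, d in meta["designs"].items()
        }
        subjects: dict = {}
        for sid in meta["subjects"]:
            subjects[sid] = {
                task: VoxelSignalMatrix(
                    z[f"sig__{sid}__{task}"], subject_id=sid, task_id=task
                )
                for task in meta["tasks"]
            }
        truth: dict = {}
        if "spatial_maps" in z:
            for sid in meta["subjects"]:
                truth[sid] = GroundTruth(
                    regressors={},
                    spatial_maps=z["spatial_maps"],
                    network_tasks=tuple(meta["network_tasks"]),
                    network_conditions=tuple(meta["network_conditions"]),
                    network_amplitudes=np.ones(z["spatial_maps"].shape[1]),
                    artifact_maps=z["artifact_maps"],
                    artifact_series={},
                    noise_sigma=meta["noise_sigma"],
                    seed=meta["seed"],
                )
    return Cohort(subjects=subjects, designs=designs, truth=truth, mask=mask)


def save_trained(trained: dict, path) -> None:
    arrays = {}
    labels = []
    for l, art in enumerate(trained["layers"]):
        arrays[f"D1__{l}"] = art["D1"].atoms
        arrays[f"D2__{l}"] = art["D2"].atoms
        arrays[f"A2__{l}"] = art["train_codes"].codes
        arrays[f"obj__{l}"] = np.array(art["D2"].objective_history)
        labels.append([[s, t, c] for s, t, c in art["train_codes"].column_labels])
    np.savez_compressed(path, **arrays)
    Path(str(path) + ".labels.json").write_text(
        json.dumps({"labels": labels, "train_subjects": list(trained["train_subjects"])})
    )


def load_trained(path) -> dict:
    from .dbn import TemporalDictionary
    from .sparse import SpatialDictionary

    side = json.loads(Path(str(path) + ".labels.json").read_text())
    layers = []
    with np.load(path) as z:
        n_layers = sum(1 for k in z.files if k.startswith("D1__"))
        for l in range(n_layers):
            D1 = TemporalDictionary(
                atoms=z[f"D1__{l}"],
                layer=l + 1,
                column_norms_pre_normalization=np.linalg.norm(z[f"D1__{l}"], axis=0),
            )
            D2 = SpatialDictionary(
                atoms=z[f"D2__{l}"],
                layer=l + 1,
                objective_history=z[f"obj__{l}"].tolist(),
            )
            labels = [tuple(x) for x in side["labels"][l]]
            labels = [(s, t, int(c)) for s, t, c in labels]
            A2 = CodeMatrix2(codes=z[f"A2__{l}"], column_labels=labels, layer=l + 1)
            layers.append({"D1": D1, "D2": D2, "train_codes": A2})
    return {
        "model": None,
        "layers": layers,
        "train_subjects": tuple(side["train_subjects"]),
    }


def save_codes(per_layer: list, path) -> None:
    arrays = {f"A2__{l}": cm.codes for l, cm in enumerate(per_layer)}
    labels = [[[s, t, c] for s, t, c in cm.column_labels] for cm in per_layer]
    np.savez_compressed(path, **arrays)
    Path(str(path) + ".labels.json").write_text(json.dumps({"labels": labels}))


def load_codes(path) -> list:
    side = json.loads(Path(str(path) + ".labels.json").read_text())
    out = []
    with np.load(path) as z:
        for l in range(len(side["labels"])):
            labels = [(s, t, int(c)) for s, t, c in side["labels"][l]]
            out.append(
                CodeMatrix2(codes=z[f"A2__{l}"], column_labels=labels, layer=l + 1)
            )
    return out
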