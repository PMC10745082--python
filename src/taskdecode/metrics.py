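"""Atom-to-reference matching.

Temporal: Pearson correlation between temporal dictionary atoms and
HRF-convolved task paradigm regressors.  Spatial: the same correlation
between spatial dictionary atoms and activation template maps, computed over
voxels.  Matching maximizes |r| (dictionary atom signs are arbitrary) and
records the sign; ties break toward the lowest atom index.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

__all__ = ["MatchReport", "pearson", "temporal_match", "spatial_match"]


@dataclass
class MatchReport:
    """Per-reference best-matching atom: (atom index, signed r, sign)."""

    entries: dict  # key -> (best_atom_index, correlation, sign)
    layer: int = 0
    kind: str = "temporal"  # "temporal" | "spatial"

    def to_frame(self):
        import pandas as pd

        rows = [
            {"key": str(k), "atom": a, "r": r, "sign": s, "layer": self.layer,
             "kind": self.kind}
            for k, (a, r, s) in self.entries.items()
        ]
        return pd.DataFrame(rows)


def pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation coefficient; raises on constant input."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError(f"length mismatch: {x.size} vs {y.size}")
    if x.size < 2:
        raise ValueError("need length >= 2")
    xc = x - x.mean()
    yc = y - y.mean()
    nx = np.linalg.norm(xc)
    ny = np.linalg.norm(yc)
    if nx == 0 or ny == 0:
        raise ValueError("correlation undefined for constant input")
    r = float(xc @ yc / (nx * ny))
    return max(-1.0, min(1.0, r))


def _match(atoms: np.ndarray, references: Mapping, layer: int, kind: str) -> MatchReport:
    atoms = np.asarray(atoms, dtype=float)
    centered = atoms - atoms.mean(axis=0, keepdims=True)
    norms = np.linalg.norm(centered, axis=0)
    usable = norms > 0
    if not np.any(usable):
        raise ValueError("no non-constant atoms to match against")
    entries = {}
    for key, ref in references.items():
        ref = np.asarray(ref, dtype=float).ravel()
        if ref.size != atoms.shape[0]:
            raise ValueError(
                f"reference {key!r} length {ref.size} != atom length {atoms.shape[0]}"
            )
        rc = ref - ref.mean()
        nr = np.linalg.norm(rc)
        if nr == 0:
            raise ValueError(f"constant reference {key!r}: correlation undefined")
        r = np.zeros(atoms.shape[1])
        r[usable] = (centered[:, usable].T @ rc) / (norms[usable] * nr)
        r = np.clip(r, -1.0, 1.0)
        best = int(np.argmax(np.abs(r)))  # argmax ties -> lowest index
        entries[key] = (best, float(r[best]), int(np.sign(r[best]) or 1))
    return MatchReport(entries=entries, layer=layer, kind=kind)


def temporal_match(D1, regressors: Mapping) -> MatchReport:
    """Best |PCC| temporal atom per task regressor.

    ``D1`` may be a TemporalDictionary or a plain (t x k) array;
    ``regressors`` maps task keys to length-t vectors.
    """
    atoms = getattr(D1, "atoms", D1)
    layer = getattr(D1, "layer", 0)
    return _match(atoms, regressors, layer, "temporal")


def spatial_match(D2, templates) -> MatchReport:
    """Best |PCC| spatial atom per activation template (over voxels).

    ``templates`` is an (n x T) array or a mapping of key -> n-vector.
    """
    atoms = getattr(D2, "atoms", D2)
    layer = getattr(D2, "layer", 0)
    if not isinstance(templates, Mapping):
        templates = np.asarray(templates, dtype=float)
        templates = {i: templates[:, i] for i in range(templates.shape[1])}
    return _match(atoms, templates, layer, "spatial")
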