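"""Stacked-RBM (deep belief network) temporal feature learning.

A stack of restricted Boltzmann machines is trained greedily, layer by
layer, on voxel time series (one sample per voxel, one visible unit per time
point).  Layer 1 uses Gaussian visible units (the data are zero-mean,
unit-norm voxel series); deeper layers train on the previous layer's hidden
activation probabilities with Bernoulli visible units.  Multilevel temporal
features are obtained by successive products of the per-layer weight
matrices, and each level's product, column-normalized, serves as a temporal
dictionary.

Training is CD-1 contrastive divergence with mini-batches, momentum and
weight decay; all randomness flows from the supplied seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import expit

__all__ = [
    "RBMParams",
    "DBNModel",
    "TemporalDictionary",
    "DEFAULT_HYPER",
    "rbm_energy",
    "train_rbm",
    "train_dbn",
    "multilevel_temporal_features",
    "normalize_dictionary",
]

#: CD-1 training defaults (the source method reports no training
#: hyperparameters; these are standard choices).
DEFAULT_HYPER = {
    "lr": 0.01,
    "epochs": 50,
    "batch": 64,
    "cd_steps": 1,
    "momentum": 0.9,
    "momentum_start_epoch": 5,
    "weight_decay": 1e-4,
    "init_std": 0.01,
}


@dataclass
class RBMParams:
    """Weights and biases of one RBM (visible x hidden)."""

    weights: np.ndarray
    visible_bias: np.ndarray
    hidden_bias: np.ndarray
    visible_type: str = "gaussian"  # "gaussian" | "bernoulli"

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        self.visible_bias = np.asarray(self.visible_bias, dtype=float).ravel()
        self.hidden_bias = np.asarray(self.hidden_bias, dtype=float).ravel()
        nv, nh = self.weights.shape
        if self.visible_bias.size != nv or self.hidden_bias.size != nh:
            raise ValueError("bias sizes do not match weight matrix")
        if not (
            np.all(np.isfinite(self.weights))
            and np.all(np.isfinite(self.visible_bias))
            and np.all(np.isfinite(self.hidden_bias))
        ):
            raise ValueError("RBM parameters must be finite")

    @property
    def n_visible(self) -> int:
        return self.weights.shape[0]

    @property
    def n_hidden(self) -> int:
        return self.weights.shape[1]

    def hidden_probs(self, v: np.ndarray) -> np.ndarray:
        return expit(v @ self.weights + self.hidden_bias)


@dataclass
class DBNModel:
    """Greedily trained RBM stack with per-layer training logs."""

    layers: list
    training_log: list = field(default_factory=list)  # per layer: per-epoch errors

    def __post_init__(self):
        for a, b in zip(self.layers, self.layers[1:]):
            if a.n_hidden != b.n_visible:
                raise ValueError("adjacent layer sizes do not chain")

    @property
    def layer_sizes(self) -> tuple[int, ...]:
        return (self.layers[0].n_visible,) + tuple(l.n_hidden for l in self.layers)


@dataclass
class TemporalDictionary:
    """Unit-norm-column temporal dictionary derived from one DBN level."""

    atoms: np.ndarray  # (t, k1)
    layer: int
    column_norms_pre_normalization: np.ndarray
    degenerate: tuple[int, ...] = ()

    @property
    def t(self) -> int:
        return self.atoms.shape[0]

    @property
    def k(self) -> int:
        return self.atoms.shape[1]


def rbm_energy(v: np.ndarray, h: np.ndarray, p: RBMParams) -> float:
    """Joint energy -<b_v, v> - <b_h, h> - v' W h (standard signed form)."""
    v = np.asarray(v, dtype=float).ravel()
    h = np.asarray(h, dtype=float).ravel()
    if v.size != p.n_visible or h.size != p.n_hidden:
        raise ValueError(
            f"state sizes ({v.size}, {h.size}) do not match RBM "
            f"({p.n_visible}, {p.n_hidden})"
        )
    return float(-(p.visible_bias @ v) - (p.hidden_bias @ h) - v @ p.weights @ h)


def train_rbm(
    samples: np.ndarray,
    n_hidden: int,
    hyper: dict | None = None,
    seed: int | np.random.SeedSequence = 0,
    visible_type: str = "gaussian",
) -> tuple[RBMParams, list]:
    """Train one RBM by CD-k; returns (params, per-epoch reconstruction errors).

    Gaussian visible units assume roughly unit-variance input; Bernoulli
    visible units expect values in [0, 1].
    """
    samples = np.asarray(samples, dtype=float)
    if samples.ndim != 2:
        raise ValueError("samples must be 2D (n_samples x n_visible)")
    if not np.all(np.isfinite(samples)):
        raise ValueError("NaN/inf in training samples")
    hp = dict(DEFAULT_HYPER)
    if hyper:
        hp.update(hyper)
    n_samples, n_visible = samples.shape
    if n_samples < hp["batch"]:
        raise ValueError(f"need >= batch ({hp['batch']}) samples, got {n_samples}")
    if any(hp[k] <= 0 for k in ("lr", "epochs", "batch", "cd_steps")):
        raise ValueError("lr, epochs, batch and cd_steps must be positive")
    rng = np.random.default_rng(seed)

    W = rng.normal(0.0, hp["init_std"], size=(n_visible, n_hidden))
    bv = np.zeros(n_visible)
    bh = np.zeros(n_hidden)
    vW = np.zeros_like(W)
    vbv = np.zeros_like(bv)
    vbh = np.zeros_like(bh)
    bernoulli = visible_type == "bernoulli"

    history: list[float] = []
    for epoch in range(int(hp["epochs"])):
        mom = hp["momentum"] if epoch >= hp["momentum_start_epoch"] else 0.5
        perm = rng.permutation(n_samples)
        errs = []
        for start in range(0, n_samples, int(hp["batch"])):
            v0 = samples[perm[start : start + int(hp["batch"])]]
            bs = v0.shape[0]
            h0p = expit(v0 @ W + bh)
            hs = (rng.random(h0p.shape) < h0p).astype(float)
            for _ in range(int(hp["cd_steps"])):
                pre = hs @ W.T + bv
                vk = expit(pre) if bernoulli else pre
                hkp = expit(vk @ W + bh)
                hs = (rng.random(hkp.shape) < hkp).astype(float)
            gW = (v0.T @ h0p - vk.T @ hkp) / bs - hp["weight_decay"] * W
            gbv = (v0 - vk).mean(axis=0)
            gbh = (h0p - hkp).mean(axis=0)
            vW = mom * vW + hp["lr"] * gW
            vbv = mom * vbv + hp["lr"] * gbv
            vbh = mom * vbh + hp["lr"] * gbh
            W += vW
            bv += vbv
            bh += vbh
            errs.append(float(((v0 - vk) ** 2).mean()))
        history.append(float(np.mean(errs)))
        if history[-1] > 10.0 * history[0]:
            warnings.warn(
                f"RBM training diverging at epoch {epoch + 1}: "
                f"error {history[-1]:.3g} > 10x initial {history[0]:.3g}",
                RuntimeWarning,
                stacklevel=2,
            )
    params = RBMParams(W, bv, bh, visible_type=visible_type)
    return params, history


def train_dbn(
    group: np.ndarray,
    layer_sizes: Sequence[int],
    hyper: dict | None = None,
    seed: int = 0,
) -> DBNModel:
    """Greedy layer-wise DBN training on (samples x t) voxel time series.

    Layer l+1 trains on layer l's hidden activation probabilities
    (mean-field propagation, not binary samples).
    """
    group = np.asarray(group, dtype=float)
    layer_sizes = tuple(int(s) for s in layer_sizes)
    if len(layer_sizes) < 2:
        raise ValueError("need at least (visible, hidden) layer sizes")
    if group.ndim != 2 or group.shape[1] != layer_sizes[0]:
        raise ValueError(
            f"group columns ({group.shape[1] if group.ndim == 2 else '?'}) "
            f"must equal layer_sizes[0] ({layer_sizes[0]})"
        )
    ss = np.random.SeedSequence(seed) if isinstance(seed, int) else seed
    layer_seeds = ss.spawn(len(layer_sizes) - 1)
    layers, logs = [], []
    x = group
    for l, (nv, nh) in enumerate(zip(layer_sizes, layer_sizes[1:])):
        params, hist = train_rbm(
            x,
            nh,
            hyper=hyper,
            seed=layer_seeds[l],
            visible_type="gaussian" if l == 0 else "bernoulli",
        )
        layers.append(params)
        logs.append(hist)
        x = params.hidden_probs(x)
    return DBNModel(layers=layers, training_log=logs)


def multilevel_temporal_features(model: DBNModel) -> list[np.ndarray]:
    """Per-level temporal features: W_j = w_1 @ w_2 @ ... @ w_j (t x k1)."""
    out = []
    acc = None
    for p in model.layers:
        acc = p.weights if acc is None else acc @ p.weights
        out.append(acc.copy())
    return out


def normalize_dictionary(W: np.ndarray, layer: int = 1) -> TemporalDictionary:
    """Scale each column to unit L2 norm; near-zero columns are flagged
    degenerate and zeroed (successive weight products inflate scale, and
    L1 coding needs all atoms on the same scale)."""
    W = np.asarray(W, dtype=float)
    if not np.all(np.isfinite(W)):
        raise ValueError("dictionary must be finite")
    norms = np.linalg.norm(W, axis=0)
    degenerate = norms < 1e-10
    safe = np.where(degenerate, 1.0, norms)
    atoms = W / safe
    atoms[:, degenerate] = 0.0
    return TemporalDictionary(
        atoms=atoms,
        layer=layer,
        column_norms_pre_normalization=norms,
        degenerate=tuple(int(i) for i in np.flatnonzero(degenerate)),
    )
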