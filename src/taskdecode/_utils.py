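"""Seed-derivation plumbing shared by all stages.

Every stochastic stage draws its RNG from :func:`derive_rng` so that a single
master seed reproduces an entire run bit-for-bit, while distinct stages,
folds and layers get statistically independent streams.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["derive_rng", "derive_seed"]


def _tag_to_int(tag) -> int:
    if isinstance(tag, str):
        return zlib.crc32(tag.encode("utf-8"))
    return int(tag) & 0xFFFFFFFF


def derive_seed(master_seed: int, *tags) -> np.random.SeedSequence:
    """Deterministically derive a seed sequence from a master seed and tags.

    Tags may be strings (stage names) or integers (fold/layer/subject
    indices); strings are hashed with CRC-32.
    """
    entropy = [int(master_seed) & 0xFFFFFFFF] + [_tag_to_int(t) for t in tags]
    return np.random.SeedSequence(entropy)


def derive_rng(master_seed: int, *tags) -> np.random.Generator:
    """A ``numpy`` Generator seeded from ``(master_seed, *tags)``."""
    return np.random.default_rng(derive_seed(master_seed, *tags))
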