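"""Deterministic seed derivation.

A single master seed controls every stochastic stage of a run. Stage names
are hashed to stable 32-bit keys (CRC-32) and combined with integer indices
into a :class:`numpy.random.SeedSequence` spawn key, so every
``(stage, index, ...)`` tuple yields an independent, reproducible stream
regardless of execution order.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["seed_sequence", "rng_for", "seed_for"]


def _key_part(part) -> int:
    if isinstance(part, (int, np.integer)):
        if part < 0:
            raise ValueError("seed key parts must be nonnegative")
        return int(part)
    return zlib.crc32(str(part).encode("utf8"))


def seed_sequence(master_seed: int, *key) -> np.random.SeedSequence:
    """SeedSequence for the stream identified by ``key`` under ``master_seed``."""
    return np.random.SeedSequence(
        int(master_seed), spawn_key=tuple(_key_part(k) for k in key)
    )


def rng_for(master_seed: int, *key) -> np.random.Generator:
    """Independent Generator for the stream identified by ``key``."""
    return np.random.default_rng(seed_sequence(master_seed, *key))


def seed_for(master_seed: int, *key) -> int:
    """A plain 31-bit integer seed (for APIs such as scikit-learn)."""
    return int(seed_sequence(master_seed, *key).generate_state(1)[0] >> 1)
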