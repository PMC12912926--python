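"""Deterministic random-stream splitting.

Every stage of the pipeline draws from its own child generator derived from
one root seed plus a tuple of string/int keys, so that any stage can be
re-run in isolation and adding stages never perturbs existing streams.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["child_seed", "rng_for"]


def _key_to_int(key: object) -> int:
    if isinstance(key, (int, np.integer)):
        return int(key) & 0xFFFFFFFF
    return zlib.crc32(str(key).encode("utf-8"))


def child_seed(root: int, *keys: object) -> np.random.SeedSequence:
    """Derive a child seed sequence from ``root`` and a tuple of keys."""
    entropy = [int(root) & 0xFFFFFFFF] + [_key_to_int(k) for k in keys]
    return np.random.SeedSequence(entropy)


def rng_for(root: int, *keys: object) -> np.random.Generator:
    """A fresh generator for the stage identified by ``keys``."""
    return np.random.default_rng(child_seed(root, *keys))
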