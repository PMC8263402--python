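"""Deterministic derivation of child random streams from one root seed.

Every stochastic stage of the pipeline draws from its own child generator,
keyed by the root seed plus a stable sequence of labels (strings are hashed
with CRC32, integers used as-is).  Child derivation is order-free: the stream
for a given (root, *keys) tuple never depends on which other streams were
created before it, so scenarios can run in any order with identical results.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["child_seed", "child_rng"]


def child_seed(root_seed: int, *keys: int | str) -> np.random.SeedSequence:
    """Build a SeedSequence for the child stream identified by ``keys``."""
    entropy: list[int] = [int(root_seed) & 0x7FFFFFFF]
    for key in keys:
        if isinstance(key, str):
            entropy.append(zlib.crc32(key.encode("utf-8")))
        else:
            entropy.append(int(key) & 0xFFFFFFFF)
    return np.random.SeedSequence(entropy)


def child_rng(root_seed: int, *keys: int | str) -> np.random.Generator:
    """Return a ``numpy`` Generator for the child stream identified by ``keys``."""
    return np.random.default_rng(child_seed(root_seed, *keys))
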