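"""Seeded random-stream discipline.

Every stochastic stage draws from its own stream keyed by
``(master seed, stage name, entity id, ...)`` so results do not depend on
execution order and individual stages can be rerun in isolation.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["stream", "child_seed"]


def _key_words(keys: tuple) -> list[int]:
    return [zlib.crc32(str(k).encode("utf-8")) for k in keys]


def stream(seed: int, *keys) -> np.random.Generator:
    """Return an independent Generator keyed by ``seed`` and ``keys``.

    ``keys`` may be strings or integers; they are hashed (CRC32) into the
    SeedSequence entropy pool, so the stream identity is stable across runs,
    platforms, and call order.
    """
    entropy = [int(seed) & 0x7FFFFFFF] + _key_words(keys)
    return np.random.default_rng(np.random.SeedSequence(entropy))


def child_seed(seed: int, *keys) -> int:
    """A 31-bit integer seed derived from a keyed stream (for APIs that want an int)."""
    return int(stream(seed, *keys).integers(0, 2**31 - 1))
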