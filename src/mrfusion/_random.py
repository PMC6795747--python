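"""Seed derivation helpers.

Every stochastic stage draws from a named substream of one master seed so a
single integer reproduces an entire run. Tags are hashed with CRC32, which is
stable across platforms and Python versions (unlike ``hash``).
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["derive_seed", "derive_rng"]


def _tag_to_int(tag: int | str) -> int:
    if isinstance(tag, str):
        return zlib.crc32(tag.encode("utf-8"))
    return int(tag)


def derive_seed(master: int, *tags: int | str) -> int:
    """Derive a child seed (< 2**31) from a master seed and named tags."""
    ss = np.random.SeedSequence([int(master)] + [_tag_to_int(t) for t in tags])
    return int(ss.generate_state(1, dtype=np.uint64)[0] % (2**31))


def derive_rng(master: int, *tags: int | str) -> np.random.Generator:
    """A Generator seeded from a named substream of ``master``."""
    ss = np.random.SeedSequence([int(master)] + [_tag_to_int(t) for t in tags])
    return np.random.default_rng(ss)
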