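"""Seed-substream plumbing.

Every stochastic routine in the package draws from a named substream derived
from one root seed, so a single integer reproduces an entire pipeline run and
stages stay independent of each other's draw order.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream"]


def substream(seed: int, name: str) -> np.random.Generator:
    """Return a Generator for the substream ``name`` under root ``seed``.

    The substream key is a CRC32 of the name, so renaming a stage changes its
    stream but nothing else does.
    """
    seed = int(seed) & 0x7FFFFFFF
    key = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([seed, key]))
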