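"""Deterministic seed-substream derivation.

A single top-level seed is fanned out into independent per-stage (and
per-participant, per-dataset, ...) substreams by hashing string/int keys
into a ``numpy`` ``SeedSequence``, so every stage is reproducible both
inside the full pipeline and in isolation.
"""

from __future__ import annotations

import zlib
from typing import Union

import numpy as np

Key = Union[str, int]


def substream(seed: int, *keys: Key) -> int:
    """Derive a child seed (< 2**31) from ``seed`` and a key path."""
    hashed = [zlib.crc32(str(k).encode("utf-8")) if isinstance(k, str) else int(k)
              for k in keys]
    ss = np.random.SeedSequence([int(seed)] + hashed)
    return int(ss.generate_state(1, dtype=np.uint64)[0] % (2 ** 31))


def rng_for(seed: int, *keys: Key) -> np.random.Generator:
    return np.random.default_rng(substream(seed, *keys))
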