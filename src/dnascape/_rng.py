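"""Deterministic RNG stream derivation.

Every randomized operation derives its own independent stream from the master
seed through a stated key derivation: CRC32 of the operation name plus an
ordinal.  Stages can therefore be regenerated independently of each other.
"""

from __future__ import annotations

import zlib

import numpy as np


def derive_rng(master_seed: int, operation: str, ordinal: int = 0) -> np.random.Generator:
    """Return a ``numpy`` Generator keyed by (master seed, operation, ordinal)."""
    key = zlib.crc32(operation.encode("utf-8")) & 0xFFFFFFFF
    ss = np.random.SeedSequence(entropy=int(master_seed), spawn_key=(key, int(ordinal)))
    return np.random.default_rng(ss)
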