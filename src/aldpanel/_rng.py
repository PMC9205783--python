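"""Seed fan-out: one master seed, named independent substreams."""

from __future__ import annotations

import hashlib

import numpy as np

__all__ = ["substream"]


def substream(seed: int, name: str) -> np.random.Generator:
    """Generator for a named substream of a master seed.

    The stream key is a stable hash of ``name``, so every module draws from
    an independent stream and can be regenerated in isolation.
    """
    digest = hashlib.sha256(name.encode()).digest()
    key = int.from_bytes(digest[:4], "little")
    return np.random.default_rng([int(seed), key])
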