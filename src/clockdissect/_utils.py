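"""Small shared helpers: seed derivation, validation."""
from __future__ import annotations

import zlib

import numpy as np


def derive_seed(base_seed: int, stage: str) -> int:
    """Derive a stage-specific seed from a global one, stable across runs.

    Keeps the result below 2**31 so it is always a valid seed for every
    RNG backend.
    """
    h = zlib.crc32(stage.encode("utf-8")) & 0x7FFFFFFF
    return (int(base_seed) * 1_000_003 + h) % (2**31 - 1)


def as_rng(rng: np.random.Generator | int | None) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def check_finite(name: str, value: float) -> None:
    if not np.isfinite(value):
        raise ValueError(f"{name} must be finite, got {value!r}")
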