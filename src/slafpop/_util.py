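"""Shared small helpers: seed derivation, rounding, DNA alphabet."""

from __future__ import annotations

import zlib

import numpy as np

BASES = "ACGT"

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def round_half_away(x: float) -> int:
    """Round to nearest integer, ties away from zero (not banker's)."""
    return int(np.floor(x + 0.5)) if x >= 0 else -int(np.floor(-x + 0.5))


def derive_seed(master: int, stage: str) -> int:
    """Derive a per-stage seed from one master seed.

    Uses CRC32 of the stage name mixed with the master seed so every stage
    is independently reproducible from the single top-level seed.
    """
    return (int(master) * 1_000_003 + zlib.crc32(stage.encode())) % (2**31 - 1)


def rng_for(seed: int, stage: str | None = None) -> np.random.Generator:
    return np.random.default_rng(seed if stage is None else derive_seed(seed, stage))
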