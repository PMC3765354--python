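"""Shared helpers: alphabets, integer encoding, rounding, seeded substreams."""

from __future__ import annotations

from decimal import Decimal, ROUND_HALF_UP

import numpy as np

# Canonical 20-letter amino-acid alphabet, alphabetical by one-letter code.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

DNA = "ACGT"
DNA_INDEX = {b: i for i, b in enumerate(DNA)}

TISSUES = ("bud", "flower", "leaf", "root", "seed", "silique")


def encode_protein(seq: str) -> np.ndarray:
    """Encode a protein as int indices into AMINO_ACIDS; unknown residues -> -1."""
    return np.array([AA_INDEX.get(c, -1) for c in seq], dtype=np.int64)


def check_protein(seq: str, allow_x: bool = True) -> None:
    allowed = set(AMINO_ACIDS) | ({"X"} if allow_x else set())
    bad = set(seq) - allowed
    if bad:
        raise ValueError(f"non-amino-acid characters in sequence: {sorted(bad)!r}")


def round_half_up(x: float, ndigits: int) -> float:
    """Round with ties away from zero at `ndigits` decimals (spreadsheet-style)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def substream(seed: int, *names: str) -> np.random.Generator:
    """Derive a named, reproducible random substream from one master seed.

    Stage names are hashed into the entropy pool so that every pipeline stage
    draws from an independent stream while all randomness flows from `seed`.
    """
    tokens = [abs(hash_name(n)) % (2**31) for n in names]
    return np.random.default_rng(np.random.SeedSequence([int(seed) % (2**31), *tokens]))


def hash_name(name: str) -> int:
    # stable across processes (unlike builtin hash with PYTHONHASHSEED)
    h = 2166136261
    for ch in name.encode():
        h = (h ^ ch) * 16777619 % (2**32)
    return h
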