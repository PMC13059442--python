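"""Nucleotide sequence helpers.

Sequences are held as uint8 code arrays (A=0, C=1, G=2, T=3) so that
reverse-complementing and one-hot encoding are cheap numpy operations.
Code 4 marks padding/N and one-hot encodes to an all-zero column.
"""

from __future__ import annotations

import numpy as np

BASES = "ACGT"
_CODE_TO_BASE = np.array(list("ACGTN"))
_BASE_TO_CODE = {b: i for i, b in enumerate("ACGTN")}
PAD = 4


def encode(seq: str) -> np.ndarray:
    """String -> uint8 code array (unknown letters become N)."""
    return np.array([_BASE_TO_CODE.get(b, PAD) for b in seq.upper()], dtype=np.uint8)


def decode(codes: np.ndarray) -> str:
    return "".join(_CODE_TO_BASE[codes])


def revcomp(codes: np.ndarray) -> np.ndarray:
    out = codes[::-1].copy()
    real = out < 4
    out[real] = 3 - out[real]
    return out


def complement_base(base: str) -> str:
    return {"A": "T", "C": "G", "G": "C", "T": "A"}[base.upper()]


def one_hot(codes: np.ndarray) -> np.ndarray:
    """(L,) codes -> (L, 4) float32 one-hot; padding rows are all-zero."""
    oh = np.zeros((len(codes), 4), dtype=np.float32)
    real = codes < 4
    oh[np.nonzero(real)[0], codes[real]] = 1.0
    return oh


def random_codes(rng: np.random.Generator, n: int) -> np.ndarray:
    return rng.integers(0, 4, size=n, dtype=np.uint8)
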