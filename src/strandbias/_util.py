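"""Shared low-level sequence helpers: normalization, encoding, complement."""

from __future__ import annotations

import numpy as np

VALID = "ACGT"
COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# byte-level normalization table: lowercase + IUPAC ambiguity codes -> N
_NORM = np.full(256, ord("N"), dtype=np.uint8)
for _b in b"ACGT":
    _NORM[_b] = _b
    _NORM[_b + 32] = _b  # lowercase

# base -> 2-bit code; N -> 4 (sentinel)
_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i


def normalize(seq: str) -> str:
    """Uppercase a nucleotide string and map anything outside ACGT to N."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _NORM[raw].tobytes().decode("ascii")


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


def encode(seq: str) -> np.ndarray:
    """Map a normalized sequence to codes A=0, C=1, G=2, T=3, N=4."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _CODE[raw]


def base_counts(codes: np.ndarray) -> np.ndarray:
    """Counts of A, C, G, T (N dropped) for a code array."""
    return np.bincount(codes, minlength=5)[:4]


def set_count(codes: np.ndarray, bases: frozenset[str]) -> int:
    counts = base_counts(codes)
    return int(sum(counts["ACGT".index(b)] for b in bases))
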