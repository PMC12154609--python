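"""Low-level DNA sequence helpers shared across the package.

Sequences cross module boundaries as plain Python strings; internally they are
encoded as uint8 arrays with A,C,G,T -> 0..3 and anything else -> 4 ("N").
"""

from __future__ import annotations

import numpy as np

# byte -> 2-bit code lookup (case-insensitive); non-ACGT -> 4
_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i

_BASES = np.frombuffer(b"ACGTN", dtype=np.uint8)

_RC_TABLE = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string to a uint8 code array (A=0, C=1, G=2, T=3, other=4)."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode("ascii")


def revcomp(seq: str) -> str:
    """Reverse complement (case preserved, N passed through)."""
    return seq.translate(_RC_TABLE)[::-1]


def random_dna(length: int, gc: float = 0.40, rng: np.random.Generator | None = None) -> str:
    """I.i.d. random DNA with the given GC fraction (G and C equiprobable)."""
    if length < 0:
        raise ValueError("length must be non-negative")
    if not 0.0 < gc < 1.0:
        raise ValueError("gc must lie in (0, 1)")
    rng = np.random.default_rng() if rng is None else rng
    at = (1.0 - gc) / 2.0
    codes = rng.choice(4, size=length, p=[at, gc / 2.0, gc / 2.0, at]).astype(np.uint8)
    return decode(codes)


def mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Substitute each ACGT site independently with probability ``rate``.

    Substituted sites receive one of the three alternative bases uniformly;
    non-ACGT characters are left untouched.
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError("rate must lie in [0, 1]")
    codes = encode(seq)
    hit = (rng.random(codes.size) < rate) & (codes < 4)
    n_hit = int(hit.sum())
    if n_hit:
        shift = rng.integers(1, 4, size=n_hit).astype(np.uint8)
        codes[hit] = (codes[hit] + shift) % 4
    return decode(codes)
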