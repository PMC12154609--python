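"""Integer-packed k-mer utilities (k <= 32, 2 bits per base, uint64 codes).

Used by the unique-32-mer index, the electronic-subtraction k-mer sets, and
satellite-monomer masking. Canonical form is the lexicographic minimum of a
k-mer code and its reverse-complement code, which coincides with string
lexicographic order under the A<C<G<T encoding.
"""

from __future__ import annotations

import numpy as np

from ._seq import encode

__all__ = ["kmer_codes", "revcomp_codes", "canonical_codes", "seq_kmers"]


def kmer_codes(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Pack every length-k window of a 0..4 code array into uint64.

    Returns ``(packed, valid)`` where ``valid[i]`` is False for windows that
    contain a non-ACGT base (their packed value is meaningless).
    """
    if not 1 <= k <= 32:
        raise ValueError("k must lie in [1, 32]")
    n = codes.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64), np.empty(0, dtype=bool)
    packed = np.zeros(n, dtype=np.uint64)
    safe = np.where(codes < 4, codes, 0).astype(np.uint64)
    for i in range(k):
        packed = (packed << np.uint64(2)) | safe[i : i + n]
    bad = np.concatenate(([0], np.cumsum(codes >= 4)))
    valid = (bad[k:] - bad[:-k]) == 0
    return packed, valid


def revcomp_codes(packed: np.ndarray, k: int) -> np.ndarray:
    """Reverse-complement of packed k-mer codes."""
    rc = np.zeros_like(packed)
    tmp = packed.copy()
    three = np.uint64(3)
    two = np.uint64(2)
    for _ in range(k):
        rc = (rc << two) | (three - (tmp & three))
        tmp = tmp >> two
    return rc


def canonical_codes(packed: np.ndarray, k: int) -> np.ndarray:
    return np.minimum(packed, revcomp_codes(packed, k))


def seq_kmers(seq: str, k: int, canonical: bool = True) -> np.ndarray:
    """All valid (ACGT-only) k-mer codes of ``seq``, optionally canonicalized."""
    packed, valid = kmer_codes(encode(seq), k)
    packed = packed[valid]
    if canonical:
        packed = canonical_codes(packed, k)
    return packed
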