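"""Electronic subtraction of sex-specific reads.

A male read is a Y-candidate when most of its k-mers are absent from a
female k-mer set: Y-specific sequence contributes k-mers no female genome
read can carry, while autosomal and X-derived male reads are fully covered.
Reads from Y regions shared with the X (PAR, X-transposed) are therefore
classified not-Y by design: the target is Y-specific sequence.

Defaults: k = 31 (odd, avoiding palindromic canonical ambiguity),
min_count = 2 (suppresses singleton sequencing-error k-mers), absent-fraction
threshold 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from ._kmers import seq_kmers

DEFAULT_K = 31
DEFAULT_MIN_COUNT = 2
DEFAULT_THRESHOLD = 0.5

VERDICT_COLUMNS = ["read_id", "absent_fraction", "label"]


@dataclass
class KmerSet:
    """Canonical k-mers observed at least ``min_count`` times, as a sorted
    packed-integer array."""

    k: int
    members: np.ndarray
    min_count: int = 1

    def __len__(self) -> int:
        return int(self.members.size)

    def contains(self, codes: np.ndarray) -> np.ndarray:
        if self.members.size == 0 or codes.size == 0:
            return np.zeros(codes.size, dtype=bool)
        idx = np.searchsorted(self.members, codes)
        idx[idx == self.members.size] = 0
        return self.members[idx] == codes


def _read_pairs(reads: Iterable) -> list[tuple[str, str]]:
    out = []
    for i, r in enumerate(reads):
        if isinstance(r, str):
            out.append((f"read{i}", r))
        elif isinstance(r, tuple):
            out.append((r[0], r[1]))
        else:  # simulated Read or SeqRecord-like
            out.append((getattr(r, "name", f"read{i}"), str(getattr(r, "sequence", getattr(r, "seq", "")))))
    return out


def build_kmer_set(
    reads: Iterable,
    k: int = DEFAULT_K,
    min_count: int = DEFAULT_MIN_COUNT,
) -> KmerSet:
    """Canonical k-mer set of a read collection at the given count floor."""
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    pairs = _read_pairs(reads)
    chunks = [seq_kmers(seq, k) for _name, seq in pairs if len(seq) >= k]
    if not chunks:
        raise ValueError("k is larger than every read")
    pooled = np.concatenate(chunks)
    uniq, counts = np.unique(pooled, return_counts=True)
    return KmerSet(k, uniq[counts >= min_count], min_count)


def classify_reads(
    male_reads: Iterable,
    female: KmerSet,
    threshold: float = DEFAULT_THRESHOLD,
) -> pd.DataFrame:
    """Per-read verdicts: absent_fraction of canonical k-mers missing from the
    female set, label 'Y-candidate' iff absent_fraction >= threshold.

    Reads shorter than k get a missing (NaN) absent_fraction and 'not-Y'.
    """
    rows = []
    for name, seq in _read_pairs(male_reads):
        if len(seq) < female.k:
            rows.append((name, np.nan, "not-Y"))
            continue
        codes = seq_kmers(seq, female.k)
        if codes.size == 0:
            rows.append((name, np.nan, "not-Y"))
            continue
        absent = 1.0 - float(female.contains(codes).mean())
        rows.append((name, absent, "Y-candidate" if absent >= threshold else "not-Y"))
    return pd.DataFrame(rows, columns=VERDICT_COLUMNS)
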