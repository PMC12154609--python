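"""Labeled genomic intervals (BED-like) and interval arithmetic.

All coordinates in this package are 0-based, half-open.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

SEQUENCE_CLASSES = ("PAR", "XTR", "ancestral", "ampliconic", "heterochromatic", "other")


@dataclass(frozen=True)
class RegionAnnotation:
    """One labeled interval on a named sequence."""

    seq_name: str
    start: int
    end: int
    label: str

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"bad interval [{self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start


def merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of half-open intervals as a sorted list of disjoint intervals."""
    ivs = sorted((s, e) for s, e in intervals if e > s)
    out: list[tuple[int, int]] = []
    for s, e in ivs:
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def total_length(intervals: Iterable[tuple[int, int]]) -> int:
    return sum(e - s for s, e in merge_intervals(intervals))


def overlap_length(iv: tuple[int, int], others: Sequence[tuple[int, int]]) -> int:
    s, e = iv
    return sum(max(0, min(e, oe) - max(s, os_)) for os_, oe in others)


def merge_annotations(regions: Sequence[RegionAnnotation]) -> list[RegionAnnotation]:
    """Merge adjacent/overlapping same-label annotations per sequence, sorted."""
    out: list[RegionAnnotation] = []
    for r in sorted(regions, key=lambda r: (r.seq_name, r.start, r.end)):
        if out and out[-1].seq_name == r.seq_name and out[-1].label == r.label and r.start <= out[-1].end:
            out[-1] = RegionAnnotation(r.seq_name, out[-1].start, max(out[-1].end, r.end), r.label)
        else:
            out.append(r)
    return out


def check_tiling(regions: Sequence[RegionAnnotation], seq_lengths: dict[str, int]) -> None:
    """Raise if regions do not partition each named sequence exactly."""
    by_seq: dict[str, list[RegionAnnotation]] = {}
    for r in regions:
        by_seq.setdefault(r.seq_name, []).append(r)
    for name, length in seq_lengths.items():
        rs = sorted(by_seq.get(name, []), key=lambda r: r.start)
        pos = 0
        for r in rs:
            if r.start != pos:
                raise ValueError(f"{name}: gap/overlap at {pos} vs region start {r.start}")
            pos = r.end
        if pos != length:
            raise ValueError(f"{name}: annotation ends at {pos}, sequence length {length}")


def write_bed(regions: Iterable[RegionAnnotation], path: str | Path) -> None:
    """BED6 with the class label in the name column."""
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{r.seq_name}\t{r.start}\t{r.end}\t{r.label}\t0\t+\n")


def read_bed(path: str | Path) -> list[RegionAnnotation]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.rstrip("\n").split("\t")
            label = f[3] if len(f) > 3 else "other"
            out.append(RegionAnnotation(f[0], int(f[1]), int(f[2]), label))
    return out
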