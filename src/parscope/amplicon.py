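"""Ampliconic-repeat and tandem-array calling from self dot-plot matches.

Amplicons are euchromatic repeats showing >99% identity over >10 kb (both
thresholds configurable). Dots on a common diagonal of a self dot plot are
chained into runs; each run's base-level ungapped identity is recomputed over
the two spanned intervals, and passing pairs define the ampliconic footprint.
Tandem arrays appear as evenly spaced off-diagonals whose smallest dominant
offset is the repeat-unit length.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from ._seq import encode
from .regions import merge_intervals, overlap_length

RUN_COLUMNS = ["a_start", "a_end", "b_start", "b_end", "offset", "n_matches"]

DEFAULT_DOT_WINDOW = 250  # bp, the triangular-plot window used throughout
DEFAULT_MAX_GAP = 2_000  # bp along-diagonal gap closed when chaining
DEFAULT_OFFSET_TOL = 500  # bp, dots within this offset band share a diagonal
DEFAULT_MIN_LEN = 10_000  # amplicon definition: span > 10 kb
DEFAULT_MIN_IDENTITY = 99.0  # amplicon definition: identity > 99%
PERIODICITY_BIN = 1_000  # bp, offset histogram bin for unit-length estimation


@dataclass(frozen=True)
class AmpliconPair:
    """Two intervals of one sequence related by >min_identity over >min_len."""

    interval_a: tuple[int, int]
    interval_b: tuple[int, int]
    identity: float
    offset: int


@dataclass(frozen=True)
class TandemArray:
    """A head-to-tail repeat array: span, unit length, and unit-count estimate."""

    interval: tuple[int, int]
    unit_length_bp: int
    n_units: int


def diagonal_runs(
    matches: pd.DataFrame,
    max_gap: int = DEFAULT_MAX_GAP,
    offset_tolerance: int = DEFAULT_OFFSET_TOL,
) -> pd.DataFrame:
    """Chain forward self-plot matches into maximal diagonal runs.

    Matches whose offsets (j - i) differ by at most ``offset_tolerance``
    (single linkage over sorted offsets) and whose along-diagonal gaps are at
    most ``max_gap`` are merged. Returns one row per run with the spanned
    intervals on both axes.
    """
    fwd = matches[matches["strand"] == "+"]
    if len(fwd) == 0:
        return pd.DataFrame(columns=RUN_COLUMNS)
    w = int(fwd["w"].iloc[0])
    df = fwd.assign(offset=fwd["j"] - fwd["i"]).sort_values(["offset", "i"])
    offsets = df["offset"].to_numpy()
    # single-linkage clustering of the sorted offsets
    new_cluster = np.concatenate(([True], np.diff(offsets) > offset_tolerance))
    cluster_id = np.cumsum(new_cluster)

    rows = []
    for _cid, grp in df.groupby(cluster_id, sort=True):
        i = grp["i"].to_numpy()
        j = grp["j"].to_numpy()
        gap_break = np.concatenate(([True], (i[1:] - (i[:-1] + w)) > max_gap))
        run_id = np.cumsum(gap_break)
        for rid in range(1, run_id[-1] + 1):
            sel = run_id == rid
            ii, jj = i[sel], j[sel]
            rows.append(
                (
                    int(ii.min()),
                    int(ii.max()) + w,
                    int(jj.min()),
                    int(jj.max()) + w,
                    int(np.median(jj - ii)),
                    int(sel.sum()),
                )
            )
    return pd.DataFrame(rows, columns=RUN_COLUMNS).sort_values(
        ["a_start", "b_start"], ignore_index=True
    )


def call_amplicons(
    seq: str,
    runs: pd.DataFrame,
    min_len: int = DEFAULT_MIN_LEN,
    min_identity: float = DEFAULT_MIN_IDENTITY,
    mask: Sequence[tuple[int, int]] | None = None,
) -> list[AmpliconPair]:
    """Recompute base-level identity over each chained run and apply the
    amplicon definition (span > min_len and identity > min_identity).

    ``mask`` intervals (e.g. heterochromatic satellite regions, which are not
    euchromatic repeats) disqualify a run when they cover more than half of
    either of its intervals.
    """
    pairs: list[AmpliconPair] = []
    if len(runs) == 0:
        return pairs
    codes = encode(seq)
    n = codes.size
    mask = list(mask) if mask else []
    for row in runs.itertuples(index=False):
        if row.a_end > n or row.b_end > n:
            raise ValueError("run coordinates outside the sequence")
        span = min(row.a_end - row.a_start, row.b_end - row.b_start)
        if span <= min_len:
            continue
        iv_a = (row.a_start, row.a_start + span)
        iv_b = (row.b_start, row.b_start + span)
        if mask and (
            overlap_length(iv_a, mask) > span / 2 or overlap_length(iv_b, mask) > span / 2
        ):
            continue
        ca = codes[iv_a[0] : iv_a[1]]
        cb = codes[iv_b[0] : iv_b[1]]
        valid = (ca < 4) & (cb < 4)
        nv = int(valid.sum())
        if nv == 0:
            continue
        ident = 100.0 * float((valid & (ca == cb)).sum()) / nv
        if ident > min_identity:
            pairs.append(AmpliconPair(iv_a, iv_b, ident, int(row.b_start - row.a_start)))
    return pairs


def amplicon_footprint(pairs: Sequence[AmpliconPair]) -> list[tuple[int, int]]:
    """Interval union of all passing pair intervals (order-independent)."""
    ivs = [p.interval_a for p in pairs] + [p.interval_b for p in pairs]
    return merge_intervals(ivs)


def tandem_periodicity(
    matches: pd.DataFrame,
    min_offset: int = 1_000,
    bin_bp: int = PERIODICITY_BIN,
) -> int:
    """Estimate the repeat-unit length of a tandem array from dot offsets.

    Offsets of forward matches are binned at ``bin_bp``; among bins holding at
    least half the maximal bin count (the dominant diagonal family and its
    multiples), the smallest bin wins and its modal exact offset is returned.
    Raises if no forward match has offset >= ``min_offset``.
    """
    fwd = matches[matches["strand"] == "+"]
    offsets = (fwd["j"] - fwd["i"]).to_numpy()
    offsets = offsets[offsets >= min_offset]
    if offsets.size == 0:
        raise ValueError("no periodic matches at or above min_offset")
    bins = offsets // bin_bp
    uniq, counts = np.unique(bins, return_counts=True)
    keep = counts >= counts.max() / 2
    smallest_bin = uniq[keep].min()
    in_bin = offsets[bins == smallest_bin]
    vals, vcounts = np.unique(in_bin, return_counts=True)
    return int(vals[np.argmax(vcounts)])


def array_span(
    matches: pd.DataFrame,
    unit: int,
    tolerance: int = DEFAULT_OFFSET_TOL,
) -> TandemArray:
    """Span of a tandem array from matches on the unit-offset diagonal.

    The merged interval of the left-hand (i-side) match windows is extended
    by one unit at its trailing edge, because the last copy of the array only
    pairs leftward. ``n_units = round(span / unit)``.
    """
    fwd = matches[matches["strand"] == "+"]
    offsets = (fwd["j"] - fwd["i"]).to_numpy()
    sel = np.abs(offsets - unit) <= tolerance
    if not sel.any():
        raise ValueError(f"no matches at offset {unit} +/- {tolerance}")
    w = int(fwd["w"].iloc[0])
    i = fwd["i"].to_numpy()[sel]
    start = int(i.min())
    end = int(i.max()) + w + unit
    return TandemArray((start, end), int(unit), int(round((end - start) / unit)))


def write_amplicons(pairs: Sequence[AmpliconPair], path) -> None:
    rows = [
        (p.interval_a[0], p.interval_a[1], p.interval_b[0], p.interval_b[1], p.identity, p.offset)
        for p in pairs
    ]
    pd.DataFrame(
        rows, columns=["a_start", "a_end", "b_start", "b_end", "identity", "offset"]
    ).to_csv(path, sep="\t", index=False, float_format="%.3f")
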