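"""Hi-C flank-linkage contig ordering.

The procedure: (1) index every genome-wide unique 32-mer (canonical form,
global count exactly one); (2) keep only mate pairs whose read footprints
overlap a unique-k-mer position (both ends by default, the stricter reading;
``either_end=True`` relaxes it); (3) count retained pairs connecting 50-kb
windows at the flanks of different contigs; (4) greedily chain the
highest-count flank pairs into simple paths to infer contig order and
orientation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from ._kmers import canonical_codes, kmer_codes
from ._seq import encode

DEFAULT_K = 32
DEFAULT_FLANK = 50_000
DEFAULT_READ_SPAN = 100


@dataclass
class UniqueKmerSet:
    """Per-contig sorted start positions of globally unique canonical k-mers."""

    k: int
    positions: dict[str, np.ndarray]

    def n_unique(self) -> int:
        return sum(p.size for p in self.positions.values())


@dataclass
class LinkMatrix:
    """Symmetric mate-pair counts between contig flank windows.

    Flank ids are ``{contig}.L`` / ``{contig}.R``; contigs shorter than twice
    the flank get overlapping windows and are flagged ambiguous-orientation.
    """

    counts: pd.DataFrame
    flank: int
    contigs: list[str]
    ambiguous: set[str] = field(default_factory=set)


@dataclass
class ScaffoldOrder:
    """Inferred contig order with orientation (+ forward, - reversed)."""

    order: list[tuple[str, str]]

    def names(self) -> list[str]:
        return [c for c, _o in self.order]


def unique_kmers(contigs: Mapping[str, str], k: int = DEFAULT_K) -> UniqueKmerSet:
    """Exactly the canonical k-mers with genome-wide count 1, with positions."""
    per_contig: list[tuple[str, np.ndarray, np.ndarray]] = []
    all_codes: list[np.ndarray] = []
    for name, seq in contigs.items():
        packed, valid = kmer_codes(encode(seq), k)
        canon = canonical_codes(packed, k) if packed.size else packed
        per_contig.append((name, canon, valid))
        all_codes.append(canon[valid])
    if all_codes:
        pooled = np.concatenate(all_codes)
        uniq, counts = np.unique(pooled, return_counts=True)
        singletons = uniq[counts == 1]
    else:
        singletons = np.empty(0, dtype=np.uint64)
    positions: dict[str, np.ndarray] = {}
    for name, canon, valid in per_contig:
        if canon.size and singletons.size:
            idx = np.searchsorted(singletons, canon)
            idx[idx == singletons.size] = 0
            hit = valid & (singletons[idx] == canon)
            positions[name] = np.flatnonzero(hit).astype(np.int64)
        else:
            positions[name] = np.empty(0, dtype=np.int64)
    return UniqueKmerSet(k, positions)


def filter_pairs(
    pairs: pd.DataFrame,
    uks: UniqueKmerSet,
    read_span: int = DEFAULT_READ_SPAN,
    either_end: bool = False,
) -> pd.DataFrame:
    """Retain pairs whose read footprints [pos, pos+read_span) overlap a
    unique k-mer (its [p, p+k) footprint). Both ends must hit unless
    ``either_end``."""

    def end_hits(contig: pd.Series, pos: pd.Series) -> np.ndarray:
        hits = np.zeros(len(pos), dtype=bool)
        for name, grp in pos.groupby(contig):
            starts = uks.positions.get(name)
            if starts is None or starts.size == 0:
                continue
            p = grp.to_numpy()
            lo = np.searchsorted(starts, p - uks.k, side="right")
            hi = np.searchsorted(starts, p + read_span, side="left")
            hits[grp.index.to_numpy()] = hi > lo
        return hits

    df = pairs.reset_index(drop=True)
    ha = end_hits(df["contig_a"], df["pos_a"])
    hb = end_hits(df["contig_b"], df["pos_b"])
    keep = (ha | hb) if either_end else (ha & hb)
    return df[keep].reset_index(drop=True)


def _flank_labels(pos: int, length: int, flank: int) -> list[str]:
    labels = []
    if pos < min(flank, length):
        labels.append("L")
    if pos >= max(length - flank, 0):
        labels.append("R")
    return labels


def flank_link_matrix(
    pairs: pd.DataFrame,
    contig_lengths: Mapping[str, int],
    flank: int = DEFAULT_FLANK,
) -> LinkMatrix:
    """Count retained pairs connecting two different contig flank windows.

    Positions outside both flanks of their contig are not counted. For
    contigs shorter than 2x flank the windows overlap; overlap positions
    count toward both flanks and the contig is flagged ambiguous.
    """
    contigs = list(contig_lengths)
    flank_ids = [f"{c}.{side}" for c in contigs for side in ("L", "R")]
    counts = pd.DataFrame(0, index=flank_ids, columns=flank_ids, dtype=int)
    ambiguous = {c for c, L in contig_lengths.items() if L < 2 * flank}
    for row in pairs.itertuples(index=False):
        if row.contig_a not in contig_lengths or row.contig_b not in contig_lengths:
            continue
        fa = _flank_labels(int(row.pos_a), contig_lengths[row.contig_a], flank)
        fb = _flank_labels(int(row.pos_b), contig_lengths[row.contig_b], flank)
        for sa in fa:
            for sb in fb:
                ia, ib = f"{row.contig_a}.{sa}", f"{row.contig_b}.{sb}"
                if ia == ib:
                    continue  # same flank window: excluded
                counts.loc[ia, ib] += 1
                counts.loc[ib, ia] += 1
    return LinkMatrix(counts, flank, contigs, ambiguous)


def order_and_orient(m: LinkMatrix) -> ScaffoldOrder:
    """Greedy path chaining of the link matrix.

    Repeatedly joins the highest-count unused flank pair between different
    contigs that keeps the join graph a set of simple paths; ties break by
    lexicographic flank id. Orientation follows which ends are joined
    (entering a contig at its L flank means '+'). Isolated contigs are
    appended in input order with '+'.
    """
    contigs = m.contigs
    input_rank = {c: i for i, c in enumerate(contigs)}

    edges = []
    ids = list(m.counts.index)
    for i, fa in enumerate(ids):
        for fb in ids[i + 1 :]:
            cnt = int(m.counts.loc[fa, fb])
            if cnt > 0 and fa.rsplit(".", 1)[0] != fb.rsplit(".", 1)[0]:
                edges.append((cnt, fa, fb))
    edges.sort(key=lambda e: (-e[0], e[1], e[2]))

    parent = {c: c for c in contigs}

    def find(c: str) -> str:
        while parent[c] != c:
            parent[c] = parent[parent[c]]
            c = parent[c]
        return c

    joined: dict[str, str] = {}  # flank id -> partner flank id
    for cnt, fa, fb in edges:
        if fa in joined or fb in joined:
            continue
        ca, cb = fa.rsplit(".", 1)[0], fb.rsplit(".", 1)[0]
        ra, rb = find(ca), find(cb)
        if ra == rb:
            continue  # would close a cycle
        parent[ra] = rb
        joined[fa] = fb
        joined[fb] = fa

    degree = {c: sum(1 for f in (f"{c}.L", f"{c}.R") if f in joined) for c in contigs}
    components: dict[str, list[str]] = {}
    for c in contigs:
        components.setdefault(find(c), []).append(c)

    order: list[tuple[str, str]] = []
    seen: set[str] = set()
    for comp in sorted(components.values(), key=lambda cs: min(input_rank[c] for c in cs)):
        terminals = sorted((c for c in comp if degree[c] <= 1), key=lambda c: input_rank[c])
        start = terminals[0]
        # enter the start contig through its unjoined flank
        entry = "L" if f"{start}.L" not in joined else "R"
        cur, side = start, entry
        while cur is not None and cur not in seen:
            seen.add(cur)
            order.append((cur, "+" if side == "L" else "-"))
            exit_flank = f"{cur}.{'R' if side == 'L' else 'L'}"
            nxt = joined.get(exit_flank)
            if nxt is None:
                cur = None
            else:
                cur, nside = nxt.rsplit(".", 1)
                side = nside
    return ScaffoldOrder(order)


def write_link_matrix(m: LinkMatrix, path) -> None:
    m.counts.to_csv(path, sep="\t")


def write_order(order: ScaffoldOrder, path) -> None:
    pd.DataFrame(order.order, columns=["contig", "orientation"]).to_csv(path, sep="\t", index=False)
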