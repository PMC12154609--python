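"""Exact-match windowed dot plots.

A dot is an exact w-bp window match between two positions, on the forward
strand or between a window and the reverse complement of another. Triangular
(self) plots report each forward match once with i < j and exclude the main
diagonal; square (pairwise) plots report both strands with no triangle
restriction. Windows containing non-ACGT characters never match. Each
matching window pair yields a single dot: palindromic content, which matches
both forward and in reverse complement, is reported as forward.

Matches are returned as a DataFrame with columns ``i``, ``j``, ``strand``
('+'/'-') and ``w``; the tabular form is the tested artifact, rendering is a
thin optional layer (see :mod:`parscope.plotting`).
"""

from __future__ import annotations

import pandas as pd

from ._seq import revcomp

MATCH_COLUMNS = ["i", "j", "strand", "w"]


def _empty_matches() -> pd.DataFrame:
    return pd.DataFrame({"i": pd.Series(dtype=int), "j": pd.Series(dtype=int),
                         "strand": pd.Series(dtype=str), "w": pd.Series(dtype=int)})


def window_index(seq: str, w: int, step: int = None) -> dict[str, list[tuple[int, str]]]:
    """Index window contents under their canonical (strand-collapsed) key.

    Returns canonical window string -> list of ``(start, orientation)`` where
    orientation '+' means the window equals the key and '-' means its reverse
    complement does. Windows with non-ACGT characters are skipped.
    """
    if not seq:
        raise ValueError("empty sequence")
    step = w if step is None else step
    if not 1 <= w <= len(seq):
        raise ValueError("window must satisfy 1 <= w <= len(seq)")
    if step < 1:
        raise ValueError("step must be >= 1")
    seq = seq.upper()
    index: dict[str, list[tuple[int, str]]] = {}
    acgt = frozenset("ACGT")
    for p in range(0, len(seq) - w + 1, step):
        win = seq[p : p + w]
        if not acgt.issuperset(win):
            continue
        rc = revcomp(win)
        if win <= rc:
            index.setdefault(win, []).append((p, "+"))
        else:
            index.setdefault(rc, []).append((p, "-"))
    return index


def self_dotplot(seq: str, w: int, step: int = None) -> pd.DataFrame:
    """Triangular self dot plot: all exact w-bp window matches with i < j.

    Forward matches pair same-orientation windows, reverse matches pair
    opposite orientations; the i == j diagonal is excluded.
    """
    index = window_index(seq, w, step)
    rows_i: list[int] = []
    rows_j: list[int] = []
    strands: list[str] = []
    for positions in index.values():
        if len(positions) < 2:
            continue
        for a in range(len(positions)):
            pa, sa = positions[a]
            for b in range(a + 1, len(positions)):
                pb, sb = positions[b]
                if pa == pb:
                    continue
                i, j = (pa, pb) if pa < pb else (pb, pa)
                rows_i.append(i)
                rows_j.append(j)
                strands.append("+" if sa == sb else "-")
    if not rows_i:
        return _empty_matches()
    df = pd.DataFrame({"i": rows_i, "j": rows_j, "strand": strands, "w": w})
    return df.sort_values(["i", "j", "strand"], ignore_index=True)


def pair_dotplot(a: str, b: str, w: int, step: int = None) -> pd.DataFrame:
    """Square dot plot between two sequences, both strands, no triangle rule.

    ``i`` indexes sequence ``a``, ``j`` indexes sequence ``b``; a '-' match
    means ``a[i:i+w] == revcomp(b[j:j+w])``.
    """
    index_a = window_index(a, w, step)
    index_b = window_index(b, w, step)
    rows_i: list[int] = []
    rows_j: list[int] = []
    strands: list[str] = []
    for key, pos_a in index_a.items():
        pos_b = index_b.get(key)
        if not pos_b:
            continue
        for pa, sa in pos_a:
            for pb, sb in pos_b:
                rows_i.append(pa)
                rows_j.append(pb)
                strands.append("+" if sa == sb else "-")
    if not rows_i:
        return _empty_matches()
    df = pd.DataFrame({"i": rows_i, "j": rows_j, "strand": strands, "w": w})
    return df.sort_values(["i", "j", "strand"], ignore_index=True)


def write_matches(matches: pd.DataFrame, seq_a: str, seq_b: str, path) -> None:
    """TSV with columns ``seq_a i seq_b j strand w``."""
    out = matches.copy()
    out.insert(0, "seq_a", seq_a)
    out.insert(2, "seq_b", seq_b)
    out.to_csv(path, sep="\t", index=False)
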