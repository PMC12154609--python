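"""GC-content profiling by region class and a permutation test for elevation.

The X-transposed region of a Y chromosome that once recombined shows elevated
GC relative to the rest of the sex-specific sequence (a footprint of
GC-biased gene conversion). These helpers compute per-window GC by region
class, bootstrap summaries, and a two-sided label-permutation test for the
difference in class means.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._seq import encode
from .regions import RegionAnnotation


@dataclass(frozen=True)
class GcSummary:
    label: str
    n_windows: int
    mean_gc: float
    ci_low: float
    ci_high: float


def gc_content(seq: str) -> float:
    """(G+C) / (A+C+G+T); non-ACGT characters are excluded from the denominator."""
    if not seq:
        raise ValueError("empty sequence")
    codes = encode(seq)
    n = int((codes < 4).sum())
    if n == 0:
        raise ValueError("no ACGT bases")
    gc = int(((codes == 1) | (codes == 2)).sum())
    return gc / n


def windowed_gc(
    seq: str,
    regions: Sequence[RegionAnnotation],
    window: int = 1_000,
) -> dict[str, np.ndarray]:
    """Per-class GC values from windows tiled from each region's start.

    Only windows fully inside a region contribute (windows straddling region
    boundaries, and any partial trailing window, are dropped).
    """
    codes = encode(seq)
    is_gc = ((codes == 1) | (codes == 2)).astype(np.int64)
    is_acgt = (codes < 4).astype(np.int64)
    cg = np.concatenate(([0], np.cumsum(is_gc)))
    cn = np.concatenate(([0], np.cumsum(is_acgt)))
    out: dict[str, list[float]] = {}
    for r in regions:
        if r.end > len(seq):
            raise ValueError("region outside sequence bounds")
        for s in range(r.start, r.end - window + 1, window):
            denom = cn[s + window] - cn[s]
            if denom > 0:
                out.setdefault(r.label, []).append((cg[s + window] - cg[s]) / denom)
    return {label: np.asarray(v) for label, v in out.items()}


def summarize_gc(
    class_values: Mapping[str, np.ndarray],
    n_boot: int = 1_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Bootstrap (percentile, nominal 95%) summary per class, one row each."""
    rng = np.random.default_rng(seed)
    rows = []
    for label, vals in class_values.items():
        vals = np.asarray(vals, dtype=float)
        if vals.size == 0:
            continue
        boots = rng.choice(vals, size=(n_boot, vals.size), replace=True).mean(axis=1)
        lo, hi = np.percentile(boots, [2.5, 97.5])
        rows.append(GcSummary(label, vals.size, float(vals.mean()), float(lo), float(hi)))
    return pd.DataFrame([r.__dict__ for r in rows])


def gc_elevation_test(
    class_a_gc: Sequence[float],
    class_b_gc: Sequence[float],
    n_perm: int = 10_000,
    seed: int = 0,
) -> tuple[float, float]:
    """Two-sided label-permutation test for mean(a) - mean(b).

    Returns ``(observed_difference, p)`` with the add-one correction
    ``p = (1 + #{|perm| >= |obs|}) / (n_perm + 1)``, so p never reaches 0.
    Degenerate all-equal input gives p = 1.
    """
    a = np.asarray(class_a_gc, dtype=float)
    b = np.asarray(class_b_gc, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both classes must be nonempty")
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    obs = float(a.mean() - b.mean())
    pool = np.concatenate([a, b])
    if np.all(pool == pool[0]):
        return obs, 1.0
    rng = np.random.default_rng(seed)
    na = a.size
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(pool)
        stat = perm[:na].mean() - perm[na:].mean()
        if abs(stat) >= abs(obs):
            count += 1
    return obs, (1 + count) / (n_perm + 1)
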