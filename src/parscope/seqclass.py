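"""Five-class sequence segmentation of a sex chromosome.

Labels every base of a Y (or X) sequence as PAR, XTR, ancestral, ampliconic,
heterochromatic, or other, from three evidence tracks:

* X-Y identity arcs stratify homologous sequence: a telomere-anchored arc at
  >= 99.9% mean identity is pseudoautosomal; arcs in [95, 99.9) are
  X-transposed; arcs in [70, 95) are ancestral gametolog sequence. The
  ancestral band is a nucleotide-identity proxy for what is really a
  gene-homology category, and is flagged as such in the output metadata.
* The ampliconic footprint comes from self dot-plot amplicon calls.
* Heterochromatin comes from satellite-monomer k-mer coverage.

Per-base precedence: heterochromatic > PAR > XTR > ancestral > ampliconic >
other. The output tiles the sequence exactly with non-overlapping intervals.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import amplicon as amp
from ._kmers import canonical_codes, kmer_codes, seq_kmers
from ._seq import encode
from .dotplot import self_dotplot
from .identity import HomologyArc, homology_arcs, sliding_identity
from .regions import RegionAnnotation, merge_annotations

PROFILE_COLUMNS = ["window_start", "satellite_fraction"]

# Precedence-ordered paint codes (higher paints over lower).
_OTHER, _AMPLICONIC, _ANCESTRAL, _XTR, _PAR, _HET = range(6)
_LABELS = {
    _OTHER: "other",
    _AMPLICONIC: "ampliconic",
    _ANCESTRAL: "ancestral",
    _XTR: "XTR",
    _PAR: "PAR",
    _HET: "heterochromatic",
}


@dataclass(frozen=True)
class ClassifyConfig:
    """Identity strata and heterochromatin defaults for classification.

    The 99.9 / 95 / 70 strata separate near-identical pseudoautosomal
    sequence, the ~99.5%-identical X-transposed stratum, and deeply diverged
    ancestral gametologs; only the 95% arc threshold is an established
    convention, the rest are this package's declared defaults.
    """

    par_min_identity: float = 99.9
    xtr_min_identity: float = 95.0
    ancestral_min_identity: float = 70.0
    window: int = 1_000
    min_par_len: int = 5_000  # telomeric arcs shorter than this are demoted to XTR
    het_k: int = 21
    het_window: int = 10_000
    het_min_fraction: float = 0.5
    dot_window: int = amp.DEFAULT_DOT_WINDOW


def satellite_profile(
    seq: str,
    monomers: Iterable[str] | Mapping[str, str],
    k: int = 21,
    window: int = 10_000,
) -> pd.DataFrame:
    """Fraction of each window covered by satellite-monomer k-mer hits.

    A base is satellite-covered when any k-mer overlapping it (either strand)
    occurs in the monomer k-mer set; monomers are treated circularly so an
    array's internal k-mers all hit regardless of phase.
    """
    if isinstance(monomers, Mapping):
        monomers = list(monomers.values())
    else:
        monomers = list(monomers)
    if not monomers:
        raise ValueError("empty monomer set")
    if any(len(m) < k for m in monomers):
        raise ValueError("k must not exceed the monomer length")
    if window < k:
        raise ValueError("window must be >= k")
    kset: list[np.ndarray] = []
    for m in monomers:
        kset.append(seq_kmers(m + m[: k - 1], k, canonical=True))  # circular
    members = np.unique(np.concatenate(kset))

    codes = encode(seq)
    packed, valid = kmer_codes(codes, k)
    canon = canonical_codes(packed, k)
    idx = np.searchsorted(members, canon)
    idx[idx == members.size] = 0
    hit = valid & (members[idx] == canon)

    cov = np.zeros(len(seq) + 1, dtype=np.int32)
    pos = np.flatnonzero(hit)
    np.add.at(cov, pos, 1)
    np.add.at(cov, pos + k, -1)
    covered = np.cumsum(cov[:-1]) > 0

    starts = np.arange(0, len(seq), window)
    fracs = [covered[s : s + window].mean() for s in starts]
    return pd.DataFrame({"window_start": starts.astype(int), "satellite_fraction": fracs})


def call_heterochromatin(
    profile: pd.DataFrame,
    min_fraction: float = 0.5,
    seq_name: str = "",
    window: int | None = None,
) -> list[RegionAnnotation]:
    """Maximal merged runs of windows with satellite_fraction >= min_fraction."""
    prof = profile.sort_values("window_start")
    starts = prof["window_start"].to_numpy()
    if window is None:
        window = int(np.diff(starts).min()) if len(starts) > 1 else 10_000
    regions: list[RegionAnnotation] = []
    for s, f in zip(starts, prof["satellite_fraction"]):
        if f >= min_fraction:
            s = int(s)
            if regions and regions[-1].end == s:
                regions[-1] = RegionAnnotation(seq_name, regions[-1].start, s + window, "heterochromatic")
            else:
                regions.append(RegionAnnotation(seq_name, s, s + window, "heterochromatic"))
    return regions


def _arc_code(arc: HomologyArc, seq_len: int, cfg: ClassifyConfig) -> int | None:
    mi = arc.mean_identity
    if mi >= cfg.par_min_identity:
        anchored = arc.start == 0 or arc.end >= seq_len - cfg.window
        if anchored and arc.end - arc.start >= cfg.min_par_len:
            return _PAR
        return _XTR  # near-identical but not a credible terminal PAR
    if mi >= cfg.xtr_min_identity:
        return _XTR
    if mi >= cfg.ancestral_min_identity:
        return _ANCESTRAL
    return None


def classify(
    y_seq: str,
    x_seq: str | None,
    identity_arcs: Sequence[HomologyArc],
    amplicon_footprint: Sequence[tuple[int, int]],
    het_regions: Sequence[RegionAnnotation],
    config: ClassifyConfig | None = None,
    seq_name: str = "Y",
) -> list[RegionAnnotation]:
    """Resolve evidence tracks into a non-overlapping five-class mosaic.

    ``identity_arcs`` should contain the arcs from each stratum threshold
    (see :func:`stratum_arcs`); overlapping arcs are resolved by precedence.
    The result tiles [0, len(y_seq)) exactly.
    """
    cfg = config or ClassifyConfig()
    n = len(y_seq)
    paint = np.full(n, _OTHER, dtype=np.uint8)

    def apply(start: int, end: int, code: int) -> None:
        s, e = max(0, int(start)), min(n, int(end))
        if e > s:
            sel = paint[s:e]
            np.maximum(sel, code, out=sel)

    for s, e in amplicon_footprint:
        apply(s, e, _AMPLICONIC)
    for code in (_ANCESTRAL, _XTR, _PAR):
        for arc in identity_arcs:
            if _arc_code(arc, n, cfg) == code:
                apply(arc.start, arc.end, code)
    for r in het_regions:
        apply(r.start, r.end, _HET)

    edges = np.flatnonzero(np.diff(paint)) + 1
    bounds = [0, *edges.tolist(), n]
    out = [
        RegionAnnotation(seq_name, bounds[i], bounds[i + 1], _LABELS[int(paint[bounds[i]])])
        for i in range(len(bounds) - 1)
    ]
    return merge_annotations(out)


def stratum_arcs(profile: pd.DataFrame, config: ClassifyConfig | None = None) -> list[HomologyArc]:
    """Arcs extracted per identity stratum, concatenated for classify().

    Each stratum's arcs are merged runs of windows whose identity falls in
    that stratum's band (e.g. [95, 99.9) for XTR), so an arc's mean identity
    is never blended across adjacent strata of different divergence.
    """
    cfg = config or ClassifyConfig()
    bands = [
        (cfg.par_min_identity, np.inf),
        (cfg.xtr_min_identity, cfg.par_min_identity),
        (cfg.ancestral_min_identity, cfg.xtr_min_identity),
    ]
    arcs: list[HomologyArc] = []
    for lo, hi in bands:
        banded = profile.copy()
        ident = banded["identity"].to_numpy(dtype=float, copy=True)
        ident[~((ident >= lo) & (ident < hi))] = np.nan
        banded["identity"] = ident
        # homology_arcs uses a strict > threshold; nudge so band-floor windows pass
        arcs.extend(homology_arcs(banded, threshold=lo - 1e-9, min_len=cfg.window))
    return arcs


def classify_chromosome(
    y_seq: str,
    x_seq: str,
    monomers: Iterable[str] | Mapping[str, str],
    config: ClassifyConfig | None = None,
    seq_name: str = "Y",
) -> list[RegionAnnotation]:
    """End-to-end pipeline: identity profile -> arcs, self dot plot ->
    amplicon footprint, satellite profile -> heterochromatin, then classify.

    The collinear X-Y comparison runs over the shared leading length of the
    two sequences.
    """
    cfg = config or ClassifyConfig()
    m = min(len(y_seq), len(x_seq))
    profile = sliding_identity(y_seq[:m], x_seq[:m], window=cfg.window, step=cfg.window)
    arcs = stratum_arcs(profile, cfg)

    sat = satellite_profile(y_seq, monomers, k=cfg.het_k, window=cfg.het_window)
    het = call_heterochromatin(sat, cfg.het_min_fraction, seq_name, window=cfg.het_window)
    het_ivs = [(r.start, r.end) for r in het]

    matches = self_dotplot(y_seq, cfg.dot_window)
    runs = amp.diagonal_runs(matches)
    pairs = amp.call_amplicons(y_seq, runs, mask=het_ivs)
    footprint = amp.amplicon_footprint(pairs)

    return classify(y_seq, x_seq, arcs, footprint, het, cfg, seq_name=seq_name)
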