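"""Synthetic sex-chromosome generator.

Builds X/Y sequence pairs whose architecture mirrors a rodent Y chromosome:
a near-identical terminal pseudoautosomal block, a ~99.5%-identical
X-transposed region, deeply diverged ancestral gametolog blocks, tandem
amplicon arrays with a fixed repeat-unit length, satellite heterochromatin
with asymmetric X/Y content, distance-decaying Hi-C mate pairs, and
male/female read sets that differ by Y-derived reads. Every preset is fully
deterministic given its seed, and each simulated genome carries an exact
truth annotation that tiles the sequence.

Divergence semantics
--------------------
For a linked (homologous) X/Y segment pair the X copy carries the shared
ancestor and the Y copy is substituted per site at exactly the segment's
``divergence``, so the realized pairwise mismatch probability equals the
stated rate. Within tandem arrays each copy is substituted from the master
unit at ``divergence / 2``, so the inter-copy pairwise divergence matches the
stated rate (two independent half-rate draws). Homology is gap-free:
substitutions only.
"""

from __future__ import annotations

import inspect
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import io as pio
from ._seq import mutate, random_dna
from .regions import RegionAnnotation, check_tiling, merge_annotations, write_bed

__all__ = [
    "SATELLITE_MONOMER",
    "SegmentSpec",
    "Blueprint",
    "SimulatedGenome",
    "Read",
    "PRESETS",
    "build_blueprint",
    "simulate_pair",
    "simulate_reads",
    "simulate_hic_pairs",
    "fragment",
]

# Synthetic 234-bp satellite monomer (fixed arbitrary sequence; only its
# repetitiveness matters, no homology to any real satellite intended).
SATELLITE_MONOMER = (
    "CTCCACTCTGATGTCATCAGTTGTTATGGTAGCAATCGTTGTGCTCGAGTTGGTGATAG"
    "AAGGCTGTTAGAAATGAATAGCTCACGGTGTTGTCGCAATTGAACCCGTAAGATATCTA"
    "TTAGCCGAATCTGCGTTGCGATACGCAGTAAGCATCCGATATGGCTAATAGTGAGGTAC"
    "GGGAAGACATAACAATAGAGTGATGACCGCGCCTCGGCGTTCCCCAGTCAGCTATCC"
)

GENOME_GC = 0.40  # background base composition
XTR_GC = 0.46  # elevated GC of the X-transposed region


@dataclass(frozen=True)
class SegmentSpec:
    """Declarative description of one synthetic sequence segment.

    ``unit_length_bp``/``copies`` describe tandem arrays (their product must
    equal ``length_bp``); ``satellite_monomer`` makes the segment an exact
    head-to-tail repeat of the named monomer.
    """

    label: str
    length_bp: int
    divergence: float = 0.0
    unit_length_bp: int | None = None
    copies: int | None = None
    satellite_monomer: str | None = None
    gc: float = GENOME_GC

    def __post_init__(self) -> None:
        if self.length_bp <= 0:
            raise ValueError("length_bp must be positive")
        if not 0.0 <= self.divergence <= 1.0:
            raise ValueError("divergence must lie in [0, 1]")
        if not 0.0 < self.gc < 1.0:
            raise ValueError("gc must lie in (0, 1)")
        if (self.unit_length_bp is None) != (self.copies is None):
            raise ValueError("unit_length_bp and copies must be given together")
        if self.unit_length_bp is not None:
            if self.unit_length_bp * self.copies != self.length_bp:
                raise ValueError("unit_length_bp * copies must equal length_bp")


@dataclass(frozen=True)
class Blueprint:
    """An ordered chromosome plan: segments are emitted telomere to telomere.

    ``homology_links`` pairs (y_index, x_index) that share a common ancestor
    copy; linked segments must have equal length (collinear, gap-free).
    """

    name: str
    y_segments: tuple[SegmentSpec, ...]
    x_segments: tuple[SegmentSpec, ...]
    homology_links: tuple[tuple[int, int], ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        for yi, xi in self.homology_links:
            if not (0 <= yi < len(self.y_segments) and 0 <= xi < len(self.x_segments)):
                raise ValueError(f"homology link ({yi},{xi}) out of range")
            if self.y_segments[yi].length_bp != self.x_segments[xi].length_bp:
                raise ValueError(f"linked segments ({yi},{xi}) differ in length")


@dataclass
class SimulatedGenome:
    """Named sequences plus an exact truth annotation and provenance."""

    sequences: dict[str, str]
    truth: list[RegionAnnotation]
    provenance: str

    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.sequences.items()}

    def write(self, outdir: str | Path, prefix: str = "genome") -> None:
        """Write a combined FASTA, one FASTA per sequence, and the truth BED."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        pio.write_fasta(self.sequences, outdir / f"{prefix}.fasta")
        for name, seq in self.sequences.items():
            pio.write_fasta({name: seq}, outdir / f"{prefix}.{name}.fasta")
        write_bed(self.truth, outdir / f"{prefix}.truth.bed")


@dataclass(frozen=True)
class Read:
    """A simulated read with its truth of origin."""

    name: str
    sequence: str
    source: str
    start: int


# ---------------------------------------------------------------------------
# presets

PAR_IDENTICAL_BLOCK_BP = 282_000  # block differing by ~5 nt between X and Y
PAR_FUNCTIONAL_BP = 300_000  # full pseudoautosomal length
PAR_DIVERGENCE = 5 / 282_000
SSTY_UNIT_BP = 85_000
SSTY_COPIES = 24  # ~2 Mb span / 85 kb unit


def _par_preset(
    seed: int = 0,
    npy_bp: int = 100_000,
    npy_divergence: float = 0.02,
) -> Blueprint:
    """Terminal 300-kb PAR (282-kb near-identical core preceded by 18 kb of
    telomere-proximal identical PAR) followed by 2%-divergent sex-specific
    sequence; both scaffolds span 400 kb from the telomere."""
    telo = PAR_FUNCTIONAL_BP - PAR_IDENTICAL_BLOCK_BP
    segs = (
        SegmentSpec("PAR", telo, 0.0),
        SegmentSpec("PAR", PAR_IDENTICAL_BLOCK_BP, PAR_DIVERGENCE),
        SegmentSpec("other", npy_bp, npy_divergence),
    )
    return Blueprint("PAR_PRESET", segs, segs, ((0, 0), (1, 1), (2, 2)), seed)


def _xtr_preset(seed: int = 0, het_bp: int = 308_000) -> Blueprint:
    """207-kb X-transposed block at 0.5% divergence with elevated GC; the X
    scaffold continues through a satellite block to span 515 kb."""
    y = (SegmentSpec("XTR", 207_000, 0.005, gc=XTR_GC),)
    x = (
        SegmentSpec("XTR", 207_000, 0.005, gc=XTR_GC),
        SegmentSpec("heterochromatic", het_bp, satellite_monomer="sat234"),
    )
    return Blueprint("XTR_PRESET", y, x, ((0, 0),), seed)


def _ssty_array_preset(seed: int = 0) -> Blueprint:
    """Compact tandem array: 24 copies of an 85-kb unit at 0.5% inter-copy divergence."""
    y = (
        SegmentSpec(
            "ampliconic",
            SSTY_UNIT_BP * SSTY_COPIES,
            0.005,
            unit_length_bp=SSTY_UNIT_BP,
            copies=SSTY_COPIES,
        ),
    )
    return Blueprint("SSTY_ARRAY_PRESET", y, (), (), seed)


def _largest_amplicon_preset(seed: int = 0) -> Blueprint:
    """3.5-Mb tandem amplicon at 99.5% inter-copy identity (70 x 50-kb units)."""
    y = (
        SegmentSpec("ampliconic", 3_500_000, 0.005, unit_length_bp=50_000, copies=70),
    )
    return Blueprint("LARGEST_AMPLICON_PRESET", y, (), (), seed)


def _med14_preset(seed: int = 0) -> Blueprint:
    """5-kb retrogene block pair at 93% identity (divergence 0.07)."""
    segs = (SegmentSpec("ancestral", 5_000, 0.07),)
    return Blueprint("MED14_PRESET", segs, segs, ((0, 0),), seed)


def _het_asymmetry_preset(seed: int = 0) -> Blueprint:
    """Satellite blocks with exactly 4-fold more heterochromatin on X than Y,
    aligned to 10-kb window boundaries."""
    y = (
        SegmentSpec("other", 50_000),
        SegmentSpec("heterochromatic", 40_000, satellite_monomer="sat234"),
        SegmentSpec("other", 10_000),
    )
    x = (
        SegmentSpec("other", 50_000),
        SegmentSpec("heterochromatic", 160_000, satellite_monomer="sat234"),
        SegmentSpec("other", 10_000),
    )
    return Blueprint("HET_ASYMMETRY_PRESET", y, x, (), seed)


def _chry_mosaic_preset(seed: int = 0) -> Blueprint:
    """Desk-scale full-architecture chromosome pair (320 kb each): XTR,
    ancestral gametolog, spacer, tandem amplicon array, satellite block,
    spacer, terminal PAR. Used for five-class segmentation recovery."""
    y = (
        SegmentSpec("XTR", 60_000, 0.005, gc=XTR_GC),
        SegmentSpec("ancestral", 30_000, 0.12),
        SegmentSpec("other", 30_000),
        SegmentSpec("ampliconic", 80_000, 0.002, unit_length_bp=20_000, copies=4),
        SegmentSpec("heterochromatic", 40_000, satellite_monomer="sat234"),
        SegmentSpec("other", 30_000),
        SegmentSpec("PAR", 50_000, PAR_DIVERGENCE),
    )
    x = (
        SegmentSpec("XTR", 60_000, 0.005, gc=XTR_GC),
        SegmentSpec("ancestral", 30_000, 0.12),
        SegmentSpec("other", 30_000),
        SegmentSpec("other", 80_000),
        SegmentSpec("heterochromatic", 40_000, satellite_monomer="sat234"),
        SegmentSpec("other", 30_000),
        SegmentSpec("PAR", 50_000, PAR_DIVERGENCE),
    )
    return Blueprint("CHRY_MOSAIC_PRESET", y, x, ((0, 0), (1, 1), (6, 6)), seed)


PRESETS: dict[str, Callable[..., Blueprint]] = {
    "PAR_PRESET": _par_preset,
    "XTR_PRESET": _xtr_preset,
    "SSTY_ARRAY_PRESET": _ssty_array_preset,
    "LARGEST_AMPLICON_PRESET": _largest_amplicon_preset,
    "MED14_PRESET": _med14_preset,
    "HET_ASYMMETRY_PRESET": _het_asymmetry_preset,
    "CHRY_MOSAIC_PRESET": _chry_mosaic_preset,
}

MONOMERS: dict[str, str] = {"sat234": SATELLITE_MONOMER}


def build_blueprint(preset_name: str, overrides: Mapping[str, object] | None = None) -> Blueprint:
    """Resolve a preset into a Blueprint, applying keyword overrides.

    Overrides address either the preset builder's parameters (e.g.
    ``npy_divergence`` for PAR_PRESET) or the blueprint ``seed``. Unknown
    preset names or unknown override keys raise ``ValueError``.
    """
    if preset_name not in PRESETS:
        raise ValueError(f"unknown preset {preset_name!r}; known: {sorted(PRESETS)}")
    overrides = dict(overrides or {})
    builder = PRESETS[preset_name]
    params = set(inspect.signature(builder).parameters)
    bad = set(overrides) - params
    if bad:
        raise ValueError(f"unknown override(s) for {preset_name}: {sorted(bad)}")
    return builder(**overrides)


# ---------------------------------------------------------------------------
# emission


def _segment_content(spec: SegmentSpec, rng: np.random.Generator) -> str:
    if spec.satellite_monomer is not None:
        monomer = MONOMERS[spec.satellite_monomer]
        reps = -(-spec.length_bp // len(monomer))
        return (monomer * reps)[: spec.length_bp]
    if spec.unit_length_bp is not None:
        master = random_dna(spec.unit_length_bp, spec.gc, rng)
        per_copy = spec.divergence / 2.0
        return "".join(mutate(master, per_copy, rng) for _ in range(spec.copies))
    return random_dna(spec.length_bp, spec.gc, rng)


def simulate_pair(bp: Blueprint) -> SimulatedGenome:
    """Emit the X and Y sequences of a blueprint with exact truth annotation.

    Same blueprint (including seed) always yields byte-identical output.
    """
    rng = np.random.default_rng(bp.seed)
    y_to_x = dict(bp.homology_links)

    y_parts: list[str] = []
    x_parts_by_index: dict[int, str] = {}
    for yi, spec in enumerate(bp.y_segments):
        ancestor = _segment_content(spec, rng)
        if yi in y_to_x:
            # X carries the ancestor; Y diverges at exactly spec.divergence
            x_parts_by_index[y_to_x[yi]] = ancestor
            y_parts.append(mutate(ancestor, spec.divergence, rng))
        else:
            y_parts.append(ancestor)

    x_parts: list[str] = []
    for xi, spec in enumerate(bp.x_segments):
        if xi in x_parts_by_index:
            x_parts.append(x_parts_by_index[xi])
        else:
            x_parts.append(_segment_content(spec, rng))

    sequences: dict[str, str] = {}
    truth: list[RegionAnnotation] = []
    for name, segs, parts in (("Y", bp.y_segments, y_parts), ("X", bp.x_segments, x_parts)):
        if not segs:
            continue
        sequences[name] = "".join(parts)
        pos = 0
        for spec in segs:
            truth.append(RegionAnnotation(name, pos, pos + spec.length_bp, spec.label))
            pos += spec.length_bp
    truth = merge_annotations(truth)
    genome = SimulatedGenome(sequences, truth, f"{bp.name}:seed={bp.seed}")
    check_tiling(genome.truth, genome.lengths())
    return genome


# ---------------------------------------------------------------------------
# reads


def simulate_reads(
    g: SimulatedGenome,
    coverage: float,
    read_length_bp: int,
    error_rate: float = 0.0,
    seed: int = 0,
) -> list[Read]:
    """Uniform-start substitution-error reads at the requested fold coverage.

    Per contig, ``round(coverage * length / read_length_bp)`` reads are drawn,
    so total bases match ``coverage x genome size`` to within one read per
    contig. Each read records its source contig (the truth label used by the
    subtraction benchmarks).
    """
    if coverage <= 0:
        raise ValueError("coverage must be positive")
    shortest = min(len(s) for s in g.sequences.values())
    if read_length_bp > shortest:
        raise ValueError("read_length_bp longer than shortest contig")
    rng = np.random.default_rng(seed)
    reads: list[Read] = []
    for name, seq in g.sequences.items():
        n = int(round(coverage * len(seq) / read_length_bp))
        starts = rng.integers(0, len(seq) - read_length_bp + 1, size=n)
        for i, s in enumerate(sorted(int(v) for v in starts)):
            frag = seq[s : s + read_length_bp]
            if error_rate > 0:
                frag = mutate(frag, error_rate, rng)
            reads.append(Read(f"{name}_read{i}", frag, name, s))
    return reads


# ---------------------------------------------------------------------------
# Hi-C mate pairs


def _sample_separations(
    rng: np.random.Generator, n: int, d_min: float, d_max: float, alpha: float
) -> np.ndarray:
    """Sample pair separations under a d^-alpha contact density.

    The d^-alpha law applies to site pairs (the polymer contact model), so on
    a scaffold of length L the marginal separation density is proportional to
    (L - d) * d^-alpha: inverse-CDF draws from d^-alpha are thinned by
    rejection with probability (L - d) / L.
    """

    def propose(m: int) -> np.ndarray:
        u = rng.random(m)
        if abs(alpha - 1.0) < 1e-12:
            d = d_min * (d_max / d_min) ** u
        else:
            a = 1.0 - alpha
            d = (d_min**a + u * (d_max**a - d_min**a)) ** (1.0 / a)
        return np.minimum(d.astype(np.int64), int(d_max) - 1)

    out = np.empty(0, dtype=np.int64)
    while out.size < n:
        d = propose(2 * (n - out.size) + 16)
        accept = rng.random(d.size) < (d_max - d) / d_max
        out = np.concatenate([out, d[accept]])
    return out[:n]


def simulate_hic_pairs(
    g: SimulatedGenome,
    n_pairs: int,
    decay_exponent: float = 1.0,
    seed: int = 0,
    partition: Mapping[str, Sequence[int]] | None = None,
    min_separation: int = 1_000,
) -> pd.DataFrame:
    """Mate pairs whose separation on the unfragmented scaffold decays as
    d^-decay_exponent, re-expressed in fragmented-contig coordinates.

    ``partition`` maps scaffold name to sorted internal breakpoints; fragments
    are named ``{scaffold}.c{i}``. Without a partition, coordinates stay on
    the intact scaffolds (all pairs intra-contig for a single-contig genome).
    """
    if n_pairs <= 0:
        raise ValueError("n_pairs must be positive")
    scaffolds = [(name, len(seq)) for name, seq in g.sequences.items() if len(seq) > min_separation]
    if not scaffolds:
        raise ValueError("genome has no scaffold longer than the minimum pair separation")
    rng = np.random.default_rng(seed)
    lengths = np.array([L for _, L in scaffolds], dtype=float)
    alloc = rng.multinomial(n_pairs, lengths / lengths.sum())

    rows: list[tuple[str, int, str, int]] = []
    for (name, L), n in zip(scaffolds, alloc):
        if n == 0:
            continue
        d = _sample_separations(rng, n, float(min_separation), float(L), decay_exponent)
        pos_a = rng.integers(0, L - d)
        pos_b = pos_a + d
        swap = rng.random(n) < 0.5
        a = np.where(swap, pos_b, pos_a)
        b = np.where(swap, pos_a, pos_b)
        if partition and name in partition:
            bps = np.asarray(sorted(partition[name]), dtype=np.int64)
            starts = np.concatenate(([0], bps))
            ia = np.searchsorted(bps, a, side="right")
            ib = np.searchsorted(bps, b, side="right")
            for j in range(n):
                rows.append(
                    (
                        f"{name}.c{int(ia[j])}",
                        int(a[j] - starts[ia[j]]),
                        f"{name}.c{int(ib[j])}",
                        int(b[j] - starts[ib[j]]),
                    )
                )
        else:
            rows.extend((name, int(a[j]), name, int(b[j])) for j in range(n))
    return pd.DataFrame(rows, columns=pio.PAIR_COLUMNS)


def fragment(
    sequences: Mapping[str, str], partition: Mapping[str, Sequence[int]]
) -> dict[str, str]:
    """Cut scaffolds at the partition breakpoints into named contigs."""
    out: dict[str, str] = {}
    for name, seq in sequences.items():
        bps = sorted(partition.get(name, []))
        edges = [0, *bps, len(seq)]
        for i in range(len(edges) - 1):
            out[f"{name}.c{i}"] = seq[edges[i] : edges[i + 1]]
    return out
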