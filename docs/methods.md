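# Methods

This note documents the models behind `parscope`'s synthetic generator and
the conventions and defaults of each analysis, including the choices made
where the underlying procedures are conventionally left unspecified.

## Synthetic X/Y generator

### What it emulates

Each preset is an ordered plan of segments (telomere to telomere) for a Y
scaffold and, where applicable, an X counterpart:

| preset | architecture |
| --- | --- |
| `PAR_PRESET` | 400-kb X/Y pair: 18-kb identical telomeric PAR + 282-kb PAR core diverging at 5/282,000 per site + 100-kb sex-specific remainder at 2% divergence |
| `XTR_PRESET` | 207-kb X-transposed block at 0.5% divergence, GC 0.46; the X scaffold continues through a 308-kb satellite block to 515 kb |
| `MED14_PRESET` | 5-kb retrogene block pair at 7% divergence (93% identity) |
| `SSTY_ARRAY_PRESET` | tandem array of 24 × 85-kb units, 0.5% inter-copy divergence (2.04 Mb) |
| `LARGEST_AMPLICON_PRESET` | tandem amplicon of 70 × 50-kb units at 99.5% inter-copy identity (3.5 Mb); the 50-kb unit is a structural placeholder, only the span and identity are meaningful |
| `HET_ASYMMETRY_PRESET` | satellite blocks of 160 kb (X) vs 40 kb (Y) — exactly 4-fold — aligned to 10-kb window boundaries |
| `CHRY_MOSAIC_PRESET` | 320-kb full-architecture pair: XTR (60 kb, d = 0.005, GC 0.46), ancestral gametolog (30 kb, d = 0.12), spacer, amplicon array (4 × 20 kb, inter-copy d = 0.002), satellite (40 kb), spacer, terminal PAR (50 kb, d = 5/282,000) |

The PAR preset reconciles the two published figures for the region — a
300-kb functional PAR and a 282-kb near-identical block — by placing the
282-kb core inside the 300-kb PAR with the remaining 18 kb as identical
telomere-proximal PAR sequence.

The mosaic preset's parameters are desk-scale choices fixed once: segment
lengths are multiples of the 1-kb profile window and the 10-kb satellite
window so truth boundaries coincide with analysis windows; its array
divergence (0.002) makes 250-bp dot windows match between copies with
probability ≈ 0.61, which keeps diagonal chains intact at the default 2-kb
gap limit.

### Divergence model

Homology is gap-free: substitutions only, no indels or rearrangements (the
X–Y comparisons this package performs are collinear identity profiles).
For a linked X/Y segment, the X copy carries the common ancestor and the Y
copy is substituted per site, independently, at exactly the segment's
divergence rate — so the realized pairwise mismatch count is
Binomial(L, d) with the stated d (e.g. expectation 5 over the 282-kb PAR
core). Within tandem arrays, each copy is substituted from the master unit
at d/2, making the *inter-copy* pairwise divergence ≈ d (two independent
half-rate draws; coincident same-site hits are negligible at these rates).

Base composition is i.i.d. at the segment's GC target (genome background
0.40; X-transposed segments 0.46 to emulate the elevated GC of a formerly
recombining region — the direction of that elevation is the modeled
phenomenon, the magnitude is a choice). Satellite segments are exact
head-to-tail repeats of a packaged 234-bp synthetic monomer (an arbitrary
fixed sequence; only its repetitiveness matters).

### Reads and Hi-C pairs

Reads have uniform start positions per contig, substitution errors only, no
quality strings, and carry their source contig as truth.
`round(coverage · L / read_length)` reads per contig keeps total bases
within one read of the requested coverage.

Hi-C mate pairs follow the polymer contact model: the probability of a
contact between two sites at separation d decays as d^-α (default α = 1,
d ≥ 1 kb), so the marginal separation density on a scaffold of length L is
∝ (L − d) · d^-α, sampled by inverse CDF plus rejection. (Sampling the
*marginal* of d as d^-α instead would over-weight separations near L by
1/(L − d) and concentrate them in the two terminal flank windows, producing
a spurious end-to-end link as strong as true junction links.) Positions are
then re-expressed in fragmented-contig coordinates given a partition.
No ligation chemistry, duplicates, or noise pairs are modeled.

### What passing tests do and do not show

The generator has no indels, no interspersed repeats, no assembly gaps and
no sequencing-error k-mer noise beyond the substitution model. Recovery
results (PAB within one window, ≥ 99% per-base class accuracy, 9/10
scaffold orderings, ≥ 0.95 subtraction precision/recall) therefore
demonstrate correctness of the algorithms under their stated assumptions,
not robustness to alignment gaps, segmental duplication polymorphism, or
base-calling error profiles of real instruments.

## Analysis conventions and defaults

**Dot plots.** Exact-match windows, default step = window (matching the
"100% identity in a w-bp window" convention of published figures); the
original scripts' step and strand handling are unpublished, so these are
declared defaults, not inferences. Reverse-complement matches are found by
canonical keying; self plots report matches once with i < j and exclude the
diagonal; palindromic window pairs (which match both ways) are reported
once, as forward. Windows containing non-ACGT characters never match.

**Identity profile.** Window 1 kb, step 1 kb. Windows with zero comparable
bases are missing (NaN), not 0%. The PAB rule — first run of ≥ 5
consecutive windows below 99.9% — is this package's convention (no explicit
published threshold exists); 99.9%/5 separates a ~99.998%-identical PAR
from a 99.5%-identical X-transposed stratum with a large margin in both
directions. The boundary is reported as the first sex-specific window start
(0-based).

**Recombination rate.** `50 / (L / 1e6)` cM/Mb from the obligate male
crossover; reported values are conventionally truncated (300 kb → 166).

**Amplicons.** Dot window 250 bp, diagonal chaining with along-diagonal
gap ≤ 2,000 bp and offset tolerance 500 bp, then *base-level ungapped*
identity recomputed over the chained spans (whether published amplicon
identities are gapped is unstated; ungapped is consistent with the gap-free
inputs here). Thresholds: span > 10 kb and identity > 99% — both strict
inequalities. Heterochromatic intervals mask amplicon calls (amplicons are
by definition euchromatic): a run is dropped when satellite regions cover
more than half of either of its intervals.

**Tandem arrays.** Offsets of forward dots are binned at 1 kb; among bins
with at least half the maximal count (the unit diagonal family and its
multiples), the smallest bin's modal exact offset is the unit. The array
span is the merged i-side extent of unit-offset dots extended by one unit
at the trailing edge (the last copy only pairs leftward);
`n_units = round(span / unit)`.

**Five-class segmentation.** Arcs are extracted per identity band —
[99.9, 100], [95, 99.9), [70, 95) — so an arc's mean identity is never
blended across strata of different divergence. A PAR call additionally
requires telomere anchoring (the arc touches either sequence end) and
≥ 5 kb of length; shorter or interior near-identical arcs are demoted to
XTR. Precedence per base: heterochromatic > PAR > XTR > ancestral >
ampliconic > other; output intervals tile the sequence exactly. The
70–95% "ancestral" band is a nucleotide-identity proxy for what is properly
a gene-homology class. Heterochromatin: satellite k-mer coverage with
k = 21, 10-kb windows, called at ≥ 0.5 coverage fraction (all declared
defaults). Monomers are treated circularly so array phase does not matter.

**GC statistics.** 1-kb windows tiled from each region's start; windows
straddling region boundaries are dropped (conservative). The elevation test
is a two-sided label permutation on the difference of class means
(10,000 permutations by default) with the add-one correction
`p = (1 + #{|perm| ≥ |obs|}) / (n_perm + 1)`; no published test statistic
exists for this comparison, so the permutation test is this package's
choice. Class summaries use a percentile bootstrap (nominal 95%).

**Hi-C linkage.** k = 32 unique-k-mer index (canonical, global count
exactly 1); pair filtering requires *both* read footprints (default span
100 bp) to overlap a unique k-mer — the stricter of the two possible
readings of "overlapping these positions" — with `either_end` as the
alternative. Flank windows are 50 kb; contigs shorter than 2 × flank have
overlapping windows whose shared positions count toward both flanks, and
the contig is flagged ambiguous-orientation. Ordering is greedy: the
highest-count unused flank pair joining different path components is
accepted; ties break lexicographically by flank id; isolated contigs append
in input order. No pair deduplication is performed. Recovery benchmarks use
a 500-kb scaffold cut into five 100-kb contigs with 10,000 simulated pairs.

**Subtraction.** k = 31 (odd, so no canonical palindrome ambiguity),
female-set count floor 2 (suppresses singleton error k-mers), Y-candidate
threshold: ≥ 0.5 of the read's canonical k-mers absent. All three are
declared conventions — no published parameters exist for this step. Reads
shorter than k get a missing absent-fraction and are not Y-candidates.
Reads from Y regions shared with X (PAR, X-transposed) classify as not-Y by
construction: the target is Y-specific sequence.

## Problem sizes

Benchmarks run at the generator's native scales: 282-kb/207-kb/5-kb block
pairs (20–200 seeds for mean identities), the 2.04-Mb and 3.5-Mb arrays at
full length, 320-kb mosaic chromosomes (10 seeds), five 100-kb contigs with
10,000 Hi-C pairs (10 seeds), 90-kb genomes at 20× coverage for
subtraction (10 seeds), and 500 replicates for permutation-test
calibration. These sizes make the full suite run in well under a minute of
compute per suite on a single CPU while keeping every statistical check at
the precision its tolerance requires.

## Known limitations

* No indel or rearrangement handling anywhere: profiles, amplicon identity
  and the PAB are meaningful only for collinear inputs.
* The ancestral class is an identity-band proxy; real gametolog annotation
  is gene-based.
* `order_and_orient` infers simple paths only; it will not detect
  misassemblies, circular structures, or ambiguous branching joins (ties
  are broken deterministically rather than reported).
* The subtraction module classifies reads by k-mer absence only; coverage-
  or alignment-based refinement is out of scope.
* GC comparisons are within-genome; no cross-species orthology machinery is
  included.
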