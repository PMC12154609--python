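"""Generator contracts: preset structure, determinism, truth tiling,
realized divergence, read and mate-pair simulation."""

import numpy as np
import pytest

import parscope as ps
from parscope.regions import check_tiling
from parscope.synthetic import PRESETS, Blueprint, SegmentSpec, SimulatedGenome


class TestBlueprints:
    def test_par_preset_has_282kb_linked_core(self):
        bp = ps.build_blueprint("PAR_PRESET", {})
        assert any(s.length_bp == 282_000 and s.label == "PAR" for s in bp.y_segments)
        # every PAR segment is linked to its X counterpart
        linked_y = {yi for yi, _xi in bp.homology_links}
        assert all(i in linked_y for i, s in enumerate(bp.y_segments) if s.label == "PAR")

    def test_seed_override_is_orthogonal_to_structure(self):
        a = ps.build_blueprint("PAR_PRESET", {})
        b = ps.build_blueprint("PAR_PRESET", {"seed": 7})
        assert a.y_segments == b.y_segments and a.x_segments == b.x_segments
        assert b.seed == 7

    def test_ssty_array_geometry(self):
        bp = ps.build_blueprint("SSTY_ARRAY_PRESET", {})
        (seg,) = bp.y_segments
        assert seg.unit_length_bp * seg.copies == seg.length_bp == 2_040_000

    def test_presets_are_deterministic_objects(self):
        for name in PRESETS:
            assert ps.build_blueprint(name, {}) == ps.build_blueprint(name, {})

    def test_unknown_preset_and_bad_override_raise(self):
        with pytest.raises(ValueError):
            ps.build_blueprint("NO_SUCH_PRESET", {})
        with pytest.raises(ValueError):
            ps.build_blueprint("PAR_PRESET", {"definitely_not_a_field": 3})

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(label="x", length_bp=0),
            dict(label="x", length_bp=100, divergence=1.5),
            dict(label="x", length_bp=100, gc=0.0),
            dict(label="x", length_bp=100, unit_length_bp=30, copies=3),
        ],
    )
    def test_segment_invariants(self, kwargs):
        with pytest.raises(ValueError):
            SegmentSpec(**kwargs)

    def test_linked_segments_must_match_length(self):
        y = (SegmentSpec("PAR", 100),)
        x = (SegmentSpec("PAR", 200),)
        with pytest.raises(ValueError):
            Blueprint("bad", y, x, ((0, 0),))


class TestSimulatePair:
    @pytest.mark.parametrize("preset", sorted(PRESETS))
    def test_truth_tiles_every_sequence(self, preset):
        g = ps.simulate_pair(ps.build_blueprint(preset, {"seed": 3}))
        check_tiling(g.truth, g.lengths())  # raises on gap/overlap
        assert all(r.label in ps.SEQUENCE_CLASSES for r in g.truth)

    def test_same_seed_byte_identical(self):
        bp = ps.build_blueprint("CHRY_MOSAIC_PRESET", {"seed": 11})
        g1, g2 = ps.simulate_pair(bp), ps.simulate_pair(bp)
        assert g1.sequences == g2.sequences
        assert g1.truth == g2.truth

    def test_zero_divergence_blocks_identical(self):
        segs = (SegmentSpec("PAR", 10_000, 0.0),)
        g = ps.simulate_pair(Blueprint("t", segs, segs, ((0, 0),), seed=1))
        assert g.sequences["Y"] == g.sequences["X"]

    def test_xtr_realized_divergence_within_3se(self):
        # binomial(L=207 kb, p=0.005): check the mean mismatch fraction over 20 seeds
        p, L, n_seeds = 0.005, 207_000, 20
        fracs = []
        for seed in range(n_seeds):
            g = ps.simulate_pair(ps.build_blueprint("XTR_PRESET", {"seed": seed}))
            d = ps.count_differences(g.sequences["Y"], g.sequences["X"][:L])
            fracs.append(d / L)
        se = np.sqrt(p * (1 - p) / (L * n_seeds))
        assert abs(np.mean(fracs) - p) < 3 * se

    def test_het_asymmetry_truth_ratio(self):
        g = ps.simulate_pair(ps.build_blueprint("HET_ASYMMETRY_PRESET", {}))
        het = {
            name: sum(r.length for r in g.truth if r.seq_name == name and r.label == "heterochromatic")
            for name in ("X", "Y")
        }
        assert het["X"] == 4 * het["Y"]


class TestSimulateReads:
    def _genome(self, rng, n=10_000):
        return SimulatedGenome({"c": ps.random_dna(n, 0.4, rng)}, [], "t")

    def test_read_count_matches_coverage(self, rng):
        reads = ps.simulate_reads(self._genome(rng), coverage=1, read_length_bp=1_000)
        assert abs(len(reads) - 10) <= 1

    def test_error_free_reads_are_exact_substrings(self, rng):
        g = self._genome(rng)
        for r in ps.simulate_reads(g, 2, 500, error_rate=0.0, seed=5):
            assert g.sequences[r.source][r.start : r.start + 500] == r.sequence

    def test_read_longer_than_contig_raises(self, rng):
        with pytest.raises(ValueError):
            ps.simulate_reads(self._genome(rng, 100), 1, 1_000)

    def test_y_read_fraction_tracks_genome_composition(self):
        sizes = {"autosome": 40_000, "X": 30_000, "Y": 20_000}
        fracs = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            g = SimulatedGenome({n: ps.random_dna(L, 0.4, rng) for n, L in sizes.items()}, [], "m")
            reads = ps.simulate_reads(g, 20, 1_000, seed=seed)
            fracs.append(np.mean([r.source == "Y" for r in reads]))
        expected = sizes["Y"] / sum(sizes.values())
        assert abs(np.mean(fracs) - expected) < 0.02


class TestHicPairs:
    def _genome(self, rng, n=200_000):
        return SimulatedGenome({"scaf": ps.random_dna(n, 0.4, rng)}, [], "t")

    def test_single_contig_all_intra(self, rng):
        pairs = ps.simulate_hic_pairs(self._genome(rng), 500, 1.0, seed=1)
        assert (pairs["contig_a"] == "scaf").all() and (pairs["contig_b"] == "scaf").all()

    def test_positions_lie_within_contigs(self, rng):
        g = self._genome(rng)
        part = {"scaf": [50_000, 100_000, 150_000]}
        pairs = ps.simulate_hic_pairs(g, 2_000, 1.0, seed=2, partition=part)
        lengths = {name: len(s) for name, s in ps.fragment(g.sequences, part).items()}
        for side in ("a", "b"):
            upper = pairs[f"contig_{side}"].map(lengths)
            assert (pairs[f"pos_{side}"] >= 0).all() and (pairs[f"pos_{side}"] < upper).all()

    def test_adjacent_contigs_share_more_links_than_distant(self, rng):
        g = self._genome(rng, 500_000)
        part = {"scaf": [100_000, 200_000, 300_000, 400_000]}
        pairs = ps.simulate_hic_pairs(g, 10_000, 1.0, seed=3, partition=part)
        idx = lambda c: int(c.rsplit("c", 1)[1])
        gaps = (pairs["contig_a"].map(idx) - pairs["contig_b"].map(idx)).abs()
        counts = gaps.value_counts()
        assert counts.get(1, 0) > counts.get(2, 0) > counts.get(4, 0)

    def test_zero_pairs_forbidden(self, rng):
        with pytest.raises(ValueError):
            ps.simulate_hic_pairs(self._genome(rng), 0, 1.0)
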