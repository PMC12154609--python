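"""Unique-k-mer indexing, mate-pair filtering, flank link counting, and
greedy contig ordering."""

import numpy as np
import pandas as pd
import pytest

import parscope as ps
from parscope.hic import (
    LinkMatrix,
    filter_pairs,
    flank_link_matrix,
    order_and_orient,
    unique_kmers,
)
from parscope.io import PAIR_COLUMNS
from parscope.regions import RegionAnnotation
from parscope.synthetic import SimulatedGenome


def pair_df(rows):
    return pd.DataFrame(rows, columns=PAIR_COLUMNS)


def brute_unique(contigs, k):
    from parscope import revcomp

    counts = {}
    for name, seq in contigs.items():
        for p in range(len(seq) - k + 1):
            km = seq[p : p + k]
            if set(km) - set("ACGT"):
                continue
            canon = min(km, revcomp(km))
            counts.setdefault(canon, []).append((name, p))
    out = {name: [] for name in contigs}
    for canon, hits in counts.items():
        if len(hits) == 1:
            out[hits[0][0]].append(hits[0][1])
    return {name: sorted(v) for name, v in out.items()}


class TestUniqueKmers:
    def test_homopolymer_has_no_unique_32mers(self):
        uks = unique_kmers({"a": "A" * 100}, 32)
        assert uks.n_unique() == 0

    def test_duplicated_contigs_kill_all_kmers(self, random_10kb):
        uks = unique_kmers({"a": random_10kb, "b": random_10kb}, 32)
        assert uks.n_unique() == 0

    def test_random_contig_nearly_all_unique(self, random_10kb):
        uks = unique_kmers({"a": random_10kb}, 32)
        assert uks.n_unique() >= 9_960  # 9,969 starts, collisions negligible

    def test_agrees_with_bruteforce(self, rng):
        contigs = {
            "a": ps.random_dna(800, 0.4, rng),
            "b": ps.random_dna(500, 0.4, rng),
        }
        contigs["c"] = contigs["a"][100:300] + ps.random_dna(200, 0.4, rng)
        uks = unique_kmers(contigs, 32)
        expected = brute_unique(contigs, 32)
        for name in contigs:
            assert uks.positions[name].tolist() == expected[name]


class TestFilterPairs:
    def test_empty_unique_set_removes_everything(self, random_10kb):
        uks = unique_kmers({"a": random_10kb, "b": random_10kb}, 32)
        pairs = pair_df([("a", 10, "b", 20)])
        assert len(filter_pairs(pairs, uks, 100)) == 0

    def test_all_unique_genome_keeps_everything(self, random_10kb):
        uks = unique_kmers({"a": random_10kb}, 32)
        pairs = pair_df([("a", 10, "a", 500), ("a", 9_000, "a", 100)])
        out = filter_pairs(pairs, uks, 100)
        assert out.equals(pairs)

    def test_end_in_duplicated_block_removed(self, rng):
        block = ps.random_dna(2_000, 0.4, rng)
        contigs = {
            "a": block + ps.random_dna(3_000, 0.4, rng),
            "b": block + ps.random_dna(3_000, 0.4, rng),
        }
        uks = unique_kmers(contigs, 32)
        pairs = pair_df([("a", 500, "b", 4_000), ("a", 3_000, "b", 4_000)])
        out = filter_pairs(pairs, uks, 100)
        assert len(out) == 1 and out.iloc[0]["pos_a"] == 3_000
        # either-end mode retains the half-unique pair
        assert len(filter_pairs(pairs, uks, 100, either_end=True)) == 2


class TestFlankLinkMatrix:
    def test_mid_contig_positions_not_counted(self):
        pairs = pair_df([("a", 150_000, "b", 10_000)])  # a-end outside both flanks
        m = flank_link_matrix(pairs, {"a": 300_000, "b": 100_000}, flank=50_000)
        assert m.counts.to_numpy().sum() == 0

    def test_counts_symmetric_and_diagonal_free(self):
        pairs = pair_df([("a", 10, "b", 10), ("b", 99_000, "a", 260_000)])
        m = flank_link_matrix(pairs, {"a": 300_000, "b": 100_000}, flank=50_000)
        c = m.counts.to_numpy()
        assert (c == c.T).all()
        assert (np.diag(c) == 0).all()
        assert m.counts.loc["a.L", "b.L"] == 1
        assert m.counts.loc["a.R", "b.R"] == 1

    def test_short_contig_flagged_ambiguous(self):
        m = flank_link_matrix(pair_df([]), {"tiny": 60_000}, flank=50_000)
        assert m.ambiguous == {"tiny"}


class TestOrderAndOrient:
    def test_single_contig_forward(self):
        m = flank_link_matrix(pair_df([]), {"solo": 200_000}, flank=50_000)
        assert order_and_orient(m).order == [("solo", "+")]

    def test_equal_count_tie_broken_by_flank_id(self):
        counts = pd.DataFrame(
            0, index=["a.L", "a.R", "b.L", "b.R"], columns=["a.L", "a.R", "b.L", "b.R"]
        )
        counts.loc["a.L", "b.L"] = counts.loc["b.L", "a.L"] = 5
        counts.loc["a.R", "b.R"] = counts.loc["b.R", "a.R"] = 5
        m = LinkMatrix(counts, 50_000, ["a", "b"])
        # lexicographically first tied edge (a.L, b.L) wins: enter a at R
        assert order_and_orient(m).order == [("a", "-"), ("b", "+")]

    def test_isolated_contigs_appended_in_input_order(self):
        m = flank_link_matrix(pair_df([]), {"z": 200_000, "a": 200_000}, flank=50_000)
        assert order_and_orient(m).order == [("z", "+"), ("a", "+")]

    @pytest.mark.parametrize("seed", range(10))
    def test_scaffold_recovery_from_simulated_pairs(self, seed):
        rng = np.random.default_rng(seed)
        scaffold = ps.random_dna(500_000, 0.4, rng)
        g = SimulatedGenome(
            {"scaf": scaffold}, [RegionAnnotation("scaf", 0, 500_000, "other")], "t"
        )
        part = {"scaf": [100_000, 200_000, 300_000, 400_000]}
        pairs = ps.simulate_hic_pairs(g, 10_000, 1.0, seed=seed, partition=part)
        contigs = ps.fragment(g.sequences, part)
        uks = unique_kmers(contigs, 32)
        kept = filter_pairs(pairs, uks, 100)
        assert len(kept) == len(pairs)  # random scaffold: everything is unique
        m = flank_link_matrix(kept, {n: len(s) for n, s in contigs.items()}, 50_000)
        got = order_and_orient(m).order
        truth = [(f"scaf.c{i}", "+") for i in range(5)]
        reverse = [(c, "-" if o == "+" else "+") for c, o in reversed(truth)]
        assert got in (truth, reverse)
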