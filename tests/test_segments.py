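"""Segment tiling, counting, normalization, classification, clustering."""

import numpy as np
import pandas as pd
import pytest

from medipseq import segments as seg
from medipseq.genome_io import GeneModel, GenomeModel

from conftest import make_blocks


class TestTileGenome:
    def test_last_segment_may_be_short(self):
        tiles = seg.tile_genome({"chr1": 250_000}, window=100_000)
        assert tiles[["start", "end"]].values.tolist() == [
            [0, 100_000], [100_000, 200_000], [200_000, 250_000]
        ]

    def test_exact_single_segment(self):
        tiles = seg.tile_genome({"chr1": 100_000}, window=100_000)
        assert len(tiles) == 1

    def test_zero_window_rejected(self):
        with pytest.raises(ValueError):
            seg.tile_genome({"chr1": 100_000}, window=0)


class TestCountBlocks:
    def setup_method(self):
        self.tiles = seg.tile_genome({"chr1": 300_000}, window=100_000)

    def test_midpoint_assigns_to_single_segment(self):
        blocks = make_blocks([("chr1", 99_950, 100_200)])  # midpoint 100075
        counts = seg.count_blocks(blocks, self.tiles, "midpoint")
        assert counts.tolist() == [0, 1, 0]

    def test_overlap_counts_in_both_segments(self):
        blocks = make_blocks([("chr1", 99_950, 100_200)])
        counts = seg.count_blocks(blocks, self.tiles, "overlap")
        assert counts.tolist() == [1, 1, 0]

    def test_midpoint_conserves_counts(self):
        rng = np.random.default_rng(3)
        starts = rng.integers(0, 299_000, size=1_000)
        blocks = make_blocks([("chr1", int(s), int(s) + 250) for s in starts])
        counts = seg.count_blocks(blocks, self.tiles, "midpoint")
        assert counts.sum() == 1_000

    def test_matches_bruteforce(self):
        rng = np.random.default_rng(4)
        starts = rng.integers(0, 299_000, size=500)
        blocks = make_blocks([("chr1", int(s), int(s) + 250) for s in starts])
        counts = seg.count_blocks(blocks, self.tiles, "midpoint")
        brute = np.zeros(3, dtype=int)
        for s in starts:
            mid = (s + s + 250) // 2
            brute[min(mid // 100_000, 2)] += 1
        assert counts.tolist() == brute.tolist()


class TestNormalize:
    def test_per_ten_million_scaling(self):
        assert seg.normalize(np.array([500]), 5_000_000)[0] == 1000.0

    def test_identity_at_ten_million_total(self):
        assert seg.normalize(np.array([123]), 10_000_000)[0] == 123.0

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            seg.normalize(np.array([1]), 0)

    def test_sum_property(self):
        rng = np.random.default_rng(5)
        raw = rng.integers(0, 100, size=50)
        total = 200_000
        norm = seg.normalize(raw, total)
        assert norm.sum() == pytest.approx(1e7 * raw.sum() / total, rel=1e-9)


class TestRatioAndAmplification:
    def test_ratio_without_pseudocount(self):
        r = seg.medip_input_ratio(np.array([200.0]), np.array([100.0]), pseudocount=0)
        assert r[0] == 2.0

    def test_pseudocount_floors_zero_over_zero(self):
        r = seg.medip_input_ratio(np.array([0.0]), np.array([0.0]), pseudocount=1)
        assert r[0] == 1.0

    def test_no_input_falls_back_to_medip(self):
        r = seg.medip_input_ratio(np.array([42.0]), None)
        assert r[0] == 42.0

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            seg.medip_input_ratio(np.array([-1.0]), np.array([1.0]))

    def test_amplified_flag_is_strictly_greater(self):
        inp = np.array([100.0] * 10 + [300.0, 350.0])  # median 100
        flags = seg.detect_amplified(inp, fold=3.0)
        assert not flags[10]  # exactly 3x median: not flagged
        assert flags[11]

    def test_all_zero_input_warns_no_flags(self):
        flags = seg.detect_amplified(np.zeros(5))
        assert not flags.any()


class TestClassifySegments:
    def test_fold_rule_examples(self):
        cls = seg.classify_segments(
            np.array([4.0, 1.0, 1.5]), np.array([1.9, 2.0, 1.0]), fold=2.0
        )
        assert cls.tolist() == ["hyper", "hypo", "nd"]

    def test_boundary_is_inclusive(self):
        cls = seg.classify_segments(np.array([2.0]), np.array([1.0]))
        assert cls[0] == "hyper"

    def test_fold_at_most_one_rejected(self):
        with pytest.raises(ValueError):
            seg.classify_segments(np.array([1.0]), np.array([1.0]), fold=1.0)

    def test_masked_segments_forced_nd(self):
        cls = seg.classify_segments(
            np.array([4.0]), np.array([1.0]), masked=np.array([True])
        )
        assert cls[0] == "nd"

    def test_antisymmetric_under_swap(self):
        rng = np.random.default_rng(6)
        a = rng.uniform(0.1, 10, size=200)
        b = rng.uniform(0.1, 10, size=200)
        forward = seg.classify_segments(a, b)
        backward = seg.classify_segments(b, a)
        swap = {"hyper": "hypo", "hypo": "hyper", "nd": "nd"}
        assert [swap[c] for c in forward] == backward.tolist()

    def test_monotone_in_sample_ratio(self):
        rng = np.random.default_rng(7)
        ref = rng.uniform(0.1, 10, size=100)
        s = rng.uniform(0.1, 10, size=100)
        rank = {"hypo": 0, "nd": 1, "hyper": 2}
        before = seg.classify_segments(s, ref)
        after = seg.classify_segments(s * 1.5, ref)
        assert all(rank[a] >= rank[b] for a, b in zip(after, before))


class TestAnnotateSegments:
    def test_counts_cpgs_and_tss(self):
        tiles = seg.tile_genome({"chr1": 200_000}, window=100_000)
        sites = pd.DataFrame({"chrom": ["chr1"] * 3, "pos": [10, 20, 150_000]})
        genes = [
            GeneModel("g1", "chr1", "+", [(50_000, 50_200), (160_000, 160_200)]),
        ]
        out = seg.annotate_segments(tiles, sites, genes)
        assert out["n_cpg"].tolist() == [2, 1]
        # gene body spans both segments but the TSS sits in the first
        assert out["n_genes"].tolist() == [1, 0]

    def test_empty_segment(self):
        tiles = seg.tile_genome({"chr1": 100_000}, window=100_000)
        out = seg.annotate_segments(
            tiles, pd.DataFrame(columns=["chrom", "pos"]), []
        )
        assert out.loc[0, ["n_cpg", "n_genes"]].tolist() == [0, 0]


class TestClusterSamples:
    def test_identical_profiles_merge_at_zero(self):
        profile = np.random.default_rng(8).uniform(0, 100, size=50)
        mat = pd.DataFrame({"A": profile, "B": profile, "C": profile[::-1]})
        linkage, labels = seg.cluster_samples(mat)
        assert labels == ["A", "B", "C"]
        assert linkage[0, 2] == pytest.approx(0.0, abs=1e-12)

    def test_scaling_is_distance_zero_after_log_in_correlation(self):
        # Pearson correlation is invariant to affine maps of the log profile
        profile = np.exp(np.random.default_rng(9).uniform(0, 5, size=100))
        mat = pd.DataFrame({"A": profile, "B": profile})
        linkage, _ = seg.cluster_samples(mat)
        assert linkage[0, 2] == pytest.approx(0.0, abs=1e-9)

    def test_planted_pattern_merges_first(self):
        rng = np.random.default_rng(10)
        base = rng.uniform(10, 100, size=200)
        pattern = rng.uniform(0.25, 4.0, size=200)
        mat = pd.DataFrame(
            {
                "A": base * pattern * rng.lognormal(0, 0.05, 200),
                "B": base * pattern * rng.lognormal(0, 0.05, 200),
                "C": base * rng.lognormal(0, 0.05, 200),
            }
        )
        linkage, labels = seg.cluster_samples(mat)
        first = sorted(labels[int(i)] for i in linkage[0, :2])
        assert first == ["A", "B"]

    def test_newick_roundtrip_topology(self, tmp_path):
        from io import StringIO

        from Bio import Phylo

        rng = np.random.default_rng(11)
        mat = pd.DataFrame(rng.uniform(0, 50, size=(100, 4)), columns=list("ABCD"))
        linkage, labels = seg.cluster_samples(mat)
        tree = Phylo.read(StringIO(seg.linkage_to_newick(linkage, labels)), "newick")
        assert sorted(t.name for t in tree.get_terminals()) == labels
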