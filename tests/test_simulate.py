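"""Generator properties: determinism, degenerate guards, sampling laws."""

import numpy as np
import pandas as pd
import pytest

from medipseq import simulate as sm
from medipseq.cpg import cpg_oe
from medipseq.genome_io import enumerate_cpg_sites


def tiny_config(seed=5, **overrides):
    defaults = dict(
        chromosome_lengths={"chrA": 500_000},
        n_genes_per_chrom=10,
        n_clusters_per_chrom=1,
        genes_per_cluster=3,
        n_intergenic_islands_per_chrom=4,
        n_satellites_per_chrom=2,
        n_repeats_per_chrom=8,
        samples=(
            sm.SampleSpec("N", "normal", "epithelial", has_input=True, n_fragments=5_000),
            sm.SampleSpec("C", "cancer", "epithelial", has_input=True, n_fragments=5_000),
        ),
        amplifications=(),
        epithelial_group=("N",),
        mesenchymal_group=(),
    )
    defaults.update(overrides)
    return sm.SimulationConfig(seed=seed, **defaults)


class TestDeterminism:
    def test_same_seed_identical_outputs(self):
        cfg = tiny_config(seed=11)
        a = sm.simulate_study(cfg)
        b = sm.simulate_study(cfg)
        assert a.genome.sequences == b.genome.sequences
        for sample in a.medip_reads:
            pd.testing.assert_frame_equal(a.medip_reads[sample], b.medip_reads[sample])
        for sample in a.input_reads:
            pd.testing.assert_frame_equal(a.input_reads[sample], b.input_reads[sample])
        pd.testing.assert_frame_equal(a.truth.island_table, b.truth.island_table)

    def test_different_seed_differs(self):
        a = sm.simulate_study(tiny_config(seed=1))
        b = sm.simulate_study(tiny_config(seed=2))
        assert a.genome.sequences != b.genome.sequences


class TestGenomeComposition:
    def test_islands_mostly_above_oe_threshold(self):
        study = sm.simulate_study(tiny_config(seed=6))
        genome = study.genome
        sites = enumerate_cpg_sites(genome)
        oe = cpg_oe(genome, sites)
        flags = study.truth.site_flags
        island_oe = oe[(flags["region"] == "island").to_numpy()]
        background_oe = oe[(flags["region"] == "background").to_numpy()]
        assert (island_oe > 0.6).mean() > 0.8
        assert (background_oe < 0.6).mean() > 0.8

    def test_zero_island_gc_yields_no_rich_islands(self):
        cfg = tiny_config(seed=7, island_gc=0.02)
        study = sm.simulate_study(cfg)
        sites = enumerate_cpg_sites(study.genome)
        oe = cpg_oe(study.genome, sites)
        flags = study.truth.site_flags
        island_sites = (flags["region"] == "island").to_numpy()
        # nearly no island CpGs exist at all, and none are CpG-rich islands
        assert island_sites.sum() < 0.05 * len(sites)

    def test_gene_models_valid_and_on_genome(self):
        study = sm.simulate_study(tiny_config(seed=8))
        lengths = study.genome.lengths
        for gene in study.sim_genome.genes:
            assert gene.end <= lengths[gene.chrom]
            assert gene.exons == sorted(gene.exons)


class TestMethylationTruth:
    def test_switch_fraction_zero_treated_equals_control(self):
        cfg = tiny_config(
            seed=9,
            emt_switch_fraction=0.0,
            emt_background_rate=0.0,
            samples=(
                sm.SampleSpec("N", "normal", "epithelial", n_fragments=2_000),
                sm.SampleSpec("ctrl", "emt_control", "epithelial", n_fragments=2_000),
                sm.SampleSpec("trt", "emt_treated", "epithelial", n_fragments=2_000),
            ),
        )
        study = sm.simulate_study(cfg)
        np.testing.assert_array_equal(
            study.truth.site_probs["ctrl"], study.truth.site_probs["trt"]
        )

    def test_background_factor_one_cancer_equals_normal_outside_islands(self):
        cfg = tiny_config(
            seed=10,
            cancer_background_factor=1.0,
            pmd_fraction=0.0,
            pmd_private_fraction=0.0,
        )
        study = sm.simulate_study(cfg)
        flags = study.truth.site_flags
        bg = (flags["region"] == "background").to_numpy()
        np.testing.assert_array_equal(
            study.truth.site_probs["N"][bg], study.truth.site_probs["C"][bg]
        )

    def test_planted_hyper_regions_are_gene_related_islands(self):
        study = sm.simulate_study(tiny_config(seed=12))
        flags = study.truth.site_flags
        planted = flags["planted_cancer_hyper"].to_numpy()
        assert planted.any()
        assert (flags.loc[planted, "region"] == "island").all()
        assert flags.loc[planted, "gene_related_island"].all()

    def test_probabilities_lie_in_unit_interval(self):
        study = sm.simulate_study(tiny_config(seed=13))
        for prob in study.truth.site_probs.values():
            assert prob.min() >= 0.0 and prob.max() <= 1.0


class TestMedipSampling:
    def test_fully_unmethylated_genome_rejected(self):
        cfg = tiny_config(
            seed=14,
            background_level=0.0,
            shore_level=0.0,
            satellite_normal_level=0.0,
            island_methylated_level=0.0,
        )
        rng = np.random.default_rng(0)
        sim = sm.generate_genome(cfg, rng)
        truth = sm.assign_methylation(cfg, sim, rng)
        with pytest.raises(ValueError, match="no methylated CpG"):
            sm.simulate_medip_reads(truth, sim, cfg.samples[0], cfg, rng)

    def test_weight_ratio_reflected_in_fragment_counts(self):
        """Two methylated regions with 3:1 methylated-CpG weight draw
        fragments at a 3:1 ratio within binomial noise."""
        cfg = tiny_config(seed=15)
        rng = np.random.default_rng(1)
        sim = sm.generate_genome(cfg, rng)
        truth = sm.assign_methylation(cfg, sim, rng)
        sample = cfg.samples[0]
        # overwrite the realized methylome: two disjoint blocks of sites
        states = np.zeros(len(truth.cpg_sites), dtype=bool)
        pos = truth.cpg_sites["pos"].to_numpy()
        region_a = (pos >= 50_000) & (pos < 60_000)
        region_b = (pos >= 300_000) & (pos < 310_000)
        idx_a = np.flatnonzero(region_a)
        idx_b = np.flatnonzero(region_b)
        n_b = max(len(idx_b) // 3, 20)
        assert len(idx_a) >= 3 * n_b
        states[idx_a[: 3 * n_b]] = True  # weight 3x
        states[idx_b[:n_b]] = True
        truth.site_states[sample.sample_id] = states
        n = 10_000
        spec = sm.SampleSpec(sample.sample_id, "normal", "epithelial", n_fragments=n)
        reads = sm.simulate_medip_reads(truth, sim, spec, cfg, rng)
        mid = (reads["start"] + reads["end"]) // 2
        in_a = ((mid >= 49_000) & (mid < 61_000)).sum()
        in_b = ((mid >= 299_000) & (mid < 311_000)).sum()
        p = 0.75
        se = np.sqrt(n * p * (1 - p))
        assert abs(in_a - p * (in_a + in_b)) < 3 * se

    def test_single_methylated_region_draws_all_fragments(self):
        cfg = tiny_config(seed=16)
        rng = np.random.default_rng(2)
        sim = sm.generate_genome(cfg, rng)
        truth = sm.assign_methylation(cfg, sim, rng)
        states = np.zeros(len(truth.cpg_sites), dtype=bool)
        pos = truth.cpg_sites["pos"].to_numpy()
        sel = (pos >= 100_000) & (pos < 102_000)
        states[sel] = True
        truth.site_states["N"] = states
        spec = sm.SampleSpec("N", "normal", "epithelial", n_fragments=500)
        reads = sm.simulate_medip_reads(truth, sim, spec, cfg, rng)
        assert (reads["start"] >= 99_000).all() and (reads["end"] <= 103_000).all()


class TestInputSampling:
    def test_uniform_without_amplification(self):
        from scipy.stats import chisquare

        cfg = tiny_config(seed=17)
        rng = np.random.default_rng(3)
        sim = sm.generate_genome(cfg, rng)
        spec = sm.SampleSpec("N", "normal", "epithelial", n_fragments=20_000)
        reads = sm.simulate_input_reads(sim, spec, cfg, rng)
        mid = ((reads["start"] + reads["end"]) // 2).to_numpy()
        counts, _ = np.histogram(mid, bins=10, range=(0, 500_000))
        stat, p = chisquare(counts)
        assert p > 1e-4  # no gross departure from uniformity

    def test_planted_amplification_density_ratio(self):
        cfg = tiny_config(
            seed=18,
            amplifications=(sm.AmplificationSpec("chrA", 200_000, 300_000, 5.0, ("N",)),),
        )
        rng = np.random.default_rng(4)
        sim = sm.generate_genome(cfg, rng)
        spec = sm.SampleSpec("N", "normal", "epithelial", n_fragments=50_000)
        reads = sm.simulate_input_reads(sim, spec, cfg, rng)
        mid = ((reads["start"] + reads["end"]) // 2).to_numpy()
        inside = ((mid >= 200_000) & (mid < 300_000)).mean() / 0.2
        outside = ((mid < 200_000) | (mid >= 300_000)).mean() / 0.8
        assert inside / outside == pytest.approx(5.0, rel=0.1)


class TestConfigValidation:
    def test_probability_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="background_level"):
            tiny_config(background_level=1.5)

    def test_fragment_range_must_cover_read_length(self):
        with pytest.raises(ValueError, match="fragment length"):
            tiny_config(fragment_length_range=(10, 20))

    def test_unknown_scenario_rejected(self):
        with pytest.raises(ValueError, match="scenario"):
            tiny_config(scenario="bogus")
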