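"""TSS binning and methylation-expression correlation."""

import numpy as np
import pandas as pd
import pytest

from medipseq import expression as ex
from medipseq.genome_io import GeneModel

from conftest import make_blocks


@pytest.fixture
def genes():
    return [
        GeneModel("gP", "chr1", "+", [(50_000, 50_200), (60_000, 60_200)]),
        GeneModel("gM", "chr1", "-", [(40_000, 40_200), (49_800, 50_001)]),  # TSS 50_000
    ]


class TestBinTssRegions:
    def test_plus_strand_first_downstream_bin(self, genes):
        bins = ex.bin_tss_regions(genes, {"chr1": 200_000})
        row = bins[(bins.gene_id == "gP") & (bins.bin == 1)].iloc[0]
        assert (row.start, row.end) == (50_000, 51_000)

    def test_minus_strand_bins_flip(self, genes):
        bins = ex.bin_tss_regions(genes, {"chr1": 200_000})
        row = bins[(bins.gene_id == "gM") & (bins.bin == 1)].iloc[0]
        assert (row.start, row.end) == (49_001, 50_001)
        up = bins[(bins.gene_id == "gM") & (bins.bin == -1)].iloc[0]
        assert (up.start, up.end) == (50_001, 51_001)

    def test_out_of_genome_bins_marked_missing(self):
        g = GeneModel("gE", "chr1", "+", [(3_000, 3_200)])
        bins = ex.bin_tss_regions([g], {"chr1": 200_000})
        assert bins[bins.bin == -10].iloc[0].missing
        assert not bins[bins.bin == -1].iloc[0].missing

    def test_twenty_bins_per_gene(self, genes):
        bins = ex.bin_tss_regions(genes, {"chr1": 200_000})
        assert bins.groupby("gene_id").size().tolist() == [20, 20]


class TestBinCounts:
    def test_counts_match_bruteforce(self, genes):
        rng = np.random.default_rng(30)
        starts = rng.integers(39_000, 61_000, size=400)
        blocks = make_blocks([("chr1", int(s), int(s) + 250) for s in starts])
        bins = ex.bin_tss_regions(genes, {"chr1": 200_000})
        counts = ex.bin_counts({"S": blocks}, bins)
        mids = (blocks["start"] + blocks["end"]) // 2
        for _, row in bins.iterrows():
            brute = ((mids >= row.start) & (mids < row.end)).sum() * 1e7 / len(blocks)
            got = counts.loc[
                (counts.gene_id == row.gene_id) & (counts.bin == row.bin), "S"
            ].iloc[0]
            assert got == pytest.approx(brute)

    def test_empty_sample_gives_zeros(self, genes):
        bins = ex.bin_tss_regions(genes, {"chr1": 200_000})
        counts = ex.bin_counts({"S": make_blocks([])}, bins)
        assert (counts["S"].fillna(0) == 0).all()


def _expr(genes, values_by_sample):
    return pd.DataFrame(values_by_sample, index=[g.gene_id for g in genes]).rename_axis(
        "gene_id"
    )


class TestCorrelateGeneBins:
    def _binned(self, genes, per_sample):
        bins = ex.bin_tss_regions(genes, {"chr1": 200_000})
        out = bins.copy()
        for sample, values in per_sample.items():
            out[sample] = values
        return out

    def test_perfect_proportionality_gives_r_one(self, genes):
        samples = [f"S{i}" for i in range(6)]
        expr_vals = np.array([1.0, 2.0, 4.0, 8.0, 16.0, 32.0])
        bins = ex.bin_tss_regions(genes, {"chr1": 200_000})
        binned = bins.copy()
        for s, v in zip(samples, expr_vals):
            binned[s] = v  # methylation exactly proportional to expression
        expr = _expr(genes, {s: [v, v] for s, v in zip(samples, expr_vals)})
        out = ex.correlate_gene_bins(binned, expr, threshold=0.5)
        assert np.allclose(out["r"], 1.0)
        assert (out["label"] == "positive").all()

    def test_constant_expression_gives_none(self, genes):
        samples = [f"S{i}" for i in range(4)]
        binned = self._binned(genes, {s: float(i) for i, s in enumerate(samples)})
        expr = _expr(genes, {s: [5.0, 5.0] for s in samples})
        out = ex.correlate_gene_bins(binned, expr)
        assert out["r"].isna().all()
        assert (out["label"] == "none").all()

    def test_fewer_than_four_samples_rejected(self, genes):
        binned = self._binned(genes, {"A": 1.0, "B": 2.0})
        expr = _expr(genes, {"A": [1, 1], "B": [2, 2]})
        with pytest.raises(ValueError, match=">= 4 samples"):
            ex.correlate_gene_bins(binned, expr)

    def test_spearman_invariant_under_monotone_rescaling(self, genes):
        rng = np.random.default_rng(31)
        samples = [f"S{i}" for i in range(6)]
        bins = ex.bin_tss_regions(genes, {"chr1": 200_000})
        binned = bins.copy()
        for s in samples:
            binned[s] = rng.uniform(0, 100, size=len(bins))
        base = {s: rng.uniform(1, 50, size=2) for s in samples}
        out1 = ex.correlate_gene_bins(binned, _expr(genes, base), method="spearman")
        cubed = {s: v**3 / 10 for s, v in base.items()}  # monotone transform
        out2 = ex.correlate_gene_bins(binned, _expr(genes, cubed), method="spearman")
        np.testing.assert_allclose(out1["r"], out2["r"], rtol=1e-12)


class TestFractionByDistance:
    def test_all_positive_bin(self):
        corr = pd.DataFrame(
            {"gene_id": ["a", "b"], "bin": [1, 1], "r": [0.9, 0.8],
             "label": ["positive", "positive"]}
        )
        out = ex.fraction_by_distance(corr)
        assert out.iloc[0].fraction_positive == 1.0
        assert out.iloc[0].fraction_negative == 0.0

    def test_empty_bin_reported_missing(self):
        corr = pd.DataFrame(
            {"gene_id": ["a"], "bin": [2], "r": [np.nan], "label": ["none"]}
        )
        out = ex.fraction_by_distance(corr)
        assert np.isnan(out.iloc[0].fraction_positive)

    def test_fractions_sum_at_most_one(self, default_study):
        result = default_study.correlation_tables()
        assert result is not None
        _, fractions = result
        defined = fractions.dropna()
        assert (
            defined["fraction_positive"] + defined["fraction_negative"] <= 1.0 + 1e-12
        ).all()


class TestPlantedCouplingRecovery:
    def test_signature_promoter_genes_mostly_negative_at_tss(self, default_study):
        """Genes whose promoter island differs between cell phenotypes have
        expression anti-correlated with promoter-bin methylation."""
        correlations, _ = default_study.correlation_tables()
        isl = default_study.truth.island_table
        coupled = set(
            isl.loc[
                isl["category"].isin(["epithelial_sig", "mesenchymal_sig"])
                & isl["gene_id"].notna(),
                "gene_id",
            ]
        )
        at_tss = correlations[
            correlations["gene_id"].isin(coupled) & correlations["bin"].isin([-1, 1])
        ]
        labeled = at_tss[at_tss["r"].notna()]
        assert len(labeled) > 20
        assert (labeled["label"] == "negative").mean() >= 0.8

    def test_distal_positive_proximal_negative_trend(self, default_study):
        """Gene-body methylation is coupled positively, promoter-island
        methylation negatively: fractions separate by distance."""
        _, fractions = default_study.correlation_tables()
        fr = fractions.set_index("bin")
        proximal_neg = fr.loc[[-1, 1], "fraction_negative"].mean()
        distal_neg = fr.loc[[-8, -9, 8, 9], "fraction_negative"].mean()
        proximal_pos = fr.loc[[-1, 1], "fraction_positive"].mean()
        distal_pos = fr.loc[[5, 6, 7, 8], "fraction_positive"].mean()
        assert proximal_neg > distal_neg
        assert distal_pos > proximal_pos
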