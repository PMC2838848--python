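"""Input/output layer: parsing, validation, CpG enumeration, round-trips."""

import numpy as np
import pandas as pd
import pytest

from medipseq import genome_io
from medipseq.genome_io import FormatError, GeneModel, GenomeModel


def write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestLoadGenome:
    def test_reads_back_single_record(self, tmp_path):
        g = genome_io.load_genome(write(tmp_path, "g.fa", ">chr1\nACGT\n"))
        assert g.names == ["chr1"]
        assert g.lengths == {"chr1": 4}

    def test_lowercase_is_uppercased(self, tmp_path):
        g = genome_io.load_genome(write(tmp_path, "g.fa", ">chr1\nacgt\n"))
        assert g.sequences["chr1"] == "ACGT"

    def test_duplicate_names_rejected(self, tmp_path):
        p = write(tmp_path, "g.fa", ">chr1\nACGT\n>chr1\nTTTT\n")
        with pytest.raises(FormatError, match="duplicate"):
            genome_io.load_genome(p)

    def test_empty_file_rejected(self, tmp_path):
        with pytest.raises(FormatError, match="no FASTA records"):
            genome_io.load_genome(write(tmp_path, "g.fa", ""))

    def test_non_iupac_bases_rejected(self):
        with pytest.raises(FormatError, match="non-IUPAC"):
            GenomeModel({"chr1": "ACGX"})

    def test_roundtrip(self, tmp_path, toy_genome):
        path = tmp_path / "out.fa"
        genome_io.write_genome(toy_genome, path)
        again = genome_io.load_genome(path)
        assert again.sequences == toy_genome.sequences


class TestEnumerateCpgSites:
    @pytest.mark.parametrize(
        "seq,expected",
        [
            ("ACGCGT", [1, 3]),
            ("AAAA", []),
            ("CGCGCG", [0, 2, 4]),
            ("NCGN", [1]),
        ],
    )
    def test_hand_enumeration(self, seq, expected):
        sites = genome_io.enumerate_cpg_sites(GenomeModel({"chr1": seq}))
        assert sites["pos"].tolist() == expected

    def test_matches_bruteforce_scan(self, toy_genome):
        seq = toy_genome.sequences["chr1"]
        brute = [i for i in range(len(seq) - 1) if seq[i : i + 2] == "CG"]
        sites = genome_io.enumerate_cpg_sites(toy_genome)
        assert sites["pos"].tolist() == brute
        # every reported site really is a CG dinucleotide
        assert all(seq[p : p + 2] == "CG" for p in sites["pos"])

    def test_sorted_by_chrom_then_pos(self):
        g = GenomeModel({"chr2": "CGCG", "chr1": "ACG"})
        sites = genome_io.enumerate_cpg_sites(g)
        # chromosome order follows the genome's declared order
        assert sites["chrom"].tolist() == ["chr2", "chr2", "chr1"]
        assert sites.groupby("chrom", sort=False)["pos"].apply(
            lambda s: s.is_monotonic_increasing
        ).all()


READS_6COL = "chr1\t100\t136\t+\t30\t.\nchr1\t200\t236\t-\t10\t.\nchr1\t300\t336\t+\t5\t.\n"


class TestLoadReads:
    def test_mapq_threshold_is_inclusive(self, tmp_path):
        # retention rule is mapq >= 10: the mapq-5 read is removed
        reads = genome_io.load_reads(write(tmp_path, "r.tsv", READS_6COL), "S")
        assert len(reads) == 2
        assert reads["mapq"].tolist() == [30, 10]
        assert reads.attrs["n_dropped_mapq"] == 1

    def test_empty_file_gives_empty_frame(self, tmp_path):
        reads = genome_io.load_reads(write(tmp_path, "r.tsv", ""), "S")
        assert reads.empty

    def test_undeclared_chromosome_rejected(self, tmp_path):
        genome = GenomeModel({"chr1": "A" * 1000})
        p = write(tmp_path, "r.tsv", "chrX\t1\t37\t+\t30\t.\n")
        with pytest.raises(FormatError, match="chrX"):
            genome_io.load_reads(p, "S", genome=genome)

    def test_negative_coordinates_rejected(self, tmp_path):
        p = write(tmp_path, "r.tsv", "chr1\t-5\t37\t+\t30\t.\n")
        with pytest.raises(FormatError, match="negative"):
            genome_io.load_reads(p, "S")

    def test_order_preserving_and_idempotent(self, tmp_path):
        p = write(tmp_path, "r.tsv", READS_6COL)
        once = genome_io.load_reads(p, "S", min_mapq=10)
        assert once["start"].tolist() == [100, 200]  # original order kept
        refiltered = once[once["mapq"] >= 10].reset_index(drop=True)
        pd.testing.assert_frame_equal(once, refiltered)

    def test_paired_roundtrip(self, tmp_path):
        reads = pd.DataFrame(
            [
                {
                    "chrom": "chr1", "start": 100, "end": 136, "strand": "+",
                    "mapq": 42, "pair_id": "p0", "mate_chrom": "chr1",
                    "mate_start": 400.0, "mate_end": 436.0, "mate_strand": "-",
                },
                {
                    "chrom": "chr1", "start": 50, "end": 86, "strand": "-",
                    "mapq": 13, "pair_id": None, "mate_chrom": None,
                    "mate_start": np.nan, "mate_end": np.nan, "mate_strand": None,
                },
            ]
        )
        path = tmp_path / "rt.tsv"
        genome_io.write_reads(reads, path)
        again = genome_io.load_reads(path, "S", min_mapq=0)
        assert again["pair_id"].tolist() == ["p0", None]
        assert again.loc[0, "mate_start"] == 400
        assert pd.isna(again.loc[1, "mate_start"])

    def test_sam_ingestion_reads_mapq_and_span(self, tmp_path):
        sam = (
            "@HD\tVN:1.6\n@SQ\tSN:chr1\tLN:1000\n"
            "r1\t0\tchr1\t101\t60\t36M\t*\t0\t0\t" + "A" * 36 + "\t*\n"
            "r2\t16\tchr1\t201\t5\t36M\t*\t0\t0\t" + "A" * 36 + "\t*\n"
        )
        reads = genome_io.load_reads(write(tmp_path, "r.sam", sam), "S", min_mapq=10)
        assert len(reads) == 1
        assert reads.loc[0, "start"] == 100  # SAM is 1-based
        assert reads.loc[0, "end"] == 136


class TestGeneTable:
    def test_minus_strand_tss_is_rightmost_end_minus_one(self, tmp_path):
        bed = "chr1\t1000\t5000\tgeneA\t0\t-\t1000\t5000\t0\t2\t200,300\t0,3700\n"
        genes = genome_io.load_gene_table(write(tmp_path, "g.bed", bed))
        assert genes[0].tss == 4999
        assert genes[0].exons == [(1000, 1200), (4700, 5000)]
        assert genes[0].introns == [(1200, 4700)]

    def test_overlapping_exons_rejected(self, tmp_path):
        bed = "chr1\t0\t500\tgeneA\t0\t+\t0\t500\t0\t2\t300,300\t0,200\n"
        with pytest.raises(FormatError, match="overlapping"):
            genome_io.load_gene_table(write(tmp_path, "g.bed", bed))

    def test_roundtrip(self, tmp_path):
        genes = [
            GeneModel("g1", "chr1", "+", [(100, 300), (800, 1000)]),
            GeneModel("g2", "chr1", "-", [(2000, 2200)]),
        ]
        path = tmp_path / "genes.bed12"
        genome_io.write_gene_table(genes, path)
        again = genome_io.load_gene_table(path)
        assert [(g.gene_id, g.tss, g.exons) for g in again] == [
            (g.gene_id, g.tss, g.exons) for g in genes
        ]


class TestTracksAndExpression:
    def test_track_interval_past_chromosome_rejected(self, tmp_path):
        genome = GenomeModel({"chr1": "A" * 100})
        p = write(tmp_path, "t.bed", "chr1\t50\t200\n")
        with pytest.raises(FormatError, match="past end"):
            genome_io.load_track(p, "cgi", genome)

    def test_malformed_row_reports_line_number(self, tmp_path):
        p = write(tmp_path, "t.bed", "chr1\t0\t10\nchr1\tfoo\t20\n")
        with pytest.raises(FormatError, match=":2"):
            genome_io.load_track(p, "cgi")

    def test_expression_missing_sample_rejected(self, tmp_path):
        p = write(tmp_path, "e.tsv", "gene_id\tA\tB\ng1\t1.0\t2.0\n")
        with pytest.raises(FormatError, match="missing declared sample"):
            genome_io.load_expression(p, required_samples=["A", "C"])

    def test_expression_duplicate_genes_rejected(self, tmp_path):
        p = write(tmp_path, "e.tsv", "gene_id\tA\ng1\t1.0\ng1\t2.0\n")
        with pytest.raises(FormatError, match="duplicate"):
            genome_io.load_expression(p)

    def test_table_roundtrip(self, tmp_path):
        df = pd.DataFrame({"chrom": ["chr1"], "start": [5], "ratio": [1.25]})
        path = tmp_path / "t.tsv"
        genome_io.write_table(df, path)
        pd.testing.assert_frame_equal(genome_io.read_table(path), df)
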