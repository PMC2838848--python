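"""Shared fixtures: session-scoped simulated studies and small helpers.

The default study is generated once per session at the standard toy scale
(2 x 5 Mb, 80k fragments/library) and shared by the recovery and
acceptance tests; unit tests use tiny constructed inputs instead.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from medipseq import pipeline
from medipseq.genome_io import GenomeModel


@pytest.fixture(scope="session")
def default_study() -> pipeline.Study:
    return pipeline.Study.from_config({"seed": 1, "simulate": {}})


@pytest.fixture(scope="session")
def default_cpg_table(default_study) -> pd.DataFrame:
    return default_study.cpg_table()


@pytest.fixture(scope="session")
def default_segments(default_study) -> pd.DataFrame:
    return default_study.segment_table()


@pytest.fixture(scope="session")
def default_emt(default_study, default_cpg_table):
    return default_study.emt_tables(default_cpg_table)


@pytest.fixture(scope="session")
def recovery_study() -> pipeline.Study:
    """Scenario planting only exact 4-fold segment hypomethylation."""
    return pipeline.Study.from_config(
        {"seed": 1, "simulate": {"scenario": "segment_recovery"}}
    )


@pytest.fixture(scope="session")
def small_sim_cfg() -> dict:
    """A fast, reduced-scale simulation config for pipeline smoke tests."""
    return {
        "seed": 7,
        "simulate": {
            "chromosome_lengths": {"chrA": 600_000, "chrB": 400_000},
            "n_genes_per_chrom": 12,
            "n_clusters_per_chrom": 1,
            "genes_per_cluster": 4,
            "n_intergenic_islands_per_chrom": 5,
            "n_satellites_per_chrom": 2,
            "n_repeats_per_chrom": 10,
            "samples": None,  # replaced below
        },
    }


def _small_samples():
    from medipseq.simulate import SampleSpec

    return (
        SampleSpec("HMEC", "normal", "epithelial", has_input=True, n_fragments=8_000),
        SampleSpec(
            "MCF7", "cancer", "epithelial", has_input=True, has_expression=True,
            n_fragments=8_000,
        ),
        SampleSpec(
            "T47D", "cancer", "epithelial", has_expression=True, n_fragments=8_000
        ),
        SampleSpec(
            "SKBR3", "cancer", "epithelial", has_expression=True, n_fragments=8_000
        ),
        SampleSpec(
            "Hs578T", "cancer", "mesenchymal", has_expression=True, n_fragments=8_000
        ),
        SampleSpec(
            "MDAMB231", "cancer", "mesenchymal", has_expression=True, n_fragments=8_000
        ),
        SampleSpec("HMC18", "cancer", "mesenchymal", n_fragments=8_000),
        SampleSpec("MCF7_EMT_control", "emt_control", "epithelial", n_fragments=8_000),
        SampleSpec("MCF7_EMT_treated", "emt_treated", "epithelial", n_fragments=8_000),
    )


@pytest.fixture(scope="session")
def small_study(small_sim_cfg) -> pipeline.Study:
    from medipseq.simulate import AmplificationSpec

    cfg = {
        "seed": small_sim_cfg["seed"],
        "simulate": {
            **{k: v for k, v in small_sim_cfg["simulate"].items() if k != "samples"},
            "samples": _small_samples(),
            "amplifications": (
                AmplificationSpec("chrB", 100_000, 200_000, 5.0, ("MCF7",)),
            ),
        },
    }
    return pipeline.Study.from_config(cfg)


@pytest.fixture
def toy_genome() -> GenomeModel:
    rng = np.random.default_rng(42)
    seq = "".join(rng.choice(list("ACGT"), size=10_000))
    return GenomeModel({"chr1": seq})


def make_blocks(rows, sample_id="S"):
    """Blocks frame from (chrom, start, end[, origin]) tuples."""
    recs = []
    for row in rows:
        chrom, start, end = row[:3]
        origin = row[3] if len(row) > 3 else "singleton"
        recs.append(
            {
                "chrom": chrom,
                "start": start,
                "end": end,
                "sample_id": sample_id,
                "origin": origin,
                "anchor": start,
                "strand": "+",
            }
        )
    columns = ["chrom", "start", "end", "sample_id", "origin", "anchor", "strand"]
    return pd.DataFrame(recs, columns=columns)
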