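"""Ground-truthed simulator for comparative MeDIP-seq studies.

The generator emulates the structure the analysis is designed to detect:

* a toy genome with a CpG-depleted background, CpG-rich islands placed at
  a configurable fraction of gene promoters (plus intergenic islands),
  low-methylation island shores, ordinary repeats and a CpG-rich
  satellite-like repeat family;
* gene models (three exons, two introns) including gene-dense cluster
  loci where cancer hypermethylation is planted;
* per-cell-type region-level methylation: a highly methylated CpG-poor
  background in normal cells, unmethylated islands except for
  epithelial/mesenchymal signature islands, cancer samples with mild
  global background loss plus strongly hypomethylated shared domains
  (partially methylated domains, PMDs), hypermethylated gene-cluster
  islands and hypomethylated satellites, and an EMT-treated sample in
  which an exact fraction of signature islands is switched to the other
  phenotype over an exact background toggle rate;
* MeDIP fragments (uniform 200-600 bp) sampled proportionally to their
  realized methylated-CpG content times local copy number, emitted as
  36 bp mapped reads (paired with a configurable probability); input
  fragments sampled uniformly weighted by copy number with planted
  amplifications.

Every planted quantity is recorded in :class:`MethylationTruth`, the
oracle for all recovery tests.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import genome_io
from .genome_io import AnnotationTrack, GeneModel, GenomeModel
from .segments import tile_genome

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class SampleSpec:
    """One sequencing library / cell population."""

    sample_id: str
    cell_type: str  # normal | cancer | emt_control | emt_treated
    signature: str  # epithelial | mesenchymal
    has_input: bool = False
    has_expression: bool = False
    n_fragments: int = 80_000
    paired_fraction: float = 0.1


@dataclass(frozen=True)
class AmplificationSpec:
    """A planted copy-number gain in specific samples."""

    chrom: str
    start: int
    end: int
    copy_fold: float
    samples: tuple[str, ...] = ("MCF7",)


def default_samples() -> tuple[SampleSpec, ...]:
    """The default roster: one normal reference, eight cancer lines (two
    without input libraries, six with expression), and an EMT pair."""
    return (
        SampleSpec("HMEC", "normal", "epithelial", has_input=True),
        SampleSpec("MCF7", "cancer", "epithelial", has_input=True, has_expression=True),
        SampleSpec("T47D", "cancer", "epithelial", has_input=True, has_expression=True),
        SampleSpec("SKBR3", "cancer", "epithelial", has_input=True, has_expression=True),
        SampleSpec("MDAMB453", "cancer", "epithelial", has_expression=True),
        SampleSpec("MRKnu1", "cancer", "epithelial"),
        SampleSpec("HMC18", "cancer", "mesenchymal", has_input=True),
        SampleSpec("Hs578T", "cancer", "mesenchymal", has_input=True, has_expression=True),
        SampleSpec("MDAMB231", "cancer", "mesenchymal", has_input=True, has_expression=True),
        SampleSpec("MCF7_EMT_control", "emt_control", "epithelial"),
        SampleSpec("MCF7_EMT_treated", "emt_treated", "epithelial"),
    )


@dataclass
class SimulationConfig:
    """All tunable study conditions.  ``seed`` is mandatory."""

    seed: int
    chromosome_lengths: dict[str, int] = field(
        default_factory=lambda: {"chr1": 5_000_000, "chr2": 5_000_000}
    )
    scenario: str = "default"  # "default" | "segment_recovery"

    # genome composition
    background_gc: float = 0.205  # per-base C and G probability outside islands
    background_cpg_keep: float = 0.22  # CG dinucleotides kept after depletion
    island_gc: float = 0.32  # per-base C and G probability inside islands/satellites
    island_length_range: tuple[int, int] = (800, 1600)
    shore_width: int = 500
    n_intergenic_islands_per_chrom: int = 30
    n_satellites_per_chrom: int = 10
    satellite_length: int = 2_000
    n_repeats_per_chrom: int = 75
    repeat_length_range: tuple[int, int] = (300, 2_000)

    # gene models
    n_genes_per_chrom: int = 100
    n_clusters_per_chrom: int = 3
    genes_per_cluster: int = 8
    cluster_span: int = 100_000
    exon_length: int = 200
    n_exons: int = 3
    intron_length_range: tuple[int, int] = (2_000, 5_000)
    promoter_island_fraction: float = 0.7

    # methylation model (per-CpG Bernoulli probabilities by region class)
    background_level: float = 0.8
    shore_level: float = 0.1
    island_methylated_level: float = 0.9
    island_unmethylated_level: float = 0.0
    satellite_normal_level: float = 0.9
    satellite_cancer_level: float = 0.05
    cancer_background_factor: float = 0.85  # mild global loss outside PMDs
    pmd_fraction: float = 0.35  # shared strongly hypomethylated 100 kb domains
    pmd_private_fraction: float = 0.05  # extra per-sample domains
    pmd_factor: float = 0.1
    signature_island_fraction: float = 0.15  # each of epithelial/mesenchymal
    emt_switch_fraction: float = 0.40
    emt_background_rate: float = 0.10
    domain_size: int = 100_000

    # segment_recovery scenario
    segment_hypo_fraction: float = 0.10
    segment_hypo_factor: float = 4.0

    # fragments and reads
    fragment_length_range: tuple[int, int] = (200, 600)
    read_length: int = 36
    low_mapq_fraction: float = 0.02

    # expression coupling
    expression_base_mean: float = 7.0
    expression_base_sd: float = 1.5
    promoter_coupling: float = 4.0  # log2 decrease per unit promoter methylation
    body_coupling: float = 3.0  # log2 increase per unit gene-body methylation
    expression_noise_sd: float = 0.3

    samples: tuple[SampleSpec, ...] = field(default_factory=default_samples)
    amplifications: tuple[AmplificationSpec, ...] = (
        AmplificationSpec("chr2", 3_500_000, 4_500_000, 5.0, ("MCF7",)),
    )
    epithelial_group: tuple[str, ...] = ("HMEC", "MCF7", "T47D")
    mesenchymal_group: tuple[str, ...] = ("HMC18", "Hs578T", "MDAMB231")

    def __post_init__(self) -> None:
        for name in (
            "background_level",
            "shore_level",
            "island_methylated_level",
            "island_unmethylated_level",
            "satellite_normal_level",
            "satellite_cancer_level",
            "pmd_fraction",
            "emt_switch_fraction",
            "emt_background_rate",
            "signature_island_fraction",
            "promoter_island_fraction",
        ):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        lo, hi = self.fragment_length_range
        if lo > hi or lo < self.read_length:
            raise ValueError("invalid fragment length range")
        if self.scenario not in ("default", "segment_recovery"):
            raise ValueError(f"unknown scenario {self.scenario!r}")

    @property
    def medip_samples(self) -> list[SampleSpec]:
        return list(self.samples)

    @property
    def bcc_sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples if s.cell_type == "cancer"]

    @property
    def reference_sample_id(self) -> str:
        for s in self.samples:
            if s.cell_type == "normal":
                return s.sample_id
        raise ValueError("no normal reference sample declared")

    def for_segment_recovery(self) -> "SimulationConfig":
        """Variant planting only exact-fold segment hypomethylation:
        a normal reference plus one tumor sample, no other cancer effects,
        no amplifications."""
        samples = (
            SampleSpec("HMEC", "normal", "epithelial", has_input=True),
            SampleSpec("TUMOR", "cancer", "epithelial", has_input=True),
        )
        return replace(
            self,
            scenario="segment_recovery",
            samples=samples,
            amplifications=(),
            epithelial_group=("HMEC",),
            mesenchymal_group=(),
        )


# ---------------------------------------------------------------------------
# genome layout


@dataclass
class SimulatedGenome:
    """Toy genome plus its annotation tracks and layout bookkeeping."""

    genome: GenomeModel
    genes: list[GeneModel]
    islands: pd.DataFrame  # island_id, chrom, start, end, gene_id, in_cluster
    cgi_track: AnnotationTrack
    repeat_track: AnnotationTrack  # ordinary repeats + satellites
    satellites: pd.DataFrame  # chrom, start, end
    clusters: pd.DataFrame  # chrom, start, end


class _Occupancy:
    """Sorted-interval overlap bookkeeping for rejection placement."""

    def __init__(self) -> None:
        self.starts: list[int] = []
        self.ends: list[int] = []

    def overlaps(self, start: int, end: int) -> bool:
        i = bisect.bisect_right(self.starts, start)
        if i > 0 and self.ends[i - 1] > start:
            return True
        return i < len(self.starts) and self.starts[i] < end

    def add(self, start: int, end: int) -> None:
        i = bisect.bisect_right(self.starts, start)
        self.starts.insert(i, start)
        self.ends.insert(i, end)


def _place(
    rng: np.random.Generator,
    length: int,
    chrom_len: int,
    occupancies: list[_Occupancy],
    margin: int = 0,
    max_tries: int = 200,
) -> int | None:
    for _ in range(max_tries):
        start = int(rng.integers(margin, chrom_len - length - margin))
        if all(not occ.overlaps(start - margin, start + length + margin) for occ in occupancies):
            return start
    return None


def _make_gene(
    gene_id: str, chrom: str, start: int, strand: str, config: SimulationConfig,
    rng: np.random.Generator,
) -> GeneModel:
    introns = rng.integers(*config.intron_length_range, size=config.n_exons - 1)
    exons = []
    pos = start
    for i in range(config.n_exons):
        exons.append((pos, pos + config.exon_length))
        if i < config.n_exons - 1:
            pos += config.exon_length + int(introns[i])
    return GeneModel(gene_id, chrom, strand, exons)


def generate_genome(config: SimulationConfig, rng: np.random.Generator) -> SimulatedGenome:
    """Build the genome sequence, gene models and annotation tracks.

    Deterministic given the generator state.  Islands receive an
    island-type base composition without CpG depletion (o/e near 1);
    everything else is CpG-depleted background (o/e well below 0.6).
    """
    max_gene_span = config.n_exons * config.exon_length + (
        config.n_exons - 1
    ) * config.intron_length_range[1]
    genes: list[GeneModel] = []
    island_rows = []
    satellite_rows = []
    repeat_rows = []
    cluster_rows = []
    sequences: dict[str, str] = {}

    for chrom, chrom_len in config.chromosome_lengths.items():
        occ_gene = _Occupancy()
        occ_rich = _Occupancy()
        occ_cluster = _Occupancy()

        # gene-dense cluster loci (planted cancer hypermethylation targets)
        for _ in range(config.n_clusters_per_chrom):
            start = _place(rng, config.cluster_span, chrom_len, [occ_cluster], margin=50_000)
            if start is None:
                continue
            occ_cluster.add(start, start + config.cluster_span)
            cluster_rows.append({"chrom": chrom, "start": start, "end": start + config.cluster_span})
            pos = start
            for _ in range(config.genes_per_cluster):
                strand = "+" if rng.random() < 0.5 else "-"
                gene = _make_gene(f"{chrom}g{len(genes):04d}", chrom, pos, strand, config, rng)
                if gene.end > start + config.cluster_span or gene.end > chrom_len:
                    break
                genes.append(gene)
                occ_gene.add(gene.start, gene.end)
                pos = gene.end + int(rng.integers(2_000, 6_000))

        # remaining genes, uniform outside clusters
        n_cluster_genes = sum(1 for g in genes if g.chrom == chrom)
        for _ in range(config.n_genes_per_chrom - n_cluster_genes):
            start = _place(
                rng, max_gene_span, chrom_len, [occ_gene, occ_cluster], margin=2_000
            )
            if start is None:
                continue
            strand = "+" if rng.random() < 0.5 else "-"
            gene = _make_gene(f"{chrom}g{len(genes):04d}", chrom, start, strand, config, rng)
            genes.append(gene)
            occ_gene.add(gene.start, gene.end)

        # promoter islands: always at cluster genes, at a fraction elsewhere
        for gene in (g for g in genes if g.chrom == chrom):
            in_cluster = occ_cluster.overlaps(gene.start, gene.end)
            if not in_cluster and rng.random() >= config.promoter_island_fraction:
                continue
            ilen = int(rng.integers(*config.island_length_range))
            s = max(gene.tss - ilen // 2, 0)
            e = min(s + ilen, chrom_len)
            if occ_rich.overlaps(s, e):
                continue
            occ_rich.add(s, e)
            island_rows.append(
                {
                    "chrom": chrom,
                    "start": s,
                    "end": e,
                    "gene_id": gene.gene_id,
                    "in_cluster": in_cluster,
                }
            )

        # intergenic islands, kept clear of genes and their promoter reach
        for _ in range(config.n_intergenic_islands_per_chrom):
            ilen = int(rng.integers(*config.island_length_range))
            start = _place(rng, ilen, chrom_len, [occ_rich], margin=0)
            if start is None:
                continue
            if occ_gene.overlaps(start - 11_000, start + ilen + 11_000):
                continue
            occ_rich.add(start, start + ilen)
            island_rows.append(
                {
                    "chrom": chrom,
                    "start": start,
                    "end": start + ilen,
                    "gene_id": None,
                    "in_cluster": False,
                }
            )

        # CpG-rich satellite-like repeat arrays
        for _ in range(config.n_satellites_per_chrom):
            start = _place(rng, config.satellite_length, chrom_len, [occ_rich], margin=1_000)
            if start is None:
                continue
            occ_rich.add(start, start + config.satellite_length)
            satellite_rows.append(
                {"chrom": chrom, "start": start, "end": start + config.satellite_length}
            )

        # ordinary repeats (background composition, may overlap gene bodies)
        for _ in range(config.n_repeats_per_chrom):
            rlen = int(rng.integers(*config.repeat_length_range))
            start = _place(rng, rlen, chrom_len, [occ_rich], margin=0)
            if start is None:
                continue
            repeat_rows.append({"chrom": chrom, "start": start, "end": start + rlen})

        # sequence: background composition, islands/satellites overwritten,
        # then CpG depletion restricted to non-rich positions
        gc = config.background_gc
        probs_bg = [0.5 - gc, gc, gc, 0.5 - gc]  # A C G T
        arr = rng.choice(BASES, size=chrom_len, p=probs_bg)
        igc = config.island_gc
        probs_rich = [0.5 - igc, igc, igc, 0.5 - igc]
        rich_mask = np.zeros(chrom_len, dtype=bool)
        for row in island_rows + satellite_rows:
            if row["chrom"] != chrom:
                continue
            arr[row["start"] : row["end"]] = rng.choice(
                BASES, size=row["end"] - row["start"], p=probs_rich
            )
            rich_mask[row["start"] : row["end"]] = True
        cg_pos = np.flatnonzero((arr[:-1] == ord("C")) & (arr[1:] == ord("G")))
        cg_pos = cg_pos[~rich_mask[cg_pos]]
        drop = cg_pos[rng.random(len(cg_pos)) >= config.background_cpg_keep]
        arr[drop + 1] = rng.choice(
            np.frombuffer(b"AT", dtype=np.uint8), size=len(drop)
        )
        sequences[chrom] = arr.tobytes().decode("ascii")

    islands = pd.DataFrame(
        island_rows, columns=["chrom", "start", "end", "gene_id", "in_cluster"]
    )
    islands = islands.sort_values(["chrom", "start"]).reset_index(drop=True)
    islands.insert(0, "island_id", np.arange(len(islands)))
    satellites = pd.DataFrame(satellite_rows, columns=["chrom", "start", "end"])
    repeats = pd.concat(
        [pd.DataFrame(repeat_rows, columns=["chrom", "start", "end"]), satellites],
        ignore_index=True,
    )
    return SimulatedGenome(
        genome=GenomeModel(sequences),
        genes=genes,
        islands=islands,
        cgi_track=AnnotationTrack("cgi", islands[["chrom", "start", "end"]]),
        repeat_track=AnnotationTrack("repeat", repeats),
        satellites=satellites,
        clusters=pd.DataFrame(cluster_rows, columns=["chrom", "start", "end"]),
    )


# ---------------------------------------------------------------------------
# methylation truth


@dataclass
class MethylationTruth:
    """Planted methylation state and all derived truth flags.

    ``site_probs``/``site_states`` are aligned with the CpG-site frame;
    states are one realized methylome per sample (Bernoulli draws from the
    region-level probabilities).
    """

    cpg_sites: pd.DataFrame
    site_flags: pd.DataFrame  # region class, island id/category, planted flags
    island_table: pd.DataFrame  # per island: category, switch/toggle flags
    site_probs: dict[str, np.ndarray]
    site_states: dict[str, np.ndarray]
    domain_table: pd.DataFrame  # 100 kb domains with PMD flags
    segment_truth: pd.DataFrame | None = None  # segment_recovery scenario


def _exact_subset(rng: np.random.Generator, n: int, fraction: float) -> np.ndarray:
    """Boolean mask selecting an exact round(fraction * n) subset."""
    k = int(round(fraction * n))
    mask = np.zeros(n, dtype=bool)
    if k:
        mask[rng.choice(n, size=k, replace=False)] = True
    return mask


def _interval_lookup(
    intervals: pd.DataFrame, chrom: str, pos: np.ndarray
) -> np.ndarray:
    """Row index of the interval containing each position, -1 if none.

    Intervals must be sorted and non-overlapping per chromosome.
    """
    sub = intervals[intervals["chrom"] == chrom]
    out = np.full(len(pos), -1, dtype=np.int64)
    if sub.empty:
        return out
    starts = sub["start"].to_numpy()
    ends = sub["end"].to_numpy()
    rows = sub.index.to_numpy()
    idx = np.searchsorted(starts, pos, side="right") - 1
    valid = (idx >= 0) & (pos < ends[np.clip(idx, 0, len(ends) - 1)])
    out[valid] = rows[idx[valid]]
    return out


def assign_methylation(
    config: SimulationConfig,
    sim: SimulatedGenome,
    rng: np.random.Generator,
) -> MethylationTruth:
    """Assign per-region methylation probabilities and realize methylomes."""
    cpg_sites = genome_io.enumerate_cpg_sites(sim.genome)
    n_sites = len(cpg_sites)

    domains = tile_genome(sim.genome, window=config.domain_size)
    n_domains = len(domains)

    # classify every CpG site: island > satellite > shore > background
    island_id = np.full(n_sites, -1, dtype=np.int64)
    region = np.full(n_sites, "background", dtype=object)
    domain_id = np.zeros(n_sites, dtype=np.int64)
    offset = 0
    sat = sim.satellites.sort_values(["chrom", "start"]).reset_index(drop=True)
    shore = config.shore_width
    shores = pd.DataFrame(
        {
            "chrom": np.repeat(sim.islands["chrom"].to_numpy(), 2),
            "start": np.stack(
                [sim.islands["start"] - shore, sim.islands["end"]], axis=1
            ).ravel(),
            "end": np.stack(
                [sim.islands["start"], sim.islands["end"] + shore], axis=1
            ).ravel(),
        }
    )
    shores["start"] = shores["start"].clip(lower=0)
    shores = shores.sort_values(["chrom", "start"]).reset_index(drop=True)
    for chrom, grp in cpg_sites.groupby("chrom", sort=False):
        pos = grp["pos"].to_numpy()
        n = len(grp)
        iid = _interval_lookup(sim.islands, chrom, pos)
        sid = _interval_lookup(sat, chrom, pos)
        shid = _interval_lookup(shores, chrom, pos)
        r = np.full(n, "background", dtype=object)
        r[shid >= 0] = "shore"
        r[sid >= 0] = "satellite"
        r[iid >= 0] = "island"
        region[offset : offset + n] = r
        island_id[offset : offset + n] = iid
        dom = domains[domains["chrom"] == chrom]
        dom_rows = dom.index.to_numpy()
        dom_idx = np.searchsorted(dom["start"].to_numpy(), pos, side="right") - 1
        domain_id[offset : offset + n] = dom_rows[dom_idx]
        offset += n

    # island categories
    islands = sim.islands.copy()
    n_islands = len(islands)
    category = np.full(n_islands, "neutral", dtype=object)
    category[islands["in_cluster"].to_numpy(dtype=bool)] = "cancer_hyper"
    free = np.flatnonzero(category == "neutral")
    perm = rng.permutation(free)
    k_sig = int(round(config.signature_island_fraction * n_islands))
    category[perm[:k_sig]] = "epithelial_sig"
    category[perm[k_sig : 2 * k_sig]] = "mesenchymal_sig"
    islands["category"] = category
    islands["gene_related"] = islands["gene_id"].notna()

    # EMT switching: exact fractions per stratum
    switched = np.zeros(n_islands, dtype=bool)
    for cat in ("epithelial_sig", "mesenchymal_sig"):
        idx = np.flatnonzero(category == cat)
        switched[idx] = _exact_subset(rng, len(idx), config.emt_switch_fraction)
    toggled = np.zeros(n_islands, dtype=bool)
    for cat in ("cancer_hyper", "neutral"):
        idx = np.flatnonzero(category == cat)
        toggled[idx] = _exact_subset(rng, len(idx), config.emt_background_rate)
    islands["emt_switched"] = switched
    islands["emt_toggled"] = toggled

    # PMD domains: shared core + per-sample private, clusters excluded
    in_cluster_domain = np.zeros(n_domains, dtype=bool)
    for row in sim.clusters.itertuples(index=False):
        hit = (
            (domains["chrom"] == row.chrom)
            & (domains["start"] < row.end)
            & (domains["end"] > row.start)
        )
        in_cluster_domain |= hit.to_numpy()
    eligible = np.flatnonzero(~in_cluster_domain)
    core = np.zeros(n_domains, dtype=bool)
    core_sel = _exact_subset(rng, len(eligible), config.pmd_fraction)
    core[eligible[core_sel]] = True
    remaining = np.flatnonzero(~core & ~in_cluster_domain)
    private: dict[str, np.ndarray] = {}
    emt_private: np.ndarray | None = None
    for spec in config.samples:
        if spec.cell_type in ("cancer", "emt_control", "emt_treated"):
            if spec.cell_type == "emt_treated" and emt_private is not None:
                private[spec.sample_id] = emt_private  # EMT pair shares domains
                continue
            mask = np.zeros(n_domains, dtype=bool)
            sel = _exact_subset(rng, len(remaining), config.pmd_private_fraction)
            mask[remaining[sel]] = True
            private[spec.sample_id] = mask
            if spec.cell_type == "emt_control":
                emt_private = mask

    # planted segment hypomethylation (segment_recovery scenario)
    segment_truth = None
    planted_segment = np.zeros(n_domains, dtype=bool)
    if config.scenario == "segment_recovery":
        planted_segment = _exact_subset(rng, n_domains, config.segment_hypo_fraction)
        segment_truth = domains.copy()
        segment_truth["planted_hypo"] = planted_segment

    # island methylation state per sample
    def island_state(spec: SampleSpec) -> np.ndarray:
        state = np.zeros(n_islands, dtype=bool)
        if config.scenario == "segment_recovery":
            # no cancer island effects planted; signatures follow phenotype
            state |= (category == "epithelial_sig") & (spec.signature == "epithelial")
            state |= (category == "mesenchymal_sig") & (spec.signature == "mesenchymal")
            return state
        state |= (category == "epithelial_sig") & (spec.signature == "epithelial")
        state |= (category == "mesenchymal_sig") & (spec.signature == "mesenchymal")
        if spec.cell_type in ("cancer", "emt_control", "emt_treated"):
            state |= category == "cancer_hyper"
        if spec.cell_type == "emt_treated":
            state ^= switched | toggled
        return state

    site_probs: dict[str, np.ndarray] = {}
    site_states: dict[str, np.ndarray] = {}
    is_island = region == "island"
    is_shore = region == "shore"
    is_satellite = region == "satellite"
    is_background = region == "background"
    for spec in config.samples:
        prob = np.empty(n_sites, dtype=float)
        prob[is_shore] = config.shore_level
        cancerous = spec.cell_type in ("cancer", "emt_control", "emt_treated")
        if config.scenario == "segment_recovery":
            factor = np.ones(n_domains)
        elif cancerous:
            factor = np.full(n_domains, config.cancer_background_factor)
            factor[core | private[spec.sample_id]] = config.pmd_factor
        else:
            factor = np.ones(n_domains)
        prob[is_background] = config.background_level * factor[domain_id[is_background]]
        if config.scenario != "segment_recovery" and cancerous:
            prob[is_satellite] = config.satellite_cancer_level
        else:
            prob[is_satellite] = config.satellite_normal_level
        state = island_state(spec)
        prob[is_island] = np.where(
            state[island_id[is_island]],
            config.island_methylated_level,
            config.island_unmethylated_level,
        )
        if config.scenario == "segment_recovery" and cancerous:
            hit = planted_segment[domain_id]
            prob[hit] = prob[hit] / config.segment_hypo_factor
        site_probs[spec.sample_id] = prob
        site_states[spec.sample_id] = rng.random(n_sites) < prob

    # per-site truth flags
    cat_by_site = np.full(n_sites, "none", dtype=object)
    sw_by_site = np.zeros(n_sites, dtype=bool)
    gene_rel_island = np.zeros(n_sites, dtype=bool)
    has_island = island_id >= 0
    cat_by_site[has_island] = category[island_id[has_island]]
    sw_by_site[has_island] = (switched | toggled)[island_id[has_island]]
    gene_rel_island[has_island] = islands["gene_related"].to_numpy()[island_id[has_island]]
    site_flags = pd.DataFrame(
        {
            "chrom": cpg_sites["chrom"],
            "pos": cpg_sites["pos"],
            "region": region,
            "island_id": island_id,
            "island_category": cat_by_site,
            "gene_related_island": gene_rel_island,
            "planted_cancer_hyper": cat_by_site == "cancer_hyper",
            "epithelial_specific": cat_by_site == "epithelial_sig",
            "mesenchymal_specific": cat_by_site == "mesenchymal_sig",
            "emt_switched": sw_by_site,
            "domain_id": domain_id,
            "in_pmd_core": core[domain_id],
        }
    )
    domain_table = domains.copy()
    domain_table["pmd_core"] = core
    domain_table["in_cluster"] = in_cluster_domain
    if segment_truth is not None:
        domain_table["planted_hypo"] = planted_segment
    return MethylationTruth(
        cpg_sites=cpg_sites,
        site_flags=site_flags,
        island_table=islands,
        site_probs=site_probs,
        site_states=site_states,
        domain_table=domain_table,
        segment_truth=segment_truth,
    )


# ---------------------------------------------------------------------------
# read simulation


def _copy_fold_at(
    config: SimulationConfig, sample_id: str, chrom: np.ndarray, pos: np.ndarray
) -> np.ndarray:
    fold = np.ones(len(pos), dtype=float)
    for amp in config.amplifications:
        if sample_id not in amp.samples:
            continue
        hit = (chrom == amp.chrom) & (pos >= amp.start) & (pos < amp.end)
        fold[hit] *= amp.copy_fold
    return fold


def _emit_reads(
    config: SimulationConfig,
    spec: SampleSpec,
    chrom: np.ndarray,
    frag_start: np.ndarray,
    frag_end: np.ndarray,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Turn fragment intervals into mapped 36 bp reads (paired or singleton)."""
    n = len(frag_start)
    rl = config.read_length
    paired = rng.random(n) < spec.paired_fraction
    side = rng.integers(0, 2, size=n)  # singleton: which fragment end was read
    mapq = rng.integers(20, 61, size=n)
    low = rng.random(n) < config.low_mapq_fraction
    mapq[low] = rng.integers(0, 10, size=int(low.sum()))

    strand = np.where(paired | (side == 0), "+", "-")
    start = np.where(strand == "+", frag_start, frag_end - rl)
    end = start + rl
    pair_id = np.where(paired, [f"p{i}" for i in range(n)], None)
    df = pd.DataFrame(
        {
            "chrom": chrom,
            "start": start.astype(np.int64),
            "end": end.astype(np.int64),
            "strand": strand,
            "mapq": mapq,
            "pair_id": pair_id,
            "mate_chrom": np.where(paired, chrom, None),
            "mate_start": np.where(paired, frag_end - rl, np.nan),
            "mate_end": np.where(paired, frag_end, np.nan),
            "mate_strand": np.where(paired, "-", None),
        }
    )
    df["sample_id"] = spec.sample_id
    return df


def simulate_medip_reads(
    truth: MethylationTruth,
    sim: SimulatedGenome,
    spec: SampleSpec,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Sample MeDIP fragments proportional to methylated-CpG content.

    Sampling picks a methylated CpG with probability proportional to its
    copy-number fold and places a uniform-length fragment uniformly among
    positions covering it; a fragment's total sampling probability is then
    proportional to the number of methylated CpGs it contains (times copy
    number).  Raises if the sample's methylome has no methylated CpG.
    """
    states = truth.site_states[spec.sample_id]
    chrom_arr = truth.cpg_sites["chrom"].to_numpy()
    pos_arr = truth.cpg_sites["pos"].to_numpy()
    weights = states.astype(float) * _copy_fold_at(config, spec.sample_id, chrom_arr, pos_arr)
    total = weights.sum()
    if total <= 0:
        raise ValueError(
            f"sample {spec.sample_id}: methylome has no methylated CpG; cannot simulate MeDIP"
        )
    n = spec.n_fragments
    anchor = rng.choice(len(weights), size=n, p=weights / total)
    lo, hi = config.fragment_length_range
    length = rng.integers(lo, hi + 1, size=n)
    offset = rng.integers(0, length)
    chrom = chrom_arr[anchor]
    pos = pos_arr[anchor]
    start = pos - offset
    lengths_map = sim.genome.lengths
    chrom_len = np.array([lengths_map[c] for c in chrom])
    start = np.clip(start, 0, chrom_len - length)
    return _emit_reads(config, spec, chrom, start, start + length, rng)


def simulate_input_reads(
    sim: SimulatedGenome,
    spec: SampleSpec,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Sample input fragments uniformly, weighted by planted copy number."""
    pieces = []  # (chrom, start, end, fold)
    for chrom, length in sim.genome.lengths.items():
        bounds = {0, length}
        for amp in config.amplifications:
            if spec.sample_id in amp.samples and amp.chrom == chrom:
                bounds.update((amp.start, amp.end))
        edges = sorted(bounds)
        for s, e in zip(edges[:-1], edges[1:]):
            fold = 1.0
            for amp in config.amplifications:
                if (
                    spec.sample_id in amp.samples
                    and amp.chrom == chrom
                    and amp.start <= s
                    and e <= amp.end
                ):
                    fold *= amp.copy_fold
            pieces.append((chrom, s, e, fold))
    w = np.array([(e - s) * f for _, s, e, f in pieces], dtype=float)
    n = spec.n_fragments
    piece_idx = rng.choice(len(pieces), size=n, p=w / w.sum())
    lo, hi = config.fragment_length_range
    length = rng.integers(lo, hi + 1, size=n)
    piece_start = np.array([pieces[i][1] for i in piece_idx])
    piece_end = np.array([pieces[i][2] for i in piece_idx])
    chrom = np.array([pieces[i][0] for i in piece_idx], dtype=object)
    pos = piece_start + (rng.random(n) * (piece_end - piece_start)).astype(np.int64)
    start = pos - rng.integers(0, length)
    lengths_map = sim.genome.lengths
    chrom_len = np.array([lengths_map[c] for c in chrom])
    start = np.clip(start, 0, chrom_len - length)
    # input libraries are sequenced as singletons
    input_spec = replace(spec, paired_fraction=0.0)
    return _emit_reads(config, input_spec, chrom, start, start + length, rng)


def simulate_expression(
    config: SimulationConfig,
    truth: MethylationTruth,
    sim: SimulatedGenome,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Expression table coupled to the planted methylome.

    log2 expression = base - promoter_coupling x promoter-island state
    + body_coupling x mean realized gene-body background methylation
    + Gaussian noise.  Promoter methylation therefore represses, gene-body
    methylation tracks expression positively.
    """
    expr_samples = [s for s in config.samples if s.has_expression]
    if not expr_samples:
        return pd.DataFrame()
    genes = sim.genes
    base = rng.normal(config.expression_base_mean, config.expression_base_sd, len(genes))
    prom_island = {
        row.gene_id: row.island_id
        for row in truth.island_table.itertuples(index=False)
        if row.gene_id is not None
    }
    # gene-body background site index ranges per gene
    flags = truth.site_flags
    body_sites: list[np.ndarray] = []
    for gene in genes:
        sel = (
            (flags["chrom"] == gene.chrom).to_numpy()
            & (flags["pos"].to_numpy() >= gene.start)
            & (flags["pos"].to_numpy() < gene.end)
            & (flags["region"].to_numpy() == "background")
        )
        body_sites.append(np.flatnonzero(sel))
    island_states = {
        s.sample_id: None for s in expr_samples
    }
    data = {}
    for spec in expr_samples:
        states = truth.site_states[spec.sample_id]
        flags_island = truth.site_flags["island_id"].to_numpy()
        log2e = np.empty(len(genes))
        for i, gene in enumerate(genes):
            prom = 0.0
            iid = prom_island.get(gene.gene_id)
            if iid is not None:
                on_island = flags_island == iid
                if on_island.any():
                    prom = float(states[on_island].mean())
            body = float(states[body_sites[i]].mean()) if len(body_sites[i]) else 0.0
            log2e[i] = (
                base[i]
                - config.promoter_coupling * prom
                + config.body_coupling * body
                + rng.normal(0.0, config.expression_noise_sd)
            )
        data[spec.sample_id] = np.power(2.0, log2e)
    out = pd.DataFrame(data, index=[g.gene_id for g in genes])
    out.index.name = "gene_id"
    return out


# ---------------------------------------------------------------------------
# whole-study convenience


@dataclass
class SimulatedStudy:
    """Everything one simulated study produces, with full ground truth."""

    config: SimulationConfig
    sim_genome: SimulatedGenome
    truth: MethylationTruth
    medip_reads: dict[str, pd.DataFrame]
    input_reads: dict[str, pd.DataFrame]
    expression: pd.DataFrame

    @property
    def genome(self) -> GenomeModel:
        return self.sim_genome.genome


def simulate_study(config: SimulationConfig) -> SimulatedStudy:
    """Run the full generator: genome, truth, reads, expression."""
    rng = np.random.default_rng(config.seed)
    sim = generate_genome(config, rng)
    truth = assign_methylation(config, sim, rng)
    medip: dict[str, pd.DataFrame] = {}
    inputs: dict[str, pd.DataFrame] = {}
    for spec in config.samples:
        medip[spec.sample_id] = simulate_medip_reads(truth, sim, spec, config, rng)
        if spec.has_input:
            inputs[spec.sample_id] = simulate_input_reads(sim, spec, config, rng)
    expression = simulate_expression(config, truth, sim, rng)
    return SimulatedStudy(config, sim, truth, medip, inputs, expression)


def write_study(study: SimulatedStudy, outdir: str | Path) -> dict[str, Path]:
    """Write all study inputs and truth tables as plain-text files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["genome"] = outdir / "genome.fa"
    genome_io.write_genome(study.genome, paths["genome"])
    paths["cgi"] = outdir / "cgi.bed"
    genome_io.write_track(study.sim_genome.cgi_track, paths["cgi"])
    paths["repeats"] = outdir / "repeats.bed"
    genome_io.write_track(study.sim_genome.repeat_track, paths["repeats"])
    paths["genes"] = outdir / "genes.bed12"
    genome_io.write_gene_table(study.sim_genome.genes, paths["genes"])
    for sample, reads in study.medip_reads.items():
        p = outdir / f"medip_{sample}.reads.tsv"
        genome_io.write_reads(reads, p)
        paths[f"medip_{sample}"] = p
    for sample, reads in study.input_reads.items():
        p = outdir / f"input_{sample}.reads.tsv"
        genome_io.write_reads(reads, p)
        paths[f"input_{sample}"] = p
    if len(study.expression):
        paths["expression"] = outdir / "expression.tsv"
        genome_io.write_expression(study.expression, paths["expression"])
    paths["island_truth"] = outdir / "truth_islands.tsv"
    genome_io.write_table(study.truth.island_table, paths["island_truth"])
    paths["site_truth"] = outdir / "truth_sites.tsv"
    genome_io.write_table(study.truth.site_flags, paths["site_truth"])
    paths["domain_truth"] = outdir / "truth_domains.tsv"
    genome_io.write_table(study.truth.domain_table, paths["domain_truth"])
    return paths
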