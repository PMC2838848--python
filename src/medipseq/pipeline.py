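"""Pipeline orchestration: config, staged execution, reports, manifest.

A single plain-text (YAML) config declares samples, group roles, file
paths (or a simulation block) and every analysis parameter; defaults are
the study values (250 bp extension, 100 kb windows, per-10M scaling,
two-fold classification, 500 bp context window, o/e split at 0.6, 10 kb
promoters, 1 kb expression bins, mapq 10).  Validation is fail-fast: bad
parameters or missing files raise before any computation, and every run
writes a manifest recording parameters, seed and input checksums.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import cpg as cpg_mod
from . import emt as emt_mod
from . import expression as expr_mod
from . import features as feat_mod
from . import genome_io
from . import read_processing
from . import segments as seg_mod
from . import simulate as sim_mod

logger = logging.getLogger(__name__)

DEFAULT_PARAMS: dict[str, Any] = {
    "min_mapq": 10,
    "ext_length": 250,
    "dedup": True,
    "window": 100_000,
    "fold": 2.0,
    "pseudocount": 1.0,
    "amp_fold": 3.0,
    "assignment": "midpoint",
    "context_window": 500,
    "oe_threshold": 0.6,
    "min_depth": 1,
    "promoter_span": 10_000,
    "max_dist": 10_000,
    "distance_bin": 500,
    "tss_span": 10_000,
    "tss_bin": 1_000,
    "corr_method": "pearson",
    "corr_threshold": 0.5,
}

_PARAM_CHECKS = {
    "min_mapq": lambda v: v >= 0,
    "ext_length": lambda v: v > 0,
    "window": lambda v: v >= 1000,
    "fold": lambda v: v > 1,
    "pseudocount": lambda v: v >= 0,
    "amp_fold": lambda v: v > 1,
    "assignment": lambda v: v in ("midpoint", "overlap"),
    "context_window": lambda v: v >= 10,
    "oe_threshold": lambda v: v > 0,
    "min_depth": lambda v: v >= 1,
    "promoter_span": lambda v: v > 0,
    "max_dist": lambda v: v > 0,
    "distance_bin": lambda v: v > 0,
    "tss_span": lambda v: v > 0,
    "tss_bin": lambda v: v > 0,
    "corr_method": lambda v: v in ("pearson", "spearman"),
    "corr_threshold": lambda v: 0 < v <= 1,
}


class ConfigError(ValueError):
    """Raised on invalid pipeline configuration (before any computation)."""


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    return cfg


def resolve_params(cfg: dict) -> dict[str, Any]:
    params = dict(DEFAULT_PARAMS)
    for key, value in (cfg.get("params") or {}).items():
        if key not in DEFAULT_PARAMS:
            raise ConfigError(f"unknown parameter {key!r}")
        params[key] = value
    for key, check in _PARAM_CHECKS.items():
        if not check(params[key]):
            raise ConfigError(f"parameter {key!r} out of range: {params[key]!r}")
    return params


class Study:
    """In-memory study inputs plus staged analysis methods."""

    def __init__(
        self,
        genome: genome_io.GenomeModel,
        genes: list[genome_io.GeneModel],
        cgi_track: genome_io.AnnotationTrack,
        repeat_track: genome_io.AnnotationTrack,
        medip_reads: dict[str, pd.DataFrame],
        input_reads: dict[str, pd.DataFrame],
        expression: pd.DataFrame,
        groups: dict[str, Any],
        params: dict[str, Any],
        truth: sim_mod.MethylationTruth | None = None,
    ) -> None:
        self.genome = genome
        self.genes = genes
        self.cgi_track = cgi_track
        self.repeat_track = repeat_track
        self.medip_reads = medip_reads
        self.input_reads = input_reads
        self.expression = expression
        self.groups = groups
        self.params = params
        self.truth = truth
        self._validate_groups()
        self.cpg_sites = genome_io.enumerate_cpg_sites(genome)
        self._blocks: dict[str, pd.DataFrame] | None = None
        self._input_blocks: dict[str, pd.DataFrame] | None = None
        self._coverage: pd.DataFrame | None = None

    # -- config plumbing -------------------------------------------------

    def _validate_groups(self) -> None:
        declared = set(self.medip_reads)
        ref = self.groups.get("reference")
        if not ref:
            raise ConfigError("groups.reference is required")
        for key in ("reference", "emt_control", "emt_treated"):
            value = self.groups.get(key)
            if value is not None and value not in declared:
                raise ConfigError(f"groups.{key}={value!r} is not a declared sample")
        for key in ("bcc", "epithelial", "mesenchymal"):
            for sample in self.groups.get(key) or []:
                if sample not in declared:
                    raise ConfigError(f"groups.{key} sample {sample!r} not declared")
        if not self.groups.get("bcc"):
            raise ConfigError("groups.bcc must list at least one test sample")
        if ref in (self.groups.get("bcc") or []):
            raise ConfigError("reference sample cannot be in groups.bcc")

    @classmethod
    def from_config(cls, cfg: dict) -> "Study":
        params = resolve_params(cfg)
        if "simulate" in cfg:
            sim_cfg = build_simulation_config(cfg)
            study = sim_mod.simulate_study(sim_cfg)
            groups = dict(cfg.get("groups") or default_groups(sim_cfg))
            medip = {
                s: reads[reads["mapq"] >= params["min_mapq"]].reset_index(drop=True)
                for s, reads in study.medip_reads.items()
            }
            inputs = {
                s: reads[reads["mapq"] >= params["min_mapq"]].reset_index(drop=True)
                for s, reads in study.input_reads.items()
            }
            return cls(
                study.genome,
                study.sim_genome.genes,
                study.sim_genome.cgi_track,
                study.sim_genome.repeat_track,
                medip,
                inputs,
                study.expression,
                groups,
                params,
                truth=study.truth,
            )
        inputs_cfg = cfg.get("inputs")
        if not inputs_cfg:
            raise ConfigError("config needs either a 'simulate' or an 'inputs' section")
        for key in ("genome", "genes", "cgi"):
            if key not in inputs_cfg:
                raise ConfigError(f"inputs.{key} is required")
        declared_files: list[Path] = []
        samples_cfg = inputs_cfg.get("samples") or []
        if not samples_cfg:
            raise ConfigError("inputs.samples must declare at least one sample")
        for entry in samples_cfg:
            if "id" not in entry or "medip" not in entry:
                raise ConfigError("each inputs.samples entry needs 'id' and 'medip'")
            declared_files.append(Path(entry["medip"]))
            if entry.get("input"):
                declared_files.append(Path(entry["input"]))
        for key in ("genome", "genes", "cgi", "repeats", "expression"):
            if inputs_cfg.get(key):
                declared_files.append(Path(inputs_cfg[key]))
        missing = [str(p) for p in declared_files if not p.exists()]
        if missing:
            raise ConfigError(f"declared input files do not exist: {missing}")

        genome = genome_io.load_genome(inputs_cfg["genome"])
        genes = genome_io.load_gene_table(inputs_cfg["genes"])
        cgi = genome_io.load_track(inputs_cfg["cgi"], "cgi", genome)
        repeats = (
            genome_io.load_track(inputs_cfg["repeats"], "repeat", genome)
            if inputs_cfg.get("repeats")
            else genome_io.AnnotationTrack("repeat", pd.DataFrame(columns=["chrom", "start", "end"]))
        )
        medip = {}
        input_reads = {}
        for entry in samples_cfg:
            sid = entry["id"]
            medip[sid] = genome_io.load_reads(
                entry["medip"], sid, min_mapq=params["min_mapq"], genome=genome
            )
            if entry.get("input"):
                input_reads[sid] = genome_io.load_reads(
                    entry["input"], sid, min_mapq=params["min_mapq"], genome=genome
                )
        expression = (
            genome_io.load_expression(inputs_cfg["expression"])
            if inputs_cfg.get("expression")
            else pd.DataFrame()
        )
        groups = dict(cfg.get("groups") or {})
        return cls(genome, genes, cgi, repeats, medip, input_reads, expression, groups, params)

    # -- staged analysis -------------------------------------------------

    @property
    def blocks(self) -> dict[str, pd.DataFrame]:
        if self._blocks is None:
            self._blocks = {
                s: read_processing.reads_to_blocks(
                    reads,
                    self.genome,
                    ext_length=self.params["ext_length"],
                    dedup=self.params["dedup"],
                )
                for s, reads in self.medip_reads.items()
            }
        return self._blocks

    @property
    def input_blocks(self) -> dict[str, pd.DataFrame]:
        if self._input_blocks is None:
            self._input_blocks = {
                s: read_processing.reads_to_blocks(
                    reads,
                    self.genome,
                    ext_length=self.params["ext_length"],
                    dedup=self.params["dedup"],
                )
                for s, reads in self.input_reads.items()
            }
        return self._input_blocks

    @property
    def coverage(self) -> pd.DataFrame:
        if self._coverage is None:
            self._coverage = cpg_mod.coverage_matrix(
                self.cpg_sites, self.blocks, min_depth=self.params["min_depth"]
            )
        return self._coverage

    def segment_table(self) -> pd.DataFrame:
        return seg_mod.build_segment_table(
            self.genome,
            self.blocks,
            self.input_blocks,
            reference=self.groups["reference"],
            window=self.params["window"],
            fold=self.params["fold"],
            pseudocount=self.params["pseudocount"],
            amp_fold=self.params["amp_fold"],
            assignment=self.params["assignment"],
            cpg_sites=self.cpg_sites,
            genes=self.genes,
        )

    def clustering(self, segment_table: pd.DataFrame) -> str:
        norm = segment_table[
            [c for c in segment_table.columns if c.startswith("norm_")]
        ].rename(columns=lambda c: c[len("norm_") :])
        linkage, labels = seg_mod.cluster_samples(norm)
        return seg_mod.linkage_to_newick(linkage, labels)

    def cpg_table(self) -> pd.DataFrame:
        table = cpg_mod.build_cpg_table(
            self.genome,
            self.cpg_sites,
            self.blocks,
            reference=self.groups["reference"],
            group=self.groups["bcc"],
            window=self.params["context_window"],
            oe_threshold=self.params["oe_threshold"],
            min_depth=self.params["min_depth"],
        )
        index = feat_mod.build_feature_index(
            self.genes, self.repeat_track, promoter_span=self.params["promoter_span"]
        )
        table["feature"] = feat_mod.assign_feature(self.cpg_sites, index)
        table["tss_distance"] = feat_mod.tss_distance(
            self.cpg_sites, self.genes, max_dist=self.params["max_dist"]
        )
        return table

    def feature_summary(self, cpg_table: pd.DataFrame) -> pd.DataFrame:
        rows = []
        for subset in ("all", "hyper", "hypo"):
            mask = (
                np.ones(len(cpg_table), dtype=bool)
                if subset == "all"
                else (cpg_table["class"] == subset).to_numpy()
            )
            counts = cpg_table.loc[mask, "feature"].value_counts()
            total = int(mask.sum())
            for feature in feat_mod.FEATURE_PRIORITY:
                n = int(counts.get(feature, 0))
                rows.append(
                    {
                        "subset": subset,
                        "feature": feature,
                        "count": n,
                        "proportion": n / total if total else float("nan"),
                    }
                )
        return pd.DataFrame(rows)

    def distance_profiles(self, cpg_table: pd.DataFrame) -> pd.DataFrame:
        frames = []
        for subset in ("hyper", "hypo"):
            profile = feat_mod.distance_profile(
                (cpg_table["class"] == subset).to_numpy(),
                cpg_table["tss_distance"].to_numpy(),
                bin_size=self.params["distance_bin"],
                max_dist=self.params["max_dist"],
            )
            profile.insert(0, "subset", subset)
            frames.append(profile)
        return pd.concat(frames, ignore_index=True)

    def correlation_tables(self) -> tuple[pd.DataFrame, pd.DataFrame] | None:
        if self.expression.empty:
            return None
        bins = expr_mod.bin_tss_regions(
            self.genes,
            self.genome,
            span=self.params["tss_span"],
            bin_size=self.params["tss_bin"],
        )
        shared = [s for s in self.expression.columns if s in self.blocks]
        binned = expr_mod.bin_counts({s: self.blocks[s] for s in shared}, bins)
        correlations = expr_mod.correlate_gene_bins(
            binned,
            self.expression,
            method=self.params["corr_method"],
            threshold=self.params["corr_threshold"],
        )
        fractions = expr_mod.fraction_by_distance(correlations)
        return correlations, fractions

    def emt_tables(
        self, cpg_table: pd.DataFrame
    ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame] | None:
        control = self.groups.get("emt_control")
        treated = self.groups.get("emt_treated")
        epithelial = self.groups.get("epithelial") or []
        mesenchymal = self.groups.get("mesenchymal") or []
        if not (control and treated and epithelial and mesenchymal):
            return None
        cov = self.coverage
        epi_specific, mes_specific = emt_mod.group_specific_sites(
            cov, epithelial, mesenchymal
        )
        changes = emt_mod.emt_cpg_changes(
            cov[control].to_numpy(), cov[treated].to_numpy()
        )
        site_table = cpg_table[["chrom", "pos", "cpg_oe", "feature"]].copy()
        site_table["epithelial_specific"] = epi_specific
        site_table["mesenchymal_specific"] = mes_specific
        site_table["emt_change"] = changes
        cgi_interior = emt_mod.cgi_interior_mask(
            self.cgi_track, self.cpg_sites, margin=self.params["ext_length"]
        )
        site_table["cgi_interior"] = cgi_interior
        fractions = emt_mod.alteration_fractions(
            epi_specific,
            mes_specific,
            changes,
            feature_labels=cpg_table["feature"].to_numpy(),
            coverage_control=cov[control].to_numpy(),
            restrict=cgi_interior,
        )
        region_fractions = emt_mod.region_alteration_fractions(
            self.cgi_track,
            self.cpg_sites,
            epi_specific,
            mes_specific,
            changes,
            cov[control].to_numpy(),
            margin=self.params["ext_length"],
        )
        cgi_table = emt_mod.emt_cgi_changes(
            self.cgi_track,
            self.blocks[control],
            self.blocks[treated],
            self.blocks[self.groups["reference"]],
            fold=self.params["fold"],
            pseudocount=self.params["pseudocount"],
        )
        return site_table, cgi_table, fractions, region_fractions


def default_groups(sim_cfg: sim_mod.SimulationConfig) -> dict[str, Any]:
    """Group roles derived from a simulation config's sample roster."""
    groups: dict[str, Any] = {
        "reference": sim_cfg.reference_sample_id,
        "bcc": sim_cfg.bcc_sample_ids,
        "epithelial": list(sim_cfg.epithelial_group),
        "mesenchymal": list(sim_cfg.mesenchymal_group),
    }
    for spec in sim_cfg.samples:
        if spec.cell_type == "emt_control":
            groups["emt_control"] = spec.sample_id
        elif spec.cell_type == "emt_treated":
            groups["emt_treated"] = spec.sample_id
    return groups


def build_simulation_config(cfg: dict) -> sim_mod.SimulationConfig:
    """Translate the config's 'simulate' section into a SimulationConfig."""
    sim_section = dict(cfg.get("simulate") or {})
    seed = cfg.get("seed", sim_section.pop("seed", None))
    if seed is None:
        raise ConfigError("a seed is required for simulation")
    scenario = sim_section.pop("scenario", "default")
    valid = {f.name for f in dataclasses.fields(sim_mod.SimulationConfig)}
    unknown = set(sim_section) - valid
    if unknown:
        raise ConfigError(f"unknown simulate keys: {sorted(unknown)}")
    sim_cfg = sim_mod.SimulationConfig(seed=int(seed), **sim_section)
    if scenario == "segment_recovery":
        sim_cfg = sim_cfg.for_segment_recovery()
    return sim_cfg


def _checksum(path: Path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            digest.update(chunk)
    return digest.hexdigest()[:16]


def run_pipeline(config: dict | str | Path, outdir: str | Path | None = None) -> dict[str, Path]:
    """Run every requested stage and write all tables plus a manifest.

    Returns a mapping of output names to written paths.  Configuration
    errors raise before any output is produced.
    """
    cfg = load_config(config) if not isinstance(config, dict) else dict(config)
    out = Path(outdir or cfg.get("outdir") or "medipseq_out")
    study = Study.from_config(cfg)  # fail-fast: validates before writing
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    def write(name: str, df: pd.DataFrame) -> None:
        path = out / f"{name}.tsv"
        genome_io.write_table(df, path)
        written[name] = path

    seg_table = study.segment_table()
    write("segments", seg_table)
    newick = study.clustering(seg_table)
    (out / "clustering.nwk").write_text(newick + "\n")
    written["clustering"] = out / "clustering.nwk"

    cpg_table = study.cpg_table()
    write("cpg_sites", cpg_table)
    write("feature_summary", study.feature_summary(cpg_table))
    write("tss_distance_profiles", study.distance_profiles(cpg_table))

    corr = study.correlation_tables()
    if corr is not None:
        correlations, fractions = corr
        write("gene_bin_correlations", correlations)
        write("correlation_fractions", fractions)

    emt_result = study.emt_tables(cpg_table)
    if emt_result is not None:
        site_table, cgi_table, fractions, region_fractions = emt_result
        write("emt_sites", site_table)
        write("emt_cgi_transitions", cgi_table)
        write("emt_alteration_fractions", fractions)
        write("emt_region_fractions", region_fractions)
        (out / "emt_cgi_read_fractions.json").write_text(
            json.dumps(cgi_table.attrs.get("fraction_reads_in_cgis", {}), indent=2)
        )
        written["emt_cgi_read_fractions"] = out / "emt_cgi_read_fractions.json"

    manifest = {
        "seed": cfg.get("seed"),
        "params": study.params,
        "groups": study.groups,
        "samples": sorted(study.medip_reads),
        "input_samples": sorted(study.input_reads),
        "inputs_checksums": {
            key: _checksum(Path(path))
            for key, path in (cfg.get("inputs") or {}).items()
            if isinstance(path, (str, Path)) and Path(path).is_file()
        },
        "outputs": {k: str(v) for k, v in written.items()},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    written["manifest"] = out / "manifest.json"
    return written
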