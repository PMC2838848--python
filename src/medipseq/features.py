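"""Genomic-feature attribution of CpG sites and TSS-distance profiles.

Each CpG receives exactly one label with priority repeat > promoter >
exon > intron > intergenic: repeats are excluded before gene features are
considered, and a promoter (the 10 kb strand-upstream flank of a TSS)
outranks exon/intron membership of another gene.  TSS distances are
strand-aware and signed: negative means upstream of the nearest TSS in
gene orientation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome_io import AnnotationTrack, GeneModel

FEATURE_PRIORITY = ["repeat", "promoter", "exon", "intron", "intergenic"]


def _merge_intervals(intervals: list[tuple[int, int]]) -> tuple[np.ndarray, np.ndarray]:
    """Merge overlapping half-open intervals; returns sorted start/end arrays."""
    if not intervals:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    intervals = sorted(intervals)
    starts, ends = [intervals[0][0]], [intervals[0][1]]
    for s, e in intervals[1:]:
        if s <= ends[-1]:
            ends[-1] = max(ends[-1], e)
        else:
            starts.append(s)
            ends.append(e)
    return np.asarray(starts, dtype=np.int64), np.asarray(ends, dtype=np.int64)


def _member_mask(
    starts: np.ndarray, ends: np.ndarray, pos: np.ndarray
) -> np.ndarray:
    if len(starts) == 0:
        return np.zeros(len(pos), dtype=bool)
    idx = np.searchsorted(starts, pos, side="right") - 1
    valid = idx >= 0
    out = np.zeros(len(pos), dtype=bool)
    out[valid] = pos[valid] < ends[idx[valid]]
    return out


@dataclass
class FeatureIndex:
    """Merged per-chromosome interval sets for each prioritized feature."""

    tracks: dict[str, dict[str, tuple[np.ndarray, np.ndarray]]]
    promoter_span: int

    def labels_for(self, chrom: str, pos: np.ndarray) -> np.ndarray:
        labels = np.full(len(pos), "intergenic", dtype=object)
        unassigned = np.ones(len(pos), dtype=bool)
        for feature in ("repeat", "promoter", "exon", "intron"):
            per_chrom = self.tracks.get(feature, {})
            if chrom not in per_chrom or not unassigned.any():
                continue
            starts, ends = per_chrom[chrom]
            hit = _member_mask(starts, ends, pos) & unassigned
            labels[hit] = feature
            unassigned &= ~hit
        return labels


def promoter_interval(gene: GeneModel, promoter_span: int = 10_000) -> tuple[int, int]:
    """Strand-upstream promoter flank of a gene's TSS (half-open)."""
    if gene.strand == "+":
        return max(gene.tss - promoter_span, 0), gene.tss
    return gene.tss + 1, gene.tss + 1 + promoter_span


def build_feature_index(
    genes: list[GeneModel],
    repeats: AnnotationTrack | None = None,
    promoter_span: int = 10_000,
) -> FeatureIndex:
    """Build the prioritized interval index for feature attribution."""
    raw: dict[str, dict[str, list[tuple[int, int]]]] = {
        "repeat": {},
        "promoter": {},
        "exon": {},
        "intron": {},
    }
    if repeats is not None:
        for row in repeats.intervals.itertuples(index=False):
            raw["repeat"].setdefault(row.chrom, []).append((row.start, row.end))
    for gene in genes:
        raw["promoter"].setdefault(gene.chrom, []).append(
            promoter_interval(gene, promoter_span)
        )
        raw["exon"].setdefault(gene.chrom, []).extend(gene.exons)
        raw["intron"].setdefault(gene.chrom, []).extend(gene.introns)
    tracks = {
        feature: {chrom: _merge_intervals(ivs) for chrom, ivs in per_chrom.items()}
        for feature, per_chrom in raw.items()
    }
    return FeatureIndex(tracks, promoter_span)


def assign_feature(cpg_sites: pd.DataFrame, index: FeatureIndex) -> np.ndarray:
    """One feature label per site (a partition over all sites)."""
    out = np.empty(len(cpg_sites), dtype=object)
    offset = 0
    for chrom, grp in cpg_sites.groupby("chrom", sort=False):
        out[offset : offset + len(grp)] = index.labels_for(chrom, grp["pos"].to_numpy())
        offset += len(grp)
    return out


def tss_distance(
    cpg_sites: pd.DataFrame, genes: list[GeneModel], max_dist: int = 10_000
) -> np.ndarray:
    """Signed distance to the nearest TSS within max_dist, NaN beyond.

    For a + strand gene the distance is pos - tss; for a - strand gene it
    is tss - pos, so negative always means upstream of the gene.  Ties in
    absolute distance are broken toward the lexicographically smaller
    gene id.
    """
    by_chrom: dict[str, list[tuple[int, str, str]]] = {}
    for gene in genes:
        by_chrom.setdefault(gene.chrom, []).append((gene.tss, gene.gene_id, gene.strand))
    indexed = {}
    for chrom, entries in by_chrom.items():
        entries.sort()  # by (tss, gene_id)
        tss = np.asarray([e[0] for e in entries], dtype=np.int64)
        ids = np.asarray([e[1] for e in entries], dtype=object)
        sign = np.asarray([1 if e[2] == "+" else -1 for e in entries], dtype=np.int64)
        indexed[chrom] = (tss, ids, sign)

    out = np.full(len(cpg_sites), np.nan)
    offset = 0
    for chrom, grp in cpg_sites.groupby("chrom", sort=False):
        n = len(grp)
        if chrom in indexed:
            tss, ids, sign = indexed[chrom]
            pos = grp["pos"].to_numpy()
            right = np.searchsorted(tss, pos, side="left")
            left = right - 1
            right_c = np.clip(right, 0, len(tss) - 1)
            left_c = np.clip(left, 0, len(tss) - 1)
            d_left = np.abs(pos - tss[left_c]).astype(float)
            d_right = np.abs(pos - tss[right_c]).astype(float)
            d_left[left < 0] = np.inf
            d_right[right >= len(tss)] = np.inf
            use_left = d_left < d_right
            tie = d_left == d_right
            if tie.any():
                # equal absolute distance: prefer the smaller gene id
                lt = ids[left_c[tie]].astype(str) <= ids[right_c[tie]].astype(str)
                use_left[tie] = lt
            chosen = np.where(use_left, left_c, right_c)
            best = np.minimum(d_left, d_right)
            signed = (pos - tss[chosen]) * sign[chosen]
            signed = signed.astype(float)
            signed[best > max_dist] = np.nan
            signed[~np.isfinite(best)] = np.nan
            out[offset : offset + n] = signed
        offset += n
    return out


def distance_profile(
    subset_mask: np.ndarray,
    distances: np.ndarray,
    bin_size: int = 500,
    max_dist: int = 10_000,
) -> pd.DataFrame:
    """Binned TSS-distance profile of a site subset against all sites.

    For each bin: the subset count, the total CpG count, and their ratio
    (the subset's relative frequency corrected for CpG density; NaN where
    the bin holds no CpGs).
    """
    distances = np.asarray(distances, dtype=float)
    subset_mask = np.asarray(subset_mask, dtype=bool)
    edges = np.arange(-max_dist, max_dist + bin_size, bin_size)
    defined = np.isfinite(distances)
    total, _ = np.histogram(distances[defined], bins=edges)
    sub, _ = np.histogram(distances[defined & subset_mask], bins=edges)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = sub / total
    return pd.DataFrame(
        {
            "bin_left": edges[:-1],
            "bin_right": edges[1:],
            "subset_count": sub,
            "total_count": total,
            "ratio": ratio,
        }
    )
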