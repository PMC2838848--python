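"""Segment-level differential methylation.

The genome is tiled into fixed windows (default 100 kb); fragment blocks
are counted per segment and sample, scaled to reads per 10 million total,
divided by the matched input library (with a pseudocount), and each test
sample is classified per segment against the reference by a symmetric
fold-change rule (default two-fold): ``hyper`` for a >= fold increase,
``hypo`` for a >= fold decrease, ``nd`` otherwise.  Segments whose input
coverage exceeds a fold of the genome-wide median are flagged as amplified
and excluded from classification, since copy-number gain inflates MeDIP
counts irrespective of methylation.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .genome_io import GeneModel, GenomeModel

logger = logging.getLogger(__name__)


def tile_genome(genome: GenomeModel | dict[str, int], window: int = 100_000) -> pd.DataFrame:
    """Tile every chromosome into consecutive half-open windows.

    The last segment of a chromosome may be shorter than ``window``.
    """
    if window < 1000:
        raise ValueError(f"window must be >= 1000 (got {window})")
    lengths = genome.lengths if isinstance(genome, GenomeModel) else dict(genome)
    rows = []
    for chrom, length in lengths.items():
        starts = np.arange(0, length, window, dtype=np.int64)
        ends = np.minimum(starts + window, length)
        rows.append(pd.DataFrame({"chrom": chrom, "start": starts, "end": ends}))
    return pd.concat(rows, ignore_index=True)


def _segment_index(segments: pd.DataFrame):
    """Per-chromosome (row offset, start array, chrom end) lookup."""
    index = {}
    for chrom, grp in segments.groupby("chrom", sort=False):
        index[chrom] = (
            grp.index.to_numpy(),
            grp["start"].to_numpy(),
            int(grp["end"].iloc[-1]),
        )
    return index


def count_blocks(
    blocks: pd.DataFrame, segments: pd.DataFrame, assignment: str = "midpoint"
) -> np.ndarray:
    """Raw block counts per segment.

    ``midpoint`` assigns each block to the single segment containing its
    midpoint (counts are conserved); ``overlap`` counts a block once in
    every segment it overlaps.
    """
    if assignment not in ("midpoint", "overlap"):
        raise ValueError(f"unknown assignment mode {assignment!r}")
    counts = np.zeros(len(segments), dtype=np.int64)
    if blocks.empty:
        return counts
    index = _segment_index(segments)
    for chrom, grp in blocks.groupby("chrom", sort=False):
        if chrom not in index:
            continue
        rows, seg_starts, chrom_end = index[chrom]
        if assignment == "midpoint":
            mid = (grp["start"].to_numpy() + grp["end"].to_numpy()) // 2
            mid = np.clip(mid, 0, chrom_end - 1)
            idx = np.searchsorted(seg_starts, mid, side="right") - 1
            np.add.at(counts, rows[idx], 1)
        else:
            start = np.clip(grp["start"].to_numpy(), 0, chrom_end - 1)
            end = np.clip(grp["end"].to_numpy(), 1, chrom_end)
            first = np.searchsorted(seg_starts, start, side="right") - 1
            last = np.searchsorted(seg_starts, end - 1, side="right") - 1
            k = 0
            while True:
                sel = first + k <= last
                if not sel.any():
                    break
                np.add.at(counts, rows[first[sel] + k], 1)
                k += 1
    return counts


def normalize(raw_counts: np.ndarray, total_blocks: int) -> np.ndarray:
    """Scale raw counts to reads per 10 million total sample reads."""
    if total_blocks <= 0:
        raise ValueError("total_blocks must be positive")
    return np.asarray(raw_counts, dtype=float) * 1e7 / total_blocks


def medip_input_ratio(
    medip_norm: np.ndarray,
    input_norm: np.ndarray | None = None,
    pseudocount: float = 1.0,
) -> np.ndarray:
    """Per-segment MeDIP/input ratio with a pseudocount on both terms.

    Samples without an input library fall back to the normalized MeDIP
    count itself (callers flag these as "no-input").
    """
    medip_norm = np.asarray(medip_norm, dtype=float)
    if (medip_norm < 0).any():
        raise ValueError("negative MeDIP counts")
    if input_norm is None:
        return medip_norm.copy()
    input_norm = np.asarray(input_norm, dtype=float)
    if (input_norm < 0).any():
        raise ValueError("negative input counts")
    return (medip_norm + pseudocount) / (input_norm + pseudocount)


def detect_amplified(input_norm: np.ndarray, fold: float = 3.0) -> np.ndarray:
    """Flag segments whose input coverage is > fold x genome-wide median."""
    input_norm = np.asarray(input_norm, dtype=float)
    median = np.median(input_norm)
    if median == 0 and input_norm.max() == 0:
        logger.warning("all-zero input counts; no amplification flags set")
        return np.zeros(len(input_norm), dtype=bool)
    return input_norm > fold * median


def classify_segments(
    sample_ratio: np.ndarray,
    reference_ratio: np.ndarray,
    fold: float = 2.0,
    masked: np.ndarray | None = None,
) -> np.ndarray:
    """Fold-change classification of each segment against the reference.

    ``hyper`` iff sample/reference >= fold, ``hypo`` iff reference/sample
    >= fold (both inclusive), else ``nd``.  Masked (e.g. amplified)
    segments are forced to ``nd``.
    """
    if fold <= 1:
        raise ValueError(f"fold must be > 1 (got {fold})")
    s = np.asarray(sample_ratio, dtype=float)
    r = np.asarray(reference_ratio, dtype=float)
    hyper = (s >= fold * r) & (s > 0)
    hypo = (r >= fold * s) & (r > 0)
    out = np.where(hyper, "hyper", np.where(hypo, "hypo", "nd")).astype(object)
    if masked is not None:
        out[np.asarray(masked, dtype=bool)] = "nd"
    return out


def annotate_segments(
    segments: pd.DataFrame, cpg_sites: pd.DataFrame, genes: list[GeneModel]
) -> pd.DataFrame:
    """Count CpG sites and gene TSSs falling inside each segment."""
    index = _segment_index(segments)
    n_cpg = np.zeros(len(segments), dtype=np.int64)
    n_genes = np.zeros(len(segments), dtype=np.int64)
    for chrom, grp in cpg_sites.groupby("chrom", sort=False):
        if chrom not in index:
            continue
        rows, seg_starts, chrom_end = index[chrom]
        pos = grp["pos"].to_numpy()
        pos = pos[pos < chrom_end]
        idx = np.searchsorted(seg_starts, pos, side="right") - 1
        np.add.at(n_cpg, rows[idx], 1)
    for gene in genes:
        if gene.chrom not in index:
            continue
        rows, seg_starts, chrom_end = index[gene.chrom]
        if gene.tss < chrom_end:
            idx = int(np.searchsorted(seg_starts, gene.tss, side="right")) - 1
            n_genes[rows[idx]] += 1
    out = segments.copy()
    out["n_cpg"] = n_cpg
    out["n_genes"] = n_genes
    return out


def cluster_samples(norm_matrix: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    """Average-linkage clustering of samples on segment profiles.

    Distance is 1 - Pearson correlation of log2(normalized count + 1)
    profiles.  Samples are ordered lexicographically before linkage so the
    tree is deterministic regardless of column order.
    """
    if norm_matrix.shape[1] < 2:
        raise ValueError("need at least two samples to cluster")
    labels = sorted(norm_matrix.columns)
    logmat = np.log2(norm_matrix[labels].to_numpy(dtype=float) + 1.0)
    corr = np.corrcoef(logmat.T)
    corr = np.nan_to_num(corr, nan=0.0)
    dist = np.clip(1.0 - corr, 0.0, None)
    np.fill_diagonal(dist, 0.0)
    linkage = hierarchy.linkage(squareform(dist, checks=False), method="average")
    return linkage, labels


def linkage_to_newick(linkage: np.ndarray, labels: list[str]) -> str:
    """Serialize a scipy linkage tree as a Newick string with branch lengths."""
    tree = hierarchy.to_tree(linkage)

    def render(node, parent_height: float) -> str:
        length = max(parent_height - node.dist, 0.0) if parent_height is not None else 0.0
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        left = render(node.left, node.dist)
        right = render(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    # root branch length is meaningless; render children against root height
    left = render(tree.left, tree.dist)
    right = render(tree.right, tree.dist)
    return f"({left},{right});"


def build_segment_table(
    genome: GenomeModel,
    blocks_by_sample: dict[str, pd.DataFrame],
    input_blocks_by_sample: dict[str, pd.DataFrame],
    reference: str,
    window: int = 100_000,
    fold: float = 2.0,
    pseudocount: float = 1.0,
    amp_fold: float = 3.0,
    assignment: str = "midpoint",
    cpg_sites: pd.DataFrame | None = None,
    genes: list[GeneModel] | None = None,
) -> pd.DataFrame:
    """Full segment table: counts, ratios, amplification flags and classes.

    ``blocks_by_sample`` maps MeDIP sample ids to block frames;
    ``input_blocks_by_sample`` maps the subset with input libraries.  Every
    non-reference sample is classified against ``reference``.
    """
    if reference not in blocks_by_sample:
        raise ValueError(f"reference sample {reference!r} has no MeDIP blocks")
    table = tile_genome(genome, window=window)
    ratios: dict[str, np.ndarray] = {}
    norms: dict[str, np.ndarray] = {}
    masks: dict[str, np.ndarray] = {}
    for sample, blocks in blocks_by_sample.items():
        raw = count_blocks(blocks, table, assignment=assignment)
        norm = normalize(raw, max(len(blocks), 1))
        norms[sample] = norm
        table[f"raw_{sample}"] = raw
        table[f"norm_{sample}"] = norm
        if sample in input_blocks_by_sample:
            iblocks = input_blocks_by_sample[sample]
            iraw = count_blocks(iblocks, table, assignment=assignment)
            inorm = normalize(iraw, max(len(iblocks), 1))
            table[f"input_norm_{sample}"] = inorm
            ratios[sample] = medip_input_ratio(norm, inorm, pseudocount)
            masks[sample] = detect_amplified(inorm, fold=amp_fold)
            table[f"amplified_{sample}"] = masks[sample]
            table[f"no_input_{sample}"] = False
        else:
            ratios[sample] = medip_input_ratio(norm, None, pseudocount)
            masks[sample] = np.zeros(len(table), dtype=bool)
            table[f"amplified_{sample}"] = False
            table[f"no_input_{sample}"] = True
        table[f"ratio_{sample}"] = ratios[sample]
    ref_mask = masks[reference]
    ref_has_input = reference in input_blocks_by_sample
    for sample in blocks_by_sample:
        if sample == reference:
            continue
        mask = masks[sample] | ref_mask
        if ref_has_input and sample in input_blocks_by_sample:
            s_vals, r_vals = ratios[sample], ratios[reference]
        else:
            # no-input fallback: compare normalized MeDIP counts on both
            # sides so the pairwise comparison stays like-for-like
            s_vals = norms[sample] + pseudocount
            r_vals = norms[reference] + pseudocount
        table[f"class_{sample}"] = classify_segments(
            s_vals, r_vals, fold=fold, masked=mask
        )
    if cpg_sites is not None and genes is not None:
        table = annotate_segments(table, cpg_sites, genes)
    return table
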