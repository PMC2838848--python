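"""Methylation-expression correlation around transcription start sites.

The +/-10 kb around each TSS is divided into 1 kb bins oriented along the
gene (bin -10..-1 upstream, +1..+10 downstream); per-10M normalized block
counts per bin are correlated across samples with each gene's expression
(log2 transforms on both sides).  Genes are labeled positively/negatively
correlated per bin at |r| >= 0.5 by default, and the per-bin fractions of
labeled genes summarize how the methylation-expression relationship
changes with distance from the TSS.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genome_io import GeneModel, GenomeModel
from .segments import normalize

logger = logging.getLogger(__name__)


def bin_tss_regions(
    genes: list[GeneModel],
    genome: GenomeModel | dict[str, int],
    span: int = 10_000,
    bin_size: int = 1_000,
) -> pd.DataFrame:
    """Strand-oriented TSS-flanking bins per gene.

    Bin indices run -span/bin .. -1 (upstream) and +1 .. +span/bin
    (downstream), flipped for - strand genes so +1 is always the first
    kilobase of the gene body.  Bins extending past a chromosome end are
    marked ``missing``.
    """
    if span % bin_size:
        raise ValueError("span must be a multiple of bin_size")
    n_bins = span // bin_size
    lengths = genome.lengths if isinstance(genome, GenomeModel) else dict(genome)
    rows = []
    ks = [k for k in range(-n_bins, n_bins + 1) if k != 0]
    for gene in genes:
        chrom_len = lengths[gene.chrom]
        t = gene.tss
        for k in ks:
            if gene.strand == "+":
                if k > 0:
                    start, end = t + (k - 1) * bin_size, t + k * bin_size
                else:
                    start, end = t + k * bin_size, t + (k + 1) * bin_size
            else:
                if k > 0:
                    start, end = t - k * bin_size + 1, t - (k - 1) * bin_size + 1
                else:
                    start, end = t - (k + 1) * bin_size + 1, t - k * bin_size + 1
            rows.append(
                {
                    "gene_id": gene.gene_id,
                    "bin": k,
                    "chrom": gene.chrom,
                    "start": start,
                    "end": end,
                    "missing": start < 0 or end > chrom_len,
                }
            )
    return pd.DataFrame(rows)


def bin_counts(
    blocks_by_sample: dict[str, pd.DataFrame], bins: pd.DataFrame
) -> pd.DataFrame:
    """Per-10M normalized block counts per (gene, bin) and sample.

    A block is assigned to a bin when its midpoint falls inside it (bins
    of different genes may overlap, so a block can be counted for several
    genes but once per gene bin).  Missing bins get NaN.
    """
    out = bins[["gene_id", "bin", "chrom", "start", "end", "missing"]].copy()
    for sample, blocks in blocks_by_sample.items():
        counts = np.zeros(len(bins), dtype=float)
        mids_by_chrom = {
            chrom: np.sort(((g["start"] + g["end"]) // 2).to_numpy())
            for chrom, g in blocks.groupby("chrom", sort=False)
        }
        offset = 0
        for chrom, grp in bins.groupby("chrom", sort=False):
            n = len(grp)
            mids = mids_by_chrom.get(chrom)
            if mids is not None and len(mids):
                lo = np.searchsorted(mids, grp["start"].to_numpy(), side="left")
                hi = np.searchsorted(mids, grp["end"].to_numpy(), side="left")
                counts[offset : offset + n] = hi - lo
            offset += n
        counts = normalize(counts, max(len(blocks), 1))
        counts[bins["missing"].to_numpy(dtype=bool)] = np.nan
        out[sample] = counts
    return out


def correlate_gene_bins(
    binned: pd.DataFrame,
    expression: pd.DataFrame,
    method: str = "pearson",
    threshold: float = 0.5,
) -> pd.DataFrame:
    """Per (gene, bin) correlation between methylation and expression.

    r is computed across the samples present in both tables between
    log2(normalized bin count + 1) and log2(expression + 1).  Labels:
    positive (r >= threshold), negative (r <= -threshold), none.  Rows
    with zero variance on either side get NaN r and label none.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown correlation method {method!r}")
    samples = [s for s in expression.columns if s in binned.columns]
    if len(samples) < 4:
        raise ValueError(
            f"need >= 4 samples shared between methylation and expression, got {len(samples)}"
        )
    known = binned["gene_id"].isin(expression.index)
    n_dropped = int((~known).sum())
    if n_dropped:
        logger.info(
            "dropping %d gene bins without expression (%d genes)",
            n_dropped,
            binned.loc[~known, "gene_id"].nunique(),
        )
    work = binned[known].reset_index(drop=True)
    meth = np.log2(work[samples].to_numpy(dtype=float) + 1.0)
    expr = np.log2(expression.loc[work["gene_id"], samples].to_numpy(dtype=float) + 1.0)
    if method == "spearman":
        meth = stats.rankdata(meth, axis=1)
        expr = stats.rankdata(expr, axis=1)
    mx = meth - np.nanmean(meth, axis=1, keepdims=True)
    ex = expr - expr.mean(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.nansum(mx * ex, axis=1) / np.sqrt(
            np.nansum(mx**2, axis=1) * np.nansum(ex**2, axis=1)
        )
    r[np.isnan(meth).any(axis=1)] = np.nan  # bins missing in any sample
    label = np.where(
        np.isnan(r),
        "none",
        np.where(r >= threshold, "positive", np.where(r <= -threshold, "negative", "none")),
    ).astype(object)
    out = work[["gene_id", "bin"]].copy()
    out["r"] = r
    out["label"] = label
    return out


def fraction_by_distance(correlations: pd.DataFrame) -> pd.DataFrame:
    """Per-bin fractions of positively/negatively correlated genes.

    Fractions are taken over genes with a defined r in the bin; bins with
    no defined genes are reported with NaN fractions.
    """
    rows = []
    for bin_idx, grp in correlations.groupby("bin"):
        defined = grp["r"].notna()
        n = int(defined.sum())
        if n:
            pos = float((grp.loc[defined, "label"] == "positive").mean())
            neg = float((grp.loc[defined, "label"] == "negative").mean())
        else:
            pos = neg = np.nan
        rows.append(
            {"bin": bin_idx, "n_genes": n, "fraction_positive": pos, "fraction_negative": neg}
        )
    return pd.DataFrame(rows).sort_values("bin").reset_index(drop=True)
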