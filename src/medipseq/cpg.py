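"""CpG-level qualitative differential methylation and sequence context.

At single-CpG resolution the MeDIP signal is treated as presence/absence:
a site is *covered* in a sample when at least ``min_depth`` deduplicated
blocks overlap the CG dinucleotide.  A site is called ``hyper`` when every
test-group sample covers it but the reference does not, and ``hypo`` when
the reference covers it but no test sample does.  Sequence context is
scored by the number of neighboring CpGs and the observed/expected CpG
ratio CpG_o/e = (N_CpG x L) / (N_C x N_G) over a centered window (default
500 bp); sites split into CpG-rich (> 0.6, the classical CpG-island
criterion) and CpG-poor.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .genome_io import GenomeModel


def cpg_depth(cpg_sites: pd.DataFrame, blocks: pd.DataFrame) -> np.ndarray:
    """Number of blocks overlapping each site's [pos, pos+2) dinucleotide."""
    depth = np.zeros(len(cpg_sites), dtype=np.int64)
    if blocks.empty or cpg_sites.empty:
        return depth
    by_chrom = {c: g for c, g in blocks.groupby("chrom", sort=False)}
    offset = 0
    for chrom, grp in cpg_sites.groupby("chrom", sort=False):
        n = len(grp)
        if chrom in by_chrom:
            b = by_chrom[chrom]
            starts = np.sort(b["start"].to_numpy())
            ends = np.sort(b["end"].to_numpy())
            pos = grp["pos"].to_numpy()
            # blocks with start < pos+2 and end > pos overlap [pos, pos+2)
            n_started = np.searchsorted(starts, pos + 2, side="left")
            n_ended = np.searchsorted(ends, pos, side="right")
            depth[offset : offset + n] = n_started - n_ended
        offset += n
    return depth


def cpg_coverage(
    cpg_sites: pd.DataFrame, blocks: pd.DataFrame, min_depth: int = 1
) -> np.ndarray:
    """Boolean coverage flags: >= min_depth blocks overlap the site."""
    return cpg_depth(cpg_sites, blocks) >= min_depth


def coverage_matrix(
    cpg_sites: pd.DataFrame,
    blocks_by_sample: dict[str, pd.DataFrame],
    min_depth: int = 1,
) -> pd.DataFrame:
    """Site x sample boolean coverage matrix (row-aligned with cpg_sites)."""
    return pd.DataFrame(
        {
            sample: cpg_coverage(cpg_sites, blocks, min_depth)
            for sample, blocks in blocks_by_sample.items()
        }
    )


def classify_cpgs(
    coverage: pd.DataFrame, reference: str, group: Sequence[str]
) -> np.ndarray:
    """Qualitative per-site classes against a reference sample.

    ``hyper``: covered in every group sample and not in the reference;
    ``hypo``: covered in the reference and in no group sample; else
    ``neither``.
    """
    if not group:
        raise ValueError("group must contain at least one sample")
    if reference in group:
        raise ValueError(f"reference {reference!r} must not be in the group")
    ref = coverage[reference].to_numpy(dtype=bool)
    grp = coverage[list(group)].to_numpy(dtype=bool)
    all_grp = grp.all(axis=1)
    any_grp = grp.any(axis=1)
    hyper = all_grp & ~ref
    hypo = ref & ~any_grp
    return np.where(hyper, "hyper", np.where(hypo, "hypo", "neither")).astype(object)


def neighbor_cpg_count(cpg_sites: pd.DataFrame, window: int = 500) -> np.ndarray:
    """Number of *other* CpG sites within the centered window per site.

    The window is [pos - window//2, pos + window//2); the site itself is
    excluded from its own count.
    """
    half = window // 2
    out = np.zeros(len(cpg_sites), dtype=np.int64)
    offset = 0
    for _, grp in cpg_sites.groupby("chrom", sort=False):
        pos = np.sort(grp["pos"].to_numpy())
        query = grp["pos"].to_numpy()
        lo = np.searchsorted(pos, query - half, side="left")
        hi = np.searchsorted(pos, query + half, side="left")
        out[offset : offset + len(grp)] = hi - lo - 1  # window always contains self
        offset += len(grp)
    return out


def cpg_oe(
    genome: GenomeModel, cpg_sites: pd.DataFrame, window: int = 500
) -> np.ndarray:
    """Observed/expected CpG ratio over a centered window per site.

    CpG_o/e = (N_CpG x L) / (N_C x N_G) where the window is
    [pos - window//2, pos + window//2) clipped to the chromosome, L is the
    clipped window length, and N_CpG counts CG dinucleotides fully inside
    the window.  Returns 0 where N_C or N_G is 0.  N bases never form CpGs
    but do count toward L.
    """
    if window < 10:
        raise ValueError(f"window must be >= 10 (got {window})")
    half = window // 2
    out = np.zeros(len(cpg_sites), dtype=float)
    offset = 0
    for chrom, grp in cpg_sites.groupby("chrom", sort=False):
        seq = genome.sequences[chrom]
        arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
        is_c = arr == ord("C")
        is_g = arr == ord("G")
        cum_c = np.concatenate([[0], np.cumsum(is_c)])
        cum_g = np.concatenate([[0], np.cumsum(is_g)])
        cg = is_c[:-1] & is_g[1:] if len(arr) > 1 else np.zeros(0, dtype=bool)
        cum_cg = np.concatenate([[0], np.cumsum(cg)])  # cum_cg[i] = # CG starts < i
        pos = grp["pos"].to_numpy()
        a = np.clip(pos - half, 0, len(arr))
        b = np.clip(pos + half, 0, len(arr))
        length = (b - a).astype(float)
        n_c = cum_c[b] - cum_c[a]
        n_g = cum_g[b] - cum_g[a]
        # CG fully inside [a, b): start q with a <= q <= b-2
        hi = np.clip(b - 1, 0, len(cum_cg) - 1)
        lo = np.clip(a, 0, len(cum_cg) - 1)
        n_cpg = cum_cg[hi] - cum_cg[lo]
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = (n_cpg * length) / (n_c * n_g)
        ratio[(n_c == 0) | (n_g == 0)] = 0.0
        out[offset : offset + len(grp)] = ratio
        offset += len(grp)
    return out


def split_by_oe(oe_values: np.ndarray, threshold: float = 0.6) -> np.ndarray:
    """Partition labels: 'cpg_rich' where o/e > threshold, else 'cpg_poor'."""
    oe_values = np.asarray(oe_values, dtype=float)
    return np.where(oe_values > threshold, "cpg_rich", "cpg_poor").astype(object)


def oe_distribution(
    oe_values: Iterable[float],
    subset: np.ndarray | None = None,
    bins: int | Sequence[float] = 40,
    range_: tuple[float, float] = (0.0, 2.0),
) -> pd.DataFrame:
    """Binned density of CpG_o/e over an optional site subset."""
    values = np.asarray(list(oe_values) if not isinstance(oe_values, np.ndarray) else oe_values)
    if subset is not None:
        values = values[np.asarray(subset, dtype=bool)]
    counts, edges = np.histogram(values, bins=bins, range=range_)
    total = counts.sum()
    density = counts / total if total else np.zeros_like(counts, dtype=float)
    return pd.DataFrame(
        {"bin_left": edges[:-1], "bin_right": edges[1:], "count": counts, "density": density}
    )


def build_cpg_table(
    genome: GenomeModel,
    cpg_sites: pd.DataFrame,
    blocks_by_sample: dict[str, pd.DataFrame],
    reference: str,
    group: Sequence[str],
    window: int = 500,
    oe_threshold: float = 0.6,
    min_depth: int = 1,
) -> pd.DataFrame:
    """Per-CpG table: context scores, coverage flags and differential class."""
    table = cpg_sites[["chrom", "pos"]].copy()
    table["neighbor_count"] = neighbor_cpg_count(cpg_sites, window=window)
    table["cpg_oe"] = cpg_oe(genome, cpg_sites, window=window)
    table["oe_class"] = split_by_oe(table["cpg_oe"].to_numpy(), threshold=oe_threshold)
    cov = coverage_matrix(cpg_sites, blocks_by_sample, min_depth=min_depth)
    for sample in cov.columns:
        table[f"covered_{sample}"] = cov[sample].to_numpy()
    table["class"] = classify_cpgs(cov, reference, group)
    return table
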