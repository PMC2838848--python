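"""Cell-type-specific methylation and EMT-induced switching.

Cell lines are grouped by phenotype (epithelial vs mesenchymal); a CpG is
*group-specific* when it is covered in every member of one group and in no
member of the other.  Comparing the EMT-induced sample against its
untreated control classifies each site as emt_hyper (gained coverage),
emt_hypo (lost coverage) or unchanged; the fraction of group-specific
sites that switched measures how far EMT moves the methylome toward the
other phenotype, against the background alteration rate over all sites.
At CpG-island resolution, per-CGI normalized counts are classified against
the reference by the two-fold rule in both control and treated states to
count hyper/hypomethylated CGIs gained and lost through EMT.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .genome_io import AnnotationTrack
from .segments import classify_segments, normalize


def group_specific_sites(
    coverage: pd.DataFrame, group_a: Sequence[str], group_b: Sequence[str]
) -> tuple[np.ndarray, np.ndarray]:
    """Masks of sites covered in all of one group and none of the other."""
    if not group_a or not group_b:
        raise ValueError("both groups need at least one sample")
    if set(group_a) & set(group_b):
        raise ValueError(f"groups overlap: {sorted(set(group_a) & set(group_b))}")
    a = coverage[list(group_a)].to_numpy(dtype=bool)
    b = coverage[list(group_b)].to_numpy(dtype=bool)
    a_specific = a.all(axis=1) & ~b.any(axis=1)
    b_specific = b.all(axis=1) & ~a.any(axis=1)
    return a_specific, b_specific


def emt_cpg_changes(
    coverage_control: np.ndarray, coverage_treated: np.ndarray
) -> np.ndarray:
    """Per-site coverage transition between control and treated samples."""
    control = np.asarray(coverage_control, dtype=bool)
    treated = np.asarray(coverage_treated, dtype=bool)
    return np.where(
        treated & ~control,
        "emt_hyper",
        np.where(control & ~treated, "emt_hypo", "unchanged"),
    ).astype(object)


def _overlap_counts(intervals: pd.DataFrame, blocks: pd.DataFrame) -> np.ndarray:
    """Blocks overlapping each half-open interval (one count per block)."""
    counts = np.zeros(len(intervals), dtype=np.int64)
    by_chrom = {c: g for c, g in blocks.groupby("chrom", sort=False)}
    offset = 0
    for chrom, grp in intervals.groupby("chrom", sort=False):
        n = len(grp)
        if chrom in by_chrom:
            b = by_chrom[chrom]
            starts = np.sort(b["start"].to_numpy())
            ends = np.sort(b["end"].to_numpy())
            s = grp["start"].to_numpy()
            e = grp["end"].to_numpy()
            counts[offset : offset + n] = np.searchsorted(
                starts, e, side="left"
            ) - np.searchsorted(ends, s, side="right")
        offset += n
    return counts


def fraction_reads_in_intervals(
    track: AnnotationTrack, blocks: pd.DataFrame
) -> float:
    """Fraction of a sample's blocks overlapping any track interval."""
    if blocks.empty:
        return float("nan")
    n_in = 0
    for chrom, grp in blocks.groupby("chrom", sort=False):
        ivs = track.for_chrom(chrom)
        if ivs.empty:
            continue
        starts = ivs["start"].to_numpy()
        ends = ivs["end"].to_numpy()
        # merged membership: a block [s,e) overlaps some interval iff the
        # first interval ending after s starts before e
        order = np.argsort(starts)
        starts, ends = starts[order], np.maximum.accumulate(ends[order])
        s = grp["start"].to_numpy()
        e = grp["end"].to_numpy()
        idx = np.searchsorted(ends, s, side="right")
        hit = (idx < len(starts)) & (starts[np.clip(idx, 0, len(starts) - 1)] < e)
        n_in += int(hit.sum())
    return n_in / len(blocks)


def emt_cgi_changes(
    cgis: AnnotationTrack,
    blocks_control: pd.DataFrame,
    blocks_treated: pd.DataFrame,
    blocks_reference: pd.DataFrame,
    fold: float = 2.0,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Per-CGI methylation status vs the reference before and after EMT.

    Counts blocks overlapping each CGI, normalizes per 10M, classifies
    both states against the reference with the fold rule, and reports the
    transition (e.g. "hyper lost" when a CGI is hyper in the control but
    not in the treated sample).  Table attrs carry the per-sample fraction
    of reads covering CGIs.
    """
    table = cgis.intervals.copy()
    norms = {}
    for name, blocks in (
        ("control", blocks_control),
        ("treated", blocks_treated),
        ("reference", blocks_reference),
    ):
        raw = _overlap_counts(table, blocks)
        norms[name] = normalize(raw, max(len(blocks), 1))
        table[f"raw_{name}"] = raw
        table[f"norm_{name}"] = norms[name]
    for name in ("control", "treated"):
        # pseudocount enters the fold comparison on both sides
        table[f"status_{name}"] = classify_segments(
            norms[name] + pseudocount, norms["reference"] + pseudocount, fold=fold
        )
    transitions = []
    for c, t in zip(table["status_control"], table["status_treated"]):
        if c == t:
            transitions.append("none")
        elif c != "nd" and t == "nd":
            transitions.append(f"{c} lost")
        elif c == "nd" and t != "nd":
            transitions.append(f"{t} gained")
        else:
            transitions.append(f"{c} to {t}")
    table["transition"] = transitions
    table.attrs["fraction_reads_in_cgis"] = {
        "control": fraction_reads_in_intervals(cgis, blocks_control),
        "treated": fraction_reads_in_intervals(cgis, blocks_treated),
        "reference": fraction_reads_in_intervals(cgis, blocks_reference),
    }
    return table


GENE_RELATED = ("promoter", "exon", "intron")


def region_alteration_fractions(
    cgis: AnnotationTrack,
    cpg_sites: pd.DataFrame,
    a_specific: np.ndarray,
    b_specific: np.ndarray,
    changes: np.ndarray,
    coverage_control: np.ndarray,
    margin: int = 250,
) -> pd.DataFrame:
    """Per-CGI (region-level) alteration fractions.

    Methylation patterns switch as regions, so the fraction of *regions*
    altered estimates the switching rate without weighting by island size.
    A CGI counts as group-specific when it contains at least one specific
    interior CpG, and as altered when the majority of those sites changed;
    background CGIs (no specific sites) are split by control coverage and
    count as altered by the majority rule over their interior sites.
    """
    interior = cgi_interior_mask(cgis, cpg_sites, margin=margin)
    # CGI row index per site (-1 outside)
    cgi_id = np.full(len(cpg_sites), -1, dtype=np.int64)
    offset = 0
    for chrom, grp in cpg_sites.groupby("chrom", sort=False):
        ivs = cgis.for_chrom(chrom)
        n = len(grp)
        if len(ivs):
            starts = ivs["start"].to_numpy()
            ends = ivs["end"].to_numpy()
            rows = ivs.index.to_numpy()
            pos = grp["pos"].to_numpy()
            idx = np.searchsorted(starts, pos, side="right") - 1
            valid = (idx >= 0) & (pos < ends[np.clip(idx, 0, len(ends) - 1)])
            cgi_id[offset : offset + n][valid] = rows[idx[valid]]
        offset += n
    cgi_id[~interior] = -1

    hypo = np.asarray(changes, dtype=object) == "emt_hypo"
    hyper = np.asarray(changes, dtype=object) == "emt_hyper"
    covered = np.asarray(coverage_control, dtype=bool)
    a_specific = np.asarray(a_specific, dtype=bool)
    b_specific = np.asarray(b_specific, dtype=bool)

    def majority(values: pd.Series) -> bool:
        return bool(values.mean() > 0.5)

    frame = pd.DataFrame(
        {
            "cgi": cgi_id,
            "a": a_specific,
            "b": b_specific,
            "hypo": hypo,
            "hyper": hyper,
            "covered": covered,
        }
    )
    frame = frame[frame["cgi"] >= 0]
    rows = []
    grouped = frame.groupby("cgi")
    a_alt, b_alt, bg_cov_alt, bg_unc_alt = [], [], [], []
    for _, g in grouped:
        if g["a"].any():
            a_alt.append(majority(g.loc[g["a"], "hypo"]))
        elif g["b"].any():
            b_alt.append(majority(g.loc[g["b"], "hyper"]))
        elif majority(g["covered"]):
            bg_cov_alt.append(majority(g.loc[g["covered"], "hypo"]))
        else:
            bg_unc_alt.append(majority(g.loc[~g["covered"], "hyper"]))

    def summarize(name: str, flags: list[bool]) -> dict:
        return {
            "group": name,
            "n_regions": len(flags),
            "fraction_altered": float(np.mean(flags)) if flags else float("nan"),
        }

    return pd.DataFrame(
        [
            summarize("a_specific_hypo", a_alt),
            summarize("b_specific_hyper", b_alt),
            summarize("background_hypo", bg_cov_alt),
            summarize("background_hyper", bg_unc_alt),
        ]
    )


def cgi_interior_mask(
    cgis: AnnotationTrack, cpg_sites: pd.DataFrame, margin: int = 250
) -> np.ndarray:
    """Sites at least ``margin`` bp inside an annotated CpG island.

    Presence/absence coverage at island borders is determined by fragments
    anchored in the flanking sequence, so alteration fractions are scored
    on island interiors, one fragment-block length (the method's spatial
    resolution) away from the boundary.
    """
    out = np.zeros(len(cpg_sites), dtype=bool)
    offset = 0
    for chrom, grp in cpg_sites.groupby("chrom", sort=False):
        ivs = cgis.for_chrom(chrom)
        n = len(grp)
        if len(ivs):
            starts = ivs["start"].to_numpy() + margin
            ends = ivs["end"].to_numpy() - margin
            keep = starts < ends
            starts, ends = starts[keep], ends[keep]
            if len(starts):
                pos = grp["pos"].to_numpy()
                idx = np.searchsorted(starts, pos, side="right") - 1
                valid = idx >= 0
                hit = np.zeros(n, dtype=bool)
                hit[valid] = pos[valid] < ends[idx[valid]]
                out[offset : offset + n] = hit
        offset += n
    return out


def alteration_fractions(
    a_specific: np.ndarray,
    b_specific: np.ndarray,
    changes: np.ndarray,
    feature_labels: np.ndarray | None = None,
    coverage_control: np.ndarray | None = None,
    restrict: np.ndarray | None = None,
) -> pd.DataFrame:
    """Conditional EMT alteration fractions per site category.

    Reports, overall and per feature category (all sites, gene-related,
    promoter/exon/intron), the fraction of group-A-specific sites that
    lost coverage (emt_hypo), the fraction of group-B-specific sites that
    gained coverage (emt_hyper), and the background rates over all sites
    in the category.  Background hypo rates are conditioned on sites
    covered in the control (only covered sites can lose coverage) when
    ``coverage_control`` is provided.  ``restrict`` limits every category
    to a site subset (e.g. CpG-rich sites, where cell-type-specific
    methylation concentrates).
    """
    a_specific = np.asarray(a_specific, dtype=bool)
    b_specific = np.asarray(b_specific, dtype=bool)
    changes = np.asarray(changes, dtype=object)
    hypo = changes == "emt_hypo"
    hyper = changes == "emt_hyper"

    base = (
        np.asarray(restrict, dtype=bool)
        if restrict is not None
        else np.ones(len(changes), dtype=bool)
    )
    categories: list[tuple[str, np.ndarray]] = [("all", base)]
    if feature_labels is not None:
        feature_labels = np.asarray(feature_labels, dtype=object)
        gene_related = np.isin(feature_labels, GENE_RELATED)
        categories.append(("gene_related", base & gene_related))
        for feat in GENE_RELATED:
            categories.append((feat, base & (feature_labels == feat)))

    def frac(num_mask: np.ndarray, denom_mask: np.ndarray) -> float:
        n = int(denom_mask.sum())
        return float((num_mask & denom_mask).sum() / n) if n else float("nan")

    rows = []
    for name, cat in categories:
        if coverage_control is not None:
            covered = np.asarray(coverage_control, dtype=bool)
            bg_hypo_denom = cat & covered & ~a_specific & ~b_specific
            bg_hyper_denom = cat & ~covered & ~a_specific & ~b_specific
        else:
            bg_hypo_denom = cat & ~a_specific & ~b_specific
            bg_hyper_denom = cat & ~a_specific & ~b_specific
        rows.append(
            {
                "category": name,
                "n_a_specific": int((cat & a_specific).sum()),
                "frac_a_specific_hypo": frac(hypo, cat & a_specific),
                "n_b_specific": int((cat & b_specific).sum()),
                "frac_b_specific_hyper": frac(hyper, cat & b_specific),
                "n_background_hypo": int(bg_hypo_denom.sum()),
                "frac_background_hypo": frac(hypo, bg_hypo_denom),
                "n_background_hyper": int(bg_hyper_denom.sum()),
                "frac_background_hyper": frac(hyper, bg_hyper_denom),
                "n_total": int(cat.sum()),
                "frac_total_hypo": frac(hypo, cat),
                "frac_total_hyper": frac(hyper, cat),
            }
        )
    return pd.DataFrame(rows)
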