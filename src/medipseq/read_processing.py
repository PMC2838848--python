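"""Fragment inference from mapped reads.

A sequenced MeDIP (or input) fragment is represented by a *block*: the
outer span of a read pair, or a fixed-length extension of a singleton read
from its 5' mapping position along its strand (default 250 bp, the
expected enriched-fragment size).  PCR duplicates - entries with identical
outer coordinates (pairs) or identical extension anchor and strand
(singletons) - are collapsed to a single block.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome_io import GenomeModel, MappedRead

logger = logging.getLogger(__name__)

BLOCK_COLUMNS = ["chrom", "start", "end", "sample_id", "origin", "anchor", "strand"]


@dataclass
class FragmentBlock:
    """Inferred genomic interval of one sequenced DNA fragment."""

    chrom: str
    start: int
    end: int
    sample_id: str
    origin: str  # "singleton" or "paired"

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty block [{self.start},{self.end})")
        if self.start < 0:
            raise ValueError("block start < 0")


def extend_singleton(
    read: MappedRead, chrom_length: int, ext_length: int = 250
) -> FragmentBlock:
    """Extend an unpaired read to a fixed-length block along its strand.

    + strand: [start, start + ext_length); - strand: [end - ext_length,
    end).  The block is clipped to [0, chrom_length).
    """
    if ext_length < read.end - read.start:
        raise ValueError(
            f"extension length {ext_length} shorter than read length {read.end - read.start}"
        )
    if read.strand == "+":
        start, end = read.start, read.start + ext_length
    else:
        start, end = read.end - ext_length, read.end
    start = max(start, 0)
    end = min(end, chrom_length)
    return FragmentBlock(read.chrom, start, end, read.sample_id, "singleton")


def pair_to_fragment(read: MappedRead) -> FragmentBlock | None:
    """Outer span of a proper read pair; None (to be counted) if the mates
    map to different chromosomes."""
    if read.mate is None:
        raise ValueError("read has no mate")
    mate_chrom, mate_start, mate_end, _ = read.mate
    if mate_chrom != read.chrom:
        return None
    return FragmentBlock(
        read.chrom,
        min(read.start, mate_start),
        max(read.end, mate_end),
        read.sample_id,
        "paired",
    )


def deduplicate(blocks: pd.DataFrame, mode: str = "outer_coords") -> pd.DataFrame:
    """Remove duplicate blocks from one sample, keeping first occurrence.

    ``outer_coords`` collapses identical (chrom, start, end); ``five_prime``
    collapses identical (chrom, anchor, strand) where the anchor is the
    singleton extension origin.  Input must come from a single sample.
    """
    if blocks.empty:
        return blocks.copy()
    if blocks["sample_id"].nunique() > 1:
        raise ValueError("deduplicate expects blocks from one sample")
    if mode == "outer_coords":
        keys = ["chrom", "start", "end"]
    elif mode == "five_prime":
        keys = ["chrom", "anchor", "strand"]
    else:
        raise ValueError(f"unknown dedup mode {mode!r}")
    out = blocks.drop_duplicates(subset=keys, keep="first").reset_index(drop=True)
    n_removed = len(blocks) - len(out)
    if n_removed:
        logger.info(
            "%s: removed %d duplicate blocks (%s mode)",
            blocks["sample_id"].iat[0],
            n_removed,
            mode,
        )
    out.attrs["n_duplicates_removed"] = n_removed
    return out


def reads_to_blocks(
    reads: pd.DataFrame,
    genome: GenomeModel,
    ext_length: int = 250,
    dedup: bool = True,
) -> pd.DataFrame:
    """Vectorized read -> block conversion for one sample's read frame.

    Paired rows (non-null mate fields on the same chromosome) become
    outer-span blocks deduplicated on outer coordinates; inter-chromosomal
    pairs are skipped and counted.  Unpaired rows become strand-extended
    singleton blocks deduplicated on (chrom, 5' anchor, strand).  The
    returned frame carries ``origin``, ``anchor`` and ``strand`` columns
    and attrs with skip/duplicate counts.
    """
    if reads.empty:
        out = pd.DataFrame(columns=BLOCK_COLUMNS)
        out.attrs.update(n_interchrom_skipped=0, n_duplicates_removed=0)
        return out
    if reads["sample_id"].nunique() > 1:
        raise ValueError("reads_to_blocks expects reads from one sample")
    sample_id = reads["sample_id"].iat[0]
    lengths = genome.lengths
    chrom_len = reads["chrom"].map(lengths)
    if chrom_len.isna().any():
        missing = sorted(set(reads.loc[chrom_len.isna(), "chrom"]))
        raise ValueError(f"reads on chromosomes absent from genome: {missing}")

    has_mate = reads["mate_chrom"].notna()
    paired = reads[has_mate]
    single = reads[~has_mate]

    frames = []
    n_skipped = 0
    n_dups = 0

    if len(paired):
        same = paired["mate_chrom"] == paired["chrom"]
        n_skipped = int((~same).sum())
        if n_skipped:
            logger.info("%s: skipped %d inter-chromosomal pairs", sample_id, n_skipped)
        p = paired[same]
        if len(p):
            start = np.minimum(p["start"].to_numpy(), p["mate_start"].to_numpy().astype(int))
            end = np.maximum(p["end"].to_numpy(), p["mate_end"].to_numpy().astype(int))
            blocks = pd.DataFrame(
                {
                    "chrom": p["chrom"].to_numpy(),
                    "start": start.astype(np.int64),
                    "end": end.astype(np.int64),
                    "sample_id": sample_id,
                    "origin": "paired",
                    "anchor": start.astype(np.int64),
                    "strand": p["strand"].to_numpy(),
                }
            )
            if dedup:
                blocks = deduplicate(blocks, "outer_coords")
                n_dups += blocks.attrs["n_duplicates_removed"]
            frames.append(blocks)

    if len(single):
        read_len = (single["end"] - single["start"]).max()
        if ext_length < read_len:
            raise ValueError(
                f"extension length {ext_length} shorter than longest read ({read_len})"
            )
        plus = single["strand"].to_numpy() == "+"
        s = single["start"].to_numpy()
        e = single["end"].to_numpy()
        anchor = np.where(plus, s, e)
        start = np.where(plus, s, e - ext_length)
        end = np.where(plus, s + ext_length, e)
        clen = chrom_len[~has_mate].to_numpy()
        start = np.maximum(start, 0)
        end = np.minimum(end, clen)
        blocks = pd.DataFrame(
            {
                "chrom": single["chrom"].to_numpy(),
                "start": start.astype(np.int64),
                "end": end.astype(np.int64),
                "sample_id": sample_id,
                "origin": "singleton",
                "anchor": anchor.astype(np.int64),
                "strand": single["strand"].to_numpy(),
            }
        )
        if dedup:
            blocks = deduplicate(blocks, "five_prime")
            n_dups += blocks.attrs["n_duplicates_removed"]
        frames.append(blocks)

    out = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=BLOCK_COLUMNS
    )
    out = out.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(
        drop=True
    )
    out.attrs["n_interchrom_skipped"] = n_skipped
    out.attrs["n_duplicates_removed"] = n_dups
    return out
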