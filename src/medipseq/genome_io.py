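"""Input/output layer: genome, annotations, mapped reads, expression tables.

All coordinates are 0-based half-open throughout the package (BED
convention); human-readable reports convert to 1-based inclusive only at
the formatting step.  A CpG site is indexed by the position of the C of the
CG dinucleotide on the + strand; the symmetric - strand CpG is the same
site.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGTN")

#: column order of the package's tab-separated mapped-read interchange format
READ_COLUMNS = [
    "chrom",
    "start",
    "end",
    "strand",
    "mapq",
    "pair_id",
    "mate_chrom",
    "mate_start",
    "mate_end",
    "mate_strand",
]


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


@dataclass
class GenomeModel:
    """Reference genome: ordered chromosomes with uppercase ACGTN sequence."""

    sequences: dict[str, str]

    def __post_init__(self) -> None:
        if not self.sequences:
            raise FormatError("genome contains no chromosomes")
        for name, seq in self.sequences.items():
            bad = set(seq) - VALID_BASES
            if bad:
                raise FormatError(
                    f"chromosome {name!r} contains non-IUPAC-ACGTN bases: {sorted(bad)}"
                )

    @property
    def names(self) -> list[str]:
        return list(self.sequences)

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.sequences.items()}

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.sequences.values())

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.sequences


@dataclass
class GeneModel:
    """A gene: strand, TSS and sorted non-overlapping exons.

    ``tss`` is the leftmost exon start for + strand genes and the rightmost
    exon end - 1 for - strand genes.  Introns are the gaps between
    consecutive exons.
    """

    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise FormatError(f"gene {self.gene_id}: strand must be + or -")
        if not self.exons:
            raise FormatError(f"gene {self.gene_id}: no exons")
        self.exons = sorted(self.exons)
        prev_end = None
        for start, end in self.exons:
            if start >= end:
                raise FormatError(f"gene {self.gene_id}: empty exon [{start},{end})")
            if prev_end is not None and start < prev_end:
                raise FormatError(f"gene {self.gene_id}: overlapping exons")
            prev_end = end

    @property
    def tss(self) -> int:
        if self.strand == "+":
            return self.exons[0][0]
        return self.exons[-1][1] - 1

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def introns(self) -> list[tuple[int, int]]:
        return [
            (self.exons[i][1], self.exons[i + 1][0])
            for i in range(len(self.exons) - 1)
            if self.exons[i][1] < self.exons[i + 1][0]
        ]


@dataclass
class AnnotationTrack:
    """Named set of half-open intervals, sorted per chromosome."""

    name: str
    intervals: pd.DataFrame  # columns chrom, start, end

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.intervals, columns=["chrom", "start", "end"])
        if len(df) and (df["start"] >= df["end"]).any():
            raise FormatError(f"track {self.name}: interval with start >= end")
        self.intervals = df.sort_values(["chrom", "start"], kind="mergesort").reset_index(
            drop=True
        )

    def __len__(self) -> int:
        return len(self.intervals)

    def for_chrom(self, chrom: str) -> pd.DataFrame:
        return self.intervals[self.intervals["chrom"] == chrom]

    def validate_against(self, genome: GenomeModel) -> None:
        lengths = genome.lengths
        for chrom, grp in self.intervals.groupby("chrom"):
            if chrom not in lengths:
                raise FormatError(f"track {self.name}: unknown chromosome {chrom!r}")
            if int(grp["end"].max()) > lengths[chrom]:
                raise FormatError(
                    f"track {self.name}: interval past end of {chrom}"
                )


@dataclass
class MappedRead:
    """One uniquely mapped read (scalar record form; pipelines use frames)."""

    chrom: str
    start: int
    end: int
    strand: str
    mapq: int
    sample_id: str
    pair_id: str | None = None
    mate: tuple[str, int, int, str] | None = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise FormatError("read with start >= end")
        if self.start < 0:
            raise FormatError("read with negative start")
        if self.mate is not None and self.mate[0] != self.chrom:
            # tolerated at load; pair_to_fragment skips and counts these
            pass


def load_genome(path: str | Path) -> GenomeModel:
    """Load a FASTA reference.  Lowercase bases are uppercased."""
    path = Path(path)
    sequences: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in sequences:
            raise FormatError(f"duplicate chromosome name {record.id!r} in {path}")
        sequences[record.id] = str(record.seq).upper()
    if not sequences:
        raise FormatError(f"no FASTA records found in {path}")
    return GenomeModel(sequences)


def write_genome(genome: GenomeModel, path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def enumerate_cpg_sites(genome: GenomeModel) -> pd.DataFrame:
    """All CG dinucleotides, one row per site, sorted by (chrom, pos).

    ``pos`` is the 0-based position of the C; the site spans [pos, pos+2).
    """
    frames = []
    for name, seq in genome.sequences.items():
        arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
        pos = np.flatnonzero((arr[:-1] == ord("C")) & (arr[1:] == ord("G")))
        frames.append(pd.DataFrame({"chrom": name, "pos": pos.astype(np.int64)}))
    if not frames:
        return pd.DataFrame(columns=["chrom", "pos"])
    out = pd.concat(frames, ignore_index=True)
    return out


def _empty_reads(sample_id: str) -> pd.DataFrame:
    df = pd.DataFrame(columns=READ_COLUMNS + ["sample_id"])
    df["sample_id"] = df["sample_id"].astype(object)
    return df


def load_reads(
    path: str | Path,
    sample_id: str,
    min_mapq: int = 10,
    genome: GenomeModel | None = None,
) -> pd.DataFrame:
    """Load mapped reads from the package TSV format or a SAM file.

    Reads with mapping quality below ``min_mapq`` are removed (the
    retention rule is ``mapq >= min_mapq``); the number dropped is logged.
    Returns a frame with READ_COLUMNS plus ``sample_id``; unpaired reads
    carry NaN mate fields.
    """
    path = Path(path)
    if path.suffix.lower() == ".sam":
        df = _read_sam(path)
    else:
        df = _read_tsv_reads(path)
    if df.empty:
        logger.warning("no reads found in %s", path)
        df = _empty_reads(sample_id)
        df.attrs["n_dropped_mapq"] = 0
        return df
    if (df["start"] < 0).any():
        raise FormatError(f"{path}: negative read coordinates")
    if (df["start"] >= df["end"]).any():
        raise FormatError(f"{path}: read with start >= end")
    if genome is not None:
        unknown = sorted(set(df["chrom"]) - set(genome.names))
        if unknown:
            raise FormatError(f"{path}: reads on undeclared chromosomes {unknown}")
    keep = df["mapq"] >= min_mapq
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("%s: dropped %d reads with mapq < %d", path, n_dropped, min_mapq)
    df = df[keep].reset_index(drop=True)
    df["sample_id"] = sample_id
    df.attrs["n_dropped_mapq"] = n_dropped
    return df


def _read_tsv_reads(path: Path) -> pd.DataFrame:
    """Tab-separated reads: 6 columns (unpaired) or 10 (with mate fields).

    Columns: chrom start end strand mapq pair_id [mate_chrom mate_start
    mate_end mate_strand]; '.' marks a missing pair_id/mate.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) not in (6, 10):
                raise FormatError(
                    f"{path}:{lineno}: expected 6 or 10 tab-separated fields, got {len(parts)}"
                )
            try:
                row = {
                    "chrom": parts[0],
                    "start": int(parts[1]),
                    "end": int(parts[2]),
                    "strand": parts[3],
                    "mapq": int(parts[4]),
                    "pair_id": None if parts[5] == "." else parts[5],
                    "mate_chrom": None,
                    "mate_start": np.nan,
                    "mate_end": np.nan,
                    "mate_strand": None,
                }
                if len(parts) == 10 and parts[6] != ".":
                    row.update(
                        mate_chrom=parts[6],
                        mate_start=int(parts[7]),
                        mate_end=int(parts[8]),
                        mate_strand=parts[9],
                    )
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            if row["strand"] not in "+-":
                raise FormatError(f"{path}:{lineno}: bad strand {row['strand']!r}")
            rows.append(row)
    return pd.DataFrame(rows, columns=READ_COLUMNS)


def _read_sam(path: Path) -> pd.DataFrame:
    """Minimal SAM ingestion: mandatory fields and MAPQ only.

    The aligned span is taken from the CIGAR reference length via pysam;
    mate coordinates come from RNEXT/PNEXT with the mate span approximated
    by the read length (sufficient for outer-coordinate fragment
    inference when the mate's leftmost position is known).
    """
    import pysam

    rows = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for rec in sam:
            if rec.is_unmapped or rec.reference_name is None:
                continue
            paired = rec.is_paired and not rec.mate_is_unmapped and rec.next_reference_name
            length = rec.reference_length or rec.query_length or 0
            rows.append(
                {
                    "chrom": rec.reference_name,
                    "start": rec.reference_start,
                    "end": rec.reference_start + max(length, 1),
                    "strand": "-" if rec.is_reverse else "+",
                    "mapq": rec.mapping_quality,
                    "pair_id": rec.query_name if paired else None,
                    "mate_chrom": rec.next_reference_name if paired else None,
                    "mate_start": rec.next_reference_start if paired else np.nan,
                    "mate_end": (
                        rec.next_reference_start + max(length, 1) if paired else np.nan
                    ),
                    "mate_strand": ("-" if rec.mate_is_reverse else "+") if paired else None,
                }
            )
    return pd.DataFrame(rows, columns=READ_COLUMNS)


def write_reads(reads: pd.DataFrame, path: str | Path) -> None:
    """Write reads in the package TSV format (10 columns, '.' for missing)."""
    with open(path, "w") as fh:
        for row in reads.itertuples(index=False):
            if row.mate_chrom is None or (
                isinstance(row.mate_chrom, float) and np.isnan(row.mate_chrom)
            ):
                mate = ".\t.\t.\t."
            else:
                mate = f"{row.mate_chrom}\t{int(row.mate_start)}\t{int(row.mate_end)}\t{row.mate_strand}"
            pair = row.pair_id if row.pair_id not in (None, np.nan) else "."
            fh.write(
                f"{row.chrom}\t{row.start}\t{row.end}\t{row.strand}\t{row.mapq}\t{pair}\t{mate}\n"
            )


def load_track(
    path: str | Path, name: str, genome: GenomeModel | None = None
) -> AnnotationTrack:
    """Load a BED3 interval track (CGIs, repeats)."""
    path = Path(path)
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: expected >= 3 BED columns")
            try:
                rows.append((parts[0], int(parts[1]), int(parts[2])))
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    track = AnnotationTrack(name, pd.DataFrame(rows, columns=["chrom", "start", "end"]))
    if genome is not None:
        track.validate_against(genome)
    return track


def write_track(track: AnnotationTrack, path: str | Path) -> None:
    track.intervals.to_csv(path, sep="\t", header=False, index=False)


def load_gene_table(path: str | Path) -> list[GeneModel]:
    """Load gene models from BED12.

    TSS is derived from strand: leftmost exon start (+) or rightmost exon
    end - 1 (-).
    """
    path = Path(path)
    genes: list[GeneModel] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 12:
                raise FormatError(f"{path}:{lineno}: expected BED12 (12 columns)")
            try:
                chrom, chrom_start = parts[0], int(parts[1])
                gene_id, strand = parts[3], parts[5]
                n_blocks = int(parts[9])
                sizes = [int(x) for x in parts[10].rstrip(",").split(",")]
                starts = [int(x) for x in parts[11].rstrip(",").split(",")]
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            if len(sizes) != n_blocks or len(starts) != n_blocks:
                raise FormatError(f"{path}:{lineno}: block count mismatch")
            if gene_id in seen:
                raise FormatError(f"{path}:{lineno}: duplicate gene id {gene_id!r}")
            seen.add(gene_id)
            exons = [
                (chrom_start + off, chrom_start + off + size)
                for off, size in zip(starts, sizes)
            ]
            try:
                genes.append(GeneModel(gene_id, chrom, strand, exons))
            except FormatError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return genes


def write_gene_table(genes: Sequence[GeneModel], path: str | Path) -> None:
    """Write gene models as BED12."""
    with open(path, "w") as fh:
        for g in genes:
            sizes = ",".join(str(e - s) for s, e in g.exons)
            starts = ",".join(str(s - g.start) for s, e in g.exons)
            fh.write(
                "\t".join(
                    [
                        g.chrom,
                        str(g.start),
                        str(g.end),
                        g.gene_id,
                        "0",
                        g.strand,
                        str(g.start),
                        str(g.end),
                        "0",
                        str(len(g.exons)),
                        sizes,
                        starts,
                    ]
                )
                + "\n"
            )


def load_expression(
    path: str | Path, required_samples: Iterable[str] | None = None
) -> pd.DataFrame:
    """Load a gene x sample expression table (TSV, header row, gene_id column).

    Values must be non-negative; units are platform-arbitrary.
    """
    df = pd.read_csv(path, sep="\t")
    if "gene_id" not in df.columns:
        raise FormatError(f"{path}: missing 'gene_id' column")
    if df["gene_id"].duplicated().any():
        raise FormatError(f"{path}: duplicate gene ids")
    df = df.set_index("gene_id")
    if (df.values < 0).any():
        raise FormatError(f"{path}: negative expression values")
    if required_samples is not None:
        missing = sorted(set(required_samples) - set(df.columns))
        if missing:
            raise FormatError(f"{path}: missing declared sample columns {missing}")
    return df


def write_expression(expr: pd.DataFrame, path: str | Path) -> None:
    expr.to_csv(path, sep="\t", index_label="gene_id")


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write any result table as TSV with header (round-trippable)."""
    df.to_csv(path, sep="\t", index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
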