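"""Ingest of aligned small-RNA reads and genomic annotations.

Supported read formats:

* the package's BED dialect — BED6 plus two integer columns (collapse
  ``count``, mapping-position ``copies``) and an optional ninth column
  carrying the read sequence 5'->3'.  The score column mirrors ``count``.
* SAM (text or BAM), via pysam; ``copies`` from the NH tag, ``count`` from a
  collapsed-read name suffix ``_xN`` when present.

Annotations: RepeatMasker ``.out`` tables and GFF3 (introns derived as the
gaps between a gene's exons).
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import pysam
from intervaltree import IntervalTree

from .model import (
    FEATURE_COLUMNS,
    READ_COLUMNS,
    FeatureSet,
    StageLibrary,
    _empty_read_frame,
    revcomp,
)

_SEQ_RE = re.compile(r"^[ACGTN]+$")
_COUNT_SUFFIX_RE = re.compile(r"_x(\d+)$")


class ParseError(ValueError):
    """Malformed input line; message names the file and line number."""


def _fetch_seq(genome, chrom: str, start: int, end: int, strand: str) -> str:
    seq = str(genome[chrom][start:end]).upper()
    return revcomp(seq) if strand == "-" else seq


def read_alignments(
    path: str | Path,
    format: str = "bed",
    library_id: str = "",
    stage: str = "",
    genome=None,
) -> StageLibrary:
    """Load one stage library from a BED-dialect or SAM/BAM file.

    ``genome`` (a mapping of chromosome name to sliceable sequence, e.g. a
    ``pyfaidx.Fasta``) supplies read sequences when the file itself does not
    carry them.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "bed":
        rows = _parse_bed(path, genome)
    elif format in ("sam", "bam"):
        rows = _parse_sam(path, genome)
    else:
        raise ValueError(f"unknown format {format!r} (expected 'bed' or 'sam')")
    df = pd.DataFrame(rows, columns=READ_COLUMNS) if rows else _empty_read_frame()
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    df["count"] = df["count"].astype(np.int64)
    df["copies"] = df["copies"].astype(np.int64)
    return StageLibrary(df, library_id=library_id or path.stem, stage=stage)


def _parse_bed(path: Path, genome) -> list[tuple]:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) == 1:  # tolerate space-separated toy files
                fields = line.split()
            if len(fields) < 8:
                raise ParseError(f"{path}:{lineno}: expected >=8 columns, got {len(fields)}")
            try:
                chrom, start, end, name = fields[0], int(fields[1]), int(fields[2]), fields[3]
                strand = fields[5]
                count, copies = int(fields[6]), int(fields[7])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from None
            if strand not in ("+", "-"):
                raise ParseError(f"{path}:{lineno}: invalid strand {strand!r}")
            seq = fields[8].upper() if len(fields) > 8 else ""
            if not seq and _SEQ_RE.match(name) and len(name) == end - start:
                seq = name.upper()
            if not seq and genome is not None:
                seq = _fetch_seq(genome, chrom, start, end, strand)
            rows.append((name, seq, chrom, start, end, strand, count, copies))
    return rows


def _parse_sam(path: Path, genome) -> list[tuple]:
    rows = []
    mode = "rb" if path.suffix == ".bam" else "r"
    with pysam.AlignmentFile(str(path), mode, check_sq=False) as fh:
        for aln in fh:
            if aln.is_unmapped:
                continue
            strand = "-" if aln.is_reverse else "+"
            start, end = aln.reference_start, aln.reference_end
            copies = aln.get_tag("NH") if aln.has_tag("NH") else 1
            m = _COUNT_SUFFIX_RE.search(aln.query_name)
            count = int(m.group(1)) if m else 1
            # query_sequence is stored reference-oriented in SAM; flip back to
            # read orientation for minus-strand alignments
            seq = (aln.query_sequence or "").upper()
            if seq and aln.is_reverse:
                seq = revcomp(seq)
            if not seq and genome is not None:
                seq = _fetch_seq(genome, aln.reference_name, start, end, strand)
            rows.append((aln.query_name, seq, aln.reference_name, start, end, strand, count, copies))
    return rows


def write_bed(lib: StageLibrary, path: str | Path) -> None:
    """Write the library in the BED6+2(+seq) dialect; round-trips all fields."""
    with open(path, "w") as fh:
        for row in lib.df.itertuples(index=False):
            cols = [
                row.chrom,
                str(row.start),
                str(row.end),
                row.read_id or (row.seq or "."),
                str(row.count),
                row.strand,
                str(row.count),
                str(row.copies),
            ]
            if row.seq:
                cols.append(row.seq)
            fh.write("\t".join(cols) + "\n")


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    sizes = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            name, size = line.split()[:2]
            sizes[name] = int(size)
    return sizes


# ---------------------------------------------------------------------------
# filtering / partitioning

def filter_by_size(lib: StageLibrary, min_nt: int, max_nt: int) -> StageLibrary:
    """Retain reads with min_nt <= length <= max_nt; recompute total_mapped."""
    if min_nt > max_nt:
        raise ValueError(f"min_nt {min_nt} > max_nt {max_nt}")
    lens = lib.lengths
    return lib.subset((lens >= min_nt) & (lens <= max_nt))


def partition_by_uniqueness(lib: StageLibrary) -> tuple[StageLibrary, StageLibrary]:
    """Split into uniquely mapping reads (copies == 1) and multi-mappers."""
    uniq = lib.df["copies"].to_numpy() == 1
    return lib.subset(uniq), lib.subset(~uniq)


def apply_exclusion_mask(lib: StageLibrary, mask: FeatureSet) -> StageLibrary:
    """Drop reads overlapping any mask interval by >= 1 bp (strand-agnostic).

    Used for rRNA/tRNA exclusion before cluster definition.
    """
    if len(mask) == 0:
        return lib
    trees: dict[str, IntervalTree] = {}
    for row in mask.df.itertuples(index=False):
        if row.end > row.start:
            trees.setdefault(row.chrom, IntervalTree()).addi(row.start, row.end)
    keep = np.ones(len(lib.df), dtype=bool)
    chroms = lib.df["chrom"].to_numpy()
    starts = lib.df["start"].to_numpy()
    ends = lib.df["end"].to_numpy()
    for i in range(len(lib.df)):
        tree = trees.get(chroms[i])
        if tree is not None and tree.overlaps(int(starts[i]), int(ends[i])):
            keep[i] = False
    return lib.subset(keep)


# ---------------------------------------------------------------------------
# annotations

def read_repeatmasker(path: str | Path) -> FeatureSet:
    """Parse a RepeatMasker .out table (3 header lines, fixed columns).

    Coordinates in .out are 1-based inclusive -> converted to 0-based
    half-open.  Strand column 'C' (complement) maps to '-'.
    """
    path = Path(path)
    rows = []
    with open(path) as fh:
        lines = fh.readlines()
    body = lines[3:] if len(lines) >= 3 else []
    if lines and not body and lines[0].strip():
        raise ParseError(f"{path}: missing RepeatMasker header (expected 3 header lines)")
    for lineno, line in enumerate(body, 4):
        if not line.strip():
            continue
        fields = line.split()
        if len(fields) < 11:
            raise ParseError(f"{path}:{lineno}: expected >=11 columns, got {len(fields)}")
        chrom = fields[4]
        start = int(fields[5]) - 1
        end = int(fields[6])
        strand_field = fields[8]
        if strand_field == "C":
            strand = "-"
        elif strand_field == "+":
            strand = "+"
        else:
            raise ParseError(f"{path}:{lineno}: invalid strand {strand_field!r}")
        name = fields[9]
        rows.append((chrom, start, end, strand, "TE", name, ""))
    return FeatureSet(pd.DataFrame(rows, columns=FEATURE_COLUMNS))


_KIND_MAP = {
    "gene": "gene",
    "mRNA": "gene",
    "exon": "exon",
    "rRNA": "rRNA",
    "rRNA_gene": "rRNA",
    "tRNA": "tRNA",
    "tRNA_gene": "tRNA",
    "miRNA": "miRNA",
}


def read_gff(path: str | Path, derive_introns: bool = True) -> FeatureSet:
    """Parse GFF3 gene/exon annotations; introns are the gaps between a
    gene's exons (derived, not read)."""
    path = Path(path)
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ParseError(f"{path}:{lineno}: expected 9 columns, got {len(fields)}")
            chrom, _src, ftype, start, end, _score, strand, _frame, attrs = fields
            kind = _KIND_MAP.get(ftype)
            if kind is None:
                continue
            attrd = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            name = attrd.get("ID") or attrd.get("Name") or f"{ftype}:{lineno}"
            parent = attrd.get("Parent", "")
            rows.append((chrom, int(start) - 1, int(end), strand, kind, name, parent))
    df = pd.DataFrame(rows, columns=FEATURE_COLUMNS)
    if derive_introns and len(df):
        df = pd.concat([df, _derive_introns(df)], ignore_index=True)
    return FeatureSet(df)


def _derive_introns(df: pd.DataFrame) -> pd.DataFrame:
    rows = []
    exons = df[df["kind"] == "exon"]
    for parent, sub in exons.groupby("parent"):
        if not parent:
            continue
        sub = sub.sort_values("start")
        prev_end = None
        n = 0
        for row in sub.itertuples(index=False):
            if prev_end is not None and row.start > prev_end:
                n += 1
                rows.append(
                    (row.chrom, prev_end, row.start, row.strand, "intron",
                     f"{parent}.intron{n}", parent)
                )
            prev_end = max(prev_end or 0, row.end)
    return pd.DataFrame(rows, columns=FEATURE_COLUMNS)
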