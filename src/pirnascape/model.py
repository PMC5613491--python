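"""Core data model: aligned small-RNA reads, stage libraries and annotation features.

Coordinates are 0-based half-open everywhere inside the package; 1-based
formats (SAM, GFF3, RepeatMasker .out) are converted on ingest.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

#: canonical ordering of the developmental stages covered by the study design
STAGE_ORDER = (
    "oocyte",
    "e0_5",
    "e8_16",
    "e16_20",
    "e20_24",
    "e24_34",
    "e34_48",
    "e2_6d",
)

#: stages before zygotic genome activation ("maternal" pool)
MATERNAL_STAGES = frozenset({"oocyte", "e0_5"})

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-preserving)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True, slots=True)
class AlignedRead:
    """One mapped small-RNA read.

    ``seq`` is the read sequence 5'->3' (i.e. minus-strand reads are already
    reverse-complemented relative to the reference). ``count`` is the collapse
    multiplicity of the sequence; ``copies`` is the number of best genomic
    mapping positions (a read is *unique* iff copies == 1).
    """

    read_id: str
    seq: str
    chrom: str
    start: int
    end: int
    strand: str
    count: int = 1
    copies: int = 1
    library_id: str = ""

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.seq and (self.end - self.start) != len(self.seq):
            raise ValueError(
                f"read {self.read_id}: span {self.end - self.start} != |seq| {len(self.seq)}"
            )
        if self.count < 1 or self.copies < 1:
            raise ValueError("count and copies must be positive")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def five_prime(self) -> int:
        """Genomic coordinate of the 5' end: start on '+', end-1 on '-'."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def three_prime(self) -> int:
        """Genomic coordinate of the 3' end: end-1 on '+', start on '-'."""
        return self.end - 1 if self.strand == "+" else self.start

    @property
    def is_unique(self) -> bool:
        return self.copies == 1


READ_COLUMNS = ["read_id", "seq", "chrom", "start", "end", "strand", "count", "copies"]


def reads_to_frame(reads: Iterable[AlignedRead]) -> pd.DataFrame:
    rows = [
        (r.read_id, r.seq, r.chrom, r.start, r.end, r.strand, r.count, r.copies)
        for r in reads
    ]
    df = pd.DataFrame(rows, columns=READ_COLUMNS)
    if df.empty:
        df = _empty_read_frame()
    return df


def _empty_read_frame() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "read_id": pd.Series(dtype=str),
            "seq": pd.Series(dtype=str),
            "chrom": pd.Series(dtype=str),
            "start": pd.Series(dtype=np.int64),
            "end": pd.Series(dtype=np.int64),
            "strand": pd.Series(dtype=str),
            "count": pd.Series(dtype=np.int64),
            "copies": pd.Series(dtype=np.int64),
        }
    )


class StageLibrary:
    """A collection of aligned reads from one developmental-stage library.

    Internally a pandas DataFrame (columns :data:`READ_COLUMNS`) for
    vectorised operations; iterate to obtain :class:`AlignedRead` objects.
    ``total_mapped`` is the normalization denominator — by default the sum of
    collapse counts weighted by 1/copies so that a multi-mapper (one row per
    mapping position) is counted once.
    """

    def __init__(
        self,
        reads: pd.DataFrame | Iterable[AlignedRead],
        library_id: str = "",
        stage: str = "",
        total_mapped: float | None = None,
    ) -> None:
        if isinstance(reads, pd.DataFrame):
            df = reads.reset_index(drop=True)
            if df.empty and len(df.columns) == 0:
                df = _empty_read_frame()
        else:
            df = reads_to_frame(reads)
        missing = [c for c in READ_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"read frame missing columns: {missing}")
        bad = set(df["strand"].unique()) - {"+", "-"}
        if bad:
            raise ValueError(f"invalid strand value(s): {sorted(bad)}")
        self.df = df
        self.library_id = library_id
        self.stage = stage
        if total_mapped is None:
            total_mapped = float((df["count"] / df["copies"]).sum())
        self.total_mapped = total_mapped

    # -- basic protocol ----------------------------------------------------
    def __len__(self) -> int:
        return len(self.df)

    def __iter__(self) -> Iterator[AlignedRead]:
        for row in self.df.itertuples(index=False):
            yield AlignedRead(
                read_id=row.read_id,
                seq=row.seq,
                chrom=row.chrom,
                start=int(row.start),
                end=int(row.end),
                strand=row.strand,
                count=int(row.count),
                copies=int(row.copies),
                library_id=self.library_id,
            )

    # -- derived columns ---------------------------------------------------
    @property
    def lengths(self) -> np.ndarray:
        return (self.df["end"] - self.df["start"]).to_numpy()

    @property
    def five_prime(self) -> np.ndarray:
        """Vector of 5'-end coordinates (start on '+', end-1 on '-')."""
        plus = self.df["strand"].to_numpy() == "+"
        return np.where(plus, self.df["start"].to_numpy(), self.df["end"].to_numpy() - 1)

    @property
    def three_prime(self) -> np.ndarray:
        plus = self.df["strand"].to_numpy() == "+"
        return np.where(plus, self.df["end"].to_numpy() - 1, self.df["start"].to_numpy())

    def replace(self, df: pd.DataFrame, total_mapped: float | None = None) -> "StageLibrary":
        """New library with the same identity but a different read frame."""
        return StageLibrary(df, self.library_id, self.stage, total_mapped)

    def subset(self, mask: np.ndarray, recompute_total: bool = True) -> "StageLibrary":
        df = self.df[mask].reset_index(drop=True)
        total = None if recompute_total else self.total_mapped
        return self.replace(df, total)


FEATURE_KINDS = ("gene", "exon", "intron", "TE", "rRNA", "tRNA", "miRNA")

FEATURE_COLUMNS = ["chrom", "start", "end", "strand", "kind", "name", "parent"]


@dataclass
class FeatureSet:
    """Genomic annotation intervals (0-based half-open).

    ``kind`` distinguishes gene/exon/intron/TE/rRNA/tRNA features; exon and
    intron features carry the parent gene name in ``parent``.
    """

    df: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=FEATURE_COLUMNS))

    def __post_init__(self) -> None:
        for col in FEATURE_COLUMNS:
            if col not in self.df.columns:
                self.df[col] = "" if col not in ("start", "end") else 0
        self.df = self.df[FEATURE_COLUMNS].reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    def of_kind(self, *kinds: str) -> "FeatureSet":
        return FeatureSet(self.df[self.df["kind"].isin(kinds)].reset_index(drop=True))

    @classmethod
    def from_records(cls, records: Sequence[tuple]) -> "FeatureSet":
        """Build from (chrom, start, end, strand, kind, name[, parent]) tuples."""
        rows = []
        for rec in records:
            rec = tuple(rec)
            if len(rec) == 6:
                rec = rec + ("",)
            rows.append(rec)
        return cls(pd.DataFrame(rows, columns=FEATURE_COLUMNS))


def merge_intervals(df: pd.DataFrame) -> pd.DataFrame:
    """Union of intervals per chromosome (strand-agnostic).

    Returns a frame with columns chrom/start/end, sorted, pairwise disjoint.
    """
    out = []
    for chrom, sub in df.sort_values(["chrom", "start"]).groupby("chrom", sort=True):
        cur_s = cur_e = None
        for s, e in zip(sub["start"], sub["end"]):
            if cur_s is None:
                cur_s, cur_e = s, e
            elif s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                out.append((chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        if cur_s is not None:
            out.append((chrom, cur_s, cur_e))
    return pd.DataFrame(out, columns=["chrom", "start", "end"])
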