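"""piRNA cluster discovery by window scanning and merging.

Clusters are defined from uniquely mapping, size-filtered (25-35 nt) reads:
fixed-size windows tile each chromosome, a window seeds a cluster when it
holds at least ``min_reads`` reads *and* at least ``min_fraction`` of the
pooled unique piRNA total, and passing windows within ``merge_distance`` of
each other are merged.  Reads are assigned to windows by their 5' end.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import StageLibrary


@dataclass(frozen=True)
class GenomicWindow:
    chrom: str
    start: int
    end: int
    unique_pirna_count: float
    plus_count: float
    minus_count: float


@dataclass
class PiRNACluster:
    chrom: str
    start: int
    end: int
    plus_count: float
    minus_count: float
    dominant_strand: str = "+"
    tie: bool = False
    rpm: float = 0.0
    rank: int = 0

    @property
    def unique_pirna_count(self) -> float:
        return self.plus_count + self.minus_count

    @property
    def length(self) -> int:
        return self.end - self.start

    def contains(self, chrom: str, pos) -> np.ndarray:
        return (chrom == self.chrom) & (pos >= self.start) & (pos < self.end)


def window_counts(
    lib: StageLibrary,
    chrom_sizes: dict[str, int],
    window_size: int = 10_000,
    step: int | None = None,
) -> list[GenomicWindow]:
    """Per-window weighted read counts (5'-end assignment).

    Windows tile each chromosome from 0 with the given step (default:
    non-overlapping, step == window_size); the last window is truncated at
    the chromosome end.  With step < window_size a read's 5' end may fall in
    several windows and is counted in each.
    """
    if step is None:
        step = window_size
    if not (window_size >= step >= 1):
        raise ValueError("require window_size >= step >= 1")
    unknown = set(lib.df["chrom"].unique()) - set(chrom_sizes)
    if unknown:
        raise ValueError(f"reads on chromosome(s) absent from chrom_sizes: {sorted(unknown)}")

    fp = lib.five_prime
    counts = lib.df["count"].to_numpy()
    plus = lib.df["strand"].to_numpy() == "+"
    chroms = lib.df["chrom"].to_numpy()

    windows: list[GenomicWindow] = []
    for chrom in sorted(chrom_sizes):
        size = chrom_sizes[chrom]
        starts = np.arange(0, max(size, 1), step)
        starts = starts[starts < size]
        on_chrom = chroms == chrom
        pos = fp[on_chrom]
        cnt = counts[on_chrom]
        pl = plus[on_chrom]
        for ws in starts:
            we = min(ws + window_size, size)
            inside = (pos >= ws) & (pos < we)
            if inside.any():
                total = float(cnt[inside].sum())
                p = float(cnt[inside & pl].sum())
            else:
                total = p = 0.0
            windows.append(GenomicWindow(chrom, int(ws), int(we), total, p, total - p))
    return windows


def call_clusters(
    windows: list[GenomicWindow],
    total_unique_pirna: float,
    min_reads: int = 1000,
    min_fraction: float = 1e-4,
    merge_distance: int = 20_000,
    lib: StageLibrary | None = None,
) -> list[PiRNACluster]:
    """Merge passing windows into clusters and rank them by read content.

    When ``lib`` is given, per-strand counts are re-tallied over each merged
    span from the reads themselves (5'-end containment); otherwise window
    counts are summed.
    """
    if not (0.0 <= min_fraction <= 1.0):
        raise ValueError(f"min_fraction must be in [0,1], got {min_fraction}")
    if total_unique_pirna <= 0:
        raise ValueError("total_unique_pirna must be positive")

    passing = [
        w
        for w in windows
        if w.unique_pirna_count >= min_reads
        and w.unique_pirna_count / total_unique_pirna >= min_fraction
    ]
    passing.sort(key=lambda w: (w.chrom, w.start))

    merged: list[PiRNACluster] = []
    for w in passing:
        if (
            merged
            and merged[-1].chrom == w.chrom
            and w.start - merged[-1].end <= merge_distance
        ):
            last = merged[-1]
            last.end = max(last.end, w.end)
            last.plus_count += w.plus_count
            last.minus_count += w.minus_count
        else:
            merged.append(
                PiRNACluster(w.chrom, w.start, w.end, w.plus_count, w.minus_count)
            )

    if lib is not None:
        _retally_strand_counts(merged, lib)
    for c in merged:
        assign_strand_dominance(c)
        c.rpm = c.unique_pirna_count / total_unique_pirna * 1e6
    # rank by descending read content, genomic order breaking ties
    order = sorted(
        range(len(merged)),
        key=lambda i: (-merged[i].unique_pirna_count, merged[i].chrom, merged[i].start),
    )
    for rank, i in enumerate(order, 1):
        merged[i].rank = rank
    return merged


def _retally_strand_counts(clusters: list[PiRNACluster], lib: StageLibrary) -> None:
    fp = lib.five_prime
    counts = lib.df["count"].to_numpy()
    plus = lib.df["strand"].to_numpy() == "+"
    chroms = lib.df["chrom"].to_numpy()
    for c in clusters:
        inside = c.contains(chroms, fp)
        c.plus_count = float(counts[inside & plus].sum())
        c.minus_count = float(counts[inside & ~plus].sum())


def assign_strand_dominance(cluster: PiRNACluster, lib: StageLibrary | None = None) -> PiRNACluster:
    """Set the dominant strand (ties broken toward '+' and flagged)."""
    if lib is not None:
        _retally_strand_counts([cluster], lib)
    if cluster.plus_count + cluster.minus_count == 0:
        raise ValueError(
            f"cluster {cluster.chrom}:{cluster.start}-{cluster.end} has zero reads"
        )
    cluster.tie = cluster.plus_count == cluster.minus_count
    cluster.dominant_strand = "+" if cluster.plus_count >= cluster.minus_count else "-"
    return cluster


def cumulative_fraction(
    clusters: list[PiRNACluster], total_unique_pirna: float
) -> pd.DataFrame:
    """Cumulative proportion of piRNA reads held by the top-k clusters.

    Returns a frame (rank, fraction); monotone non-decreasing, ending at the
    total in-cluster fraction (<= 1).
    """
    ranked = sorted(clusters, key=lambda c: c.rank)
    fractions = np.cumsum([c.unique_pirna_count for c in ranked]) / total_unique_pirna
    return pd.DataFrame(
        {"rank": np.arange(1, len(ranked) + 1), "fraction": fractions}
    )


def multimapper_rescue_fraction(
    multi: StageLibrary, clusters: list[PiRNACluster]
) -> float:
    """Fraction of multi-mapping piRNA-sized reads with >= 1 mapping position
    whose 5' end falls inside a cluster.

    Each collapsed read (sequence) is counted once, by its collapse count,
    regardless of how many of its positions lie in clusters.
    """
    if len(multi) == 0:
        return 0.0
    df = multi.df
    fp = multi.five_prime
    chroms = df["chrom"].to_numpy()
    in_cluster = np.zeros(len(df), dtype=bool)
    for c in clusters:
        in_cluster |= c.contains(chroms, fp)
    # group positions of the same collapsed read (same seq, falling back to
    # read_id when sequences are absent)
    key = df["seq"].where(df["seq"] != "", df["read_id"])
    grouped = pd.DataFrame(
        {"key": key, "count": df["count"], "hit": in_cluster}
    ).groupby("key").agg(count=("count", "max"), hit=("hit", "any"))
    total = grouped["count"].sum()
    if total == 0:
        return 0.0
    return float(grouped.loc[grouped["hit"], "count"].sum() / total)


def clusters_to_frame(clusters: list[PiRNACluster]) -> pd.DataFrame:
    """Clusters as a BED6-plus table (plus/minus counts, rpm, tie flag)."""
    return pd.DataFrame(
        [
            {
                "chrom": c.chrom,
                "start": c.start,
                "end": c.end,
                "name": f"cluster_{c.rank}",
                "score": int(c.unique_pirna_count),
                "strand": c.dominant_strand,
                "plus_count": c.plus_count,
                "minus_count": c.minus_count,
                "rpm": c.rpm,
                "tie": int(c.tie),
            }
            for c in sorted(clusters, key=lambda c: (c.chrom, c.start))
        ]
    )
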