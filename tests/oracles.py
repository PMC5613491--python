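"""Independent brute-force reference implementations used to cross-check the
indexed/vectorised code paths on small inputs."""

from __future__ import annotations

import numpy as np
import pandas as pd


def brute_force_pairs(df: pd.DataFrame, max_offset: int, convention: str = "five_prime"):
    """O(n^2) enumeration of opposite-strand overlap pairs.

    Returns a sorted list of (plus_index, minus_index, offset, weight).
    Deliberately written from the definition: for every plus/minus read pair
    on one chromosome, compute the overlap from the end coordinates directly.
    """
    out = []
    for i in range(len(df)):
        ri = df.iloc[i]
        if ri["strand"] != "+":
            continue
        for j in range(len(df)):
            rj = df.iloc[j]
            if rj["strand"] != "-" or rj["chrom"] != ri["chrom"]:
                continue
            if convention == "five_prime":
                o = (rj["end"] - 1) - ri["start"] + 1
            else:
                o = (ri["end"] - 1) - rj["start"] + 1
            if 1 <= o <= max_offset:
                out.append((i, j, int(o), float(ri["count"] * rj["count"])))
    return sorted(out)


def brute_force_clusters(
    reads: pd.DataFrame,
    chrom_sizes: dict[str, int],
    window_size: int,
    step: int,
    total: float,
    min_reads: int,
    min_fraction: float,
    merge_distance: int,
):
    """Direct re-implementation of window thresholding + merging.

    Every window is evaluated explicitly by iterating over reads; passing
    windows are merged by a simple left-to-right scan.  Returns a list of
    (chrom, start, end) spans.
    """
    fp = np.where(reads["strand"] == "+", reads["start"], reads["end"] - 1)
    passing = []
    for chrom in sorted(chrom_sizes):
        size = chrom_sizes[chrom]
        ws = 0
        while ws < size:
            we = min(ws + window_size, size)
            n = 0.0
            for pos, rchrom, rcount in zip(fp, reads["chrom"], reads["count"]):
                if rchrom == chrom and ws <= pos < we:
                    n += rcount
            if n >= min_reads and n / total >= min_fraction:
                passing.append((chrom, ws, we))
            ws += step
    merged = []
    for chrom, s, e in passing:
        if merged and merged[-1][0] == chrom and s - merged[-1][2] <= merge_distance:
            merged[-1] = (chrom, merged[-1][1], max(merged[-1][2], e))
        else:
            merged.append((chrom, s, e))
    return merged
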