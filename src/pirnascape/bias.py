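"""Per-position nucleotide frequencies and information content (1U/10A bias).

Sequences are handled in DNA space (the RNA alphabet's "U" is "T" here) and in read
orientation, i.e. minus-strand reads are already reverse-complemented.
Positions are 1-based in the API, matching how the 1U and 10A biases are
named.  Reads shorter than a position are excluded from that position's
denominator; reads containing N are excluded from matrices altogether.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import StageLibrary

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}


def _seq_count_arrays(reads) -> tuple[list[str], np.ndarray]:
    if isinstance(reads, StageLibrary):
        return list(reads.df["seq"]), reads.df["count"].to_numpy(dtype=float)
    if isinstance(reads, pd.DataFrame):
        return list(reads["seq"]), reads["count"].to_numpy(dtype=float)
    seqs, counts = [], []
    for r in reads:
        if isinstance(r, str):
            seqs.append(r)
            counts.append(1.0)
        else:
            seqs.append(r.seq)
            counts.append(float(r.count))
    return seqs, np.asarray(counts)


@dataclass
class NucleotideMatrix:
    """Position x base frequency matrix with per-position information content.

    ``freq`` rows sum to 1 where ``support`` > 0; zero-support rows are
    flagged in ``no_support`` and left as zeros rather than NaN.
    """

    freq: np.ndarray        # (n_positions, 4) over A,C,G,T
    info: np.ndarray        # bits, in [0, 2]
    support: np.ndarray     # weighted read count per position
    no_support: np.ndarray  # bool flags

    @property
    def n_positions(self) -> int:
        return self.freq.shape[0]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.freq, columns=list(BASES))
        df.insert(0, "position", np.arange(1, self.n_positions + 1))
        df["info"] = self.info
        df["support"] = self.support
        return df


def _char_matrix(seqs: list[str], n_positions: int) -> np.ndarray:
    """Reads as a (n, n_positions) byte matrix, '.'-padded past each read's end."""
    padded = "".join(
        s[:n_positions] + "." * (n_positions - min(len(s), n_positions)) for s in seqs
    )
    return np.frombuffer(padded.encode("ascii"), dtype=np.uint8).reshape(-1, n_positions)


def nucleotide_matrix(reads, n_positions: int = 18, weighted: bool = True) -> NucleotideMatrix:
    """Count-weighted base frequencies over the first ``n_positions`` of reads.

    ``weighted=False`` treats every collapsed sequence once (distinct-sequence
    logo) instead of weighting by collapse count.
    """
    seqs, counts = _seq_count_arrays(reads)
    keep = [i for i, s in enumerate(seqs) if s and "N" not in s]
    seqs = [seqs[i] for i in keep]
    counts = counts[keep]
    if not weighted:
        counts = np.ones_like(counts)
    tally = np.zeros((n_positions, 4))
    if seqs:
        chars = _char_matrix(seqs, n_positions)
        for b, col in _BASE_INDEX.items():
            tally[:, col] = ((chars == ord(b)) * counts[:, None]).sum(axis=0)
    support = tally.sum(axis=1)
    no_support = support == 0
    freq = np.zeros_like(tally)
    np.divide(tally, support[:, None], out=freq, where=~no_support[:, None])
    info = np.array([info_content(freq[i]) if not no_support[i] else 0.0 for i in range(n_positions)])
    return NucleotideMatrix(freq=freq, info=info, support=support, no_support=no_support)


def base_fraction_at(reads, position: int, base: str) -> float:
    """Count-weighted fraction of reads with ``base`` at 1-based ``position``,
    among reads long enough to have that position."""
    if position < 1:
        raise ValueError("position is 1-based and must be >= 1")
    base = base.upper().replace("U", "T")
    seqs, counts = _seq_count_arrays(reads)
    i = position - 1
    chars = np.array([s[i] if len(s) > i else "" for s in seqs])
    long_enough = chars != ""
    den = counts[long_enough].sum()
    num = counts[long_enough & (chars == base)].sum()
    return float(num / den) if den else 0.0


def info_content(freq_row) -> float:
    """Information content 2 + sum_b f log2 f in bits (0*log 0 := 0)."""
    f = np.asarray(freq_row, dtype=float)
    if (f < 0).any():
        raise ValueError("negative frequency")
    nz = f[f > 0]
    return float(2.0 + (nz * np.log2(nz)).sum())
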