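"""Sense-antisense overlap statistics: the ping-pong signature.

The diagnostic of secondary piRNA biogenesis is an excess of read pairs on
opposite strands whose 5' ends overlap by exactly 10 nt.  The 5'-5' overlap
length between a plus-strand read and a minus-strand read is::

    o = five_prime(minus) - five_prime(plus) + 1

so that coincident 5' ends give o = 1 and the ping-pong configuration gives
o = 10 (the first ten bases of the two reads are complementary, putting the
10A of one read opposite the 1U of the other).  A 3'-3' convention is defined
analogously on 3' ends (o = three_prime(plus) - three_prime(minus) + 1).

Three summaries are computed per offset o in 1..max_offset:

* ``raw_pairs`` — summed pair weights, count(plus) x count(minus);
* ``pct_reads`` — percentage of partnered reads (both strands pooled) having
  at least one partner at o, out of all reads having any partner (a read may
  contribute to several offsets, so the vector may sum above 100);
* ``scaled``/``normalized`` — each partnered read contributes its count split
  across offsets in proportion to its partners' counts at each offset, summed
  over both strands; ``normalized`` rescales to sum to 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import StageLibrary

CONVENTIONS = ("five_prime", "three_prime")


def _read_frame(reads) -> pd.DataFrame:
    if isinstance(reads, StageLibrary):
        return reads.df
    return reads


def _anchors(df: pd.DataFrame, convention: str) -> np.ndarray:
    plus = df["strand"].to_numpy() == "+"
    start = df["start"].to_numpy()
    end1 = df["end"].to_numpy() - 1
    if convention == "five_prime":
        return np.where(plus, start, end1)
    if convention == "three_prime":
        return np.where(plus, end1, start)
    raise ValueError(f"unknown convention {convention!r}")


def _offset_sign(convention: str) -> int:
    # five_prime: minus_anchor = plus_anchor + (o-1); three_prime: the mirror
    return 1 if convention == "five_prime" else -1


@dataclass(frozen=True)
class OverlapPair:
    """One sense-antisense pair; indices refer to rows of the read frame."""

    plus_index: int
    minus_index: int
    offset: int
    weight: float
    convention: str = "five_prime"


def find_overlap_pairs(
    reads, max_offset: int = 25, convention: str = "five_prime"
) -> list[OverlapPair]:
    """All opposite-strand pairs with overlap 1 <= o <= max_offset.

    Indexed implementation: reads are hashed by (chrom, anchor) and each
    offset is resolved by a dictionary join, so runtime is
    O(n + pairs) rather than the O(n^2) of naive enumeration.
    Pair weight is count(plus) x count(minus).
    """
    if max_offset < 1:
        raise ValueError("max_offset must be >= 1")
    df = _read_frame(reads)
    if df.empty:
        return []
    anchor = _anchors(df, convention)
    plus = df["strand"].to_numpy() == "+"
    chrom = df["chrom"].to_numpy()
    count = df["count"].to_numpy(dtype=float)
    sign = _offset_sign(convention)

    minus_index: dict[tuple[str, int], list[int]] = {}
    for i in np.flatnonzero(~plus):
        minus_index.setdefault((chrom[i], int(anchor[i])), []).append(int(i))

    pairs: list[OverlapPair] = []
    for i in np.flatnonzero(plus):
        for o in range(1, max_offset + 1):
            key = (chrom[i], int(anchor[i]) + sign * (o - 1))
            for j in minus_index.get(key, ()):
                pairs.append(
                    OverlapPair(int(i), j, o, count[i] * count[j], convention)
                )
    return pairs


@dataclass
class OverlapSignature:
    """Per-offset overlap summaries; index o lives at position o-1."""

    max_offset: int
    convention: str
    raw_pairs: np.ndarray
    pct_reads: np.ndarray
    scaled: np.ndarray
    normalized: np.ndarray
    no_pairs: bool = False

    @property
    def offsets(self) -> np.ndarray:
        return np.arange(1, self.max_offset + 1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "offset": self.offsets,
                "raw_pairs": self.raw_pairs,
                "pct_reads": self.pct_reads,
                "scaled": self.scaled,
                "normalized": self.normalized,
            }
        )


def _partner_matrices(df, max_offset, convention):
    """Per-strand anchor tables and cross-strand partner-count matrices.

    Returns (cp, A, cm, B): cp[i] is the summed count at the i-th distinct
    plus anchor and A[i, o-1] the summed count of its minus partners at
    offset o; (cm, B) mirror this for minus anchors.
    """
    anchor = _anchors(df, convention)
    plus = df["strand"].to_numpy() == "+"
    tab = pd.DataFrame(
        {"chrom": df["chrom"].to_numpy(), "anchor": anchor, "count": df["count"].to_numpy(dtype=float)}
    )
    p = tab[plus].groupby(["chrom", "anchor"], as_index=False)["count"].sum()
    m = tab[~plus].groupby(["chrom", "anchor"], as_index=False)["count"].sum()
    sign = _offset_sign(convention)

    p = p.reset_index(drop=True)
    m = m.reset_index(drop=True)
    A = np.zeros((len(p), max_offset))
    B = np.zeros((len(m), max_offset))
    for chrom in pd.unique(tab["chrom"]):
        pc = p[p["chrom"] == chrom]
        mc = m[m["chrom"] == chrom]
        if pc.empty or mc.empty:
            continue
        manch = mc["anchor"].to_numpy()
        mcnt = mc["count"].to_numpy()
        panch = pc["anchor"].to_numpy()
        pcnt = pc["count"].to_numpy()
        prow = pc.index.to_numpy()
        mrow = mc.index.to_numpy()
        for o in range(1, max_offset + 1):
            # minus partners of each plus anchor
            target = panch + sign * (o - 1)
            pos = np.searchsorted(manch, target)
            ok = (pos < len(manch)) & (manch[np.clip(pos, 0, len(manch) - 1)] == target)
            A[prow[ok], o - 1] = mcnt[pos[ok]]
            # plus partners of each minus anchor
            target = manch - sign * (o - 1)
            pos = np.searchsorted(panch, target)
            ok = (pos < len(panch)) & (panch[np.clip(pos, 0, len(panch) - 1)] == target)
            B[mrow[ok], o - 1] = pcnt[pos[ok]]
    return p["count"].to_numpy(), A, m["count"].to_numpy(), B


def compute_signature(
    reads, max_offset: int = 25, convention: str = "five_prime"
) -> OverlapSignature:
    """Full overlap signature via the anchor-indexed fast path."""
    if max_offset < 1:
        raise ValueError("max_offset must be >= 1")
    df = _read_frame(reads)
    zeros = np.zeros(max_offset)
    if df.empty:
        return OverlapSignature(max_offset, convention, zeros.copy(), zeros.copy(),
                                zeros.copy(), zeros.copy(), no_pairs=True)
    cp, A, cm, B = _partner_matrices(df, max_offset, convention)

    raw = (cp[:, None] * A).sum(axis=0)
    # pct_reads: partnered reads pooled across strands
    p_any = A.sum(axis=1) > 0
    m_any = B.sum(axis=1) > 0
    partnered_total = cp[p_any].sum() + cm[m_any].sum()
    if partnered_total == 0:
        return OverlapSignature(max_offset, convention, raw, zeros.copy(),
                                zeros.copy(), zeros.copy(), no_pairs=True)
    pct = 100.0 * (
        (cp[:, None] * (A > 0)).sum(axis=0) + (cm[:, None] * (B > 0)).sum(axis=0)
    ) / partnered_total
    # scaled: each partnered read's count split across offsets in proportion
    # to its partner counts there ("...and vice versa"), then summed
    scaled = zeros.copy()
    for cnt, M, any_ in ((cp, A, p_any), (cm, B, m_any)):
        if any_.any():
            share = M[any_] / M[any_].sum(axis=1, keepdims=True)
            scaled += (cnt[any_, None] * share).sum(axis=0)
    normalized = scaled / scaled.sum()
    return OverlapSignature(max_offset, convention, raw, pct, scaled, normalized)


# ---------------------------------------------------------------------------
# explicit-pair route (reference semantics, used on locus-scale inputs and as
# the cross-check against the indexed path)

def offset_percentages(pairs: list[OverlapPair], reads, max_offset: int = 25) -> np.ndarray:
    """pct_reads vector from an explicit pair list (see module docstring)."""
    df = _read_frame(reads)
    count = df["count"].to_numpy(dtype=float)
    partner_offsets: dict[int, set[int]] = {}
    for pr in pairs:
        partner_offsets.setdefault(pr.plus_index, set()).add(pr.offset)
        partner_offsets.setdefault(pr.minus_index, set()).add(pr.offset)
    pct = np.zeros(max_offset)
    total = sum(count[i] for i in partner_offsets)
    if total == 0:
        return pct
    for i, offs in partner_offsets.items():
        for o in offs:
            pct[o - 1] += count[i]
    return 100.0 * pct / total


def scaled_signature(pairs: list[OverlapPair], reads, max_offset: int = 25) -> tuple[np.ndarray, np.ndarray]:
    """(scaled, normalized) vectors from an explicit pair list."""
    df = _read_frame(reads)
    count = df["count"].to_numpy(dtype=float)
    # per read: summed partner counts at each offset
    partner_counts: dict[int, np.ndarray] = {}
    for pr in pairs:
        partner_counts.setdefault(pr.plus_index, np.zeros(max_offset))[pr.offset - 1] += count[pr.minus_index]
        partner_counts.setdefault(pr.minus_index, np.zeros(max_offset))[pr.offset - 1] += count[pr.plus_index]
    scaled = np.zeros(max_offset)
    for i, vec in partner_counts.items():
        scaled += count[i] * vec / vec.sum()
    total = scaled.sum()
    normalized = scaled / total if total > 0 else scaled.copy()
    return scaled, normalized


# ---------------------------------------------------------------------------

def paired_mask(reads, offset: int = 10, convention: str = "five_prime") -> np.ndarray:
    """Boolean mask over the read frame: has >= 1 antisense partner at
    exactly ``offset``."""
    df = _read_frame(reads)
    if df.empty:
        return np.zeros(0, dtype=bool)
    anchor = _anchors(df, convention)
    plus = df["strand"].to_numpy() == "+"
    chrom = df["chrom"].to_numpy()
    sign = _offset_sign(convention)
    plus_anchors = {(c, int(a)) for c, a in zip(chrom[plus], anchor[plus])}
    minus_anchors = {(c, int(a)) for c, a in zip(chrom[~plus], anchor[~plus])}
    mask = np.zeros(len(df), dtype=bool)
    for i in range(len(df)):
        if plus[i]:
            mask[i] = (chrom[i], int(anchor[i]) + sign * (offset - 1)) in minus_anchors
        else:
            mask[i] = (chrom[i], int(anchor[i]) - sign * (offset - 1)) in plus_anchors
    return mask


def partition_by_pingpong(
    reads, pairs: list[OverlapPair] | None = None, offset: int = 10,
    convention: str = "five_prime",
):
    """Split reads into those participating in >= 1 pair at exactly ``offset``
    (the ping-pong partition fed to the 1U/10A contrast) and the rest."""
    df = _read_frame(reads)
    if pairs is not None:
        mask = np.zeros(len(df), dtype=bool)
        for pr in pairs:
            if pr.offset == offset:
                mask[pr.plus_index] = True
                mask[pr.minus_index] = True
    else:
        mask = paired_mask(df, offset, convention)
    if isinstance(reads, StageLibrary):
        return reads.subset(mask, recompute_total=False), reads.subset(~mask, recompute_total=False)
    return df[mask].reset_index(drop=True), df[~mask].reset_index(drop=True)


def restrict_to_loci(reads, loci) -> pd.DataFrame:
    """Reads whose 5' end falls inside any locus (chrom, start, end)."""
    df = _read_frame(reads)
    if df.empty:
        return df
    plus = df["strand"].to_numpy() == "+"
    fp = np.where(plus, df["start"].to_numpy(), df["end"].to_numpy() - 1)
    chrom = df["chrom"].to_numpy()
    inside = np.zeros(len(df), dtype=bool)
    for loc in loci:
        c, s, e = (loc.chrom, loc.start, loc.end) if hasattr(loc, "chrom") else loc[:3]
        inside |= (chrom == c) & (fp >= s) & (fp < e)
    return df[inside].reset_index(drop=True)


def locus_pingpong_fraction(reads, sense_strand: str, offset: int = 10) -> float | None:
    """Fraction of unique sense-strand reads (by count) with >= 1 offset-10
    antisense partner; reads should already be restricted to the locus.

    Returns None (undefined) when the locus has no sense reads.
    """
    df = _read_frame(reads)
    mask = paired_mask(df, offset)
    sense = (df["strand"].to_numpy() == sense_strand) & (df["copies"].to_numpy() == 1)
    total = df.loc[sense, "count"].sum()
    if total == 0:
        return None
    return float(df.loc[sense & mask, "count"].sum() / total)


def participation_fraction(reads, offset: int = 10) -> float:
    """Count-weighted fraction of reads having an antisense partner at
    exactly ``offset`` (the per-stage ping-pong participation metric)."""
    df = _read_frame(reads)
    if df.empty:
        return 0.0
    mask = paired_mask(df, offset)
    return float(df.loc[mask, "count"].sum() / df["count"].sum())


def stagewise_signature(
    libraries: dict[str, StageLibrary] | list[StageLibrary],
    clusters=None,
    max_offset: int = 25,
    convention: str = "five_prime",
) -> pd.DataFrame:
    """Normalized overlap signature per developmental stage (stage x offset).

    When ``clusters`` is given, reads are first restricted to cluster spans.
    """
    if isinstance(libraries, dict):
        items = list(libraries.items())
    else:
        items = [(lib.stage or lib.library_id, lib) for lib in libraries]
    rows = {}
    for stage, lib in items:
        df = lib.df if clusters is None else restrict_to_loci(lib, clusters)
        sig = compute_signature(df, max_offset, convention)
        rows[stage] = sig.normalized
    out = pd.DataFrame.from_dict(rows, orient="index", columns=np.arange(1, max_offset + 1))
    out.index.name = "stage"
    return out
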