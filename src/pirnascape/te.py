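"""Transposable-element content of clusters and permutation enrichment test;
sense/antisense piRNA profiles on TE consensus sequences.

The enrichment test mirrors the random-window resampling design: the genome
is tiled into 1-kb windows, the TE-covered fraction of each window is
computed from merged RepeatMasker annotations, and the mean fraction over
cluster windows is compared with means over repeated random draws of an
equal number of windows from the genome-wide tiling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bias import NucleotideMatrix, nucleotide_matrix
from .model import FeatureSet, StageLibrary, merge_intervals


def tile_windows(
    regions: pd.DataFrame | dict[str, int],
    window_size: int = 1000,
    drop_short: bool = True,
) -> pd.DataFrame:
    """1-kb (by default) tiling of a region set or of whole chromosomes.

    ``regions`` is either a chrom/start/end frame or a chrom_sizes mapping.
    Trailing windows shorter than ``window_size`` are dropped (comparable
    denominators for per-window fractions).
    """
    if isinstance(regions, dict):
        regions = pd.DataFrame(
            [(c, 0, s) for c, s in sorted(regions.items())],
            columns=["chrom", "start", "end"],
        )
    rows = []
    for row in regions.itertuples(index=False):
        for ws in range(int(row.start), int(row.end), window_size):
            we = ws + window_size
            if we > row.end:
                if drop_short:
                    break
                we = int(row.end)
            rows.append((row.chrom, ws, we))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def te_fraction_per_window(te_features: FeatureSet, windows: pd.DataFrame) -> np.ndarray:
    """Fraction of each window's bases covered by >= 1 TE annotation.

    Overlapping annotations are merged first so shared bases are not
    double-counted.
    """
    merged = merge_intervals(te_features.df[["chrom", "start", "end"]])
    out = np.zeros(len(windows))
    for chrom, sub in windows.groupby("chrom"):
        te = merged[merged["chrom"] == chrom]
        if te.empty:
            continue
        ts = te["start"].to_numpy()
        te_ = te["end"].to_numpy()
        ws = sub["start"].to_numpy()
        we = sub["end"].to_numpy()
        # overlap of each window with each merged TE interval, summed;
        # interval lists are small after merging so broadcast is fine
        ov = np.clip(
            np.minimum(we[:, None], te_[None, :]) - np.maximum(ws[:, None], ts[None, :]),
            0,
            None,
        ).sum(axis=1)
        out[sub.index] = ov / (we - ws)
    return out


@dataclass
class EnrichmentResult:
    observed_mean: float
    genome_mean: float
    perm_means: np.ndarray
    perm_sd: float
    z: float
    p_empirical: float
    n_cluster_windows: int
    n_genome_windows: int
    seed: int


def enrichment_permutation(
    cluster_fractions: np.ndarray,
    genome_fractions: np.ndarray,
    n_perm: int = 1000,
    seed: int = 0,
    background_fractions: np.ndarray | None = None,
) -> EnrichmentResult:
    """Permutation test of mean per-window TE fraction in clusters.

    Each permutation draws ``len(cluster_fractions)`` windows without
    replacement from the genome-wide tiling (``genome_fractions``, which may
    include the cluster windows, mirroring unrestricted random sampling).
    ``background_fractions`` (e.g. genome excluding clusters) only affects
    the reported ``genome_mean`` baseline; it defaults to
    ``genome_fractions``.  The empirical p-value uses the add-one rule
    p = (1 + #{perm >= observed}) / (n_perm + 1).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    cluster_fractions = np.asarray(cluster_fractions, dtype=float)
    genome_fractions = np.asarray(genome_fractions, dtype=float)
    k = len(cluster_fractions)
    if len(genome_fractions) < k:
        raise ValueError("need at least as many genome windows as cluster windows")
    rng = np.random.default_rng(seed)
    observed = float(cluster_fractions.mean())
    perm_means = np.empty(n_perm)
    for i in range(n_perm):
        perm_means[i] = genome_fractions[
            rng.choice(len(genome_fractions), size=k, replace=False)
        ].mean()
    perm_sd = float(perm_means.std(ddof=1)) if n_perm > 1 else 0.0
    z = (observed - perm_means.mean()) / perm_sd if perm_sd > 0 else float("nan")
    p = (1 + int((perm_means >= observed).sum())) / (n_perm + 1)
    baseline = background_fractions if background_fractions is not None else genome_fractions
    return EnrichmentResult(
        observed_mean=observed,
        genome_mean=float(np.asarray(baseline, dtype=float).mean()),
        perm_means=perm_means,
        perm_sd=perm_sd,
        z=float(z),
        p_empirical=float(p),
        n_cluster_windows=k,
        n_genome_windows=len(genome_fractions),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# consensus-space profiles

@dataclass
class TEProfile:
    te_id: str
    consensus_length: int
    sense_norm: dict[str, float] = field(default_factory=dict)
    antisense_norm: dict[str, float] = field(default_factory=dict)


def te_consensus_profile(
    te_alignments: dict[str, StageLibrary],
    total_unique_genome_pirnas: dict[str, float],
    consensus_lengths: dict[str, int],
) -> list[TEProfile]:
    """Per-TE, per-stage sense/antisense piRNA levels on consensus sequences.

    Alignments use the consensus id as the chromosome.  Each row contributes
    count/copies (multi-mapping positions split the weight); sums are scaled
    per million unique genome-mapped piRNAs of the matching stage.
    """
    profiles = {te: TEProfile(te, L) for te, L in consensus_lengths.items()}
    for stage, lib in te_alignments.items():
        denom = total_unique_genome_pirnas[stage] / 1e6
        df = lib.df
        unknown = set(df["chrom"].unique()) - set(consensus_lengths)
        if unknown:
            raise ValueError(f"unknown consensus id(s): {sorted(unknown)}")
        w = df["count"].to_numpy(dtype=float) / df["copies"].to_numpy(dtype=float)
        sense = df["strand"].to_numpy() == "+"
        grouped = pd.DataFrame({"te": df["chrom"], "w": w, "sense": sense}).groupby(
            ["te", "sense"]
        )["w"].sum()
        for te in profiles:
            profiles[te].sense_norm[stage] = float(grouped.get((te, True), 0.0)) / denom
            profiles[te].antisense_norm[stage] = float(grouped.get((te, False), 0.0)) / denom
    return list(profiles.values())


def te_orientation_summary(
    te_alignments: StageLibrary,
) -> tuple[float | None, NucleotideMatrix, NucleotideMatrix]:
    """Weighted antisense share of TE-mapped reads plus sense / antisense
    nucleotide matrices (sense = '+' in consensus space)."""
    df = te_alignments.df if isinstance(te_alignments, StageLibrary) else te_alignments
    w = df["count"].to_numpy(dtype=float) / df["copies"].to_numpy(dtype=float)
    sense = df["strand"].to_numpy() == "+"
    total = w.sum()
    share = float(w[~sense].sum() / total) if total > 0 else None
    sense_mat = nucleotide_matrix(df[sense])
    anti_mat = nucleotide_matrix(df[~sense])
    return share, sense_mat, anti_mat


def profiles_to_frame(profiles: list[TEProfile]) -> pd.DataFrame:
    rows = []
    for p in profiles:
        for stage in p.sense_norm:
            rows.append(
                (p.te_id, p.consensus_length, stage, p.sense_norm[stage], p.antisense_norm[stage])
            )
    return pd.DataFrame(
        rows, columns=["te_id", "consensus_length", "stage", "sense_norm", "antisense_norm"]
    )
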