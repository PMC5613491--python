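"""End-to-end orchestration: ingest -> clusters -> bias -> pingpong ->
TE enrichment -> maternal/zygotic dynamics, with a machine-readable summary.

The same engine drives the CLI `pirnascape all` and the reproducibility
script; on simulated inputs the planted truth is used to add recovery
metrics to the summary.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import bias, clusters, dynamics, io_reads, pingpong, te
from .model import MATERNAL_STAGES, FeatureSet, StageLibrary
from .simulate import (
    Simulation,
    SimulationParams,
    simulate_genome,
    simulate_libraries,
    simulate_te_alignments,
    truth_metrics,
)

log = logging.getLogger("pirnascape")


@dataclass
class RunConfig:
    outdir: str = "pirnascape_out"
    seed: int = 42
    sim: SimulationParams | None = None   # simulate when set, else load paths
    genome_path: str | None = None
    manifest_path: str | None = None      # TSV: library_id, stage, path, format
    repeats_path: str | None = None
    gff_path: str | None = None
    mask_path: str | None = None
    min_len: int = 25
    max_len: int = 35
    window_size: int = 10_000
    step: int | None = None
    min_reads: int = 1000
    min_fraction: float = 1e-4
    merge_distance: int = 20_000
    max_offset: int = 25
    n_perm: int = 1000
    te_window: int = 1000
    threshold_rpkm: float = 100.0
    pseudocount: float = 1.0
    log_level: str = "INFO"


def _prepare_libraries(
    libraries: dict[str, StageLibrary],
    mask: FeatureSet | None,
    min_len: int,
    max_len: int,
):
    """Size-filter, mask and partition each stage library."""
    unique, multi, totals = {}, {}, {}
    for stage, lib in libraries.items():
        filtered = io_reads.filter_by_size(lib, min_len, max_len)
        if mask is not None and len(mask):
            filtered = io_reads.apply_exclusion_mask(filtered, mask)
        u, m = io_reads.partition_by_uniqueness(filtered)
        unique[stage], multi[stage] = u, m
        totals[stage] = float(u.df["count"].sum())
    return unique, multi, totals


def _pool(stage_libs: dict[str, StageLibrary], name: str = "pooled") -> StageLibrary:
    dfs = [lib.df for lib in stage_libs.values() if len(lib)]
    df = pd.concat(dfs, ignore_index=True) if dfs else next(iter(stage_libs.values())).df
    return StageLibrary(df, library_id=name, stage=name)


def analyze(
    sim: Simulation,
    libraries: dict[str, StageLibrary],
    te_alignments: dict[str, StageLibrary] | None = None,
    config: RunConfig | None = None,
) -> dict:
    """Run the full analysis on (typically simulated) inputs; returns the
    summary dictionary of headline metrics per section."""
    cfg = config or RunConfig()
    summary: dict = {}

    # ---- ingest ----------------------------------------------------------
    mask = None  # simulated genomes carry no rRNA/tRNA annotations
    unique, multi, totals = _prepare_libraries(libraries, mask, cfg.min_len, cfg.max_len)
    pooled_unique = _pool(unique)
    pooled_multi = _pool(multi)
    total_unique = float(pooled_unique.df["count"].sum())
    summary["ingest"] = {
        "stages": list(libraries),
        "unique_pirna_counts": totals,
        "pooled_unique_total": total_unique,
    }
    log.info("ingest: %d stages, %.0f pooled unique piRNA counts", len(libraries), total_unique)

    # ---- clusters --------------------------------------------------------
    windows = clusters.window_counts(pooled_unique, sim.chrom_sizes, cfg.window_size, cfg.step)
    called = clusters.call_clusters(
        windows, total_unique, cfg.min_reads, cfg.min_fraction, cfg.merge_distance,
        lib=pooled_unique,
    )
    curve = clusters.cumulative_fraction(called, total_unique)
    in_cluster_fraction = float(curve["fraction"].iloc[-1]) if len(curve) else 0.0
    rescue = clusters.multimapper_rescue_fraction(pooled_multi, called)
    summary["clusters"] = {
        "n_clusters": len(called),
        "in_cluster_read_fraction": in_cluster_fraction,
        "multimapper_rescue_fraction": rescue,
        "total_cluster_bp": int(sum(c.length for c in called)),
    }
    log.info("clusters: %d called, %.1f%% of unique piRNAs inside",
             len(called), 100 * in_cluster_fraction)

    # ---- sequence bias ---------------------------------------------------
    cluster_reads = pingpong.restrict_to_loci(pooled_unique, called)
    dom_by_pos = {(c.chrom, c.start, c.end): c.dominant_strand for c in called}
    dom_mask = np.zeros(len(cluster_reads), dtype=bool)
    fp = np.where(
        cluster_reads["strand"].to_numpy() == "+",
        cluster_reads["start"].to_numpy(),
        cluster_reads["end"].to_numpy() - 1,
    )
    for c in called:
        inside = (
            (cluster_reads["chrom"].to_numpy() == c.chrom) & (fp >= c.start) & (fp < c.end)
        )
        dom_mask |= inside & (cluster_reads["strand"].to_numpy() == c.dominant_strand)
    dominant_mat = bias.nucleotide_matrix(cluster_reads[dom_mask])
    opposite_mat = bias.nucleotide_matrix(cluster_reads[~dom_mask])
    summary["bias"] = {
        "dominant_1U": bias.base_fraction_at(cluster_reads[dom_mask], 1, "T"),
        "opposite_10A": bias.base_fraction_at(cluster_reads[~dom_mask], 10, "A"),
        "dominant_info_pos1": float(dominant_mat.info[0]),
    }

    # ---- ping-pong -------------------------------------------------------
    stage_sig = pingpong.stagewise_signature(unique, called, cfg.max_offset)
    participation = {
        stage: pingpong.participation_fraction(pingpong.restrict_to_loci(lib, called))
        for stage, lib in unique.items()
    }
    summary["pingpong"] = {
        "signature_argmax": {s: int(stage_sig.loc[s].idxmax()) for s in stage_sig.index},
        "offset10_participation": participation,
        "normalized_at_10": {s: float(stage_sig.loc[s, 10]) for s in stage_sig.index},
    }

    # ---- TE enrichment ---------------------------------------------------
    cluster_bed = pd.DataFrame(
        [(c.chrom, c.start, c.end) for c in called], columns=["chrom", "start", "end"]
    )
    genome_windows = te.tile_windows(sim.chrom_sizes, cfg.te_window)
    cluster_windows = te.tile_windows(cluster_bed, cfg.te_window) if len(cluster_bed) else cluster_bed
    genome_fr = te.te_fraction_per_window(sim.te_table, genome_windows)
    cluster_fr = te.te_fraction_per_window(sim.te_table, cluster_windows) if len(
        cluster_windows
    ) else np.zeros(0)
    if len(cluster_fr):
        enr = te.enrichment_permutation(cluster_fr, genome_fr, cfg.n_perm, seed=cfg.seed)
        summary["te_enrichment"] = {
            "observed_mean": enr.observed_mean,
            "genome_mean": enr.genome_mean,
            "z": enr.z,
            "p_empirical": enr.p_empirical,
        }
    else:
        summary["te_enrichment"] = {"p_empirical": None}
    if te_alignments:
        pooled_te = _pool(te_alignments, "te_pooled")
        share, _smat, _amat = te.te_orientation_summary(pooled_te)
        summary["te_enrichment"]["antisense_share"] = share

    # ---- maternal / zygotic dynamics -------------------------------------
    gene_set = sim.gff.of_kind("gene")
    sense_cov = {
        stage: dynamics.feature_coverage(unique[stage], gene_set, "sense")
        for stage in unique
    }
    both_cov = {
        stage: dynamics.feature_coverage(unique[stage], gene_set, "both")
        for stage in unique
    }
    gene_lengths = (gene_set.df["end"] - gene_set.df["start"]).to_numpy(dtype=float)
    rpkm_by_stage = pd.DataFrame(
        {
            stage: dynamics.rpkm(sense_cov[stage].to_numpy(), gene_lengths, totals[stage])
            for stage in unique
        },
        index=gene_set.df["name"],
    )
    total_rpkm_by_stage = pd.DataFrame(
        {
            stage: dynamics.rpkm(both_cov[stage].to_numpy(), gene_lengths, totals[stage])
            for stage in unique
        },
        index=gene_set.df["name"],
    )
    mz = {
        name: dynamics.pool_maternal_zygotic(row.to_dict(), cfg.pseudocount)
        for name, row in rpkm_by_stage.iterrows()
    }
    truth_genes = sim.truth.genes.set_index("name")
    activated = truth_genes.index[truth_genes["activated"]]
    up_frac = float(
        np.mean([mz[g].cls == "up" for g in activated if g in mz])
    ) if len(activated) else float("nan")
    fc_pirna = pd.Series({g: mz[g].fold_change for g in mz})
    fc_mrna = truth_genes["activation"]
    corr = dynamics.mz_correlation(fc_pirna, fc_mrna)
    target_table = dynamics.pirna_target_table(
        total_rpkm_by_stage, gene_set, sim.te_table, cfg.threshold_rpkm
    )
    summary["mz"] = {
        "activated_classified_up_fraction": up_frac,
        "spearman_rho": corr["all"]["rho"],
        "spearman_p": corr["all"]["p"],
        "n_genes": corr["all"]["n"],
        "targets_passing_threshold": int(len(target_table)),
        "n_planted_genes": int(len(truth_genes)),
    }

    # ---- truth recovery --------------------------------------------------
    summary["recovery"] = truth_metrics(sim, called, stage_sig)

    # stash non-JSON artifacts for callers that want them
    summary["_artifacts"] = {
        "clusters": called,
        "stage_signature": stage_sig,
        "cumulative": curve,
        "rpkm": rpkm_by_stage,
        "dominant_matrix": dominant_mat,
        "opposite_matrix": opposite_mat,
        "unique": unique,
        "multi": multi,
    }
    return summary


def run_all(config: RunConfig) -> dict:
    """Validate the configuration, run the pipeline and write the output
    tree (TSV/BED tables, JSON summary, parameter echo)."""
    logging.basicConfig(level=config.log_level)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    if config.sim is None:
        raise NotImplementedError(
            "run_all currently drives the simulated pipeline; for real data "
            "call the module functions directly (see examples/)"
        )
    sim = simulate_genome(config.sim)
    libraries = simulate_libraries(sim)
    te_alns = simulate_te_alignments(sim)
    summary = analyze(sim, libraries, te_alns, config)

    art = summary.pop("_artifacts")
    clusters.clusters_to_frame(art["clusters"]).to_csv(
        outdir / "clusters.bed", sep="\t", index=False, header=False
    )
    art["cumulative"].to_csv(outdir / "cumulative_fraction.tsv", sep="\t", index=False)
    art["stage_signature"].to_csv(outdir / "signature_by_stage.tsv", sep="\t")
    art["rpkm"].to_csv(outdir / "gene_sense_rpkm.tsv", sep="\t")
    art["dominant_matrix"].to_frame().to_csv(
        outdir / "bias_dominant.tsv", sep="\t", index=False
    )
    art["opposite_matrix"].to_frame().to_csv(
        outdir / "bias_opposite.tsv", sep="\t", index=False
    )
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, default=_jsonify)
    import yaml
    from dataclasses import asdict

    with open(outdir / "run_config.yaml", "w") as fh:
        yaml.safe_dump(asdict(config), fh, sort_keys=False)
    summary["_artifacts"] = art
    return summary


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
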