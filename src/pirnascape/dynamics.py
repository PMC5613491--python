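"""Feature-level piRNA coverage, RPKM normalization, maternal/zygotic pooling
and piRNA-mRNA fold-change correlation.

"Maternal" pools the pre-zygotic-activation libraries (oocyte, 0-5 h);
"zygotic" pools everything from 8 h onward.  Fold changes use a pseudocount
so that features absent from one pool remain comparable, and features are
classed up (> 2x), down (< 0.5x) or unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .model import MATERNAL_STAGES, FeatureSet, StageLibrary


def feature_coverage(
    lib: StageLibrary,
    features: FeatureSet,
    strand_mode: str = "both",
) -> pd.Series:
    """Weighted read counts per feature (indexed by feature name).

    A read is assigned to the features containing its 5' end; when k
    eligible features overlap at that point the read's count is split
    equally among them.  ``strand_mode`` restricts eligibility to features
    on the read's strand ("sense"), the opposite strand ("antisense") or any
    ("both").  Multi-mapper rows weigh count/copies.
    """
    if strand_mode not in ("sense", "antisense", "both"):
        raise ValueError(f"invalid strand_mode {strand_mode!r}")
    fdf = features.df
    trees: dict[str, IntervalTree] = {}
    for i, row in enumerate(fdf.itertuples(index=False)):
        if row.end > row.start:
            trees.setdefault(row.chrom, IntervalTree()).addi(row.start, row.end, i)
    totals = pd.Series(0.0, index=fdf["name"])

    df = lib.df
    fp = lib.five_prime
    weight = df["count"].to_numpy(dtype=float) / df["copies"].to_numpy(dtype=float)
    chroms = df["chrom"].to_numpy()
    strands = df["strand"].to_numpy()
    fstrand = fdf["strand"].to_numpy()
    fname = fdf["name"].to_numpy()

    # group identical (chrom, 5', strand) queries to cut tree lookups
    qdf = pd.DataFrame({"chrom": chroms, "fp": fp, "strand": strands, "w": weight})
    for (chrom, pos, strand), sub in qdf.groupby(["chrom", "fp", "strand"], sort=False):
        tree = trees.get(chrom)
        if tree is None:
            continue
        hits = [iv.data for iv in tree.at(int(pos))]
        if strand_mode == "sense":
            hits = [h for h in hits if fstrand[h] == strand]
        elif strand_mode == "antisense":
            hits = [h for h in hits if fstrand[h] != strand]
        if not hits:
            continue
        share = sub["w"].sum() / len(hits)
        for h in hits:
            totals[fname[h]] += share
    return totals


def rpkm(counts, feature_length, library_total_25_35) -> float | np.ndarray:
    """Reads per million (of the 25-35-nt library total) per kb of feature."""
    feature_length = np.asarray(feature_length, dtype=float)
    if np.any(feature_length <= 0) or library_total_25_35 <= 0:
        raise ValueError("feature length and library total must be positive")
    out = np.asarray(counts, dtype=float) / (library_total_25_35 / 1e6) / (feature_length / 1000.0)
    return float(out) if out.ndim == 0 else out


def stage_pool(stage: str) -> str:
    """Classify a stage label as maternal or zygotic."""
    if stage in MATERNAL_STAGES:
        return "maternal"
    if stage.startswith("e") or stage in ("2_6d",):
        return "zygotic"
    raise ValueError(f"stage {stage!r} not classifiable as maternal or zygotic")


@dataclass
class MZComparison:
    maternal_value: float
    zygotic_value: float
    fold_change: float
    cls: str  # up / down / unchanged

    @classmethod
    def from_values(cls, maternal: float, zygotic: float, pseudocount: float = 1.0) -> "MZComparison":
        fc = (zygotic + pseudocount) / (maternal + pseudocount)
        if fc > 2.0:
            label = "up"
        elif fc < 0.5:
            label = "down"
        else:
            label = "unchanged"
        return cls(maternal, zygotic, fc, label)


def pool_maternal_zygotic(
    stage_values: dict[str, float], pseudocount: float = 1.0
) -> MZComparison:
    """Average normalized values over the maternal and zygotic stage pools
    and classify the fold change at 2x thresholds."""
    pools: dict[str, list[float]] = {"maternal": [], "zygotic": []}
    for stage, value in stage_values.items():
        pools[stage_pool(stage)].append(value)
    for name, vals in pools.items():
        if not vals:
            raise ValueError(f"no stage in the {name} pool")
    return MZComparison.from_values(
        float(np.mean(pools["maternal"])), float(np.mean(pools["zygotic"])), pseudocount
    )


def mz_correlation(
    fc_pirna: pd.Series, fc_mrna: pd.Series, te_flags: pd.Series | None = None
) -> dict[str, dict[str, float]]:
    """Spearman correlation of log2 fold changes, overall and for the
    TE-flagged subset.  Returns {"all": {rho, p, n}, "te": {...}}."""

    def _spearman(x: pd.Series, y: pd.Series) -> dict[str, float]:
        joined = pd.concat([x, y], axis=1, join="inner").replace(
            [np.inf, -np.inf], np.nan
        ).dropna()
        n = len(joined)
        if n < 3:
            return {"rho": float("nan"), "p": float("nan"), "n": n}
        rho, p = stats.spearmanr(joined.iloc[:, 0], joined.iloc[:, 1])
        return {"rho": float(rho), "p": float(p), "n": n}

    x = np.log2(fc_pirna)
    y = np.log2(fc_mrna)
    out = {"all": _spearman(x, y)}
    if te_flags is not None:
        idx = te_flags[te_flags].index
        out["te"] = _spearman(x.loc[x.index.intersection(idx)], y.loc[y.index.intersection(idx)])
    return out


def pirna_target_table(
    exonic_rpkm: pd.DataFrame,
    gene_spans: FeatureSet,
    te_annotations: FeatureSet,
    threshold_rpkm: float = 100.0,
) -> pd.DataFrame:
    """Putative piRNA target genes: exonic piRNA RPKM >= threshold in at
    least one stage, with a ``te_related`` flag set when a TE annotation
    overlaps the gene span.

    ``exonic_rpkm`` is a gene x stage frame of exonic piRNA RPKM values.
    """
    best = exonic_rpkm.max(axis=1)
    keep = best[best >= threshold_rpkm].index
    trees: dict[str, IntervalTree] = {}
    for row in te_annotations.df.itertuples(index=False):
        if row.end > row.start:
            trees.setdefault(row.chrom, IntervalTree()).addi(row.start, row.end)
    genes = gene_spans.df.set_index("name")
    rows = []
    for name in keep:
        te_related = False
        if name in genes.index:
            g = genes.loc[name]
            tree = trees.get(g["chrom"])
            te_related = bool(tree is not None and tree.overlaps(int(g["start"]), int(g["end"])))
        rec = {"name": name, "max_exonic_rpkm": float(best[name]), "te_related": te_related}
        rec.update({f"rpkm_{c}": float(exonic_rpkm.loc[name, c]) for c in exonic_rpkm.columns})
        rows.append(rec)
    return pd.DataFrame(rows)
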