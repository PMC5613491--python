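"""Synthetic small-RNA-seq generator with planted ground truth.

Emulates the statistical structure the analysis assumes: a random genome
carrying discrete uni-stranded piRNA clusters whose TE insertions are
oriented antisense to the planted dominant strand; stage-resolved read
libraries with a 28-nt-peaked length distribution, 1U-biased primary piRNAs,
ping-pong secondary piRNAs (5'-5' offset exactly 10) restricted to
zygotic-activation stages, 22-nt miRNA-like background and uniform
degradation background.  Every read carries a genome-consistent sequence,
collapse count and an exact mapping-position count, and the generator
returns a truth manifest (planted intervals, per-read provenance, secondary
-> template pairing) for parameter-recovery tests.

The 10A bias of secondary reads is *not* a parameter: it emerges because a
secondary read's tenth base is complementary to its template's first base.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .model import FeatureSet, StageLibrary, revcomp

_LETTERS = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMP = np.zeros(256, dtype=np.uint8)
for a, b in zip(b"ACGTN", b"TGCAN"):
    _COMP[a] = b

_A, _T = ord("A"), ord("T")


def _rc_arr(arr: np.ndarray) -> np.ndarray:
    return _COMP[arr][::-1]


def _to_str(arr: np.ndarray) -> str:
    return arr.tobytes().decode("ascii")


# ---------------------------------------------------------------------------
# parameters

@dataclass
class GenomeParams:
    n_chroms: int = 4
    chrom_length: int = 1_250_000


@dataclass
class ClusterParams:
    n: int = 8
    min_length: int = 60_000
    max_length: int = 120_000
    dominance: float = 0.8           # P(primary read on the dominant strand), 4:1
    uni_stranded: bool = True


@dataclass
class TEParams:
    n_consensus: int = 5
    consensus_length: int = 1500
    insertions_per_cluster: int = 8
    substitution_rate: float = 0.01   # per-copy divergence -> mix of unique/multi reads
    gene_flank: int = 500             # TE transcript UTRs extending past the insertion
    antisense_share: float = 0.75     # consensus-space alignments, pooled over stages
    sense_zygotic_shift: float = 0.10
    te_read_fraction: float = 0.10    # share of a library aligning to consensuses


@dataclass
class ReadParams:
    depth: int = 200_000
    length_mean: float = 28.0
    length_sd: float = 1.5
    min_len: int = 25
    max_len: int = 35
    p_1U: float = 0.8
    mirna_fraction: float = 0.15
    degradation_fraction: float = 0.10
    n_mirna_loci: int = 20


@dataclass
class PingPongParams:
    active_stages: tuple[str, ...] = ("e8_16", "e16_20")
    secondary_rate: float = 0.12      # secondary share of piRNA-class reads
    offset: int = 10                  # fixed by the mechanism


@dataclass
class SimulationParams:
    seed: int = 42
    stages: tuple[str, ...] = ("oocyte", "e0_5", "e8_16", "e16_20")
    genome: GenomeParams = field(default_factory=GenomeParams)
    clusters: ClusterParams = field(default_factory=ClusterParams)
    te: TEParams = field(default_factory=TEParams)
    reads: ReadParams = field(default_factory=ReadParams)
    pingpong: PingPongParams = field(default_factory=PingPongParams)

    def __post_init__(self) -> None:
        for p in (
            self.clusters.dominance,
            self.te.substitution_rate,
            self.te.antisense_share,
            self.reads.p_1U,
            self.reads.mirna_fraction,
            self.reads.degradation_fraction,
            self.pingpong.secondary_rate,
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability parameter out of [0,1]: {p}")
        if self.reads.depth < 0:
            raise ValueError("depth must be >= 0")
        if self.pingpong.offset != 10:
            raise ValueError("the ping-pong offset is fixed at 10 by the mechanism")
        total_cluster = self.clusters.n * self.clusters.max_length
        if total_cluster >= self.genome.n_chroms * self.genome.chrom_length / 2:
            raise ValueError("cluster total length must be < genome length / 2")


# ---------------------------------------------------------------------------
# truth containers

@dataclass
class PlantedCluster:
    chrom: str
    start: int
    end: int
    dominant_strand: str
    weight: float  # relative expression


@dataclass
class TEInsertion:
    chrom: str
    start: int
    end: int
    strand: str
    te_id: str
    gene_name: str


@dataclass
class SyntheticTruth:
    clusters: list[PlantedCluster]
    insertions: list[TEInsertion]
    genes: pd.DataFrame          # name, chrom, start, end, strand, maternal_mrna, activation, activated
    mirna_loci: pd.DataFrame     # chrom, pos, strand, weight
    reads: dict[str, pd.DataFrame] = field(default_factory=dict)
    # per-stage molecule frames: chrom, start, end, strand, seq, label,
    # template_five_prime (secondary reads only, else -1)


@dataclass
class Simulation:
    params: SimulationParams
    genome: dict[str, np.ndarray]        # chrom -> uint8 letter array
    chrom_sizes: dict[str, int]
    consensus: dict[str, str]
    truth: SyntheticTruth
    te_table: FeatureSet
    gff: FeatureSet

    def seq(self, chrom: str, start: int, end: int, strand: str = "+") -> str:
        arr = self.genome[chrom][start:end]
        return _to_str(_rc_arr(arr) if strand == "-" else arr)


def _streams(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


# ---------------------------------------------------------------------------
# genome

def simulate_genome(params: SimulationParams) -> Simulation:
    """Random genome with planted clusters, TE insertions and annotations.

    Deterministic given ``params.seed``: identical parameters reproduce the
    genome byte-for-byte.
    """
    rng = _streams(params.seed, 4)[0]
    gp, cp, tp = params.genome, params.clusters, params.te
    chroms = [f"chr{i + 1}" for i in range(gp.n_chroms)]
    genome = {
        c: _LETTERS[rng.integers(0, 4, gp.chrom_length)] for c in chroms
    }
    chrom_sizes = {c: gp.chrom_length for c in chroms}

    consensus = {
        f"TE{j + 1}": _to_str(_LETTERS[rng.integers(0, 4, tp.consensus_length)])
        for j in range(tp.n_consensus)
    }

    # place clusters round-robin across chromosomes, non-overlapping with margin
    margin = 30_000
    placed: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    clusters: list[PlantedCluster] = []
    for k in range(cp.n):
        chrom = chroms[k % len(chroms)]
        length = int(rng.integers(cp.min_length, cp.max_length + 1))
        for _attempt in range(1000):
            start = int(rng.integers(margin, gp.chrom_length - length - margin))
            end = start + length
            if all(end + margin <= s or start >= e + margin for s, e in placed[chrom]):
                placed[chrom].append((start, end))
                break
        else:
            raise RuntimeError("infeasible cluster packing; reduce n or lengths")
        strand = "+" if rng.random() < 0.5 else "-"
        weight = float(rng.lognormal(0.0, 0.7))
        clusters.append(PlantedCluster(chrom, start, end, strand, weight))

    # TE insertions: copies of a consensus, 1% substitutions, oriented
    # antisense to the cluster's dominant strand; one TE-ORF gene each
    insertions: list[TEInsertion] = []
    te_rows, gff_rows, gene_rows = [], [], []
    gene_idx = 0
    for cl in clusters:
        # non-overlapping slots of 2x consensus length, jittered within the slot
        n_slots = (cl.end - cl.start - tp.consensus_length) // (2 * tp.consensus_length)
        slots = np.sort(
            rng.choice(n_slots, size=min(tp.insertions_per_cluster, n_slots), replace=False)
        )
        for slot in slots:
            start = cl.start + int(slot) * 2 * tp.consensus_length + int(
                rng.integers(0, tp.consensus_length // 2)
            )
            end = start + tp.consensus_length
            te_id = f"TE{int(rng.integers(1, tp.n_consensus + 1))}"
            strand = "-" if cl.dominant_strand == "+" else "+"
            copy = np.frombuffer(consensus[te_id].encode(), dtype=np.uint8).copy()
            subs = rng.random(len(copy)) < tp.substitution_rate
            copy[subs] = _LETTERS[
                (np.searchsorted(_LETTERS, copy[subs]) + rng.integers(1, 4, subs.sum())) % 4
            ]
            genome[cl.chrom][start:end] = copy if strand == "+" else _rc_arr(copy)
            gene_idx += 1
            gene_name = f"te_gene_{gene_idx}"
            insertions.append(TEInsertion(cl.chrom, start, end, strand, te_id, gene_name))
            te_rows.append((cl.chrom, start, end, strand, "TE", te_id, ""))
            # the TE transcript extends past the insertion into flanking
            # (unique) sequence, like read-through UTRs of a real element
            g_start = max(cl.start, start - tp.gene_flank)
            g_end = min(cl.end, end + tp.gene_flank)
            gff_rows.append((cl.chrom, g_start, g_end, strand, "gene", gene_name, ""))
            gff_rows.append((cl.chrom, g_start, g_end, strand, "exon", f"{gene_name}.e1", gene_name))
            maternal_mrna = float(rng.lognormal(1.0, 0.4))
            activated = bool(rng.random() < 0.7)
            activation = float(rng.lognormal(np.log(4.0), 0.3)) if activated else float(
                rng.lognormal(0.0, 0.15)
            )
            gene_rows.append(
                (gene_name, cl.chrom, g_start, g_end, strand, maternal_mrna, activation, activated)
            )

    # fixed miRNA-like loci outside clusters
    mirna_rows = []
    for _ in range(params.reads.n_mirna_loci):
        while True:
            chrom = chroms[int(rng.integers(0, len(chroms)))]
            pos = int(rng.integers(100, gp.chrom_length - 100))
            if all(not (s - 50 <= pos < e + 50) for s, e in placed[chrom]):
                break
        mirna_rows.append(
            (chrom, pos, "+" if rng.random() < 0.5 else "-", float(rng.lognormal(0.0, 1.0)))
        )

    truth = SyntheticTruth(
        clusters=clusters,
        insertions=insertions,
        genes=pd.DataFrame(
            gene_rows,
            columns=["name", "chrom", "start", "end", "strand",
                     "maternal_mrna", "activation", "activated"],
        ),
        mirna_loci=pd.DataFrame(mirna_rows, columns=["chrom", "pos", "strand", "weight"]),
    )
    from .model import FEATURE_COLUMNS  # local import to avoid cycle noise

    return Simulation(
        params=params,
        genome=genome,
        chrom_sizes=chrom_sizes,
        consensus=consensus,
        truth=truth,
        te_table=FeatureSet(pd.DataFrame(te_rows, columns=FEATURE_COLUMNS)),
        gff=FeatureSet(pd.DataFrame(gff_rows, columns=FEATURE_COLUMNS)),
    )


# ---------------------------------------------------------------------------
# read libraries

def _sample_lengths(rng, rp: ReadParams, n: int) -> np.ndarray:
    L = np.rint(rng.normal(rp.length_mean, rp.length_sd, n)).astype(int)
    return np.clip(L, rp.min_len, rp.max_len)


def _cluster_position_pools(sim: Simulation):
    """Per cluster and strand: candidate 5' positions split by whether the
    read would start with U (T in DNA space)."""
    pools = []
    for cl in sim.truth.clusters:
        arr = sim.genome[cl.chrom][cl.start:cl.end]
        pos = np.arange(cl.start, cl.end)
        by_strand = {}
        for strand in "+-":
            # read 5' base: genome base on '+', its complement on '-'
            is_u = arr == (_T if strand == "+" else _A)
            by_strand[strand] = (pos[is_u], pos[~is_u])
        pools.append(by_strand)
    return pools


def _emit_reads(sim, chroms, fives, strands, lengths, labels, template_fp) -> pd.DataFrame:
    """Materialise reads (coordinates clipped to chromosomes, sequences cut
    from the genome in read orientation)."""
    rows = []
    for chrom, f, strand, L, label, tfp in zip(
        chroms, fives, strands, lengths, labels, template_fp
    ):
        size = sim.chrom_sizes[chrom]
        f = int(min(max(f, 0), size - 1))
        L = int(L)
        if strand == "+":
            start, end = f, min(f + L, size)
        else:
            start, end = max(f - L + 1, 0), f + 1
        arr = sim.genome[chrom][start:end]
        seq = _to_str(_rc_arr(arr) if strand == "-" else arr)
        rows.append((chrom, start, end, strand, seq, label, tfp))
    return pd.DataFrame(
        rows,
        columns=["chrom", "start", "end", "strand", "seq", "label", "template_five_prime"],
    )


def _build_te_region_index(sim: Simulation, k: int = 25):
    """Exact-match index of candidate read 5' positions around TE insertions.

    Maps the first k read bases to (strand, five_prime, chrom) candidates;
    only TE neighbourhoods are indexed because the i.i.d. background makes
    off-TE k-mer collisions vanishingly rare (4^25 >> genome size).
    """
    index: dict[str, list[tuple[str, int, str]]] = {}
    pad = 34
    for ins in sim.truth.insertions:
        g = sim.genome[ins.chrom]
        lo = max(ins.start - pad, 0)
        hi = min(ins.end + pad, len(g))
        for f in range(lo, hi):
            if f + k <= len(g):
                key = _to_str(g[f:f + k])
                index.setdefault(key, []).append(("+", f, ins.chrom))
            if f - k + 1 >= 0:
                key = _to_str(_rc_arr(g[f - k + 1:f + 1]))
                index.setdefault(key, []).append(("-", f, ins.chrom))
    return index


def _mapping_positions(sim, index, seq, origin):
    """All exact genomic matches of ``seq`` (read-oriented); origin is
    (chrom, start, end, strand) and is always included."""
    k = 25
    L = len(seq)
    hits = []
    for strand, f, chrom in index.get(seq[:k], ()):
        g = sim.genome[chrom]
        if strand == "+":
            s, e = f, f + L
            if e > len(g) or _to_str(g[s:e]) != seq:
                continue
        else:
            s, e = f - L + 1, f + 1
            if s < 0 or _to_str(_rc_arr(g[s:e])) != seq:
                continue
        hits.append((chrom, s, e, strand))
    if origin not in hits:
        hits.append(origin)
    return sorted(set(hits))


def simulate_libraries(
    sim: Simulation, params: SimulationParams | None = None
) -> dict[str, StageLibrary]:
    """Generate per-stage read libraries; truth frames land in
    ``sim.truth.reads[stage]``.

    Collapse is sequence-level: identical sequences become one record with a
    collapse count, expanded to one row per exact mapping position with
    ``copies`` = number of positions.
    """
    params = params or sim.params
    rp, ppp, cp = params.reads, params.pingpong, params.clusters
    pools = _cluster_position_pools(sim)
    cluster_w = np.array([c.weight * (c.end - c.start) for c in sim.truth.clusters])
    cluster_w = cluster_w / cluster_w.sum()
    chrom_names = list(sim.chrom_sizes)
    chrom_p = np.array([sim.chrom_sizes[c] for c in chrom_names], dtype=float)
    chrom_p /= chrom_p.sum()
    te_index = _build_te_region_index(sim)
    genes = sim.truth.genes
    gene_w = (genes["maternal_mrna"] * genes["activation"]).to_numpy()
    gene_w = gene_w / gene_w.sum()

    stage_rngs = _streams(params.seed + 1, len(params.stages))
    libraries: dict[str, StageLibrary] = {}
    for stage, rng in zip(params.stages, stage_rngs):
        n_deg = int(round(rp.depth * rp.degradation_fraction))
        n_mir = int(round(rp.depth * rp.mirna_fraction))
        n_pi = rp.depth - n_deg - n_mir
        active = stage in ppp.active_stages
        n_sec = int(round(n_pi * ppp.secondary_rate)) if active else 0
        n_pri = n_pi - n_sec

        # --- primary piRNAs -------------------------------------------------
        ci = rng.choice(len(pools), size=n_pri, p=cluster_w)
        on_dom = rng.random(n_pri) < cp.dominance
        strands = np.array(
            [
                sim.truth.clusters[c].dominant_strand
                if d
                else ("-" if sim.truth.clusters[c].dominant_strand == "+" else "+")
                for c, d in zip(ci, on_dom)
            ]
        )
        with_u = rng.random(n_pri) < rp.p_1U
        fives = np.empty(n_pri, dtype=np.int64)
        for i in range(n_pri):
            u_pos, other_pos = pools[ci[i]][strands[i]]
            pool = u_pos if (with_u[i] and len(u_pos)) else other_pos
            if len(pool) == 0:  # pathological cluster with no U starts
                pool = np.concatenate([u_pos, other_pos])
            fives[i] = pool[rng.integers(0, len(pool))]
        pri = _emit_reads(
            sim,
            [sim.truth.clusters[c].chrom for c in ci],
            fives,
            strands,
            _sample_lengths(rng, rp, n_pri),
            ["primary"] * n_pri,
            [-1] * n_pri,
        )

        # --- secondary piRNAs (ping-pong, active stages only) ---------------
        frames = [pri]
        if n_sec:
            pri_fp = np.where(
                pri["strand"].to_numpy() == "+",
                pri["start"].to_numpy(),
                pri["end"].to_numpy() - 1,
            )
            # templates: dominant-strand primaries inside each TE gene span,
            # genes drawn in proportion to their zygotic transcript level
            gene_templates = []
            for g in genes.itertuples(index=False):
                dom = next(
                    c.dominant_strand
                    for c in sim.truth.clusters
                    if c.chrom == g.chrom and c.start <= g.start and g.end <= c.end
                )
                mask = (
                    (pri["chrom"].to_numpy() == g.chrom)
                    & (pri["strand"].to_numpy() == dom)
                    & (pri_fp >= g.start)
                    & (pri_fp < g.end)
                )
                gene_templates.append(np.flatnonzero(mask))
            gi = rng.choice(len(genes), size=n_sec, p=gene_w)
            t_idx = np.empty(n_sec, dtype=np.int64)
            for i, g in enumerate(gi):
                cand = gene_templates[g]
                if len(cand) == 0:  # fall back to any primary on that chromosome
                    cand = np.flatnonzero(
                        pri["chrom"].to_numpy() == genes.iloc[g]["chrom"]
                    )
                t_idx[i] = cand[rng.integers(0, len(cand))]
            t_strand = pri["strand"].to_numpy()[t_idx]
            t_fp = pri_fp[t_idx]
            sec_strand = np.where(t_strand == "+", "-", "+")
            sec_fp = np.where(t_strand == "+", t_fp + ppp.offset - 1, t_fp - ppp.offset + 1)
            sec = _emit_reads(
                sim,
                pri["chrom"].to_numpy()[t_idx],
                sec_fp,
                sec_strand,
                _sample_lengths(rng, rp, n_sec),
                ["secondary"] * n_sec,
                t_fp,
            )
            frames.append(sec)

        # --- miRNA-like 22-nt background ------------------------------------
        if n_mir:
            loci = sim.truth.mirna_loci
            lw = loci["weight"].to_numpy()
            li = rng.choice(len(loci), size=n_mir, p=lw / lw.sum())
            mir = _emit_reads(
                sim,
                loci["chrom"].to_numpy()[li],
                loci["pos"].to_numpy()[li],
                loci["strand"].to_numpy()[li],
                np.full(n_mir, 22),
                ["mirna"] * n_mir,
                [-1] * n_mir,
            )
            frames.append(mir)

        # --- uniform degradation background ---------------------------------
        if n_deg:
            dchrom = rng.choice(chrom_names, size=n_deg, p=chrom_p)
            dlen = rng.integers(18, 36, n_deg)
            dstrand = np.where(rng.random(n_deg) < 0.5, "+", "-")
            dstart = np.array(
                [rng.integers(0, sim.chrom_sizes[c] - L) for c, L in zip(dchrom, dlen)]
            )
            dfp = np.where(dstrand == "+", dstart, dstart + dlen - 1)
            deg = _emit_reads(
                sim, dchrom, dfp, dstrand, dlen, ["degradation"] * n_deg, [-1] * n_deg
            )
            frames.append(deg)

        molecules = pd.concat(frames, ignore_index=True)
        sim.truth.reads[stage] = molecules
        libraries[stage] = _collapse(sim, te_index, molecules, stage)
    return libraries


def _collapse(sim, te_index, molecules: pd.DataFrame, stage: str) -> StageLibrary:
    grouped = molecules.groupby("seq", sort=False)
    rows = []
    rid = 0
    for seq, sub in grouped:
        first = sub.iloc[0]
        origin = (first["chrom"], int(first["start"]), int(first["end"]), first["strand"])
        positions = _mapping_positions(sim, te_index, seq, origin)
        copies = len(positions)
        count = len(sub)
        rid += 1
        for chrom, s, e, strand in positions:
            rows.append((f"{stage}_r{rid}", seq, chrom, s, e, strand, count, copies))
    df = pd.DataFrame(
        rows,
        columns=["read_id", "seq", "chrom", "start", "end", "strand", "count", "copies"],
    )
    return StageLibrary(df, library_id=stage, stage=stage)


# ---------------------------------------------------------------------------
# consensus-space TE alignments

def simulate_te_alignments(
    sim: Simulation, params: SimulationParams | None = None
) -> dict[str, StageLibrary]:
    """Consensus-space alignments with a planted antisense share.

    Maternal stages run antisense-heavier, zygotic stages sense-heavier by
    ``sense_zygotic_shift``, so the stage-balanced pooled share equals
    ``antisense_share``.  Antisense reads are 1U-sampled; zygotic sense
    reads are placed at the ping-pong offset from a sampled antisense read
    (emergent 10A); maternal sense reads are 1U-sampled (TE fragments in
    sense orientation to a transcript, not ping-pong products).
    """
    params = params or sim.params
    tp, rp, ppp = params.te, params.reads, params.pingpong
    cons_arr = {
        te: np.frombuffer(s.encode(), dtype=np.uint8) for te, s in sim.consensus.items()
    }
    te_ids = list(sim.consensus)
    rngs = _streams(params.seed + 2, len(params.stages))
    out: dict[str, StageLibrary] = {}
    for stage, rng in zip(params.stages, rngs):
        n = int(round(rp.depth * tp.te_read_fraction))
        active = stage in ppp.active_stages
        a_share = tp.antisense_share + (-tp.sense_zygotic_shift if active else tp.sense_zygotic_shift)
        rows = []
        for i in range(n):
            te = te_ids[int(rng.integers(0, len(te_ids)))]
            arr = cons_arr[te]
            L = int(_sample_lengths(rng, rp, 1)[0])
            antisense = rng.random() < a_share
            if antisense or not active:
                strand = "-" if antisense else "+"
                # 1U preference against the appropriate strand
                target = _A if strand == "-" else _T
                cand = np.flatnonzero(arr == target)
                if rng.random() < rp.p_1U and len(cand):
                    f = int(cand[rng.integers(0, len(cand))])
                else:
                    f = int(rng.integers(0, len(arr)))
                start, end = (f, min(f + L, len(arr))) if strand == "+" else (
                    max(f - L + 1, 0), f + 1
                )
            else:
                # zygotic sense read: offset-10 partner of an antisense 5' end
                cand = np.flatnonzero(arr == _A)
                tf = int(cand[rng.integers(0, len(cand))]) if len(cand) else int(
                    rng.integers(0, len(arr))
                )
                f = tf - ppp.offset + 1
                f = min(max(f, 0), len(arr) - 1)
                strand = "+"
                start, end = f, min(f + L, len(arr))
            sarr = arr[start:end]
            seq = _to_str(_rc_arr(sarr) if strand == "-" else sarr)
            rows.append((te, start, end, strand, seq))
        mol = pd.DataFrame(rows, columns=["chrom", "start", "end", "strand", "seq"])
        grouped = mol.groupby(["chrom", "start", "end", "strand", "seq"], sort=False).size()
        df = grouped.reset_index(name="count")
        df.insert(0, "read_id", [f"{stage}_te{i}" for i in range(len(df))])
        df["copies"] = 1
        df = df[["read_id", "seq", "chrom", "start", "end", "strand", "count", "copies"]]
        out[stage] = StageLibrary(df, library_id=f"{stage}_te", stage=stage)
    return out


def simulate_mz_tables(
    n_features: int = 200, seed: int = 0, coupling: float = 0.8, noise_sd: float = 0.8,
    te_fraction: float = 0.7,
) -> pd.DataFrame:
    """Feature-level maternal/zygotic tables with a planted positive coupling
    between mRNA up-regulation and sense piRNA gain (cleavage of activated
    transcripts).  Returns columns fc_mrna, fc_pirna_sense, te_related."""
    rng = np.random.default_rng(seed)
    log_fc_mrna = rng.normal(1.0, 1.0, n_features)
    log_fc_pirna = coupling * log_fc_mrna + rng.normal(0.0, noise_sd, n_features)
    return pd.DataFrame(
        {
            "feature": [f"f{i}" for i in range(n_features)],
            "fc_mrna": np.exp2(log_fc_mrna),
            "fc_pirna_sense": np.exp2(log_fc_pirna),
            "te_related": rng.random(n_features) < te_fraction,
        }
    ).set_index("feature")


# ---------------------------------------------------------------------------
# truth-vs-pipeline metrics

def interval_precision_recall(
    truth_intervals, called_intervals
) -> tuple[float, float]:
    """Base-level precision and recall of called intervals against planted
    ones.  Intervals are (chrom, start, end) triples or objects with those
    attributes."""

    def _norm(ivs):
        out = {}
        for iv in ivs:
            c, s, e = (
                (iv.chrom, iv.start, iv.end) if hasattr(iv, "chrom") else iv[:3]
            )
            out.setdefault(c, []).append((s, e))
        return out

    def _len(by_chrom):
        return sum(e - s for ivs in by_chrom.values() for s, e in ivs)

    t, c = _norm(truth_intervals), _norm(called_intervals)
    inter = 0
    for chrom in set(t) & set(c):
        for s1, e1 in t[chrom]:
            for s2, e2 in c[chrom]:
                inter += max(0, min(e1, e2) - max(s1, s2))
    called_len, truth_len = _len(c), _len(t)
    precision = inter / called_len if called_len else 0.0
    recall = inter / truth_len if truth_len else 0.0
    return precision, recall


def dominant_strand_accuracy(truth_clusters, called_clusters) -> float:
    """Share of called clusters whose dominant strand matches the planted
    cluster they overlap most."""
    if not called_clusters:
        return 0.0
    hits = 0
    for c in called_clusters:
        best, best_ov = None, 0
        for t in truth_clusters:
            if t.chrom != c.chrom:
                continue
            ov = max(0, min(t.end, c.end) - max(t.start, c.start))
            if ov > best_ov:
                best, best_ov = t, ov
        if best is not None and best.dominant_strand == c.dominant_strand:
            hits += 1
    return hits / len(called_clusters)


def truth_metrics(sim: Simulation, called_clusters, stage_signatures: pd.DataFrame) -> dict:
    """Recovery report: cluster interval precision/recall, dominant-strand
    accuracy and the per-stage argmax of the normalized overlap signature."""
    precision, recall = interval_precision_recall(sim.truth.clusters, called_clusters)
    argmax = {
        stage: int(stage_signatures.loc[stage].idxmax()) for stage in stage_signatures.index
    }
    return {
        "cluster_precision": precision,
        "cluster_recall": recall,
        "dominant_strand_accuracy": dominant_strand_accuracy(
            sim.truth.clusters, called_clusters
        ),
        "signature_argmax": argmax,
    }


# ---------------------------------------------------------------------------
# writers (all plain text)

def write_outputs(sim: Simulation, libraries: dict[str, StageLibrary], outdir: str | Path) -> None:
    """FASTA, chrom.sizes, RepeatMasker-style .out, GFF3, per-stage BED,
    truth manifest (JSON) and a params echo (YAML)."""
    from . import io_reads

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "genome.fa", "w") as fh:
        for chrom, arr in sim.genome.items():
            fh.write(f">{chrom}\n")
            s = _to_str(arr)
            for i in range(0, len(s), 60):
                fh.write(s[i:i + 60] + "\n")
    with open(outdir / "genome.chrom.sizes", "w") as fh:
        for chrom, size in sim.chrom_sizes.items():
            fh.write(f"{chrom}\t{size}\n")
    with open(outdir / "te_consensus.fa", "w") as fh:
        for te, s in sim.consensus.items():
            fh.write(f">{te}\n{s}\n")
    with open(outdir / "repeats.out", "w") as fh:
        fh.write("   SW  perc perc perc  query     position in query    matching repeat\n")
        fh.write("score  div. del. ins.  sequence  begin end   (left)   repeat class/family  begin end (left) ID\n")
        fh.write("\n")
        for i, ins in enumerate(sim.truth.insertions, 1):
            strand = "C" if ins.strand == "-" else "+"
            fh.write(
                f"  255  1.0  0.0  0.0  {ins.chrom}  {ins.start + 1} {ins.end} (0) "
                f"{strand} {ins.te_id} Unknown 1 {ins.end - ins.start} (0) {i}\n"
            )
    with open(outdir / "annotations.gff3", "w") as fh:
        fh.write("##gff-version 3\n")
        for row in sim.gff.df.itertuples(index=False):
            attrs = f"ID={row.name}" + (f";Parent={row.parent}" if row.parent else "")
            fh.write(
                f"{row.chrom}\tpirnascape_sim\t{row.kind}\t{row.start + 1}\t{row.end}"
                f"\t.\t{row.strand}\t.\t{attrs}\n"
            )
    for stage, lib in libraries.items():
        io_reads.write_bed(lib, outdir / f"reads_{stage}.bed")
    manifest = {
        "clusters": [asdict(c) for c in sim.truth.clusters],
        "insertions": [asdict(i) for i in sim.truth.insertions],
        "genes": sim.truth.genes.to_dict(orient="records"),
        "mirna_loci": sim.truth.mirna_loci.to_dict(orient="records"),
    }
    with open(outdir / "truth.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    import yaml

    with open(outdir / "params.yaml", "w") as fh:
        yaml.safe_dump(asdict(sim.params), fh, sort_keys=False)
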