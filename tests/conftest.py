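import numpy as np
import pandas as pd
import pytest

import pirnascape as pk


def make_reads(rows, library_id="test", stage=""):
    """Build a StageLibrary from (chrom, start, end, strand[, count, copies, seq]) tuples."""
    recs = []
    for i, row in enumerate(rows):
        chrom, start, end, strand = row[:4]
        count = row[4] if len(row) > 4 else 1
        copies = row[5] if len(row) > 5 else 1
        seq = row[6] if len(row) > 6 else "A" * (end - start)
        recs.append(
            pk.AlignedRead(
                read_id=f"r{i}", seq=seq, chrom=chrom, start=start, end=end,
                strand=strand, count=count, copies=copies,
            )
        )
    return pk.StageLibrary(recs, library_id=library_id, stage=stage)


def random_read_frame(rng, n, chrom_len=2000, max_offset_span=40, n_chroms=2):
    """Random small read table with clustered 5' ends so overlaps occur."""
    chroms = [f"c{i}" for i in range(n_chroms)]
    rows = []
    for i in range(n):
        chrom = chroms[rng.integers(0, n_chroms)]
        strand = "+" if rng.random() < 0.5 else "-"
        fp = int(rng.integers(50, 50 + max_offset_span))
        L = int(rng.integers(25, 36))
        if strand == "+":
            start, end = fp, fp + L
        else:
            start, end = fp - L + 1, fp + 1
        rows.append(
            (f"r{i}", "A" * L, chrom, start, end, strand, int(rng.integers(1, 6)), 1)
        )
    return pd.DataFrame(
        rows, columns=["read_id", "seq", "chrom", "start", "end", "strand", "count", "copies"]
    )


@pytest.fixture(scope="session")
def sim42():
    """Full default simulation (seed 42): genome, libraries, TE alignments."""
    params = pk.SimulationParams(seed=42)
    sim = pk.simulate_genome(params)
    libraries = pk.simulate_libraries(sim)
    te_alignments = pk.simulate_te_alignments(sim)
    return sim, libraries, te_alignments


@pytest.fixture(scope="session")
def sim42_summary(sim42):
    sim, libraries, te_alignments = sim42
    return pk.analyze(sim, libraries, te_alignments)


@pytest.fixture(scope="session")
def small_sim():
    """Scaled-down simulation for fast module-level checks."""
    params = pk.SimulationParams(seed=7)
    params.genome.n_chroms = 2
    params.genome.chrom_length = 400_000
    params.clusters.n = 3
    params.clusters.min_length = 40_000
    params.clusters.max_length = 60_000
    params.reads.depth = 15_000
    sim = pk.simulate_genome(params)
    libraries = pk.simulate_libraries(sim)
    return sim, libraries
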