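import numpy as np
import pandas as pd
import pytest

import pirnascape as pk


def tiny_params(seed=3, depth=4000):
    p = pk.SimulationParams(seed=seed)
    p.genome.n_chroms = 2
    p.genome.chrom_length = 300_000
    p.clusters.n = 2
    p.clusters.min_length = 40_000
    p.clusters.max_length = 50_000
    p.reads.depth = depth
    return p


class TestGenome:
    def test_requested_number_of_clusters_planted(self):
        sim = pk.simulate_genome(tiny_params())
        assert len(sim.truth.clusters) == 2

    def test_identical_seed_reproduces_genome(self):
        a = pk.simulate_genome(tiny_params())
        b = pk.simulate_genome(tiny_params())
        for chrom in a.genome:
            assert np.array_equal(a.genome[chrom], b.genome[chrom])
        assert [c.__dict__ for c in a.truth.clusters] == [c.__dict__ for c in b.truth.clusters]

    def test_te_density_higher_inside_clusters(self):
        sim = pk.simulate_genome(tiny_params())
        cluster_bed = pd.DataFrame(
            [(c.chrom, c.start, c.end) for c in sim.truth.clusters],
            columns=["chrom", "start", "end"],
        )
        inside = pk.te_fraction_per_window(sim.te_table, pk.tile_windows(cluster_bed)).mean()
        genome_wide = pk.te_fraction_per_window(
            sim.te_table, pk.tile_windows(sim.chrom_sizes)
        ).mean()
        assert inside > genome_wide

    def test_insertions_are_antisense_to_dominant_strand(self):
        sim = pk.simulate_genome(tiny_params())
        by_chrom = {}
        for c in sim.truth.clusters:
            by_chrom.setdefault(c.chrom, []).append(c)
        for ins in sim.truth.insertions:
            host = next(
                c for c in by_chrom[ins.chrom] if c.start <= ins.start and ins.end <= c.end
            )
            assert ins.strand != host.dominant_strand

    def test_probability_parameters_validated(self):
        p = tiny_params()
        p.reads.p_1U = 1.4
        with pytest.raises(ValueError):
            pk.SimulationParams(
                seed=1, genome=p.genome, clusters=p.clusters, te=p.te,
                reads=p.reads, pingpong=p.pingpong,
            )

    def test_offset_is_pinned_to_ten(self):
        p = tiny_params()
        p.pingpong.offset = 9
        with pytest.raises(ValueError):
            pk.SimulationParams(seed=1, pingpong=p.pingpong)


@pytest.fixture(scope="module")
def tiny():
    params = tiny_params()
    sim = pk.simulate_genome(params)
    libraries = pk.simulate_libraries(sim)
    return sim, libraries


class TestLibraries:
    def test_identical_seed_reproduces_libraries(self):
        a = pk.simulate_libraries(pk.simulate_genome(tiny_params(seed=9, depth=1500)))
        b = pk.simulate_libraries(pk.simulate_genome(tiny_params(seed=9, depth=1500)))
        for stage in a:
            assert a[stage].df.equals(b[stage].df)

    def test_inactive_stage_has_no_secondary_reads(self, tiny):
        sim, _ = tiny
        for stage in sim.params.stages:
            if stage not in sim.params.pingpong.active_stages:
                labels = sim.truth.reads[stage]["label"]
                assert (labels != "secondary").all()

    def test_every_secondary_overlaps_its_template_by_ten(self, tiny):
        sim, _ = tiny
        for stage in sim.params.pingpong.active_stages:
            tr = sim.truth.reads[stage]
            sec = tr[tr["label"] == "secondary"]
            assert len(sec) > 0
            fp = np.where(sec["strand"] == "+", sec["start"], sec["end"] - 1)
            # 5'-5' offset = |five_prime(secondary) - five_prime(template)| + 1
            assert (np.abs(fp - sec["template_five_prime"].to_numpy()) + 1 == 10).all()

    def test_emergent_tenth_position_adenine(self, tiny):
        sim, _ = tiny
        stage = sim.params.pingpong.active_stages[0]
        tr = sim.truth.reads[stage]
        sec = tr[tr["label"] == "secondary"]
        ten_a = np.mean([s[9] == "A" for s in sec["seq"]])
        assert ten_a >= sim.params.reads.p_1U - 0.05

    def test_read_sequences_match_genome(self, tiny):
        sim, libraries = tiny
        lib = next(iter(libraries.values()))
        sub = lib.df.head(200)
        for row in sub.itertuples(index=False):
            assert row.seq == sim.seq(row.chrom, row.start, row.end, row.strand)

    def test_length_distribution_peaks_at_28(self, tiny):
        sim, _ = tiny
        stage = sim.params.stages[0]
        tr = sim.truth.reads[stage]
        pirna = tr[tr["label"].isin(["primary", "secondary"])]
        lengths = (pirna["end"] - pirna["start"]).value_counts()
        assert lengths.idxmax() == 28

    def test_both_unique_and_multi_mapping_reads_exist(self, tiny):
        _, libraries = tiny
        copies = pd.concat([l.df["copies"] for l in libraries.values()])
        assert (copies == 1).any() and (copies > 1).any()

    def test_multimapper_rows_share_sequence_and_count(self, tiny):
        _, libraries = tiny
        df = next(iter(libraries.values())).df
        multi = df[df["copies"] > 1]
        if len(multi):
            g = multi.groupby("seq")
            assert (g["count"].nunique() == 1).all()
            assert (g.size() == g["copies"].first()).all()

    def test_degradation_only_genome_yields_no_clusters(self):
        # all piRNA mass switched off: background alone must not call clusters
        for seed in range(5):
            p = tiny_params(seed=100 + seed, depth=3000)
            p.reads.degradation_fraction = 1.0
            p.reads.mirna_fraction = 0.0
            sim = pk.simulate_genome(p)
            libs = pk.simulate_libraries(sim)
            pooled = pk.StageLibrary(
                pd.concat([l.df for l in libs.values()], ignore_index=True)
            )
            uniq, _ = pk.partition_by_uniqueness(pk.filter_by_size(pooled, 25, 35))
            total = float(uniq.df["count"].sum())
            windows = pk.window_counts(uniq, sim.chrom_sizes)
            called = pk.call_clusters(windows, total, min_reads=1000)
            assert called == []


class TestTruthMetrics:
    def test_perfect_recovery_of_identical_intervals(self):
        ivs = [("c", 0, 100), ("c", 500, 800)]
        from pirnascape.simulate import interval_precision_recall

        p, r = interval_precision_recall(ivs, ivs)
        assert p == 1.0 and r == 1.0

    def test_half_overlap_scores_half(self):
        from pirnascape.simulate import interval_precision_recall

        p, r = interval_precision_recall([("c", 0, 100)], [("c", 50, 150)])
        assert p == pytest.approx(0.5) and r == pytest.approx(0.5)

    def test_uniform_reads_recover_roughly_cluster_fraction_precision(self):
        # shuffled (uniform) positions: windows pass everywhere, so called
        # spans cover most of the genome and precision ~ cluster share
        p = tiny_params(seed=5, depth=3000)
        sim = pk.simulate_genome(p)
        rng = np.random.default_rng(0)
        n = 5000
        rows = {
            "read_id": [f"r{i}" for i in range(n)],
            "seq": ["A" * 28] * n,
            "chrom": rng.choice(list(sim.chrom_sizes), n),
            "strand": np.where(rng.random(n) < 0.5, "+", "-"),
            "count": np.ones(n, dtype=np.int64),
            "copies": np.ones(n, dtype=np.int64),
        }
        start = np.array([rng.integers(0, sim.chrom_sizes[c] - 28) for c in rows["chrom"]])
        df = pd.DataFrame({**rows, "start": start, "end": start + 28})
        lib = pk.StageLibrary(df)
        windows = pk.window_counts(lib, sim.chrom_sizes)
        called = pk.call_clusters(windows, float(n), min_reads=1, min_fraction=0.0)
        from pirnascape.simulate import interval_precision_recall

        precision, recall = interval_precision_recall(sim.truth.clusters, called)
        genome_len = sum(sim.chrom_sizes.values())
        cluster_share = sum(c.end - c.start for c in sim.truth.clusters) / genome_len
        assert recall > 0.95  # everything is called, so truth is covered
        assert precision == pytest.approx(cluster_share, rel=0.1)
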