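import numpy as np
import pytest

import pirnascape as pk
from pirnascape.clusters import GenomicWindow

from conftest import make_reads
from oracles import brute_force_clusters


def _windows_from_counts(counts, window=10_000, chrom="c"):
    """Helper: windows tiled from 0 with the given unique counts, all '+'."""
    return [
        GenomicWindow(chrom, i * window, (i + 1) * window, c, c, 0.0)
        for i, c in enumerate(counts)
    ]


class TestWindowCounts:
    def test_tiling_truncates_last_window(self):
        lib = make_reads([("c", 0, 25, "+")])
        w = pk.window_counts(lib, {"c": 25_000}, 10_000, 10_000)
        assert [(x.start, x.end) for x in w] == [(0, 10_000), (10_000, 20_000), (20_000, 25_000)]

    def test_five_prime_rule_at_boundary(self):
        lib = make_reads([("c", 9_999, 10_027, "+")])
        w = pk.window_counts(lib, {"c": 25_000}, 10_000, 10_000)
        assert w[0].unique_pirna_count == 1 and w[1].unique_pirna_count == 0

    def test_counts_are_collapse_weighted(self):
        lib = make_reads([("c", 10, 38, "+", 2), ("c", 20, 48, "+", 3), ("c", 30, 58, "+", 5)])
        w = pk.window_counts(lib, {"c": 10_000}, 10_000, 10_000)
        assert w[0].unique_pirna_count == 10

    def test_unknown_chromosome_is_named(self):
        lib = make_reads([("weird", 0, 28, "+")])
        with pytest.raises(ValueError, match="weird"):
            pk.window_counts(lib, {"c": 10_000})


class TestCallClusters:
    def test_windows_within_merge_distance_fuse(self):
        w = _windows_from_counts([2000, 0, 2000])
        called = pk.call_clusters(w, 4000, min_reads=1000, merge_distance=20_000)
        assert len(called) == 1
        assert (called[0].start, called[0].end) == (0, 30_000)

    def test_windows_beyond_merge_distance_stay_separate(self):
        w = _windows_from_counts([2000, 0, 0, 0, 2000])
        called = pk.call_clusters(w, 4000, min_reads=1000, merge_distance=20_000)
        assert len(called) == 2

    def test_window_below_min_reads_is_not_a_seed(self):
        called = pk.call_clusters(_windows_from_counts([999]), 999, min_reads=1000)
        assert called == []

    def test_min_fraction_threshold_applies(self):
        # 2000 reads but only 0.002% of the pooled total
        called = pk.call_clusters(_windows_from_counts([2000]), 1e8, min_fraction=1e-4)
        assert called == []

    def test_invalid_min_fraction_rejected(self):
        with pytest.raises(ValueError):
            pk.call_clusters(_windows_from_counts([2000]), 2000, min_fraction=1.5)

    def test_every_cluster_holds_at_least_min_reads(self, small_sim):
        sim, libraries = small_sim
        pooled = pk.StageLibrary(
            __import__("pandas").concat([l.df for l in libraries.values()], ignore_index=True)
        )
        uniq, _ = pk.partition_by_uniqueness(pk.filter_by_size(pooled, 25, 35))
        total = float(uniq.df["count"].sum())
        windows = pk.window_counts(uniq, sim.chrom_sizes)
        called = pk.call_clusters(windows, total, min_reads=300, lib=uniq)
        assert called and all(c.unique_pirna_count >= 300 for c in called)

    def test_merging_is_idempotent(self):
        w = _windows_from_counts([2000, 0, 2000, 0, 0, 0, 3000])
        once = pk.call_clusters(w, 7000, min_reads=1000)
        rederived = [
            GenomicWindow(c.chrom, c.start, c.end, c.unique_pirna_count, c.plus_count, c.minus_count)
            for c in once
        ]
        twice = pk.call_clusters(rederived, 7000, min_reads=1000)
        assert [(c.start, c.end) for c in once] == [(c.start, c.end) for c in twice]

    def test_matches_bruteforce_on_random_small_chromosomes(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            sizes = {"cA": 100_000, "cB": 60_000}
            rows = []
            for i in range(400):
                chrom = "cA" if rng.random() < 0.6 else "cB"
                fp = int(rng.integers(0, sizes[chrom] - 40))
                rows.append((chrom, fp, fp + 28, "+", int(rng.integers(1, 30))))
            lib = make_reads(rows)
            total = float(lib.df["count"].sum())
            windows = pk.window_counts(lib, sizes, 10_000, 5_000)
            called = pk.call_clusters(windows, total, min_reads=50, min_fraction=1e-4,
                                      merge_distance=20_000)
            expected = brute_force_clusters(
                lib.df, sizes, 10_000, 5_000, total, 50, 1e-4, 20_000
            )
            assert [(c.chrom, c.start, c.end) for c in called] == expected


class TestStrandDominance:
    def test_majority_strand_wins(self):
        c = pk.PiRNACluster("c", 0, 10_000, plus_count=800, minus_count=200)
        assert pk.assign_strand_dominance(c).dominant_strand == "+"
        assert not c.tie

    def test_tie_breaks_to_plus_and_flags(self):
        c = pk.PiRNACluster("c", 0, 10_000, plus_count=500, minus_count=500)
        pk.assign_strand_dominance(c)
        assert c.dominant_strand == "+" and c.tie

    def test_zero_read_cluster_rejected(self):
        c = pk.PiRNACluster("c", 0, 10_000, plus_count=0, minus_count=0)
        with pytest.raises(ValueError):
            pk.assign_strand_dominance(c)


class TestCumulativeFraction:
    def test_single_cluster_reaches_one(self):
        c = pk.PiRNACluster("c", 0, 10_000, 100, 0, rank=1)
        curve = pk.cumulative_fraction([c], 100)
        assert curve["fraction"].iloc[-1] == pytest.approx(1.0)

    def test_hand_computed_curve(self):
        cs = [
            pk.PiRNACluster("c", i * 10_000, (i + 1) * 10_000, n, 0, rank=i + 1)
            for i, n in enumerate([40, 30, 20, 10])
        ]
        curve = pk.cumulative_fraction(cs, 100)
        assert list(curve["fraction"]) == pytest.approx([0.4, 0.7, 0.9, 1.0])

    def test_empty_cluster_list(self):
        assert len(pk.cumulative_fraction([], 100)) == 0


class TestMultimapperRescue:
    def test_any_in_cluster_position_counts_as_rescued(self):
        # same collapsed read (same seq) at two positions, one inside a cluster
        seq = "A" * 28
        lib = make_reads(
            [("c", 100, 128, "+", 2, 2, seq), ("c", 90_000, 90_028, "+", 2, 2, seq)]
        )
        cluster = pk.PiRNACluster("c", 0, 10_000, 10, 0)
        assert pk.multimapper_rescue_fraction(lib, [cluster]) == 1.0

    def test_no_clusters_gives_zero(self):
        lib = make_reads([("c", 100, 128, "+", 2, 2)])
        assert pk.multimapper_rescue_fraction(lib, []) == 0.0

    def test_simulated_multimappers_land_in_clusters(self, small_sim):
        sim, libraries = small_sim
        import pandas as pd

        pooled = pk.StageLibrary(
            pd.concat([l.df for l in libraries.values()], ignore_index=True)
        )
        _, multi = pk.partition_by_uniqueness(pk.filter_by_size(pooled, 25, 35))
        truth = [pk.PiRNACluster(c.chrom, c.start, c.end, 1, 0) for c in sim.truth.clusters]
        # all planted repeats are inside clusters, so rescue should be ~total
        assert pk.multimapper_rescue_fraction(multi, truth) >= 0.95
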