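import numpy as np
import pandas as pd
import pytest

import pirnascape as pk
from pirnascape.pingpong import compute_signature, paired_mask

from conftest import make_reads, random_read_frame
from oracles import brute_force_pairs


class TestOverlapPairs:
    def test_ping_pong_configuration_gives_offset_ten(self):
        # plus 5'=100; minus spanning [82,110) has 5'=109 -> 109-100+1 = 10
        lib = make_reads([("c", 100, 128, "+"), ("c", 82, 110, "-")])
        pairs = pk.find_overlap_pairs(lib)
        assert len(pairs) == 1 and pairs[0].offset == 10

    def test_coincident_five_primes_are_offset_one(self):
        lib = make_reads([("c", 100, 128, "+"), ("c", 73, 101, "-")])  # minus 5'=100
        pairs = pk.find_overlap_pairs(lib)
        assert len(pairs) == 1 and pairs[0].offset == 1

    def test_offset_zero_is_excluded(self):
        lib = make_reads([("c", 100, 128, "+"), ("c", 72, 100, "-")])  # minus 5'=99
        assert pk.find_overlap_pairs(lib) == []

    def test_pair_weight_is_count_product(self):
        lib = make_reads([("c", 100, 128, "+", 3), ("c", 82, 110, "-", 4)])
        assert pk.find_overlap_pairs(lib)[0].weight == 12

    def test_invalid_max_offset(self):
        with pytest.raises(ValueError):
            pk.find_overlap_pairs(make_reads([("c", 0, 28, "+")]), max_offset=0)

    def test_three_prime_convention_coincident_ends(self):
        # plus 3' = 127; minus 3' = start = 127 -> offset 1
        lib = make_reads([("c", 100, 128, "+"), ("c", 127, 155, "-")])
        pairs = pk.find_overlap_pairs(lib, convention="three_prime")
        assert len(pairs) == 1 and pairs[0].offset == 1


class TestSignatures:
    def test_single_pair_concentrates_everything_at_its_offset(self):
        lib = make_reads([("c", 100, 128, "+", 5), ("c", 82, 110, "-", 2)])
        sig = compute_signature(lib)
        assert sig.normalized[9] == pytest.approx(1.0)
        assert sig.pct_reads[9] == pytest.approx(100.0)
        assert sig.raw_pairs[9] == pytest.approx(10.0)

    def test_no_pairs_is_flagged_zero_vector(self):
        lib = make_reads([("c", 100, 128, "+")])
        sig = compute_signature(lib)
        assert sig.no_pairs and not sig.normalized.any()

    def test_hand_evaluated_scaled_signature(self):
        # one sense read (count 1) with partner counts {offset 9: 1, offset 10: 3}
        lib = make_reads(
            [
                ("c", 100, 128, "+", 1),
                ("c", 81, 109, "-", 1),   # 5'=108 -> offset 9
                ("c", 82, 110, "-", 3),   # 5'=109 -> offset 10
            ]
        )
        sig = compute_signature(lib)
        # plus read splits 1 as (0.25, 0.75); each minus read contributes its
        # full count at its single offset: scaled = (1.25, 3.75) at (9, 10)
        assert sig.scaled[8] == pytest.approx(1.25)
        assert sig.scaled[9] == pytest.approx(3.75)
        assert sig.normalized[8] == pytest.approx(0.25)
        assert sig.normalized[9] == pytest.approx(0.75)

    def test_hand_enumerated_read_percentages(self):
        # s1 partners at {10,11}; s2 at {9,10}; a1 at {9,10}; a2 at {10,11}
        lib = make_reads(
            [
                ("c", 100, 128, "+"),
                ("c", 101, 129, "+"),
                ("c", 82, 110, "-"),
                ("c", 83, 111, "-"),
            ]
        )
        sig = compute_signature(lib)
        assert sig.pct_reads[9] == pytest.approx(100.0)
        assert sig.pct_reads[8] == pytest.approx(50.0)
        assert sig.pct_reads[10] == pytest.approx(50.0)

    def test_explicit_pair_route_agrees_with_indexed_route(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            df = random_read_frame(rng, 60)
            pairs = pk.find_overlap_pairs(df)
            scaled, normalized = pk.scaled_signature(pairs, df)
            pct = pk.offset_percentages(pairs, df)
            sig = compute_signature(df)
            assert np.allclose(scaled, sig.scaled)
            assert np.allclose(normalized, sig.normalized)
            assert np.allclose(pct, sig.pct_reads)

    def test_normalized_sums_to_one_when_pairs_exist(self):
        rng = np.random.default_rng(5)
        df = random_read_frame(rng, 100)
        sig = compute_signature(df)
        if not sig.no_pairs:
            assert sig.normalized.sum() == pytest.approx(1.0, abs=1e-9)

    def test_normalized_invariant_to_uniform_count_scaling(self):
        rng = np.random.default_rng(8)
        df = random_read_frame(rng, 80)
        sig1 = compute_signature(df)
        df2 = df.copy()
        df2["count"] = df2["count"] * 7
        sig2 = compute_signature(df2)
        assert np.allclose(sig1.normalized, sig2.normalized)

    def test_strand_swap_and_coordinate_reversal_symmetry(self):
        rng = np.random.default_rng(13)
        df = random_read_frame(rng, 80)
        L = 10_000
        mirrored = df.copy()
        mirrored["strand"] = np.where(df["strand"] == "+", "-", "+")
        mirrored["start"] = L - df["end"]
        mirrored["end"] = L - df["start"]
        a = compute_signature(df)
        b = compute_signature(mirrored)
        assert np.allclose(a.raw_pairs, b.raw_pairs)
        assert np.allclose(a.scaled, b.scaled)


class TestPartition:
    def test_offset_ten_pair_plus_solitary_read(self):
        lib = make_reads(
            [("c", 100, 128, "+"), ("c", 82, 110, "-"), ("c", 500, 528, "+")]
        )
        paired, unpaired = pk.partition_by_pingpong(lib)
        assert len(paired) == 2 and len(unpaired) == 1

    def test_no_offset_ten_pairs_leaves_paired_empty(self):
        lib = make_reads([("c", 100, 128, "+"), ("c", 81, 109, "-")])  # offset 9
        paired, _ = pk.partition_by_pingpong(lib)
        assert len(paired) == 0

    def test_simulated_secondary_reads_are_paired(self, small_sim):
        sim, libraries = small_sim
        active = sim.params.pingpong.active_stages[0]
        truth = sim.truth.reads[active]
        mask = paired_mask(
            truth.assign(count=1, copies=1)[
                ["chrom", "start", "end", "strand", "count", "copies"]
            ]
        )
        sec = truth["label"].to_numpy() == "secondary"
        assert mask[sec].mean() >= 0.95


class TestLocusFraction:
    def test_sense_reads_without_antisense_partner(self):
        df = make_reads([("c", 100, 128, "+"), ("c", 200, 228, "+")]).df
        assert pk.locus_pingpong_fraction(df, "+") == 0.0

    def test_single_fully_paired_sense_read(self):
        df = make_reads([("c", 100, 128, "+"), ("c", 82, 110, "-")]).df
        assert pk.locus_pingpong_fraction(df, "+") == 1.0

    def test_no_sense_reads_is_undefined(self):
        df = make_reads([("c", 82, 110, "-")]).df
        assert pk.locus_pingpong_fraction(df, "+") is None


class TestStagewise:
    def test_identical_libraries_give_identical_rows(self):
        lib = make_reads([("c", 100, 128, "+"), ("c", 82, 110, "-")], stage="s1")
        lib2 = pk.StageLibrary(lib.df.copy(), stage="s2")
        out = pk.stagewise_signature({"s1": lib, "s2": lib2})
        assert np.allclose(out.loc["s1"], out.loc["s2"])

    def test_participation_rises_with_ping_pong_activation(self, small_sim):
        sim, libraries = small_sim
        truth_clusters = sim.truth.clusters
        per_stage = {}
        for stage, lib in libraries.items():
            uniq, _ = pk.partition_by_uniqueness(pk.filter_by_size(lib, 25, 35))
            reads = pk.pingpong.restrict_to_loci(uniq, truth_clusters)
            per_stage[stage] = pk.participation_fraction(reads)
        active = set(sim.params.pingpong.active_stages)
        for on in active:
            for off in set(sim.params.stages) - active:
                assert per_stage[on] > per_stage[off]
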