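"""End profiles, normalization, smoothing, replicate bands, readthrough and
oligo(A) selection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from polterm.read_profiles import (ProfileTrack, ReadRecord, ReplicateBundle,
                                   aggregate_replicates,
                                   difference_and_cumulative, end_profile,
                                   normalize_unit, read_length_stats,
                                   readthrough_fraction, readthrough_test,
                                   select_polyA, smooth_blackman,
                                   terminal_a_run)


def reads_df(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name",
                                       "count", "strand", "tail"])


class TestEndProfile:
    def test_plus_strand_conventions(self):
        df = reads_df([("ref", 10, 35, "r1", 1, "+", "")])
        five = end_profile(df, "five_prime", 50)
        three = end_profile(df, "three_prime", 50)
        assert five.values[10] == 1 and five.values.sum() == 1
        assert three.values[34] == 1 and three.values.sum() == 1

    def test_minus_strand_swaps_ends(self):
        df = reads_df([("ref", 10, 35, "r1", 1, "-", "")])
        five = end_profile(df, "five_prime", 50)
        three = end_profile(df, "three_prime", 50)
        assert five.values[34] == 1
        assert three.values[10] == 1

    def test_multiplicity_weighting(self):
        df = reads_df([("ref", 10, 35, "r1", 2, "+", ""),
                       ("ref", 20, 35, "r2", 3, "+", "")])
        three = end_profile(df, "three_prime", 50)
        assert three.values[34] == 5

    def test_coverage_mode(self):
        df = reads_df([("ref", 2, 5, "r1", 1, "+", "")])
        cov = end_profile(df, "coverage", 8)
        assert cov.values.tolist() == [0, 0, 1, 1, 1, 0, 0, 0]

    def test_total_equals_total_multiplicity(self, synthetic_replicates,
                                             element_map):
        reps, _ = synthetic_replicates
        df = reps[0]
        for mode in ("five_prime", "three_prime"):
            t = end_profile(df, mode, element_map.ref_length)
            assert t.values.sum() == df["count"].sum()

    def test_off_reference_read_named_in_error(self):
        df = reads_df([("ref", 10, 80, "bad_read", 1, "+", "")])
        with pytest.raises(ValueError, match="bad_read"):
            end_profile(df, "three_prime", 50)


class TestNormalizeUnit:
    def test_arithmetic(self):
        t = ProfileTrack(np.array([2.0, 2.0, 0.0, 0.0]))
        n = normalize_unit(t)
        assert np.allclose(n.values, [0.5 + 1e-7, 0.5 + 1e-7, 1e-7, 1e-7])

    def test_unit_sum_invariant(self):
        t = ProfileTrack(np.arange(100, dtype=float), unit_start=10,
                         unit_length=80)
        n = normalize_unit(t)
        assert n.unit_values().sum() == pytest.approx(1 + 80 * 1e-7)

    def test_double_normalization_rejected(self):
        t = normalize_unit(ProfileTrack(np.array([1.0, 1.0])))
        with pytest.raises(ValueError):
            normalize_unit(t)

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            normalize_unit(ProfileTrack(np.zeros(10)))

    def test_single_bin(self):
        n = normalize_unit(ProfileTrack(np.array([0.0, 3.0, 0.0])))
        assert n.values[1] == pytest.approx(1 + 1e-7)


class TestSmoothBlackman:
    def test_constant_track_unchanged(self):
        t = ProfileTrack(np.full(50, 3.7))
        s = smooth_blackman(t, 10)
        assert np.allclose(s.values, 3.7)

    def test_impulse_reproduces_kernel(self):
        v = np.zeros(51)
        v[25] = 1.0
        s = smooth_blackman(ProfileTrack(v), 10)
        kernel = np.blackman(10)
        kernel /= kernel.sum()
        window = s.values[s.values > 1e-12]
        assert np.allclose(np.sort(window), np.sort(kernel[kernel > 1e-12]))

    def test_signal_conserved_away_from_edges(self):
        rng = np.random.default_rng(0)
        v = np.zeros(200)
        v[50:150] = rng.random(100)
        s = smooth_blackman(ProfileTrack(v), 10)
        assert s.values.sum() == pytest.approx(v.sum(), abs=1e-9)

    def test_window_validation(self):
        with pytest.raises(ValueError):
            smooth_blackman(ProfileTrack(np.ones(5)), 10)
        with pytest.raises(ValueError):
            smooth_blackman(ProfileTrack(np.ones(5)), 1)


class TestAggregateReplicates:
    def test_identical_replicates(self):
        t = ProfileTrack(np.array([1.0, 2.0]))
        s = aggregate_replicates([t, t, t])
        for col in ("median", "q25", "q75", "min", "max"):
            assert np.allclose(s[col], [1.0, 2.0])

    def test_median_of_three(self):
        tracks = [ProfileTrack(np.array([float(v)])) for v in (1, 2, 3)]
        assert aggregate_replicates(tracks)["median"][0] == 2.0

    def test_linear_interpolation_quartiles(self):
        tracks = [ProfileTrack(np.array([float(v)])) for v in (1, 2, 3, 4)]
        s = aggregate_replicates(tracks)
        assert s["q25"][0] == pytest.approx(1.75)
        assert s["q75"][0] == pytest.approx(3.25)

    def test_band_ordering_invariant(self):
        rng = np.random.default_rng(1)
        tracks = [ProfileTrack(rng.random(30)) for _ in range(5)]
        s = aggregate_replicates(tracks)
        assert (s["min"] <= s["q25"]).all()
        assert (s["q25"] <= s["median"]).all()
        assert (s["median"] <= s["q75"]).all()
        assert (s["q75"] <= s["max"]).all()

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError):
            ReplicateBundle([ProfileTrack(np.ones(3)),
                             ProfileTrack(np.ones(4))])


class TestDifferenceAndCumulative:
    def make_summary(self, med, q25=None, q75=None):
        med = np.asarray(med, float)
        return pd.DataFrame({"median": med,
                             "q25": med if q25 is None else np.asarray(q25),
                             "q75": med if q75 is None else np.asarray(q75),
                             "min": med, "max": med})

    def test_equal_summaries(self):
        a = self.make_summary([1, 2, 3])
        diff, (ca, cb), mask = difference_and_cumulative(a, a)
        assert np.allclose(diff, 0)
        assert not mask.any()

    def test_cumulative_sums(self):
        a = self.make_summary([1, 1, 1])
        _, (ca, _), _ = difference_and_cumulative(a, a)
        assert ca.tolist() == [1, 2, 3]

    def test_disjoint_bands_all_masked(self):
        a = self.make_summary([1, 1], q25=[0.9, 0.9], q75=[1.1, 1.1])
        b = self.make_summary([3, 3], q25=[2.9, 2.9], q75=[3.1, 3.1])
        _, _, mask = difference_and_cumulative(a, b)
        assert mask.all()


class TestReadthrough:
    def test_toy_fractions(self):
        # 4-bin track, site at unit position 2: downstream = positions 3, 4
        t = ProfileTrack(np.array([1.0, 1.0, 1.0, 1.0]))
        assert readthrough_fraction(t, 2) == pytest.approx(0.5)
        t2 = ProfileTrack(np.array([2.0, 2.0, 0.0, 0.0]))
        assert readthrough_fraction(t2, 2) == 0.0
        t3 = ProfileTrack(np.array([0.0, 0.0, 3.0, 1.0]))
        assert readthrough_fraction(t3, 2) == 1.0

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            readthrough_fraction(ProfileTrack(np.zeros(4)), 2)

    def test_wilcoxon_separates_shifted_groups(self):
        a = [0.01, 0.012, 0.011, 0.013, 0.009, 0.010, 0.012]
        b = [0.05, 0.055, 0.049, 0.060]
        stat, p = readthrough_test(a, b)
        assert p < 0.01
        _, p_same = readthrough_test(a, a)
        assert p_same > 0.5


class TestSelectPolyA:
    @pytest.mark.parametrize("tail, selected", [
        ("AAA", True), ("AAAA", True), ("AA", False),
        ("AAAT", False), ("TAAA", True), ("", False), (".", False)])
    def test_terminal_run_rule(self, tail, selected):
        df = reads_df([("ref", 0, 10, "r", 1, "+", tail)])
        sel, _ = select_polyA(df, min_a=3)
        assert (len(sel) == 1) is selected

    def test_whole_tail_mode_stricter(self):
        df = reads_df([("ref", 0, 10, "r1", 1, "+", "TAAA"),
                       ("ref", 0, 10, "r2", 1, "+", "AAAA")])
        sel, _ = select_polyA(df, min_a=3, whole_tail=True)
        assert sel["name"].tolist() == ["r2"]

    def test_min_a_zero_selects_all(self, synthetic_replicates):
        reps, _ = synthetic_replicates
        sel, _ = select_polyA(reps[0], min_a=0)
        assert len(sel) == len(reps[0])

    def test_fraction_track_in_unit_interval(self, synthetic_replicates,
                                             element_map):
        reps, _ = synthetic_replicates
        _, frac = select_polyA(reps[0], min_a=3,
                               length=element_map.ref_length)
        assert (frac.values >= 0).all() and (frac.values <= 1).all()

    @settings(max_examples=200, deadline=None)
    @given(st.text(alphabet="ACGTN", max_size=12), st.integers(0, 5))
    def test_matches_brute_force_scanner(self, tail, min_a):
        run = 0
        for ch in reversed(tail):
            if ch != "A":
                break
            run += 1
        assert (terminal_a_run(tail) >= min_a) == (run >= min_a)


class TestReadLengthStats:
    def test_median_of_lengths(self):
        df = reads_df([("ref", 0, 20, "a", 1, "+", ""),
                       ("ref", 0, 25, "b", 1, "+", ""),
                       ("ref", 0, 30, "c", 1, "+", "")])
        assert read_length_stats(df)["median"] == 25

    def test_single_read(self):
        df = reads_df([("ref", 5, 45, "a", 1, "+", "")])
        assert read_length_stats(df)["median"] == 40

    def test_anchor_restriction(self):
        df = reads_df([("ref", 5, 45, "a", 1, "+", ""),
                       ("ref", 9, 15, "b", 1, "+", "")])
        st_ = read_length_stats(df, anchor_5p=10)  # unit pos 10 -> index 9
        assert st_["n"] == 1 and st_["median"] == 6

    def test_empty_selection_rejected(self):
        df = reads_df([("ref", 5, 45, "a", 1, "+", "")])
        with pytest.raises(ValueError):
            read_length_stats(df, anchor_5p=400)


class TestReadRecord:
    def test_validation(self):
        with pytest.raises(ValueError):
            ReadRecord("ref", 35, 10)
        with pytest.raises(ValueError):
            ReadRecord("ref", 1, 5, strand="x")
        with pytest.raises(ValueError):
            ReadRecord("ref", 1, 5, tail="AXA")

    def test_five_three_peak_distance_on_cleavage_fixture(self, element_map):
        # 5'-end peak at B0-2, 3'-end peak ~25 nt downstream (the planted
        # co-transcriptional cleavage geometry)
        from polterm.synthetic_data import ReadSimSpec, simulate_reads
        spec = ReadSimSpec(n_reads=15_000, n_replicates=1,
                           cleavage5p_fraction=1.0, seed=5)
        df = simulate_reads(spec, element_map)[0]
        five = end_profile(df, "five_prime", element_map.ref_length)
        three = end_profile(df, "three_prime", element_map.ref_length)
        d = int(np.argmax(three.values)) - int(np.argmax(five.values))
        assert abs(d - (spec.cleaved_length_median - 1)) <= 1
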