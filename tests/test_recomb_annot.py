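import math

import numpy as np
import pytest

from g4recomb import (GeneticMap, Peak, PeakSet, ValidationError,
                      compare_to_null, flank_genetic_distance,
                      fraction_below_average, mean_center_rate, rate_profile)
from g4recomb import synthdata as sd
from g4recomb.recomb_annot import center_rates

from conftest import peakset_from_intervals
from oracles import bp_integral_cm


def peaks_at(centers, chrom="1", half=50):
    return PeakSet("p", [Peak(chrom, c - half, c + half) for c in centers])


class TestMeanCenterRate:
    def test_constant_region(self, uniform_map):
        res = mean_center_rate(peaks_at([1000, 5000, 9000]), {"1": uniform_map})
        assert res.mean == 2.0 and res.sem == 0.0 and res.n_used == 3

    def test_two_point_sem(self, toy_map):
        res = mean_center_rate(peaks_at([600, 1600]), {"1": toy_map})
        assert res.mean == pytest.approx(2.0)
        assert res.sem == pytest.approx(1.0)

    def test_out_of_map_excluded_not_imputed(self, toy_map):
        res = mean_center_rate(peaks_at([600, 50_000]), {"1": toy_map})
        assert res.n_used == 1 and res.n_excluded == 1
        assert res.mean == 1.0

    def test_no_usable_peaks_rejected(self, toy_map):
        with pytest.raises(ValidationError):
            mean_center_rate(peaks_at([50_000]), {"1": toy_map})

    def test_union_weighted_mean_exact(self, toy_map):
        a, b = peaks_at([200, 600]), peaks_at([1600])
        union = PeakSet("u", a.peaks + b.peaks)
        ra = mean_center_rate(a, {"1": toy_map})
        rb = mean_center_rate(b, {"1": toy_map})
        ru = mean_center_rate(union, {"1": toy_map})
        assert ru.mean == pytest.approx(
            (ra.mean * ra.n_used + rb.mean * rb.n_used) / (ra.n_used + rb.n_used))

    def test_parameter_recovery_on_landscape(self, landscape):
        """Cold-preferring peaks recover the analytic expected mean rate."""
        maps, truth = landscape
        spec = sd.PeakPlacementSpec(n_peaks=500, cold_preference=0.8, seed=3)
        peaks, _ = sd.make_peaks(spec, truth)
        cold_rate = truth["spec"]["background_rate"] * truth["spec"]["coldspot_fraction"]
        mu = 0.8 * cold_rate + 0.2 * truth["genome_average_rate"]
        res = mean_center_rate(peaks, maps)
        assert abs(res.mean - mu) < 3 * res.sem


class TestRateProfile:
    def test_uniform_map_flat(self, uniform_map):
        prof = rate_profile(peaks_at([500_000]), {"1": uniform_map},
                            flank=5000, step=50)
        assert np.all(prof.mean_rate == 2.0)
        assert prof.offsets[0] == -5000 and prof.offsets[-1] == 5000

    def test_single_peak_is_raw_series(self, toy_map):
        prof = rate_profile(peaks_at([1100]), {"1": toy_map}, flank=500, step=100)
        vals, _ = toy_map.rate_at_many(1100 + prof.offsets)
        assert np.array_equal(prof.mean_rate, vals)
        assert np.all(prof.n_peaks == 1)

    def test_offset_zero_equals_mean_center_rate(self, landscape):
        maps, truth = landscape
        peaks, _ = sd.make_peaks(sd.PeakPlacementSpec(n_peaks=80, seed=4), truth)
        prof = rate_profile(peaks, maps)
        res = mean_center_rate(peaks, maps)
        mid = prof.offsets.size // 2
        assert prof.offsets[mid] == 0
        assert prof.mean_rate[mid] == pytest.approx(res.mean, abs=1e-12)

    def test_planted_dip_recovered_exactly(self):
        """A rate depression at every peak center shows as the profile minimum."""
        centers = [10_000, 30_000, 50_000]
        pos, rates = [0], [1.2]
        for c in centers:
            pos += [c - 250, c + 250]
            rates += [0.2, 1.2]
        pos.append(100_000)
        rates.append(0.0)
        pos_a = np.array(pos)
        rate_a = np.array(rates)
        cum = np.concatenate([[0.0], np.cumsum(rate_a[:-1] * np.diff(pos_a) / 1e6)])
        gmap = GeneticMap("1", pos_a, rate_a, cum)
        prof = rate_profile(peaks_at(centers), {"1": gmap}, flank=5000, step=50)
        mid = prof.offsets.size // 2
        assert prof.mean_rate[mid] == pytest.approx(0.2, abs=1e-12)
        assert prof.mean_rate[0] == pytest.approx(1.2, abs=1e-12)
        assert prof.mean_rate[-1] == pytest.approx(1.2, abs=1e-12)
        assert prof.mean_rate.min() == pytest.approx(0.2, abs=1e-12)
        assert prof.mean_rate.argmin() in range(mid - 5, mid + 6)

    def test_step_must_divide_flank(self, uniform_map):
        with pytest.raises(ValueError):
            rate_profile(peaks_at([1000]), {"1": uniform_map}, flank=5000, step=33)


class TestFlankGeneticDistance:
    def test_uniform_closed_form(self, uniform_map):
        df = flank_genetic_distance(peaks_at([300_000, 600_000]),
                                    {"1": uniform_map}, flank=10_000)
        assert np.allclose(df["cm"], 2.0 * 20_000 / 1e6)
        assert not df["clamped"].any()

    def test_zero_flank(self, uniform_map):
        df = flank_genetic_distance(peaks_at([300_000]), {"1": uniform_map}, flank=0)
        assert np.allclose(df["cm"], 0.0)

    def test_matches_per_bp_oracle_on_landscape(self, landscape):
        maps, truth = landscape
        peaks, _ = sd.make_peaks(sd.PeakPlacementSpec(n_peaks=20, seed=9), truth)
        df = flank_genetic_distance(peaks, maps, flank=10_000)
        for row in df.itertuples(index=False):
            m = maps[row.chrom]
            oracle = bp_integral_cm(m.positions, m.rates,
                                    row.center - 10_000, row.center + 10_000)
            assert row.cm == pytest.approx(oracle, abs=1e-9)

    def test_clamped_windows_flagged(self, toy_map):
        df = flank_genetic_distance(peaks_at([600]), {"1": toy_map}, flank=10_000)
        assert df["clamped"].all()
        assert df["cm"].iloc[0] == pytest.approx(0.004)


class TestFractionBelowAverage:
    def test_all_cold(self, toy_map):
        # centers in the rate-1.0 interval; genome average is 2.0
        assert fraction_below_average(peaks_at([300, 700]), {"1": toy_map}) == 1.0

    def test_exactly_at_average_is_not_below(self, uniform_map):
        assert fraction_below_average(peaks_at([1000]), {"1": uniform_map}) == 0.0

    def test_cold_preference_expectation(self, landscape):
        """Below-average bp is exactly the coldspot bp here, so the expected
        fraction equals the expected coldspot fraction."""
        maps, truth = landscape
        peaks, ptruth = sd.make_peaks(
            sd.PeakPlacementSpec(n_peaks=500, cold_preference=0.8, seed=11), truth)
        frac = fraction_below_average(peaks, maps)
        p = ptruth["expected_cold_fraction"]
        ci = 2.576 * math.sqrt(p * (1 - p) / 500)
        assert abs(frac - p) < ci

    def test_order_invariant(self, toy_map):
        a = peaks_at([300, 700, 1600])
        b = PeakSet("r", list(reversed(a.peaks)))
        assert fraction_below_average(a, {"1": toy_map}) == \
            fraction_below_average(b, {"1": toy_map})


class TestCompareToNull:
    def test_identical_vectors(self):
        res = compare_to_null([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.t == pytest.approx(0.0) and res.p == pytest.approx(1.0)

    def test_textbook_pooled_t(self):
        """[1,2,3] vs [4,5,6]: hand-computed pooled-variance t and p."""
        res = compare_to_null([1, 2, 3], [4, 5, 6])
        # s^2 = 1 in both groups -> s_p^2 = 1, t = -3 / sqrt(2/3)
        t_hand = -3.0 / math.sqrt(2.0 / 3.0)
        assert res.t == pytest.approx(t_hand, abs=1e-12)
        from scipy.stats import t as tdist
        assert res.p == pytest.approx(2 * tdist.sf(abs(t_hand), df=4), abs=1e-12)
        assert res.mean_observed == 2.0 and res.mean_null == 5.0
        assert res.sem_observed == pytest.approx(1.0 / math.sqrt(3.0))

    def test_swap_negates_t_keeps_p(self):
        a = compare_to_null([1, 2, 3], [4, 5, 7])
        b = compare_to_null([4, 5, 7], [1, 2, 3])
        assert a.t == pytest.approx(-b.t) and a.p == pytest.approx(b.p)

    def test_zero_variance_different_means(self):
        res = compare_to_null([1.0, 1.0], [2.0, 2.0])
        assert res.p == 0.0 and math.isinf(res.t)

    def test_short_vectors_rejected(self):
        with pytest.raises(ValidationError):
            compare_to_null([1.0], [1.0, 2.0])

    def test_welch_option(self):
        a = np.r_[np.zeros(50), 10.0]
        b = np.ones(5)
        student = compare_to_null(a, b)
        welch = compare_to_null(a, b, welch=True)
        assert student.t != pytest.approx(welch.t)


def test_center_rates_groups_by_chromosome(landscape):
    maps, truth = landscape
    peaks = PeakSet("x", [Peak("1", 100, 300), Peak("2", 100, 300),
                          Peak("9", 100, 300)])  # chromosome 9 unmapped
    vals, excluded = center_rates(peaks, maps)
    assert vals.size == 2 and excluded == 1
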