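"""Occupancy correction: densities, CIs, classification, T_P, statistics."""

import math

import numpy as np
import pytest
from scipy import stats

from thermowalk.correction import (
    AVOIDED,
    NEUTRAL,
    PREFERRED,
    OccupancyProfile,
    avoidance_starts,
    bh_fdr,
    binomial_bin_ci,
    classify_bins,
    correct_profile,
    default_bins,
    median_with_ci,
    occupancy_density,
    paired_t_test,
    permutation_test,
    preference_index,
    preference_range,
    preferred_temperature,
)
from thermowalk.simulator import GradientArena


class TestOccupancyDensity:
    def test_fixed_animal_is_a_unit_mass(self, arena):
        bins = default_bins(arena)
        v = occupancy_density(np.full(50, 10.0), arena, bins)
        assert v.sum() == pytest.approx(1.0)
        assert v.max() == pytest.approx(1.0)

    def test_equal_time_in_two_bins(self, arena):
        bins = default_bins(arena)
        pos = np.array([10.0] * 25 + [40.0] * 25)
        v = occupancy_density(pos, arena, bins)
        assert sorted(v[v > 0]) == pytest.approx([0.5, 0.5])

    def test_normalization_for_random_input(self, arena, rng):
        v = occupancy_density(rng.uniform(0, 50, 1000), arena, default_bins(arena))
        assert v.sum() == pytest.approx(1.0)

    def test_empty_input_rejected(self, arena):
        with pytest.raises(ValueError):
            occupancy_density(np.array([]), arena, default_bins(arena))


class TestMedianWithCI:
    def test_identical_individuals_have_zero_width(self):
        rows = np.tile(np.array([0.2, 0.3, 0.5]), (6, 1))
        med, (lo, hi) = median_with_ci(rows)
        assert np.allclose(med, [0.2, 0.3, 0.5])
        assert np.allclose(lo, med) and np.allclose(hi, med)

    def test_median_of_three_values(self):
        rows = np.array([[0.1], [0.2], [0.3]])
        med, _ = median_with_ci(rows)
        assert med[0] == pytest.approx(0.2)

    def test_bootstrap_matches_independent_oracle(self):
        # duplicate-implementation oracle with the same seeded generator
        rng0 = np.random.Generator(np.random.PCG64(77))
        rows = rng0.dirichlet(np.ones(4), size=5)
        med, (lo, hi) = median_with_ci(rows, method="bootstrap", n_boot=2000, seed=11)

        oracle_rng = np.random.Generator(np.random.PCG64(11))
        idx = oracle_rng.integers(0, 5, size=(2000, 5))
        boots = np.median(rows[idx], axis=1)
        o_lo = np.quantile(boots, 0.025, axis=0)
        o_hi = np.quantile(boots, 0.975, axis=0)
        o_med = np.median(rows, axis=0)
        assert np.allclose(med, o_med)
        assert np.allclose(lo, np.minimum(o_lo, o_med))
        assert np.allclose(hi, np.maximum(o_hi, o_med))

    def test_exact_interval_brackets_median_and_orders(self, rng):
        rows = rng.dirichlet(np.ones(6), size=25)
        med, (lo, hi) = median_with_ci(rows, method="exact")
        assert np.all(lo <= med + 1e-12) and np.all(hi >= med - 1e-12)

    def test_exact_interval_coverage_for_gaussian_bins(self, rng):
        # distribution-free CI should cover the true median ~>= 95% of the time
        hits = 0
        n_rep = 400
        for _ in range(n_rep):
            rows = rng.normal(0.5, 0.1, size=(20, 1))
            _, (lo, hi) = median_with_ci(rows, method="exact")
            hits += lo[0] <= 0.5 <= hi[0]
        assert hits / n_rep >= 0.93

    def test_too_few_individuals_rejected(self):
        with pytest.raises(ValueError, match="binomial"):
            median_with_ci(np.ones((2, 3)))

    def test_unknown_method_rejected(self, rng):
        with pytest.raises(ValueError):
            median_with_ci(rng.random((5, 3)), method="jackknife")


class TestBinomialBinCI:
    def test_zero_count_lower_bound_is_zero(self):
        lo, hi = binomial_bin_ci(np.array([0.0, 0.5]), 10)
        assert lo[0] == 0.0

    def test_full_count_upper_bound_is_one(self):
        lo, hi = binomial_bin_ci(np.array([1.0]), 10)
        assert hi[0] == 1.0

    def test_half_of_ten_matches_beta_quantiles(self):
        lo, hi = binomial_bin_ci(np.array([0.5]), 10)
        assert lo[0] == pytest.approx(stats.beta.ppf(0.025, 5, 6), rel=1e-9)
        assert hi[0] == pytest.approx(stats.beta.ppf(0.975, 6, 5), rel=1e-9)
        assert (lo[0], hi[0]) == pytest.approx((0.187, 0.813), abs=0.001)

    def test_requires_samples(self):
        with pytest.raises(ValueError):
            binomial_bin_ci(np.array([0.5]), 0)


class TestPreferenceIndex:
    def test_identical_vectors_give_zero(self):
        v = np.array([0.25, 0.75])
        assert np.allclose(preference_index(v, v), 0.0)

    def test_subtraction_example(self):
        out = preference_index(np.array([0.5, 0.5]), np.array([0.25, 0.75]))
        assert np.allclose(out, [0.25, -0.25])

    def test_conservation(self, rng):
        a = rng.dirichlet(np.ones(10))
        b = rng.dirichlet(np.ones(10))
        assert abs(preference_index(a, b).sum()) < 1e-12

    def test_bin_mismatch_rejected(self):
        with pytest.raises(ValueError):
            preference_index(np.ones(3) / 3, np.ones(4) / 4)


class TestClassification:
    def test_ci_rule(self):
        lo = np.array([0.01, -0.05, -0.01])
        hi = np.array([0.05, -0.01, 0.02])
        assert list(classify_bins(lo, hi)) == [PREFERRED, AVOIDED, NEUTRAL]

    def test_quantization_guard_suppresses_hairline_calls(self):
        lo = np.array([0.0004, 0.01])
        hi = np.array([0.0009, 0.05])
        assert list(classify_bins(lo, hi, atol=0.0008)) == [NEUTRAL, PREFERRED]

    def test_stable_under_bin_permutation(self, rng):
        lo, hi = rng.normal(0, 0.02, 12), rng.normal(0.01, 0.02, 12)
        lo, hi = np.minimum(lo, hi), np.maximum(lo, hi)
        perm = rng.permutation(12)
        direct = classify_bins(lo, hi)
        permuted = classify_bins(lo[perm], hi[perm])
        assert list(permuted) == list(direct[perm])


class TestDerivedScalars:
    def test_single_preferred_bin(self):
        centers = np.array([20.0, 22.0, 24.0])
        labels = np.array([NEUTRAL, PREFERRED, NEUTRAL], dtype=object)
        index = np.array([0.0, 0.3, -0.3])
        assert preferred_temperature(centers, index, labels) == pytest.approx(22.0)

    def test_weighted_mean(self):
        centers = np.array([20.0, 22.0])
        labels = np.array([PREFERRED, PREFERRED], dtype=object)
        index = np.array([0.1, 0.3])
        assert preferred_temperature(centers, index, labels) == pytest.approx(21.5)

    def test_no_preferred_bin_is_undefined(self):
        centers = np.array([20.0])
        assert math.isnan(preferred_temperature(centers, np.array([0.0]),
                                                np.array([NEUTRAL], dtype=object)))

    def test_avoidance_starts_example(self):
        # labels (A,A,N,P,N,A) on 1 degree bins from 14
        edges = np.arange(14.0, 21.0)
        labels = np.array([AVOIDED, AVOIDED, NEUTRAL, PREFERRED, NEUTRAL, AVOIDED], dtype=object)
        cold, hot = avoidance_starts(edges, labels)
        assert cold == pytest.approx(16.0)
        assert hot == pytest.approx(19.0)
        assert preference_range(edges, labels) == pytest.approx(1.0)

    def test_all_preferred_profile(self):
        edges = np.arange(14.0, 19.0)
        labels = np.array([PREFERRED] * 4, dtype=object)
        cold, hot = avoidance_starts(edges, labels)
        assert math.isnan(cold) and math.isnan(hot)
        assert preference_range(edges, labels) == pytest.approx(4.0)

    def test_interior_avoided_island_does_not_move_starts(self):
        edges = np.arange(14.0, 21.0)
        labels = np.array([AVOIDED, NEUTRAL, AVOIDED, NEUTRAL, NEUTRAL, AVOIDED], dtype=object)
        cold, hot = avoidance_starts(edges, labels)
        assert cold == pytest.approx(15.0)
        assert hot == pytest.approx(19.0)

    def test_no_avoided_runs(self):
        edges = np.arange(14.0, 17.0)
        labels = np.array([NEUTRAL, NEUTRAL], dtype=object)
        cold, hot = avoidance_starts(edges, labels)
        assert math.isnan(cold) and math.isnan(hot)
        assert preference_range(edges, labels) == 0.0


class TestCorrectProfile:
    def test_index_sums_to_zero_and_ci_rule_holds(self, arena, rng):
        bins = default_bins(arena)
        rows = rng.dirichlet(np.ones(bins.size - 1), size=20)
        obs = OccupancyProfile.from_individuals(rows, bins, n_time_samples=500)
        null = rng.dirichlet(np.ones(bins.size - 1))
        prof = correct_profile(obs, null)
        assert abs(prof.index.sum()) < 1e-12
        assert prof.preference_range <= (prof.tolerance_range if not math.isnan(prof.tolerance_range)
                                         else np.inf)

    def test_individual_vectors_must_sum_to_one(self, arena):
        bins = default_bins(arena)
        with pytest.raises(ValueError):
            OccupancyProfile.from_individuals(np.full((5, bins.size - 1), 0.9), bins)


class TestPermutationTest:
    def test_exhaustive_small_example(self):
        p = permutation_test([1.0, 2.0], [3.0, 4.0],
                             statistic=lambda a, b: float(np.mean(a) - np.mean(b)))
        assert p == pytest.approx(1.0 / 3.0)

    def test_identical_samples_give_p_one(self):
        assert permutation_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == pytest.approx(1.0)

    def test_monte_carlo_mode_is_seeded(self):
        rng = np.random.Generator(np.random.PCG64(3))
        a, b = rng.normal(0, 1, 12), rng.normal(1, 1, 12)
        p1 = permutation_test(a, b, n_perm=500, seed=9)
        p2 = permutation_test(a, b, n_perm=500, seed=9)
        assert p1 == p2
        assert 0.0 < p1 <= 1.0

    def test_clear_separation_is_significant(self):
        p = permutation_test(np.arange(8.0), np.arange(8.0) + 50.0)
        assert p < 0.01

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            permutation_test([], [1.0])

    def test_type_one_error_rate(self):
        # 5-vs-5 normal null replicates through the exhaustive path
        rng = np.random.Generator(np.random.PCG64(99))
        n_rep = 500
        rej = sum(
            permutation_test(rng.normal(size=5), rng.normal(size=5)) <= 0.05
            for _ in range(n_rep)
        )
        rate = rej / n_rep
        assert 0.02 <= rate <= 0.08


class TestBHFDR:
    def test_single_value_unchanged(self):
        assert bh_fdr([0.2])[0] == pytest.approx(0.2)

    def test_step_up_hand_computation(self):
        assert np.allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]), 0.04)

    def test_equal_values_stay_equal(self):
        out = bh_fdr([0.3, 0.3, 0.3])
        assert np.allclose(out, 0.3)

    def test_monotone_in_rank_and_capped(self, rng):
        p = rng.random(25)
        adj = bh_fdr(p)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-12)
        assert np.all(adj <= 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.2])


def test_paired_t_wrapper_matches_scipy(rng):
    a, b = rng.normal(0, 1, 15), rng.normal(0.5, 1, 15)
    t, p = paired_t_test(a, b)
    ref = stats.ttest_rel(a, b)
    assert t == pytest.approx(ref.statistic)
    assert p == pytest.approx(ref.pvalue)
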