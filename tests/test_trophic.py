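import numpy as np
import pytest
from scipy import stats

from sulaniche.trophic import (
    centroid_distance,
    delta_value,
    mdc,
    niche_overlap_prob,
    position_permutation_test,
    ratio_from_delta,
    sea_bayesian,
    sea_compare,
    univariate_width_test,
    width_permutation_test,
)


class TestDelta:
    def test_equal_ratios_zero_per_mil(self):
        assert delta_value(0.011, 0.011) == 0.0

    def test_one_per_mil(self):
        assert delta_value(1.001 * 0.0112372, 0.0112372) == pytest.approx(1.0)

    def test_round_trip(self, rng):
        r_std = 0.0036765
        r = r_std * (1 + rng.uniform(-0.05, 0.05, 20))
        assert np.allclose(ratio_from_delta(delta_value(r, r_std), r_std), r)

    def test_nonpositive_standard_rejected(self):
        with pytest.raises(ValueError):
            delta_value(0.01, 0.0)


class TestPositionWidth:
    def test_identical_groups_zero_ed(self, rng):
        g = rng.standard_normal((10, 2))
        assert centroid_distance(g, g) == 0.0

    def test_printed_group_means_distance(self):
        """Rounded 2016 vs 2019 male means: sqrt(0.3^2 + 0.6^2) = 0.6708 per mil."""
        m2016 = np.tile([-15.1, 12.6], (5, 1))
        m2019 = np.tile([-14.8, 12.0], (5, 1))
        assert centroid_distance(m2016, m2019) == pytest.approx(0.6708, abs=5e-4)

    def test_ed_translation_invariant(self, rng):
        a, b = rng.standard_normal((8, 2)), rng.standard_normal((9, 2))
        shift = np.array([3.7, -1.2])
        assert centroid_distance(a + shift, b + shift) == pytest.approx(centroid_distance(a, b))

    def test_mdc_single_observation_zero(self):
        assert mdc([[1.0, 2.0]]) == 0.0

    def test_mdc_unit_square(self):
        square = [[0, 0], [0, 1], [1, 0], [1, 1]]
        assert mdc(square) == pytest.approx(np.sqrt(2) / 2)

    def test_mdc_scales_about_centroid(self, rng):
        g = rng.standard_normal((15, 2))
        centered = g - g.mean(axis=0)
        assert mdc(centered * 5) == pytest.approx(5 * mdc(centered))

    def test_extreme_separation_minimal_p(self, rng):
        a = rng.standard_normal((10, 2))
        b = rng.standard_normal((10, 2)) + 10 * np.sqrt(2)  # ~10 pooled SDs
        res = position_permutation_test(a, b, n_perm=999, seed=0)
        assert res.p == pytest.approx(1 / 1000)

    def test_identical_groups_p_near_one(self, rng):
        g = rng.standard_normal((8, 2))
        res = position_permutation_test(g, g, n_perm=499, seed=0)
        assert res.observed == 0.0
        assert res.p > 0.9

    def test_width_detects_dispersion_ratio(self, rng):
        a = rng.standard_normal((20, 2))
        b = (a - a.mean(axis=0)) * 5 + a.mean(axis=0)
        res = width_permutation_test(a, b, n_perm=999, seed=0)
        assert res.p <= 0.01

    def test_width_identical_groups(self, rng):
        g = rng.standard_normal((10, 2))
        res = width_permutation_test(g, g, n_perm=499, seed=0)
        assert res.observed == 0.0
        assert res.p > 0.9

    def test_p_never_exactly_zero(self, rng):
        a = rng.standard_normal((5, 2))
        b = rng.standard_normal((5, 2)) + 100
        assert position_permutation_test(a, b, n_perm=99, seed=0).p > 0.0

    def test_small_groups_rejected(self, rng):
        with pytest.raises(ValueError):
            position_permutation_test(rng.standard_normal((2, 2)), rng.standard_normal((5, 2)))


class TestSEA:
    def test_retained_draw_count_at_default_chain_settings(self, rng):
        """2 chains x (20000 - 1000) / 10 = 3800 retained draws."""
        post = sea_bayesian(rng.standard_normal((30, 2)), chains=2, iters=20000, burn_in=1000, thin=10, seed=0)
        assert len(post.areas) == 3800

    def test_posterior_area_matches_analytic_large_n(self, rng):
        X = rng.standard_normal((10_000, 2))
        post = sea_bayesian(X, chains=2, iters=4000, burn_in=500, thin=10, seed=1)
        expected = np.pi * stats.chi2.ppf(0.95, 2)  # unit covariance
        assert post.median_area == pytest.approx(expected, rel=0.02)

    def test_rotation_invariance_of_area(self, rng):
        X = rng.standard_normal((60, 2)) @ np.diag([2.0, 0.5])
        theta = 0.7
        R = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        a = sea_bayesian(X, chains=1, iters=3000, burn_in=500, thin=5, seed=3)
        b = sea_bayesian(X @ R.T, chains=1, iters=3000, burn_in=500, thin=5, seed=3)
        assert np.median(a.areas) == pytest.approx(np.median(b.areas), rel=0.05)

    def test_covariance_draws_positive_definite(self, rng):
        post = sea_bayesian(rng.standard_normal((20, 2)), chains=1, iters=1000, burn_in=100, thin=10, seed=4)
        eig = np.linalg.eigvalsh(post.cov_draws)
        assert (eig > 0).all()

    def test_chain_convergence_diagnostic(self, rng):
        post = sea_bayesian(rng.standard_normal((40, 2)), chains=2, iters=5000, burn_in=500, thin=10, seed=5)
        assert post.rhat < 1.05

    def test_too_small_group_rejected(self, rng):
        with pytest.raises(ValueError):
            sea_bayesian(rng.standard_normal((3, 2)))


class TestCompareOverlap:
    def test_same_draws_pp_zero(self, rng):
        post = sea_bayesian(rng.standard_normal((20, 2)), chains=1, iters=1000, burn_in=100, thin=10, seed=0)
        assert sea_compare(post, post) == 0.0  # strict inequality never holds on tied draws

    def test_pp_partition(self, rng):
        a = sea_bayesian(rng.standard_normal((20, 2)), chains=1, iters=2000, burn_in=200, thin=10, seed=1)
        b = sea_bayesian(rng.standard_normal((20, 2)) * 1.3, chains=1, iters=2000, burn_in=200, thin=10, seed=2)
        m = min(len(a.areas), len(b.areas))
        ties = float(np.mean(a.areas[:m] == b.areas[:m]))
        assert sea_compare(a, b) + sea_compare(b, a) + ties == pytest.approx(1.0)

    def test_fourfold_area_difference_detected(self, rng):
        a = sea_bayesian(rng.standard_normal((50, 2)) * 2.0, chains=2, iters=3000, burn_in=300, thin=10, seed=3)
        b = sea_bayesian(rng.standard_normal((50, 2)), chains=2, iters=3000, burn_in=300, thin=10, seed=4)
        assert sea_compare(a, b) > 0.95

    def test_overlap_huge_target_region(self, rng):
        a = sea_bayesian(rng.standard_normal((30, 2)), chains=1, iters=1000, burn_in=200, thin=10, seed=5)
        b = sea_bayesian(rng.standard_normal((30, 2)) * 1000.0, chains=1, iters=1000, burn_in=200, thin=10, seed=6)
        res = niche_overlap_prob(a, b, n_mc=500, seed=0)
        assert res["median_pct"] > 99.0

    def test_overlap_identical_populations_near_alpha(self, rng):
        X = rng.standard_normal((2000, 2))
        a = sea_bayesian(X, chains=1, iters=2000, burn_in=200, thin=10, seed=7)
        b = sea_bayesian(X, chains=1, iters=2000, burn_in=200, thin=10, seed=8)
        res = niche_overlap_prob(a, b, alpha=0.95, n_mc=2000, seed=1)
        assert res["median_pct"] == pytest.approx(95.0, abs=1.5)

    def test_overlap_is_directional(self, rng):
        small = sea_bayesian(rng.standard_normal((40, 2)) * 0.3, chains=1, iters=2000, burn_in=200, thin=10, seed=9)
        big = sea_bayesian(rng.standard_normal((40, 2)) * 3.0, chains=1, iters=2000, burn_in=200, thin=10, seed=10)
        ab = niche_overlap_prob(small, big, n_mc=1000, seed=2)["median_pct"]
        ba = niche_overlap_prob(big, small, n_mc=1000, seed=2)["median_pct"]
        assert ab > ba + 20.0  # small niche sits inside big one, not vice versa


class TestBartlett:
    def test_identical_variances_zero_statistic(self):
        a = np.array([[1.0, 0], [2.0, 0], [3.0, 0]])
        b = a + np.array([10.0, 0])  # same variance, shifted
        res = univariate_width_test([a, b], axis="d13C")
        assert res["statistic"] == pytest.approx(0.0, abs=1e-12)
        assert res["df"] == 1

    def test_statistic_invariant_to_per_group_shift(self, rng):
        a = rng.standard_normal((15, 2))
        b = rng.standard_normal((12, 2)) * 1.4
        k1 = univariate_width_test([a, b], axis="d15N")["statistic"]
        k2 = univariate_width_test([a + 100, b - 50], axis="d15N")["statistic"]
        assert k1 == pytest.approx(k2)

    def test_zero_variance_rejected(self):
        a = np.zeros((5, 2))
        with pytest.raises(ValueError):
            univariate_width_test([a, a], axis="d13C")
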