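"""Descriptives, MLE fitting, discrete K-S, bootstrap GOF, group tests."""
import math

import numpy as np
import pytest
from scipy import stats

from crisprstat import (
    SizeSample,
    ArraySizeModel,
    compare_fits,
    fit_geometric,
    fit_poisson,
    gof_test,
    kruskal_wallis,
    ks_statistic_discrete,
    probability_plot_points,
    summarize,
    welch_t_test,
)
from crisprstat.sizedist import family_cdf, loglik


class TestSummarize:
    def test_symmetric_sample(self):
        s = summarize([1, 2, 3])
        assert s.mean == 2 and s.median == 2

    def test_interpolated_quartiles(self):
        s = summarize([1, 2, 3, 4])
        assert s.q1 == pytest.approx(1.75)
        assert s.q3 == pytest.approx(3.25)

    def test_degenerate_single_value(self):
        s = summarize([7])
        assert (s.mean, s.q1, s.median, s.q3) == (7, 7, 7, 7)

    def test_empty_sample_errors(self):
        with pytest.raises(ValueError):
            summarize([])


class TestMLE:
    def test_printed_estimate_pair(self):
        """A sample with mean 38.277 gives p_hat = 0.025 to three decimals
        and lambda_hat equal to the mean."""
        counts = np.array([38] * 723 + [39] * 277)
        assert counts.mean() == pytest.approx(38.277)
        geo = fit_geometric(counts)
        poi = fit_poisson(counts)
        assert round(geo.theta, 3) == 0.025
        assert poi.theta == pytest.approx(38.277)

    def test_all_zero_boundary(self):
        assert fit_geometric([0, 0, 0]).theta == 1.0
        assert fit_poisson([0, 0]).theta == 0.0

    def test_closed_form_on_ones(self):
        assert fit_geometric([1, 1, 1]).theta == pytest.approx(0.5)

    def test_poisson_loglik_matches_direct_sum(self):
        fit = fit_poisson([2, 4])
        assert fit.theta == 3
        direct = sum(math.log(math.exp(-3) * 3**k / math.factorial(k)) for k in (2, 4))
        assert fit.loglik == pytest.approx(direct)

    def test_geometric_loglik_matches_direct_sum(self):
        fit = fit_geometric([1, 1, 1])
        p = 0.5
        direct = 3 * math.log((1 - p) * p)
        assert fit.loglik == pytest.approx(direct)

    def test_closed_forms_match_grid_search(self):
        """Closed-form p_hat and lambda_hat agree with a dense grid search
        of the log-likelihood on 100 random samples."""
        rng = np.random.default_rng(11)
        p_grid = np.arange(0.0005, 1.0, 0.0005)
        for _ in range(100):
            p_true = rng.uniform(0.01, 0.6)
            x = rng.geometric(p_true, size=int(rng.integers(5, 80))) - 1
            geo = fit_geometric(x)
            ll = len(x) * np.log(p_grid) + x.sum() * np.log1p(-p_grid)
            assert abs(geo.theta - p_grid[np.argmax(ll)]) <= 0.0005
            poi = fit_poisson(x)
            lam_grid = np.linspace(max(x.mean() - 2, 0.001), x.mean() + 2, 4001)
            ll_p = np.array([loglik(x, "poisson", lam) for lam in lam_grid])
            assert abs(poi.theta - lam_grid[np.argmax(ll_p)]) <= lam_grid[1] - lam_grid[0]


class TestDiscreteKS:
    def test_identical_distributions_give_zero(self):
        # point mass at 0 vs geometric with p = 1 (also a point mass at 0)
        assert ks_statistic_discrete([0, 0, 0], "geometric", 1.0) == 0.0

    def test_hand_computed_supremum(self):
        # F0(4) = 1 - 0.5**5 vs F_data(4) = 0
        d = ks_statistic_discrete([5, 5, 5], "geometric", 0.5)
        assert d == pytest.approx(1 - 0.5**5)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(3)
        x = rng.geometric(0.1, 40) - 1
        d1 = ks_statistic_discrete(x, "poisson", 9.0)
        d2 = ks_statistic_discrete(rng.permutation(x), "poisson", 9.0)
        assert d1 == d2

    def test_matches_exhaustive_scan(self):
        """The vectorized statistic equals a pointwise scan over every
        support value for samples with max <= 50."""
        rng = np.random.default_rng(5)
        for _ in range(50):
            x = rng.integers(0, 51, size=int(rng.integers(3, 30)))
            for family, theta in (("geometric", 0.2), ("poisson", 8.0)):
                d = ks_statistic_discrete(x, family, theta)
                brute = max(
                    abs(float(family_cdf(family, theta, k)) - np.mean(x <= k))
                    for k in range(0, int(x.max()) + 1)
                )
                assert d == pytest.approx(brute)

    def test_invalid_theta_errors(self):
        with pytest.raises(ValueError):
            ks_statistic_discrete([1, 2], "geometric", 1.5)
        with pytest.raises(ValueError):
            ks_statistic_discrete([1, 2], "poisson", -1.0)


class TestGof:
    def test_fixed_seed_is_reproducible(self):
        x = np.random.default_rng(1).geometric(0.05, 60) - 1
        a = gof_test(x, "geometric", n_boot=99, seed=10)
        b = gof_test(x, "geometric", n_boot=99, seed=10)
        assert a == b

    def test_overdispersed_data_rejects_poisson(self):
        """Geometric data with mean ~38 is far too dispersed for Poisson."""
        x = np.random.default_rng(2).geometric(0.025, 200) - 1
        res = gof_test(x, "poisson", n_boot=199, seed=0)
        assert res.p_value < 0.01

    def test_small_n_boot_rejected(self):
        with pytest.raises(ValueError):
            gof_test([1, 2, 3], "geometric", n_boot=10)

    def test_poisson_rejected_on_geometric_data_with_high_power(self):
        """Fitting Poisson to geometric-like data (p = 0.025, n = 811) is
        rejected at alpha = 0.05 in at least 95% of 50 replicates."""
        rng = np.random.default_rng(17)
        rejections = 0
        for _ in range(50):
            x = rng.geometric(0.025, 811) - 1
            res = gof_test(x, "poisson", n_boot=99,
                           seed=int(rng.integers(2**31)))
            rejections += res.p_value < 0.05
        assert rejections >= 48


class TestCompareFits:
    def test_geometric_wins_on_overdispersed_sample(self):
        x = np.random.default_rng(4).geometric(0.025, 811) - 1
        ranked = compare_fits(x, n_boot=99, seed=0)
        assert ranked[0][0].family == "geometric"
        assert ranked[0][0].loglik > ranked[1][0].loglik

    def test_poisson_wins_on_underdispersed_sample(self):
        ranked = compare_fits([5, 5, 5, 5, 5, 5], n_boot=99, seed=0)
        assert ranked[0][0].family == "poisson"

    def test_ranking_stable_under_permutation(self):
        rng = np.random.default_rng(6)
        x = rng.geometric(0.05, 100) - 1
        r1 = compare_fits(x, n_boot=99, seed=1)
        r2 = compare_fits(rng.permutation(x), n_boot=99, seed=1)
        assert [f.family for f, _ in r1] == [f.family for f, _ in r2]
        assert r1[0][0].loglik == pytest.approx(r2[0][0].loglik)


class TestGroupTests:
    def test_welch_identical_samples(self):
        t, df, p = welch_t_test([1, 2, 3], [1, 2, 3])
        assert t == 0 and p == pytest.approx(1.0)

    def test_welch_hand_formula(self):
        t, df, p = welch_t_test([1, 2, 3], [4, 5, 6])
        # means 2 and 5, variances 1, n = 3: t = -3 / sqrt(2/3)
        assert t == pytest.approx(-3 / math.sqrt(2 / 3))
        assert df == pytest.approx(4.0)

    def test_welch_antisymmetry(self):
        t1, _, p1 = welch_t_test([1, 5, 9], [2, 2, 3])
        t2, _, p2 = welch_t_test([2, 2, 3], [1, 5, 9])
        assert t1 == pytest.approx(-t2) and p1 == pytest.approx(p2)

    def test_kruskal_identical_groups(self):
        h, df, p = kruskal_wallis([[1, 2, 3], [1, 2, 3], [1, 2, 3]])
        assert h == pytest.approx(0.0) and df == 2

    def test_kruskal_hand_ranks(self):
        h, df, p = kruskal_wallis([[1, 2], [3, 4]])
        assert h == pytest.approx(2.4) and df == 1

    def test_kruskal_rank_invariance(self):
        groups = [[1, 4, 9], [2, 3, 10], [5, 6, 7]]
        h1, *_ = kruskal_wallis(groups)
        h2, *_ = kruskal_wallis([[g * g for g in grp] for grp in groups])
        assert h1 == pytest.approx(h2)


class TestProbabilityPlot:
    def test_plotting_positions(self):
        pts = probability_plot_points([3, 1, 2], "poisson", 2.0)
        assert pts.shape == (3, 1 + 1)
        assert list(pts[:, 1]) == [1, 2, 3]
        expected = stats.poisson.ppf([0.25, 0.5, 0.75], 2.0)
        assert list(pts[:, 0]) == list(expected)

    def test_single_observation_position_is_half(self):
        pts = probability_plot_points([4], "geometric", 0.2)
        assert pts[0, 0] == stats.geom.ppf(0.5, 0.2) - 1

    def test_well_fitted_sample_hugs_identity(self):
        x = np.random.default_rng(8).geometric(0.025, 2000) - 1
        p_hat = fit_geometric(x).theta
        pts = probability_plot_points(x, "geometric", p_hat)
        r = np.corrcoef(pts[:, 0], pts[:, 1])[0, 1]
        assert r >= 0.99


class TestModelObject:
    def test_model_results_round_trip(self):
        x = np.random.default_rng(9).geometric(0.05, 150) - 1
        res = ArraySizeModel(x, label="demo").fit(n_boot=99, seed=0)
        assert res.best_family == "geometric"
        text = res.summary()
        assert "demo" in text and "p_hat" in text
        d = res.to_dict()
        assert set(d["fits"]) == {"geometric", "poisson"}
        assert 0 <= d["gof"]["geometric"]["p_value"] <= 1

    def test_sample_invariants(self):
        with pytest.raises(ValueError):
            SizeSample("x", np.array([]))
        with pytest.raises(ValueError):
            SizeSample("x", np.array([-1, 2]))
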