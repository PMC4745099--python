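"""Classical test battery: ANOVA, KS, Lilliefors, beta fits, bootstrap joint."""

import numpy as np
import pytest
from scipy import stats as sps

from claysub.stats import (
    CouplingSpec,
    FitError,
    anova_oneway,
    bootstrap_joint,
    clay_per_volume,
    compare_kurtosis,
    fit_beta_moments,
    ks_two_sample,
    lilliefors_normality,
    normalized_consumption,
    to_percent,
)

from conftest import make_unit


class TestAnova:
    def test_hand_computed_sum_of_squares(self):
        # SSB = 1.5, SSW = 4, df = (1, 4) -> F = 1.5
        r = anova_oneway([[1, 2, 3], [2, 3, 4]])
        assert r.F == pytest.approx(1.5)
        assert (r.df_between, r.df_within) == (1, 4)

    def test_identical_groups_give_zero_f(self):
        r = anova_oneway([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]])
        assert r.F == 0.0

    def test_equals_squared_t_statistic(self, rng):
        """Two-group ANOVA is the square of the pooled-variance t test
        (100 random instances)."""
        for _ in range(100):
            n = rng.integers(3, 12)
            x = rng.normal(size=n)
            y = rng.normal(loc=rng.normal(), size=n)
            r = anova_oneway([x, y])
            t = sps.ttest_ind(x, y, equal_var=True)
            assert r.F == pytest.approx(t.statistic**2, rel=1e-10)
            assert r.p == pytest.approx(t.pvalue, rel=1e-10)

    def test_matches_scipy_f_oneway(self, rng):
        groups = [rng.normal(loc=i, size=8) for i in range(4)]
        r = anova_oneway(groups)
        ref = sps.f_oneway(*groups)
        assert r.F == pytest.approx(ref.statistic, rel=1e-12)
        assert r.p == pytest.approx(ref.pvalue, rel=1e-12)

    def test_unbalanced_rejected(self):
        with pytest.raises(ValueError, match="unbalanced"):
            anova_oneway([[1, 2, 3], [1, 2]])

    def test_zero_within_variance_flagged(self):
        r = anova_oneway([[1.0, 1.0], [2.0, 2.0]])
        assert r.degenerate and r.p == 0.0 and np.isinf(r.F)

    def test_order_invariance(self, rng):
        x, y = rng.normal(size=10), rng.normal(size=10)
        a = anova_oneway([x, y])
        b = anova_oneway([x[::-1], y[::-1]])
        assert a.F == pytest.approx(b.F)


class TestRatios:
    def test_normalized_consumption_lab_means(self):
        u = make_unit(initial_wood=3.44, leftover=1.15)
        assert normalized_consumption(u) == pytest.approx(0.6657, abs=1e-4)

    @pytest.mark.parametrize("leftover,expected", [(3.44, 0.0), (0.0, 1.0)])
    def test_consumption_bounds(self, leftover, expected):
        u = make_unit(initial_wood=3.44, leftover=leftover)
        assert normalized_consumption(u) == expected

    def test_clay_per_volume_lab_loaded(self):
        u = make_unit(clay=58.9, initial_volume=207.21, final_volume=34.15)
        assert clay_per_volume(u) == pytest.approx(1.7247, abs=1e-4)

    def test_clay_per_volume_lab_unloaded(self):
        u = make_unit(arm="unloaded", clay=48.50, initial_volume=200.50)
        assert clay_per_volume(u) == pytest.approx(0.2419, abs=1e-4)

    def test_zero_clay(self):
        assert clay_per_volume(make_unit(clay=0.0)) == 0.0


def brute_force_ks(x, y):
    """Exhaustive sup of |ECDF_x - ECDF_y| over all pooled evaluation points."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    pts = np.concatenate([x, y])
    return max(
        abs(np.mean(x <= p) - np.mean(y <= p)) for p in pts
    )


class TestKolmogorovSmirnov:
    def test_identical_samples_give_zero(self):
        x = [1.0, 2.0, 3.0]
        d, p = ks_two_sample(x, x)
        assert d == 0.0

    def test_disjoint_supports_give_one(self):
        x = np.arange(10.0)
        d, _ = ks_two_sample(x, x + 100.0)
        assert d == 1.0

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(50):
            x = rng.normal(size=rng.integers(3, 15))
            y = rng.normal(loc=0.5, size=rng.integers(3, 15))
            d, _ = ks_two_sample(x, y)
            assert d == pytest.approx(brute_force_ks(x, y), abs=1e-12)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            ks_two_sample([], [1.0])


class TestLilliefors:
    def test_normal_sample_not_rejected(self, rng):
        x = rng.standard_normal(150)
        assert lilliefors_normality(x, n_mc=1000, seed=1) > 0.01

    def test_exponential_sample_rejected(self, rng):
        x = rng.exponential(size=100)
        assert lilliefors_normality(x, n_mc=2000, seed=1) < 0.01

    def test_deterministic_given_seed(self, rng):
        x = rng.standard_normal(60)
        assert lilliefors_normality(x, seed=5) == lilliefors_normality(x, seed=5)

    def test_agrees_with_statsmodels_on_statistic_scale(self, rng):
        """Cross-check against the independent table-based implementation:
        both p-values land on the same side of 0.05 for clear cases."""
        sm = pytest.importorskip("statsmodels.stats.diagnostic")
        x_norm = rng.standard_normal(120)
        x_exp = rng.exponential(size=120)
        for x, low in [(x_norm, False), (x_exp, True)]:
            p_mc = lilliefors_normality(x, n_mc=2000, seed=2)
            p_sm = sm.lilliefors(x, dist="norm")[1]
            assert (p_mc < 0.05) == (p_sm < 0.05) == low

    def test_constant_sample_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            lilliefors_normality([2.0] * 10)


class TestBetaFit:
    def test_moment_inversion_exact_on_matched_sample(self):
        # symmetric two-point sample engineered so the ddof=1 moments are
        # exactly (0.5, 0.05) -> Beta(2, 2)
        k = 10
        d = np.sqrt(0.05 * (2 * k - 1) / (2 * k))
        x = 100 * np.concatenate([np.full(k, 0.5 - d), np.full(k, 0.5 + d)])
        fit = fit_beta_moments(x)
        assert fit.a == pytest.approx(2.0, abs=1e-9)
        assert fit.b == pytest.approx(2.0, abs=1e-9)

    def test_symmetric_sample_gives_equal_parameters(self, rng):
        x = rng.beta(3, 3, size=501)
        x = np.concatenate([x, 1 - x])  # force exact mean 0.5
        fit = fit_beta_moments(100 * x)
        assert fit.a == pytest.approx(fit.b, rel=1e-9)

    def test_refit_self_consistency(self, rng):
        fit0 = fit_beta_moments(100 * rng.beta(2.5, 4.0, size=500))
        sample = 100 * sps.beta.rvs(fit0.a, fit0.b, size=10_000, random_state=rng)
        fit1 = fit_beta_moments(sample)
        assert fit1.a == pytest.approx(fit0.a, rel=0.10)
        assert fit1.b == pytest.approx(fit0.b, rel=0.10)

    def test_impossible_moments_raise(self):
        # variance of {0, 100} exceeds m(1-m) after clamping
        with pytest.raises(FitError):
            fit_beta_moments([0.0, 100.0, 0.0, 100.0])

    def test_to_percent_clamps_open_support(self):
        out = to_percent([0.0, 5.0, 10.0])
        assert out[0] == 0.01 and out[-1] == pytest.approx(99.99)


class TestBootstrapJoint:
    def test_exactly_n_rows(self):
        fit = fit_beta_moments([20.0, 40.0, 60.0, 80.0, 35.0, 55.0])
        m = bootstrap_joint(fit, fit, CouplingSpec("independent"), n=10_000, seed=0)
        assert m.bootstrap_samples.shape == (10_000, 2)

    def test_independent_coupling_has_null_rank_correlation(self):
        fit = fit_beta_moments([20.0, 40.0, 60.0, 80.0, 35.0, 55.0])
        m = bootstrap_joint(fit, fit, CouplingSpec("independent"), n=10_000, seed=1)
        assert abs(m.rank_correlation) < 0.03

    def test_copula_rank_correlation_matches_request(self):
        fit = fit_beta_moments([20.0, 40.0, 60.0, 80.0, 35.0, 55.0])
        m = bootstrap_joint(fit, fit, CouplingSpec("gaussian_copula", -0.6), n=10_000, seed=2)
        assert m.rank_correlation == pytest.approx(-0.6, abs=0.03)

    def test_marginals_within_ks_distance_of_fitted_betas(self):
        clay = fit_beta_moments([20.0, 40.0, 60.0, 80.0, 35.0, 55.0])
        wood = fit_beta_moments([10.0, 30.0, 25.0, 45.0, 15.0, 38.0])
        m = bootstrap_joint(clay, wood, CouplingSpec("gaussian_copula", -0.5), n=10_000, seed=3)
        for col, fit in ((0, clay), (1, wood)):
            d = sps.kstest(m.bootstrap_samples[:, col] / 100.0, sps.beta(fit.a, fit.b).cdf).statistic
            assert d < 0.02

    def test_bootstrap_mean_within_3se_of_beta_mean(self):
        fit = fit_beta_moments([20.0, 40.0, 60.0, 80.0, 35.0, 55.0])
        m = bootstrap_joint(fit, fit, CouplingSpec("independent"), n=10_000, seed=4)
        beta_sd = 100 * sps.beta(fit.a, fit.b).std()
        se = beta_sd / np.sqrt(10_000)
        assert abs(m.bootstrap_samples[:, 0].mean() - fit.mean_percent) < 3 * se

    def test_n_below_minimum_rejected(self):
        fit = fit_beta_moments([20.0, 40.0, 60.0])
        with pytest.raises(ValueError):
            bootstrap_joint(fit, fit, CouplingSpec("independent"), n=50)


class TestKurtosis:
    def _model(self, samples):
        fit = fit_beta_moments([20.0, 40.0, 60.0, 80.0])
        from claysub.stats import JointDistributionModel

        s = np.asarray(samples)
        centred = s - s.mean(axis=0)
        cov = np.cov(s, rowvar=False)
        maha2 = np.einsum("ij,jk,ik->i", centred, np.linalg.inv(cov), centred)
        return JointDistributionModel(
            marginal_clay=fit,
            marginal_wood=fit,
            coupling=CouplingSpec("independent"),
            bootstrap_samples=s,
            excess_kurtosis=tuple(
                float(sps.kurtosis(s[:, j], fisher=True, bias=False)) for j in (0, 1)
            ),
            joint_excess_kurtosis=float(np.mean(maha2**2) - 8.0),
            rank_correlation=0.0,
        )

    def test_flat_vs_peaked_flags_platykurtic(self, rng):
        flat = self._model(100 * rng.random((5000, 2)))
        peaked = self._model(np.clip(50 + 2 * rng.standard_normal((5000, 2)), 0, 100))
        report = compare_kurtosis(flat, peaked)
        assert report.loaded_more_platykurtic
        assert all(d < 0 for d in report.margin_difference)

    def test_identical_samples_have_zero_difference(self, rng):
        s = 100 * rng.random((2000, 2))
        report = compare_kurtosis(self._model(s), self._model(s))
        assert report.joint_difference == 0.0
        assert report.margin_difference == (0.0, 0.0)

    def test_normal_draws_have_near_zero_excess_kurtosis(self, rng):
        n = 20_000
        s = np.clip(50 + 3 * rng.standard_normal((n, 2)), 0, 100)
        m = self._model(s)
        se = np.sqrt(24 / n)  # SE of excess kurtosis under normality
        assert abs(m.excess_kurtosis[0]) < 3 * se
        assert abs(m.excess_kurtosis[1]) < 3 * se
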