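import numpy as np
import pytest
from scipy import stats

from firthgee import (
    CovariateSpec,
    ScenarioConfig,
    calibrate_intercept,
    detect_separation,
    fit_auggee1,
    fit_gee,
    generate_dataset,
    make_dental_fixture,
)
from firthgee.simulate import (
    CLUSTER_SIZE_PARAMS,
    generate_covariates,
    generate_outcomes,
    sample_cluster_sizes,
)


class TestClusterSizes:
    @pytest.mark.parametrize("tag", ["small", "moderate", "large"])
    def test_within_bounds_and_near_mean(self, rng, tag):
        mean, lo, hi = CLUSTER_SIZE_PARAMS[tag]
        cfg = ScenarioConfig(n_clusters=20000, cluster_size=tag)
        sizes = sample_cluster_sizes(cfg, rng)
        assert sizes.min() >= lo and sizes.max() <= hi
        # truncation barely moves the mean for these parameter choices
        assert abs(sizes.mean() - mean) < 0.5


class TestCovariates:
    def test_between_cluster_constancy_and_marginals(self, rng):
        spec = CovariateSpec()
        sizes = np.full(4000, 5)
        X = generate_covariates(4000, sizes, spec, rng)
        ids = np.repeat(np.arange(4000), sizes)
        for j in (0, 1):  # X1, X2 constant within cluster
            per = [np.ptp(X[ids == i, j]) for i in range(50)]
            assert np.allclose(per, 0.0)
        # within-cluster covariates actually vary
        assert any(np.ptp(X[ids == i, 4]) > 0 for i in range(50))
        prev = X[:, :3].mean(axis=0)
        assert np.allclose(prev, spec.prevalences, atol=0.03)
        assert set(np.unique(X[:, 3])) <= {0.0, 1.0, 2.0, 3.0}

    def test_winsorization_bound_respected(self, rng):
        spec = CovariateSpec()
        sizes = np.full(20000, 2)
        X = generate_covariates(20000, sizes, spec, rng)
        lo, hi = spec.x5_bounds
        assert X[:, 4].max() <= hi + 1e-12
        assert X[:, 4].min() >= max(lo, 0.0) - 1e-12


class TestInterceptCalibration:
    def test_zero_slopes_closed_form(self, rng):
        b0 = calibrate_intercept(np.zeros(5), CovariateSpec(), 0.3, rng)
        assert b0 == pytest.approx(np.log(0.3 / 0.7), abs=1e-3)

    def test_monotone_in_target(self, rng):
        spec = CovariateSpec()
        slopes = ScenarioConfig().slopes
        b_low = calibrate_intercept(slopes, spec, 0.1, rng, n_mc=100_000)
        b_high = calibrate_intercept(slopes, spec, 0.3, rng, n_mc=100_000)
        assert b_low < b_high

    def test_achieved_marginal_rate(self, rng):
        cfg = ScenarioConfig(n_clusters=20000, event_rate=0.1)
        cfg.beta0 = calibrate_intercept(cfg.slopes, cfg.covariates, 0.1, rng)
        data, beta, pi = generate_dataset(cfg, rng)
        assert data.y.mean() == pytest.approx(0.1, abs=0.01)
        assert pi.mean() == pytest.approx(0.1, abs=0.005)


class TestOutcomes:
    def _resid_corr(self, data, pi):
        e = (data.y - pi) / np.sqrt(pi * (1 - pi))
        num = den = 0.0
        for sl, n in zip(data.cluster_slices, data.n_i):
            if n < 2:
                continue
            es = e[sl]
            num += es.sum() ** 2 - (es**2).sum()
            den += n * (n - 1)
        return num / den

    def test_zero_latent_correlation_gives_independence(self, rng):
        cfg = ScenarioConfig(n_clusters=20000, latent_corr=0.0, event_rate=0.3)
        cfg.beta0 = calibrate_intercept(cfg.slopes, cfg.covariates, 0.3, rng)
        data, _, pi = generate_dataset(cfg, rng)
        assert abs(self._resid_corr(data, pi)) < 0.02

    def test_comonotone_limit_identical_outcomes(self, rng):
        X = np.ones((30, 2))
        X[:, 1] = 0.7  # identical covariate rows
        sizes = np.full(10, 3)
        y = generate_outcomes(X, np.array([0.0, 0.5]), sizes, 1.0, rng)
        for i in range(10):
            assert np.ptp(y[3 * i: 3 * i + 3]) == 0.0

    def test_marginal_probability_exact(self, rng):
        """P(Y=1|x) = expit(x beta) holds exactly under the latent-threshold
        construction, whatever the latent correlation."""
        n = 200_000
        X = np.column_stack([np.ones(n), rng.standard_normal(n)])
        sizes = np.full(n // 4, 4)
        beta = np.array([-1.0, 0.8])
        y = generate_outcomes(X, beta, sizes, 0.9, rng)
        pi = 1 / (1 + np.exp(-(X @ beta)))
        assert y.mean() == pytest.approx(pi.mean(), abs=0.005)

    def test_same_seed_bit_identical(self):
        cfg = ScenarioConfig(n_clusters=50)
        cfg.beta0 = -3.0
        d1, _, _ = generate_dataset(cfg, np.random.default_rng(77))
        d2, _, _ = generate_dataset(cfg, np.random.default_rng(77))
        assert np.array_equal(d1.y, d2.y) and np.array_equal(d1.X, d2.X)


class TestDetectSeparation:
    def test_quasi_complete_toy(self):
        X = np.column_stack([np.ones(4), [0.0, 0, 1, 1]])
        y = np.array([0.0, 0, 1, 1])
        sep, gamma = detect_separation(X, y)
        assert sep and gamma is not None

    def test_balanced_table_not_separable(self):
        X = np.column_stack([np.ones(8), [0.0, 0, 0, 0, 1, 1, 1, 1]])
        y = np.array([0.0, 1, 0, 1, 0, 1, 0, 1])
        sep, gamma = detect_separation(X, y)
        assert not sep and gamma is None

    def test_rare_covariate_with_no_events(self):
        rng = np.random.default_rng(1)
        n = 100
        rare = (np.arange(n) < 8).astype(float)
        X = np.column_stack([np.ones(n), rare, rng.standard_normal(n)])
        y = (rng.random(n) < 0.3).astype(float)
        y[rare == 1] = 0.0
        assert detect_separation(X, y)[0]


class TestDentalFixture:
    def test_structure_and_behavior(self):
        d = make_dental_fixture()
        assert d.N == 134
        assert d.n_obs == 533
        assert 0.02 < d.y.mean() < 0.09
        assert d.X[:, 4].sum() == 24  # rare covariate rows
        assert d.y[d.X[:, 4] == 1].sum() == 0
        assert detect_separation(d.X, d.y)[0]
        gee = fit_gee(d, "exchangeable")
        assert not gee.converged
        aug = fit_auggee1(d, "exchangeable")
        assert aug.converged
        assert np.all(np.isfinite(aug.beta))
        assert abs(aug.beta[4]) < 10

    def test_deterministic(self):
        d1, d2 = make_dental_fixture(), make_dental_fixture()
        assert np.array_equal(d1.y, d2.y) and np.array_equal(d1.X, d2.X)
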