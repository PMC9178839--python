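import numpy as np
import pytest
import statsmodels.api as sm

from firthgee import (
    ClusteredDataset,
    GEE,
    estimate_alpha,
    fit_gee,
    gee_score,
    working_matrix,
)
from tests.conftest import make_clustered


def _dataset(ids, y, X, weights=None):
    return ClusteredDataset(
        cluster_ids=np.asarray(ids), y=np.asarray(y, float),
        X=np.asarray(X, float), weights=weights,
    )


class TestScore:
    def test_independent_score_is_weighted_logistic_score(self, rng):
        d = make_clustered(rng, weights=None)
        w = rng.uniform(0.5, 2.0, size=d.n_obs)
        d = ClusteredDataset(cluster_ids=d.cluster_ids, y=d.y, X=d.X, weights=w)
        beta = np.array([0.1, -0.2, 0.3])
        U, _ = gee_score(beta, None, d, "independent")
        pi = 1 / (1 + np.exp(-(d.X @ beta)))
        assert np.allclose(U, d.X.T @ (d.weights * (d.y - pi)), atol=1e-10)

    def test_zero_at_solution(self, rng):
        d = make_clustered(rng)
        fit = fit_gee(d, "independent", tol=1e-10, max_iter=100)
        U, _ = gee_score(fit.beta, None, d, "independent")
        assert np.max(np.abs(U)) < 1e-6

    def test_two_obs_cluster_exchangeable_hand_computation(self):
        """Single 2-observation cluster: U from an explicit 2x2 inversion."""
        X = np.array([[1.0, 0.5], [1.0, -1.0]])
        y = np.array([1.0, 0.0])
        d = _dataset([1, 1], y, X)
        beta = np.array([0.2, 0.4])
        alpha = 0.5
        U, I = gee_score(beta, alpha, d, "exchangeable")
        pi = 1 / (1 + np.exp(-(X @ beta)))
        W = np.diag(pi * (1 - pi))
        R = working_matrix("exchangeable", alpha, 2)
        V = np.sqrt(W) @ R @ np.sqrt(W)
        U_hand = X.T @ W @ np.linalg.inv(V) @ (y - pi)
        I_hand = X.T @ W @ np.linalg.inv(V) @ W @ X
        assert np.allclose(U, U_hand, atol=1e-12)
        assert np.allclose(I, I_hand, atol=1e-12)


class TestAlphaMoment:
    """Residuals are (y - pi)/sqrt(pi(1-pi)); with an intercept-only model at
    beta = 0 they are exactly +/-1, so the printed formula can be checked
    directly."""

    def test_perfectly_correlated_pair(self):
        d = _dataset([1, 1], [1, 1], np.ones((2, 1)))
        assert estimate_alpha(d, np.zeros(1), "exchangeable") == pytest.approx(1.0)

    def test_perfectly_anticorrelated_pair(self):
        d = _dataset([1, 1], [1, 0], np.ones((2, 1)))
        assert estimate_alpha(d, np.zeros(1), "exchangeable") == pytest.approx(-1.0)

    def test_balanced_clusters_average_to_zero(self):
        d = _dataset([1, 1, 2, 2], [1, 1, 1, 0], np.ones((4, 1)))
        assert estimate_alpha(d, np.zeros(1), "exchangeable") == pytest.approx(0.0)

    def test_singleton_clusters_excluded(self):
        d = _dataset([1, 1, 2], [1, 1, 0], np.ones((3, 1)))
        assert estimate_alpha(d, np.zeros(1), "exchangeable") == pytest.approx(1.0)

    def test_all_singletons_errors(self):
        d = _dataset([1, 2], [1, 0], np.ones((2, 1)))
        with pytest.raises(ValueError, match="independent"):
            estimate_alpha(d, np.zeros(1), "exchangeable")

    def test_ar1_uses_lag_one_products(self):
        # residuals (+1, -1, +1): lag-1 products (-1, -1) -> alpha = -1
        d = _dataset([1, 1, 1], [1, 0, 1], np.ones((3, 1)))
        assert estimate_alpha(d, np.zeros(1), "ar1") == pytest.approx(-1.0)


class TestFitGEE:
    def test_independent_equals_ml(self, small_data):
        fit = fit_gee(small_data, "independent", tol=1e-8, max_iter=100)
        ml = sm.GLM(small_data.y, small_data.X, family=sm.families.Binomial()).fit()
        assert np.allclose(fit.beta, ml.params, atol=1e-6)
        assert fit.converged

    def test_separated_data_not_converged(self, separated_data):
        fit = fit_gee(separated_data, "exchangeable")
        assert not fit.converged
        assert fit.reason

    def test_cluster_permutation_invariance(self, rng):
        d = make_clustered(rng, n_clusters=10)
        perm = rng.permutation(10)
        # relabel clusters so their order of appearance changes
        order = np.argsort([list(perm).index(c) for c in d.cluster_ids], kind="stable")
        d2 = ClusteredDataset(
            cluster_ids=d.cluster_ids[order], y=d.y[order], X=d.X[order]
        )
        f1 = fit_gee(d, "exchangeable", tol=1e-8, max_iter=100)
        f2 = fit_gee(d2, "exchangeable", tol=1e-8, max_iter=100)
        assert np.allclose(f1.beta, f2.beta, atol=1e-8)
        assert f1.alpha == pytest.approx(f2.alpha, abs=1e-10)

    def test_alpha_recovery_exchangeable(self):
        """On a large simulated exchangeable sample the moment estimate lands
        near the empirical outcome correlation."""
        rng = np.random.default_rng(99)
        d = make_clustered(rng, n_clusters=400, size_range=(4, 4), p=1,
                           within_corr=0.6)
        fit = fit_gee(d, "exchangeable")
        assert fit.converged
        assert 0.1 < fit.alpha < 0.6  # achieved binary corr < latent 0.6

    def test_estimator_class_sklearn_surface(self, rng):
        d = make_clustered(rng)
        est = GEE(corstr="exchangeable")
        est.fit(d.X[:, 1:], d.y, clusters=d.cluster_ids)
        assert est.coef_.shape == (2,)
        assert np.isfinite(est.intercept_)
        assert est.cov_morel_.shape == (3, 3)
        ci = est.conf_int()
        assert np.all(ci.lower < ci.upper)
        params = est.get_params()
        assert params["corstr"] == "exchangeable"
        # clone-ability via get/set params
        est2 = GEE(**params)
        est2.fit(d.X[:, 1:], d.y, clusters=d.cluster_ids)
        assert np.allclose(est.params_, est2.params_)

    def test_singleton_clusters_handled_in_beta_update(self, rng):
        d = make_clustered(rng, n_clusters=20, size_range=(1, 3))
        assert (d.n_i == 1).any()
        fit = fit_gee(d, "exchangeable")
        assert np.all(np.isfinite(fit.beta))
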