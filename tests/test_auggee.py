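import numpy as np
import pytest
from scipy.linalg import sqrtm

from firthgee import (
    AugmentedGEE,
    ClusteredDataset,
    SingleStepAugmentedGEE,
    build_augmented,
    fit_auggee,
    fit_auggee1,
    fit_firth,
    fit_gee,
    generalized_hat,
    hat_diagonals,
    working_matrix,
)
from tests.conftest import make_clustered


class TestGeneralizedHat:
    def test_independent_reduces_to_ordinary_hat(self, small_data):
        beta = np.array([0.2, -0.3, 0.4])
        gh = generalized_hat(beta, None, small_data, "independent")
        pi = 1 / (1 + np.exp(-(small_data.X @ beta)))
        assert np.allclose(gh.diagonals, hat_diagonals(small_data.X, pi), atol=1e-10)

    @pytest.mark.parametrize("structure,alpha", [
        ("exchangeable", 0.5),
        ("exchangeable", -0.1),
        ("ar1", 0.7),
        ("independent", None),
    ])
    def test_trace_is_number_of_parameters(self, rng, structure, alpha):
        d = make_clustered(rng, n_clusters=7, size_range=(1, 5), p=3)
        beta = rng.normal(scale=0.5, size=d.X.shape[1])
        gh = generalized_hat(beta, alpha, d, structure)
        assert gh.trace == pytest.approx(d.X.shape[1], abs=1e-8)
        assert np.all((gh.diagonals >= -1e-12) & (gh.diagonals <= 1 + 1e-12))

    def test_two_obs_single_cluster_hand_computed(self):
        """Direct matrix oracle: Omega^{1/2} X (X'Omega X)^{-1} X' Omega^{1/2}
        assembled with scipy.linalg.sqrtm."""
        X = np.array([[1.0, 0.4], [1.0, -0.8]])
        y = np.array([1.0, 0.0])
        d = ClusteredDataset(cluster_ids=np.array([1, 1]), y=y, X=X)
        beta = np.array([0.3, 0.5])
        alpha = 0.5
        pi = 1 / (1 + np.exp(-(X @ beta)))
        W12 = np.diag(np.sqrt(pi * (1 - pi)))
        Rinv = np.linalg.inv(working_matrix("exchangeable", alpha, 2))
        Omega = W12 @ Rinv @ W12
        O12 = np.real(sqrtm(Omega))
        H = O12 @ X @ np.linalg.inv(X.T @ Omega @ X) @ X.T @ O12
        gh = generalized_hat(beta, alpha, d, "exchangeable")
        assert np.allclose(gh.blocks[0], H, atol=1e-10)
        assert np.allclose(gh.diagonals, np.diag(H), atol=1e-10)


class TestBuildAugmented:
    def test_counts_weights_and_flip(self, rng):
        d = make_clustered(rng, n_clusters=2, size_range=(3, 3), p=2)
        fl = fit_firth(d.X, d.y)
        aug = build_augmented(d, fl.hat)
        assert aug.data.N == 6
        assert aug.data.n_obs == 18
        # pseudo-observation total weight = p + 1
        assert aug.data.weights[6:].sum() == pytest.approx(d.X.shape[1], abs=1e-8)
        # copy 2 keeps the outcome, copy 3 flips it; flipping twice restores
        y0 = aug.data.y[:6]
        assert np.array_equal(aug.data.y[6:12], y0)
        assert np.array_equal(1 - aug.data.y[12:], y0)

    def test_zero_leverage_rows_carry_zero_weight(self, rng):
        d = make_clustered(rng, n_clusters=2, size_range=(2, 2), p=1)
        h = np.array([0.0, 0.3, 0.2, 0.0])
        aug = build_augmented(d, h)
        w = aug.data.weights
        assert w[4] == 0.0 and w[8] == 0.0

    def test_merged_pseudo_cluster_variant(self, rng):
        d = make_clustered(rng, n_clusters=3, size_range=(2, 2), p=1)
        aug = build_augmented(d, np.full(d.n_obs, 0.1), pseudo_clusters="N")
        assert aug.data.N == 3
        assert np.array_equal(aug.data.n_i, 3 * d.n_i)


class TestFitAugGEE:
    def test_independent_equals_firth(self, small_data):
        fl = fit_firth(small_data.X, small_data.y)
        for fit in (fit_auggee(small_data, "independent"),
                    fit_auggee1(small_data, "independent")):
            assert np.max(np.abs(fit.beta - fl.beta)) < 1e-4
            assert fit.converged

    def test_single_step_is_composition_of_public_pieces(self, small_data):
        """augGEE1 = Firth fit -> ordinary-hat augmentation -> one weighted
        GEE solve warm-started at the Firth estimate."""
        fl = fit_firth(small_data.X, small_data.y)
        aug = build_augmented(small_data, fl.hat)
        manual = fit_gee(aug.data, "exchangeable", beta0=fl.beta, alpha0=0.0)
        fit = fit_auggee1(small_data, "exchangeable")
        assert np.allclose(fit.beta, manual.beta, atol=1e-12)
        assert fit.alpha == pytest.approx(manual.alpha, abs=1e-12)

    def test_separated_exchangeable_finite(self, separated_data):
        for fit in (fit_auggee(separated_data, "exchangeable"),
                    fit_auggee1(separated_data, "exchangeable")):
            assert np.all(np.isfinite(fit.beta))
            assert abs(fit.beta[1]) < 10

    def test_rescaling_covariate_rescales_estimate_and_se(self, small_data):
        d = small_data
        X2 = d.X.copy()
        X2[:, 2] *= 10
        d2 = ClusteredDataset(cluster_ids=d.cluster_ids, y=d.y, X=X2)
        f1 = fit_auggee1(d, "exchangeable")
        f2 = fit_auggee1(d2, "exchangeable")
        assert f1.beta[2] / f2.beta[2] == pytest.approx(10.0, rel=1e-6)
        se1 = np.sqrt(np.diag(f1.cov_morel))
        se2 = np.sqrt(np.diag(f2.cov_morel))
        assert se1[2] / se2[2] == pytest.approx(10.0, rel=1e-6)

    def test_auggee1_independent_never_fails(self, separated_data):
        fit = fit_auggee1(separated_data, "independent")
        assert fit.converged
        assert np.all(np.isfinite(fit.beta))

    def test_consistency_pseudo_weight_becomes_negligible(self):
        """|E[beta1_hat] - truth| shrinks as the number of clusters grows:
        the pseudo observations keep total weight p+1 while the data grow."""
        beta_true = np.array([-0.3, 0.6, 0.6])
        errs = []
        for N in (20, 160):
            ests = []
            rng = np.random.default_rng(42)
            for _ in range(30):
                d = make_clustered(rng, n_clusters=N, size_range=(3, 4), p=2,
                                   beta=beta_true)
                ests.append(fit_auggee1(d, "exchangeable").beta[1])
            errs.append(abs(np.mean(ests) - beta_true[1]))
        assert errs[1] < errs[0] + 0.05

    def test_estimator_classes(self, small_data):
        d = small_data
        for cls, fn in ((AugmentedGEE, fit_auggee), (SingleStepAugmentedGEE, fit_auggee1)):
            est = cls(corstr="exchangeable")
            est.fit(d.X[:, 1:], d.y, clusters=d.cluster_ids)
            assert np.allclose(est.params_, fn(d, "exchangeable").beta)
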