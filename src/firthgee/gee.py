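"""Ordinary weighted GEE for marginal logistic regression.

Solves sum_i X_i' Delta_i V_i^{-1} (y_i - pi_i) = 0 by alternating a moment
update of the working correlation parameter alpha with one Fisher-scoring
step for beta.  Under an independent working structure this reduces exactly
to (weighted) maximum-likelihood logistic regression.  The scale parameter
is fixed at 1 and Pearson residuals are not dispersion-rescaled.

A fit is flagged non-convergent when the max |delta beta| < tol criterion is
not met within ``max_iter`` iterations, when the estimated correlation
parameter leaves (-1, 1), or on any numerical failure; the solver never
raises on divergence.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from . import _core
from .data import ClusteredDataset, GEEFit
from .firth import ml_logistic
from .variance import confint, covariance_pair

__all__ = ["GEE", "fit_gee", "gee_score", "estimate_alpha"]


def gee_score(beta, alpha, data: ClusteredDataset, structure: str):
    """Estimating function U and model-based information I at (beta, alpha)."""
    groups = _core.ClusterGroups(data)
    bad = _core.check_alpha_admissible(structure, alpha, groups.n_max)
    if bad is not None:
        raise _core.SingularCorrelationError(bad)
    U, I, _ = _core.score_info(groups, np.asarray(beta, dtype=float), alpha, structure)
    return U, I


def estimate_alpha(data: ClusteredDataset, beta, structure: str):
    """Moment estimate of alpha from Pearson residuals at ``beta``."""
    if structure == "independent":
        raise ValueError("alpha is not defined for the independent structure")
    groups = _core.ClusterGroups(data)
    return _core.estimate_alpha(groups, np.asarray(beta, dtype=float), structure)


def _assemble_fit(data, res, method, n_outer, n_inner) -> GEEFit:
    """Attach sandwich/Morel covariances (always on the ORIGINAL data at the
    final estimates) and wrap the solver result into a GEEFit."""
    q = data.X.shape[1]
    cov_s = np.full((q, q), np.nan)
    cov_m = np.full((q, q), np.nan)
    try:
        cov_s, cov_m = covariance_pair(data, res.beta, res.alpha, res.structure)
    except (np.linalg.LinAlgError, ValueError, FloatingPointError):
        pass
    return GEEFit(
        beta=res.beta,
        alpha=res.alpha,
        converged=res.converged,
        n_outer=n_outer,
        n_inner=n_inner,
        cov_sandwich=cov_s,
        cov_morel=cov_m,
        fitted=res.fitted,
        method=method,
        reason=res.reason,
    )


def fit_gee(
    data: ClusteredDataset,
    structure: str = "exchangeable",
    beta0=None,
    alpha0=None,
    tol: float = 1e-3,
    max_iter: int = 30,
    alpha_fixed=None,
) -> GEEFit:
    """Fit ordinary GEE.  Default start: plain ML logistic regression on the
    pooled data (large but finite under separation)."""
    groups = _core.ClusterGroups(data)
    if beta0 is None:
        beta0, _ = ml_logistic(data.X, data.y, data.weights)
    res = _core.solve_gee(
        groups, structure, beta0, alpha0=alpha0, tol=tol, max_iter=max_iter,
        alpha_fixed=alpha_fixed,
    )
    res.structure = structure
    return _assemble_fit(data, res, "gee", res.n_iter, 0)


class _ClusteredRegressionBase(BaseEstimator):
    """Shared scikit-learn plumbing for the clustered marginal estimators.

    ``X`` passed to :meth:`fit` must not contain an intercept column; one is
    always added.  Cluster labels are passed to :meth:`fit` via ``clusters``
    (observations with the same label form a cluster); with ``clusters=None``
    every observation is its own cluster.
    """

    _method = "gee"

    def _build_dataset(self, X, y, clusters, sample_weight):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        n = X.shape[0]
        if clusters is None:
            clusters = np.arange(n)
        Xd = np.column_stack([np.ones(n), X])
        self.n_features_in_ = X.shape[1]
        return ClusteredDataset(cluster_ids=np.asarray(clusters), y=y, X=Xd,
                                weights=sample_weight)

    def _solve(self, data: ClusteredDataset) -> GEEFit:  # pragma: no cover
        raise NotImplementedError

    def fit(self, X, y, clusters=None, sample_weight=None):
        data = self._build_dataset(X, y, clusters, sample_weight)
        fit = self._solve(data)
        self._data_n_clusters = data.N
        self.params_ = fit.beta
        self.intercept_ = float(fit.beta[0])
        self.coef_ = fit.beta[1:]
        self.alpha_ = fit.alpha
        self.converged_ = fit.converged
        self.reason_ = fit.reason
        self.n_iter_ = fit.n_outer
        self.n_inner_ = fit.n_inner
        self.cov_sandwich_ = fit.cov_sandwich
        self.cov_morel_ = fit.cov_morel
        self.fitted_ = fit.fitted
        self.result_ = fit
        return self

    def predict_proba(self, X):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        p1 = _core.expit(self.intercept_ + X @ self.coef_)
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X):
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)

    def conf_int(self, level=0.95):
        """t-based confidence intervals from the Morel-corrected covariance
        (degrees of freedom = number of clusters)."""
        return confint(self.params_, self.cov_morel_, self._data_n_clusters, level=level)

    def standard_errors(self, corrected=True):
        cov = self.cov_morel_ if corrected else self.cov_sandwich_
        return np.sqrt(np.clip(np.diag(cov), 0.0, None))


class GEE(_ClusteredRegressionBase):
    """Ordinary GEE for a marginal logistic model on clustered binary data.

    Parameters
    ----------
    corstr : working correlation structure, one of
        {"independent", "exchangeable", "ar1", "unstructured"}.
    tol : convergence tolerance on max |delta beta| (default 0.001).
    max_iter : iteration cap (default 30).
    alpha_fixed : hold the working correlation parameter fixed at this value
        instead of estimating it by the method of moments.

    Attributes (after fit)
    ----------------------
    coef_, intercept_ : coefficient estimates (params_ stacks both,
        intercept first).
    alpha_ : working correlation parameter estimate.
    converged_ : bool; ``reason_`` holds the failure description.
    cov_sandwich_, cov_morel_ : robust and small-sample-corrected
        covariance of params_.
    fitted_ : marginal fitted probabilities per training observation.
    """

    _method = "gee"

    def __init__(self, corstr="exchangeable", tol=1e-3, max_iter=30, alpha_fixed=None):
        self.corstr = corstr
        self.tol = tol
        self.max_iter = max_iter
        self.alpha_fixed = alpha_fixed

    def _solve(self, data):
        return fit_gee(
            data, structure=self.corstr, tol=self.tol, max_iter=self.max_iter,
            alpha_fixed=self.alpha_fixed,
        )
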