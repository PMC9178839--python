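"""Firth's logistic regression (FL) for independent data.

FL maximizes the likelihood penalized by the Jeffreys invariant prior
|I(beta)|^{1/2}; on the score scale this adds
1/2 trace(I(beta)^{-1} dI(beta)/dbeta_m) to each score component, which keeps
all coefficient estimates finite even under separation and removes the
leading-order bias of maximum likelihood.

FL is also exactly maximum likelihood on an augmented, weighted dataset built
by stacking three copies of the data: the original rows with weight 1, a copy
with weight h_i/2, and a copy with the outcome flipped and weight h_i/2,
where h_i is the leverage (hat-matrix diagonal).  That representation is what
the augmented GEE estimators generalize to clustered data.

Within this package FL plays two roles: a stand-alone estimator for
independent data, and the supplier of starting values and hat diagonals to
every GEE method.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator

from .data import ClusteredDataset

__all__ = [
    "FirthFit",
    "AugmentedIndependent",
    "fit_firth",
    "hat_diagonals",
    "augment_independent",
    "FirthLogisticRegression",
    "ml_logistic",
]

_CLIP = 1e-10


def _expit(eta):
    with np.errstate(over="ignore"):
        pi = 1.0 / (1.0 + np.exp(-eta))
    return np.clip(pi, _CLIP, 1.0 - _CLIP)


@dataclass
class FirthFit:
    """Result of a Firth-penalized logistic regression fit."""

    beta: np.ndarray
    hat: np.ndarray
    se: np.ndarray
    penalized_loglik: float
    converged: bool
    n_iter: int
    fitted: np.ndarray


@dataclass
class AugmentedIndependent:
    """Augmented independent-data representation of FL: 3 N* rows with
    weights (1, h/2, h/2) and the outcome flipped in the third copy."""

    y: np.ndarray
    X: np.ndarray
    weights: np.ndarray
    source_index: np.ndarray


def _check_rank(X, weights):
    w = np.asarray(weights, dtype=float)
    Xw = X * np.sqrt(w)[:, None]
    rank = np.linalg.matrix_rank(Xw)
    if rank < X.shape[1]:
        # name a maximal independent set's complement as the offending columns
        _, R = np.linalg.qr(Xw)
        diag = np.abs(np.diag(R))
        bad = np.flatnonzero(diag < 1e-8 * max(diag.max(), 1.0))
        raise np.linalg.LinAlgError(
            f"design matrix is rank deficient (rank {rank} < {X.shape[1]}); "
            f"collinear column indices: {bad.tolist()}"
        )


def hat_diagonals(X, pi, weights=None):
    """Diagonal of H = W^{1/2} X (X'WX)^{-1} X'W^{1/2}, W = diag(w pi(1-pi)).

    h_i lies in [0, 1] and sums to the number of columns of X.
    """
    X = np.asarray(X, dtype=float)
    pi = np.asarray(pi, dtype=float)
    w = np.ones(len(pi)) if weights is None else np.asarray(weights, dtype=float)
    Wd = w * pi * (1.0 - pi)
    XtWX = X.T @ (Wd[:, None] * X)
    Xi = np.linalg.solve(XtWX, X.T)  # (q, n)
    return Wd * np.einsum("nq,qn->n", X, Xi)


def _penalized_loglik(X, y, w, beta):
    pi = _expit(X @ beta)
    ll = float(np.sum(w * (y * np.log(pi) + (1.0 - y) * np.log(1.0 - pi))))
    Wd = w * pi * (1.0 - pi)
    sign, logdet = np.linalg.slogdet(X.T @ (Wd[:, None] * X))
    if sign <= 0:
        return -np.inf
    return ll + 0.5 * logdet


def fit_firth(X, y, weights=None, tol=1e-6, max_iter=50):
    """Fit Firth's logistic regression by Newton-Raphson on the modified
    score with step-halving (up to 5 halvings whenever the penalized
    likelihood would decrease).

    ``X`` must include the intercept column.  Returns a :class:`FirthFit`
    with finite coefficients even for separable data.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, q = X.shape
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    _check_rank(X, w)
    beta = np.zeros(q)
    ll = _penalized_loglik(X, y, w, beta)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        pi = _expit(X @ beta)
        Wd = w * pi * (1.0 - pi)
        XtWX = X.T @ (Wd[:, None] * X)
        h = hat_diagonals(X, pi, w)
        score = X.T @ (w * (y - pi) + h * (0.5 - pi))
        try:
            delta = np.linalg.solve(XtWX, score)
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(f"singular X'WX: {exc}") from exc
        # step-halving keeps the penalized log-likelihood non-decreasing
        step = delta
        for _ in range(6):
            ll_new = _penalized_loglik(X, y, w, beta + step)
            if ll_new >= ll - 1e-12:
                break
            step = step / 2.0
        beta = beta + step
        ll = _penalized_loglik(X, y, w, beta)
        if np.max(np.abs(step)) < tol:
            converged = True
            break
    pi = _expit(X @ beta)
    h = hat_diagonals(X, pi, w)
    Wd = w * pi * (1.0 - pi)
    cov = np.linalg.inv(X.T @ (Wd[:, None] * X))
    return FirthFit(
        beta=beta,
        hat=h,
        se=np.sqrt(np.diag(cov)),
        penalized_loglik=ll,
        converged=converged,
        n_iter=it,
        fitted=pi,
    )


def augment_independent(data: ClusteredDataset, fit: FirthFit) -> AugmentedIndependent:
    """Stack three copies of the data: originals (weight w), a copy with
    weight w*...; here the classic FL weights (1, h/2, h/2) with the outcome
    flipped in the third copy.  Maximum likelihood on this augmented data
    (iterating the hat updates) reproduces the FL estimate."""
    y, X, h = data.y, data.X, fit.hat
    aug_y = np.concatenate([y, y, 1.0 - y])
    aug_X = np.vstack([X, X, X])
    aug_w = np.concatenate([data.weights, h / 2.0, h / 2.0])
    src = np.tile(np.arange(data.n_obs), 3)
    return AugmentedIndependent(y=aug_y, X=aug_X, weights=aug_w, source_index=src)


def ml_logistic(X, y, weights=None, tol=1e-8, max_iter=25):
    """Plain maximum-likelihood logistic regression by IRLS.

    Deliberately tolerant: it stops after ``max_iter`` iterations without
    raising even when the data are separable (coefficients are then large
    but finite), mimicking the default behaviour of standard GLM fitters.
    Used as the penalty-agnostic default start for ordinary GEE.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, q = X.shape
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    beta = np.zeros(q)
    converged = False
    for _ in range(max_iter):
        pi = _expit(X @ beta)
        Wd = w * pi * (1.0 - pi)
        score = X.T @ (w * (y - pi))
        XtWX = X.T @ (Wd[:, None] * X)
        delta, *_ = np.linalg.lstsq(XtWX, score, rcond=None)
        beta = beta + delta
        if not np.all(np.isfinite(beta)):
            beta = np.nan_to_num(beta, nan=0.0, posinf=0.0, neginf=0.0)
            break
        if np.max(np.abs(delta)) < tol:
            converged = True
            break
    return beta, converged


class FirthLogisticRegression(BaseEstimator):
    """Firth-penalized logistic regression (independent observations).

    scikit-learn style estimator.  ``X`` passed to :meth:`fit` must NOT
    contain an intercept column; one is always added.

    Parameters
    ----------
    tol : convergence tolerance on max |delta beta| (default 1e-6).
    max_iter : Newton-Raphson iteration cap (default 50).

    Attributes
    ----------
    coef_ : slope estimates, shape (p,).
    intercept_ : intercept estimate.
    hat_ : per-observation leverage h_i.
    se_ : approximate standard errors from (X'WX)^{-1}, intercept first.
    penalized_loglik_ : maximized Jeffreys-penalized log-likelihood.
    converged_ : bool.
    """

    def __init__(self, tol=1e-6, max_iter=50):
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X, y, sample_weight=None):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        Xd = np.column_stack([np.ones(X.shape[0]), X])
        res = fit_firth(Xd, y, weights=sample_weight, tol=self.tol, max_iter=self.max_iter)
        self.params_ = res.beta
        self.intercept_ = float(res.beta[0])
        self.coef_ = res.beta[1:]
        self.hat_ = res.hat
        self.se_ = res.se
        self.penalized_loglik_ = res.penalized_loglik
        self.converged_ = res.converged
        self.n_iter_ = res.n_iter
        self.n_features_in_ = X.shape[1]
        return self

    def predict_proba(self, X):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        p1 = _expit(self.intercept_ + X @ self.coef_)
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X):
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)
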