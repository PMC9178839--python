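"""Penalized GEE: Firth-type modification of the estimating function.

The GEE are treated as score equations and modified as in Firth's logistic
regression: U*(beta, alpha) = U(beta, alpha)
+ 1/2 trace(I(beta, alpha)^{-1} dI(beta, alpha)/dbeta) = 0, with
I(beta, alpha) = -E(dU/dbeta) the model-based information.  The derivative of
I is taken analytically with alpha held fixed (only the variance weights W_i
depend on beta, through d[pi(1-pi)]/dbeta_m = pi(1-pi)(1-2pi) x_m).

Fitting alternates (i) a moment update of alpha from the unpenalized Pearson
residuals with (ii) one penalized Newton step
beta^{k+1} = beta^k + I(beta^k, alpha^k)^{-1} U*(beta^k, alpha^k); note the
beta step uses the alpha from the previous iteration (the algorithm's printed
form), starting from the Firth-logistic estimate with an identity working
matrix.  Under an independent working structure the penalty equals the
classic Firth term exactly, so penalized GEE reproduces Firth's logistic
regression.  Finite estimates are NOT guaranteed under separation for
non-independent structures, unlike for Firth's logistic regression itself.
"""

from __future__ import annotations

import numpy as np

from . import _core
from .data import ClusteredDataset, GEEFit
from .firth import fit_firth
from .gee import _assemble_fit, _ClusteredRegressionBase

__all__ = ["PenalizedGEE", "fit_pengee", "information_derivative", "penalty_vector"]


def information_derivative(beta, alpha, data: ClusteredDataset, structure: str):
    """Analytic derivative of I(beta, alpha) = sum_i X_i' W_i^{1/2}
    R_i(alpha)^{-1} W_i^{1/2} X_i with respect to each beta_m (alpha fixed).

    Returns an array of shape (p+1, p+1, p+1); entry [m] is dI/dbeta_m.
    Used mainly for validation — the solver computes the penalty
    trace(I^{-1} dI/dbeta_m) without materializing these matrices.
    """
    beta = np.asarray(beta, dtype=float)
    q = data.X.shape[1]
    out = np.zeros((q, q, q))
    groups = _core.ClusterGroups(data)
    for g in groups.groups:
        pi = _core.expit(g.X @ beta)
        s = np.sqrt(g.w * pi * (1.0 - pi))
        # d s_j / d beta_m = 1/2 s_j (1 - 2 pi_j) x_jm
        ds = 0.5 * s[..., None] * (1.0 - 2.0 * pi)[..., None] * g.X  # (m_c, n, q)
        K = s[..., None] * g.X
        QK = _core.apply_rinv(structure, alpha, K)
        for m in range(q):
            Km = ds[:, :, m][..., None] * g.X
            term = np.einsum("cnq,cnr->qr", Km, QK)  # (S'X)' Q (SX)
            out[m] += term + term.T
    return out


def penalty_vector(beta, alpha, data: ClusteredDataset, structure: str):
    """The Firth-type penalty 1/2 trace(I^{-1} dI/dbeta_m), one entry per
    coefficient.  Under independence it equals 1/2 sum_i h_i (1-2 pi_i) x_im."""
    groups = _core.ClusterGroups(data)
    _, _, pen = _core.score_info(
        groups, np.asarray(beta, dtype=float), alpha, structure, penalized=True
    )
    return pen


def fit_pengee(
    data: ClusteredDataset,
    structure: str = "exchangeable",
    tol: float = 1e-3,
    max_iter: int = 20,
    alpha_fixed=None,
) -> GEEFit:
    """Fit penalized GEE, starting from the Firth-logistic estimate (identity
    working correlation).  Returns ``converged=False`` with a reason instead
    of raising on divergence."""
    groups = _core.ClusterGroups(data)
    fl = fit_firth(data.X, data.y, data.weights)
    res = _core.solve_gee(
        groups, structure, fl.beta, alpha0=0.0 if structure != "independent" else None,
        tol=tol, max_iter=max_iter, penalized=True, alpha_fixed=alpha_fixed,
        lag_alpha=True,
    )
    res.structure = structure
    return _assemble_fit(data, res, "pengee", res.n_iter, 0)


class PenalizedGEE(_ClusteredRegressionBase):
    """Firth-type penalized GEE (see module docstring).

    Parameters as for :class:`firthgee.GEE`; the outer iteration cap defaults
    to 20.  With ``corstr="independent"`` the estimates coincide with
    :class:`firthgee.FirthLogisticRegression`.
    """

    _method = "pengee"

    def __init__(self, corstr="exchangeable", tol=1e-3, max_iter=20, alpha_fixed=None):
        self.corstr = corstr
        self.tol = tol
        self.max_iter = max_iter
        self.alpha_fixed = alpha_fixed

    def _solve(self, data):
        return fit_pengee(
            data, structure=self.corstr, tol=self.tol, max_iter=self.max_iter,
            alpha_fixed=self.alpha_fixed,
        )
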