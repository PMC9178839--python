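"""Vectorized per-cluster linear algebra shared by the GEE-type solvers.

Clusters are grouped by size so that all per-cluster operations run as batched
3-d array operations.  The weighted-GEE dialect throughout treats observation
weights as scale factors (the working variance of an observation is
pi(1-pi)/w), so the estimating function reduces to the weighted logistic score
under an independent working structure.
"""

from __future__ import annotations

from types import SimpleNamespace

import numpy as np

from .data import ClusteredDataset, SingularCorrelationError, working_matrix

PI_CLIP = 1e-10


def expit(eta):
    """Logistic mean function, clipped away from {0, 1} for numerical safety."""
    with np.errstate(over="ignore"):
        pi = 1.0 / (1.0 + np.exp(-eta))
    return np.clip(pi, PI_CLIP, 1.0 - PI_CLIP)


class ClusterGroups:
    """Clusters of a :class:`ClusteredDataset` grouped by size.

    Each group holds stacked arrays ``X`` (m, n, q), ``y`` (m, n), ``w``
    (m, n), the original cluster indices and the original row indices, so
    per-observation quantities can be scattered back to file order.
    """

    def __init__(self, data: ClusteredDataset):
        self.q = data.X.shape[1]
        self.n_obs = data.n_obs
        self.N = data.N
        self.n_max = int(data.n_i.max())
        starts = np.concatenate([[0], np.cumsum(data.n_i)[:-1]])
        self.groups = []
        for n in np.unique(data.n_i):
            cl = np.flatnonzero(data.n_i == n)
            rows = starts[cl][:, None] + np.arange(n)[None, :]
            self.groups.append(
                SimpleNamespace(
                    n=int(n),
                    clusters=cl,
                    rows=rows,
                    X=data.X[rows],
                    y=data.y[rows],
                    w=data.weights[rows],
                )
            )

    def scatter_obs(self, values_per_group):
        """Assemble per-observation values (list aligned with groups) back
        into original row order."""
        out = np.empty(self.n_obs)
        for g, v in zip(self.groups, values_per_group):
            out[g.rows] = v
        return out


# ---------------------------------------------------------------------------
# working correlation helpers

def check_alpha_admissible(structure, alpha, n_max):
    """Return None if R(alpha) is invertible for every cluster size up to
    n_max, else a human-readable reason."""
    if structure == "independent" or alpha is None:
        return None
    if structure == "exchangeable":
        a = float(alpha)
        if not np.isfinite(a):
            return "correlation parameter is not finite"
        if a >= 1.0 or (n_max > 1 and 1.0 + (n_max - 1) * a <= 0.0):
            return f"exchangeable correlation {a:.4g} makes R singular"
    elif structure == "ar1":
        a = float(alpha)
        if not np.isfinite(a) or abs(a) >= 1.0:
            return f"AR(1) correlation {a:.4g} outside (-1, 1)"
    elif structure == "unstructured":
        try:
            working_matrix("unstructured", alpha, n_max)
        except (SingularCorrelationError, ValueError) as exc:
            return str(exc)
    return None


def _rinv_matrix(structure, alpha, n):
    """Explicit R(alpha)^{-1} for one cluster size."""
    if structure == "independent" or n == 1:
        return np.eye(n)
    if structure == "exchangeable":
        a = float(alpha)
        c = a / (1.0 + (n - 1) * a)
        return (np.eye(n) - c * np.ones((n, n))) / (1.0 - a)
    R = working_matrix(structure, alpha, n)
    return np.linalg.inv(R)


def apply_rinv(structure, alpha, B):
    """Apply R(alpha)^{-1} along axis 1 of a batched array B (m, n, ...)."""
    n = B.shape[1]
    if structure == "independent" or alpha is None or n == 1:
        return B
    if structure == "exchangeable":
        a = float(alpha)
        c = a / (1.0 + (n - 1) * a)
        return (B - c * B.sum(axis=1, keepdims=True)) / (1.0 - a)
    Q = _rinv_matrix(structure, alpha, n)
    return np.einsum("jk,mk...->mj...", Q, B)


# ---------------------------------------------------------------------------
# estimating function, information and Firth-type penalty

def score_info(groups: ClusterGroups, beta, alpha, structure, penalized=False):
    """Estimating function U, model-based information I and (optionally) the
    Firth-type penalty vector 1/2 trace(I^{-1} dI/dbeta_m).

    Returns ``(U, I, pen)`` where ``pen`` is ``None`` unless ``penalized``.
    The penalized estimating function is ``U + pen``.
    """
    q = groups.q
    U = np.zeros(q)
    I = np.zeros((q, q))
    cache = []
    for g in groups.groups:
        eta = g.X @ beta
        pi = expit(eta)
        v = pi * (1.0 - pi)
        s = np.sqrt(g.w * v)
        r = g.y - pi
        K = s[..., None] * g.X
        QK = apply_rinv(structure, alpha, K)
        I += np.einsum("mnq,mnr->qr", K, QK)
        with np.errstate(divide="ignore", invalid="ignore"):
            u = np.where(s > 0, g.w * r / s, 0.0)
        U += np.einsum("mnq,mn->q", QK, u)
        if penalized:
            cache.append((pi, s, K, QK, g.X))
    pen = None
    if penalized:
        A = np.linalg.inv(I)
        pen = np.zeros(q)
        for pi, s, K, QK, X in cache:
            QKA = QK @ A
            gdiag = np.einsum("mnq,mnq->mn", QKA, X)
            c = 0.5 * s * (1.0 - 2.0 * pi) * gdiag
            pen += np.einsum("mnq,mn->q", X, c)
    return U, I, pen


def fitted_probabilities(groups: ClusterGroups, beta):
    return groups.scatter_obs([expit(g.X @ beta) for g in groups.groups])


def pearson_residuals(groups: ClusterGroups, beta):
    """Scale-weighted Pearson residuals sqrt(w) (y - pi) / sqrt(pi(1-pi)),
    grouped (list of (m, n) arrays aligned with groups)."""
    out = []
    for g in groups.groups:
        pi = expit(g.X @ beta)
        e = np.sqrt(g.w) * (g.y - pi) / np.sqrt(pi * (1.0 - pi))
        out.append(e)
    return out


def estimate_alpha(groups: ClusterGroups, beta, structure):
    """Moment estimate of the working correlation parameter.

    Exchangeable: average over clusters of the mean pairwise residual
    product (clusters of size one contribute nothing and are excluded from
    the averaging denominator).  AR(1): lag-one products.  Unstructured:
    per-(j, k) pairwise means over the clusters long enough to contribute.
    """
    if structure == "independent":
        return None
    res = pearson_residuals(groups, beta)
    if structure == "exchangeable":
        # (1/N) sum_i [sum_{j != k} e_ij e_ik / (n_i (n_i - 1))] over the
        # clusters with at least one pair; residuals carry the sqrt(w) scale
        # factor while the pair-count denominator does not (the dialect of
        # weighted-GEE engines), which deliberately damps the contribution
        # of low-weight pseudo observations whose flipped outcomes are not
        # mean-centered
        terms = []
        for g, e in zip(groups.groups, res):
            n = g.n
            if n < 2:
                continue
            pair_sum = e.sum(axis=1) ** 2 - (e**2).sum(axis=1)
            terms.append(pair_sum / (n * (n - 1)))
        if not terms:
            raise ValueError(
                "no cluster with at least two observations; "
                "use the independent working structure"
            )
        return float(np.mean(np.concatenate(terms)))
    if structure == "ar1":
        terms = []
        for g, e in zip(groups.groups, res):
            if g.n < 2:
                continue
            terms.append((e[:, :-1] * e[:, 1:]).sum(axis=1) / (g.n - 1))
        if not terms:
            raise ValueError("no cluster with at least two observations")
        return float(np.mean(np.concatenate(terms)))
    if structure == "unstructured":
        n_max = groups.n_max
        num = np.zeros((n_max, n_max))
        cnt = np.zeros((n_max, n_max))
        for g, e in zip(groups.groups, res):
            n = g.n
            if n < 2:
                continue
            num[:n, :n] += np.einsum("mj,mk->jk", e, e)
            cnt[:n, :n] += e.shape[0]
        A = np.divide(num, cnt, out=np.zeros_like(num), where=cnt > 0)
        np.fill_diagonal(A, 1.0)
        return A
    raise ValueError(structure)


def alpha_in_open_unit_interval(structure, alpha):
    """The non-convergence rule's admissibility check: alpha in (-1, 1)."""
    if structure == "independent" or alpha is None:
        return True
    a = np.asarray(alpha, dtype=float)
    off = a[~np.eye(a.shape[0], dtype=bool)] if a.ndim == 2 else a
    return bool(np.all(np.isfinite(off)) and np.all(np.abs(off) < 1.0))


# ---------------------------------------------------------------------------
# the alternating Fisher-scoring solver

def solve_gee(
    groups: ClusterGroups,
    structure: str,
    beta0,
    alpha0=None,
    tol: float = 1e-3,
    max_iter: int = 30,
    penalized: bool = False,
    alpha_fixed=None,
    lag_alpha: bool = False,
):
    """Alternate a moment update of alpha with one (penalized) Fisher-scoring
    step for beta until max |delta beta| < tol.

    With ``lag_alpha`` the beta step at iteration k uses the alpha from
    iteration k-1 (the convention of the penalized algorithm); otherwise it
    uses the freshly updated alpha.  ``alpha_fixed`` suppresses the moment
    update entirely.  Never raises on divergence: returns a namespace with
    ``converged=False`` and a ``reason``.
    """
    beta = np.asarray(beta0, dtype=float).copy()
    alpha_curr = alpha0 if structure != "independent" else None
    alpha_last = alpha_curr
    converged = False
    reason = ""
    n_iter = 0
    for k in range(1, max_iter + 1):
        n_iter = k
        # moment update of alpha at the current beta
        if structure == "independent":
            alpha_new = None
        elif alpha_fixed is not None:
            alpha_new = alpha_fixed
        else:
            try:
                alpha_new = estimate_alpha(groups, beta, structure)
            except (ValueError, FloatingPointError) as exc:
                reason = f"correlation estimation failed: {exc}"
                break
        alpha_use = alpha_curr if (lag_alpha and alpha_curr is not None) else alpha_new
        if lag_alpha and alpha_curr is None and structure != "independent":
            # first iteration with no previous alpha: identity working matrix
            alpha_use = 0.0
        bad = check_alpha_admissible(structure, alpha_use, groups.n_max)
        alpha_last = alpha_new
        alpha_curr = alpha_new
        if bad is not None:
            reason = bad
            break
        try:
            U, I, pen = score_info(groups, beta, alpha_use, structure, penalized=penalized)
            if penalized:
                U = U + pen
            delta = np.linalg.solve(I, U)
        except np.linalg.LinAlgError as exc:
            reason = f"singular information matrix: {exc}"
            break
        beta = beta + delta
        if not np.all(np.isfinite(beta)):
            reason = "coefficient estimates diverged"
            break
        if np.max(np.abs(delta)) < tol:
            converged = True
            break
    if not converged and not reason:
        reason = f"no convergence within {max_iter} iterations"
    if converged:
        # report alpha at the final beta
        if structure != "independent" and alpha_fixed is None:
            try:
                alpha_last = estimate_alpha(groups, beta, structure)
            except (ValueError, FloatingPointError):
                pass
        elif alpha_fixed is not None:
            alpha_last = alpha_fixed
        if not alpha_in_open_unit_interval(structure, alpha_last):
            converged = False
            reason = "estimated correlation parameter outside (-1, 1)"
    fitted = fitted_probabilities(groups, beta)
    return SimpleNamespace(
        beta=beta,
        alpha=alpha_last,
        converged=converged,
        n_iter=n_iter,
        reason=reason,
        fitted=fitted,
    )


# ---------------------------------------------------------------------------
# generalized hat matrix (leverage for clustered data)

def generalized_hat_diagonals(groups: ClusterGroups, beta, alpha, structure):
    """Diagonals of the block-diagonal generalized hat matrix
    H_i = Omega_i^{1/2} X_i (sum_j X_j' Omega_j X_j)^{-1} X_i' Omega_i^{1/2},
    Omega_i = W_i^{1/2} R_i(alpha)^{-1} W_i^{1/2}, returned in original row
    order.  The trace over all blocks equals the number of regression
    parameters p + 1.
    """
    bad = check_alpha_admissible(structure, alpha, groups.n_max)
    if bad is not None:
        raise SingularCorrelationError(bad)
    M = np.zeros((groups.q, groups.q))
    per_group = []
    for g in groups.groups:
        pi = expit(g.X @ beta)
        s = np.sqrt(g.w * pi * (1.0 - pi))
        n = g.n
        Q = _rinv_matrix(structure, alpha, n)
        # Omega_i = diag(s) Q diag(s)
        Omega = s[:, :, None] * Q[None, :, :] * s[:, None, :]
        M += np.einsum("mnq,mnk,mkr->qr", g.X, Omega, g.X)
        per_group.append(Omega)
    try:
        Minv = np.linalg.inv(M)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(f"singular whole-data information: {exc}") from exc
    h_groups = []
    for g, Omega in zip(groups.groups, per_group):
        lam, V = np.linalg.eigh(Omega)
        lam = np.clip(lam, 0.0, None)
        sqrtO = np.einsum("mij,mj,mkj->mik", V, np.sqrt(lam), V)
        B = sqrtO @ g.X
        h = np.einsum("mnq,qr,mnr->mn", B, Minv, B)
        h_groups.append(h)
    return groups.scatter_obs(h_groups)


# ---------------------------------------------------------------------------
# sandwich building blocks

def sandwich_parts(groups: ClusterGroups, beta, alpha, structure):
    """Bread I0 and per-cluster score contributions d_i (in original cluster
    order) evaluated at (beta, alpha)."""
    bad = check_alpha_admissible(structure, alpha, groups.n_max)
    if bad is not None:
        raise SingularCorrelationError(bad)
    q = groups.q
    I0 = np.zeros((q, q))
    d = np.zeros((groups.N, q))
    for g in groups.groups:
        pi = expit(g.X @ beta)
        v = pi * (1.0 - pi)
        s = np.sqrt(g.w * v)
        K = s[..., None] * g.X
        QK = apply_rinv(structure, alpha, K)
        I0 += np.einsum("mnq,mnr->qr", K, QK)
        with np.errstate(divide="ignore", invalid="ignore"):
            u = np.where(s > 0, g.w * (g.y - pi) / s, 0.0)
        d[g.clusters] = np.einsum("mnq,mn->mq", QK, u)
    return I0, d
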