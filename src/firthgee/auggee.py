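"""Iterated and single-step augmented GEE.

Both estimators carry the augmented-data representation of Firth's logistic
regression over to clustered data: the dataset is tripled into 3N clusters —
the originals with weight 1, a pseudo-cluster copy with weight h/2, and a
pseudo-cluster copy with the outcome flipped and weight h/2 — and a weighted
GEE is solved on the augmented data.  The leverages h come from the
generalized (working-covariance-weighted) hat matrix with per-cluster blocks

    H_i = Omega_i^{1/2} X_i (sum_j X_j' Omega_j X_j)^{-1} X_i' Omega_i^{1/2},
    Omega_i = W_i^{1/2} R_i(alpha)^{-1} W_i^{1/2},

whose total trace is always p + 1, so the pseudo observations carry total
weight p + 1 and become negligible as the sample grows (the estimators are
consistent).

The iterated algorithm (augGEE) re-augments at each outer step using the
generalized hat at the current (beta, alpha); the single-step algorithm
(augGEE1) augments once using the ordinary independence hat matrix from the
Firth fit and solves a single weighted GEE, warm-started at the Firth
estimate.  With an independent working structure both reproduce Firth's
logistic regression; augGEE1 with an independent structure always returns
finite estimates and serves as the fallback estimator in simulations.

Reported covariances are sandwich + Morel applied to the ORIGINAL data at
the final (beta, alpha), not to the augmented pseudo-data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _core
from .data import ClusteredDataset, GEEFit
from .firth import fit_firth
from .gee import _assemble_fit, _ClusteredRegressionBase

__all__ = [
    "GeneralizedHat",
    "AugmentedClustered",
    "generalized_hat",
    "build_augmented",
    "fit_auggee",
    "fit_auggee1",
    "AugmentedGEE",
    "SingleStepAugmentedGEE",
]


@dataclass
class GeneralizedHat:
    """Per-cluster blocks and diagonals of the generalized hat matrix."""

    blocks: list
    diagonals: np.ndarray  # in original row order

    @property
    def trace(self) -> float:
        return float(self.diagonals.sum())


@dataclass
class AugmentedClustered:
    """Augmented dataset of 3N clusters with provenance to the source rows."""

    data: ClusteredDataset
    source_row: np.ndarray      # augmented row -> original row index
    source_cluster: np.ndarray  # augmented cluster -> original cluster index


def generalized_hat(beta, alpha, data: ClusteredDataset, structure: str) -> GeneralizedHat:
    """Generalized hat matrix at (beta, alpha).

    The inner inverse uses the whole-data information sum_j X_j' Omega_j X_j,
    which is what makes trace(H) = p + 1 hold exactly.  With an independent
    structure the diagonals coincide with the ordinary Firth hat diagonals.
    """
    beta = np.asarray(beta, dtype=float)
    groups = _core.ClusterGroups(data)
    diag = _core.generalized_hat_diagonals(groups, beta, alpha, structure)
    # explicit blocks, cluster by cluster (small matrices; clarity over speed)
    pi = _core.expit(data.X @ beta)
    s = np.sqrt(data.weights * pi * (1.0 - pi))
    M = np.zeros((data.X.shape[1],) * 2)
    omegas = []
    for sl, n in zip(data.cluster_slices, data.n_i):
        Q = _core._rinv_matrix(structure, alpha, int(n))
        Om = s[sl][:, None] * Q * s[sl][None, :]
        M += data.X[sl].T @ Om @ data.X[sl]
        omegas.append(Om)
    Minv = np.linalg.inv(M)
    blocks = []
    for sl, Om in zip(data.cluster_slices, omegas):
        lam, V = np.linalg.eigh(Om)
        sqrtO = (V * np.sqrt(np.clip(lam, 0.0, None))) @ V.T
        B = sqrtO @ data.X[sl]
        blocks.append(B @ Minv @ B.T)
    return GeneralizedHat(blocks=blocks, diagonals=diag)


def build_augmented(
    data: ClusteredDataset, hat_diagonals: np.ndarray, pseudo_clusters: str = "3N"
) -> AugmentedClustered:
    """Triple the data into the augmented weighted dataset.

    Copies 1-2 keep the outcome, copy 3 flips it; weights are
    (w, h/2, h/2).  With ``pseudo_clusters="3N"`` (default, reflecting the
    data-augmentation construction) each copy forms its own cluster; with
    ``"N"`` the pseudo rows are merged into their source cluster.
    """
    h = np.asarray(hat_diagonals, dtype=float)
    if h.shape[0] != data.n_obs:
        raise ValueError("need one hat diagonal per observation")
    y = np.concatenate([data.y, data.y, 1.0 - data.y])
    X = np.vstack([data.X, data.X, data.X])
    w = np.concatenate([data.weights, h / 2.0, h / 2.0])
    src_row = np.tile(np.arange(data.n_obs), 3)
    cl_index = np.concatenate(
        [np.full(n, i) for i, n in enumerate(data.n_i)]
    )
    N = data.N
    if pseudo_clusters == "3N":
        ids = np.concatenate([cl_index, cl_index + N, cl_index + 2 * N])
        src_cluster = np.concatenate([np.arange(N)] * 3)
    elif pseudo_clusters == "N":
        ids = np.concatenate([cl_index, cl_index, cl_index])
        src_cluster = np.arange(N)
    else:
        raise ValueError("pseudo_clusters must be '3N' or 'N'")
    aug = ClusteredDataset(
        cluster_ids=ids, y=y, X=X, weights=w, columns=data.columns
    )
    return AugmentedClustered(data=aug, source_row=src_row, source_cluster=src_cluster)


def _finish(data, beta, alpha, structure, converged, reason, n_outer, n_inner, method):
    res = type("R", (), {})()
    res.beta = beta
    res.alpha = alpha
    res.converged = converged
    res.reason = reason
    res.structure = structure
    groups = _core.ClusterGroups(data)
    res.fitted = _core.fitted_probabilities(groups, beta)
    return _assemble_fit(data, res, method, n_outer, n_inner)


def fit_auggee(
    data: ClusteredDataset,
    structure: str = "exchangeable",
    tol: float = 1e-3,
    max_outer: int = 20,
    inner_max_iter: int = 30,
    pseudo_clusters: str = "3N",
    alpha_fixed=None,
) -> GEEFit:
    """Iterated augmented GEE: alternate generalized-hat augmentation with a
    weighted GEE solve on the augmented data until the outer criterion
    max |delta beta| < tol is met (cap ``max_outer``).  Inner fits are
    warm-started at the previous outer estimate."""
    fl = fit_firth(data.X, data.y, data.weights)
    beta = fl.beta
    alpha = 0.0 if structure != "independent" else None
    groups = _core.ClusterGroups(data)
    converged = False
    reason = ""
    n_inner_total = 0
    k = 0
    for k in range(1, max_outer + 1):
        try:
            h = _core.generalized_hat_diagonals(groups, beta, alpha, structure)
        except (np.linalg.LinAlgError, ValueError) as exc:
            reason = f"generalized hat failed: {exc}"
            break
        aug = build_augmented(data, h, pseudo_clusters=pseudo_clusters)
        aug_groups = _core.ClusterGroups(aug.data)
        inner = _core.solve_gee(
            aug_groups, structure, beta0=beta, alpha0=alpha, tol=tol,
            max_iter=inner_max_iter, alpha_fixed=alpha_fixed,
        )
        n_inner_total += inner.n_iter
        delta = np.max(np.abs(inner.beta - beta))
        beta, alpha = inner.beta, inner.alpha
        if not np.all(np.isfinite(beta)) or (
            not inner.converged and inner.reason and "iterations" not in inner.reason
        ):
            reason = f"inner GEE failed: {inner.reason}"
            break
        if delta < tol:
            converged = True
            break
    if converged and not _core.alpha_in_open_unit_interval(structure, alpha):
        converged = False
        reason = "estimated correlation parameter outside (-1, 1)"
    if not converged and not reason:
        reason = f"no outer convergence within {max_outer} iterations"
    return _finish(data, beta, alpha, structure, converged, reason, k, n_inner_total,
                   "auggee")


def fit_auggee1(
    data: ClusteredDataset,
    structure: str = "exchangeable",
    tol: float = 1e-3,
    inner_max_iter: int = 30,
    pseudo_clusters: str = "3N",
    alpha_fixed=None,
) -> GEEFit:
    """Single-step augmented GEE: Firth fit, one augmentation with the
    ORDINARY (independence) hat diagonals, then a single weighted GEE solve
    on the 3N-cluster augmented data, warm-started at the Firth estimate."""
    fl = fit_firth(data.X, data.y, data.weights)
    aug = build_augmented(data, fl.hat, pseudo_clusters=pseudo_clusters)
    aug_groups = _core.ClusterGroups(aug.data)
    inner = _core.solve_gee(
        aug_groups, structure, beta0=fl.beta,
        alpha0=0.0 if structure != "independent" else None,
        tol=tol, max_iter=inner_max_iter, alpha_fixed=alpha_fixed,
    )
    return _finish(data, inner.beta, inner.alpha, structure, inner.converged,
                   inner.reason, 1, inner.n_iter, "auggee1")


class AugmentedGEE(_ClusteredRegressionBase):
    """Iterated augmented GEE estimator (see module docstring).

    Parameters
    ----------
    corstr : working correlation structure.
    tol : outer/inner convergence tolerance on max |delta beta|.
    max_outer : outer iteration cap (default 20).
    inner_max_iter : iteration cap of each inner weighted GEE solve
        (default 30).
    pseudo_clusters : "3N" (default) or "N" — whether pseudo copies form
        their own clusters or are merged into the source cluster.
    """

    _method = "auggee"

    def __init__(self, corstr="exchangeable", tol=1e-3, max_outer=20,
                 inner_max_iter=30, pseudo_clusters="3N", alpha_fixed=None):
        self.corstr = corstr
        self.tol = tol
        self.max_outer = max_outer
        self.inner_max_iter = inner_max_iter
        self.pseudo_clusters = pseudo_clusters
        self.alpha_fixed = alpha_fixed

    def _solve(self, data):
        return fit_auggee(
            data, structure=self.corstr, tol=self.tol, max_outer=self.max_outer,
            inner_max_iter=self.inner_max_iter, pseudo_clusters=self.pseudo_clusters,
            alpha_fixed=self.alpha_fixed,
        )


class SingleStepAugmentedGEE(_ClusteredRegressionBase):
    """Single-step augmented GEE estimator (see module docstring).

    With ``corstr="independent"`` this is exactly Firth's logistic
    regression and always returns finite estimates.
    """

    _method = "auggee1"

    def __init__(self, corstr="exchangeable", tol=1e-3, inner_max_iter=30,
                 pseudo_clusters="3N", alpha_fixed=None):
        self.corstr = corstr
        self.tol = tol
        self.inner_max_iter = inner_max_iter
        self.pseudo_clusters = pseudo_clusters
        self.alpha_fixed = alpha_fixed

    def _solve(self, data):
        return fit_auggee1(
            data, structure=self.corstr, tol=self.tol,
            inner_max_iter=self.inner_max_iter,
            pseudo_clusters=self.pseudo_clusters, alpha_fixed=self.alpha_fixed,
        )
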