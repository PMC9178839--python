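"""Sandwich covariance, Morel small-sample correction and t-based intervals.

The robust (sandwich) covariance S = I0^{-1} I1 I0^{-1} combines the
model-based bread I0 with the empirical meat I1 built from per-cluster score
contributions d_i.  With few clusters the sandwich underestimates the
variance; the Morel correction inflates the centered meat and adds a bread
term delta * phi * I0^{-1}.  Confidence intervals use quantiles of the
t-distribution with the number of clusters as degrees of freedom.

For the augmented GEE estimators these formulas are applied to the ORIGINAL
data at the final (beta, alpha) — not to the augmented pseudo-data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from ._core import ClusterGroups, sandwich_parts
from .data import ClusteredDataset

__all__ = [
    "SandwichParts",
    "ConfidenceInterval",
    "compute_sandwich_parts",
    "sandwich",
    "morel_correction",
    "confint",
]


@dataclass
class SandwichParts:
    """Building blocks of the sandwich and its Morel correction."""

    I0: np.ndarray           # bread: model-based information
    d: np.ndarray            # per-cluster score contributions, shape (N, p+1)
    N: int
    n_obs: int

    @property
    def I1(self) -> np.ndarray:
        return self.d.T @ self.d

    def I1_star(self) -> np.ndarray:
        """Centered, small-sample-inflated meat."""
        N, q = self.N, self.I0.shape[0]
        Nstar = self.n_obs
        dbar = self.d.mean(axis=0)
        dc = self.d - dbar
        infl = (Nstar - 1) / (Nstar - q) * N / (N - 1)
        return infl * (dc.T @ dc)


@dataclass
class ConfidenceInterval:
    lower: np.ndarray
    upper: np.ndarray
    level: float
    df: int


def compute_sandwich_parts(data: ClusteredDataset, beta, alpha, structure) -> SandwichParts:
    groups = ClusterGroups(data)
    I0, d = sandwich_parts(groups, np.asarray(beta, dtype=float), alpha, structure)
    return SandwichParts(I0=I0, d=d, N=data.N, n_obs=data.n_obs)


def sandwich(data: ClusteredDataset, beta, alpha, structure) -> np.ndarray:
    """Robust covariance S = I0^{-1} I1 I0^{-1} evaluated at (beta, alpha)."""
    parts = compute_sandwich_parts(data, beta, alpha, structure)
    I0inv = np.linalg.inv(parts.I0)
    return I0inv @ parts.I1 @ I0inv


def morel_correction(parts: SandwichParts, alpha=None) -> np.ndarray:
    """Morel small-sample corrected covariance
    S* = I0^{-1} I1* I0^{-1} + delta * phi * I0^{-1}
    with delta = min(0.5, (p+1)/(N-p-1)) and
    phi = max(1, trace(alpha I0^{-1} I1*)/(p+1)).

    ``alpha`` is the scalar working correlation parameter; for the
    unstructured structure pass the mean off-diagonal estimate (the printed
    phi formula assumes a scalar), and for independent working correlation
    alpha = 0 (phi = 1).
    """
    q = parts.I0.shape[0]
    N = parts.N
    if N <= q:
        warnings.warn(
            f"number of clusters ({N}) <= number of parameters ({q}); "
            "Morel delta capped at 0.5",
            stacklevel=2,
        )
        delta = 0.5
    else:
        delta = min(0.5, q / (N - q))
    I1s = parts.I1_star()
    I0inv = np.linalg.inv(parts.I0)
    if alpha is None:
        a = 0.0
    elif np.ndim(alpha) == 2:
        A = np.asarray(alpha, dtype=float)
        a = float(A[~np.eye(A.shape[0], dtype=bool)].mean())
    else:
        a = float(alpha)
    phi = max(1.0, a * float(np.trace(I0inv @ I1s)) / q)
    return I0inv @ I1s @ I0inv + delta * phi * I0inv


def _scalar_alpha(structure, alpha):
    if structure == "independent" or alpha is None:
        return 0.0
    a = np.asarray(alpha, dtype=float)
    if a.ndim == 2:
        mask = ~np.eye(a.shape[0], dtype=bool)
        return float(a[mask].mean())
    return float(a)


def covariance_pair(data: ClusteredDataset, beta, alpha, structure):
    """(sandwich, Morel-corrected) covariance pair on the given data."""
    parts = compute_sandwich_parts(data, beta, alpha, structure)
    I0inv = np.linalg.inv(parts.I0)
    S = I0inv @ parts.I1 @ I0inv
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        Sstar = morel_correction(parts, alpha=_scalar_alpha(structure, alpha))
    return S, Sstar


def confint(beta, cov, N, level=0.95) -> ConfidenceInterval:
    """Symmetric t-based interval beta_m +/- t_{df=N, (1+level)/2} * SE_m.

    The degrees of freedom equal the number of clusters N.
    """
    beta = np.asarray(beta, dtype=float)
    se = np.sqrt(np.clip(np.diag(np.asarray(cov, dtype=float)), 0.0, None))
    tq = stats.t.ppf(0.5 + level / 2.0, df=N)
    return ConfidenceInterval(lower=beta - tq * se, upper=beta + tq * se, level=level, df=N)
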