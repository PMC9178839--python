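"""Core containers, long-format I/O and validation shared by all estimators.

The central container is :class:`ClusteredDataset`: a long-format view of a
clustered binary-outcome study, one row per observation, rows grouped
contiguously by cluster, with a leading intercept column in the design matrix
and non-negative per-observation scale weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ClusteredDataset",
    "WorkingCorrelation",
    "GEEFit",
    "SingularCorrelationError",
    "ValidationError",
    "read_clustered",
    "write_clustered",
    "working_matrix",
]

STRUCTURES = ("independent", "exchangeable", "ar1", "unstructured")


class ValidationError(ValueError):
    """Raised when input data violate the container invariants."""


class SingularCorrelationError(np.linalg.LinAlgError):
    """Raised when a working correlation matrix is singular or not positive
    definite for the requested parameter and cluster size."""


@dataclass
class ClusteredDataset:
    """Long-format clustered binary data.

    Parameters
    ----------
    cluster_ids : array of labels, one per observation.  After
        canonicalization rows are grouped contiguously by cluster, preserving
        first-appearance order of cluster ids and within-cluster row order
        (the latter matters for the AR(1) working structure).
    y : binary outcomes in {0, 1}.
    X : design matrix with a leading intercept column of ones,
        shape (n_obs, p + 1).
    weights : non-negative per-observation scale factors (default 1).  They
        multiply each observation's contribution to the estimating function,
        i.e. the working variance of an observation is pi(1-pi)/w.
    """

    cluster_ids: np.ndarray
    y: np.ndarray
    X: np.ndarray
    weights: np.ndarray = None
    columns: Sequence[str] = None

    # derived, filled in __post_init__
    N: int = field(init=False, default=0)
    n_i: np.ndarray = field(init=False, default=None)
    cluster_slices: list = field(init=False, default=None)

    def __post_init__(self):
        self.cluster_ids = np.asarray(self.cluster_ids)
        self.y = np.asarray(self.y, dtype=float)
        self.X = np.asarray(self.X, dtype=float)
        n_obs = self.y.shape[0]
        if self.cluster_ids.shape[0] != n_obs or self.X.shape[0] != n_obs:
            raise ValidationError("cluster_ids, y and X must have equal length")
        if self.weights is None:
            self.weights = np.ones(n_obs)
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape[0] != n_obs:
            raise ValidationError("weights must have one entry per observation")
        if np.any(self.weights < 0):
            raise ValidationError("weights must be non-negative")
        bad = ~np.isin(self.y, (0.0, 1.0))
        if np.any(bad):
            rows = np.flatnonzero(bad)
            raise ValidationError(
                f"outcome must be binary in {{0, 1}}; offending rows: {rows.tolist()[:20]}"
            )
        if self.X.ndim != 2:
            raise ValidationError("X must be two-dimensional")
        if not np.allclose(self.X[:, 0], 1.0):
            raise ValidationError("first column of X must be the intercept (all ones)")
        if self.columns is None:
            self.columns = ["(Intercept)"] + [f"x{j}" for j in range(1, self.X.shape[1])]
        self._canonicalize()

    def _canonicalize(self):
        """Group rows contiguously by cluster, first-appearance order,
        preserving within-cluster row order."""
        ids = self.cluster_ids
        _, first = np.unique(ids, return_index=True)
        order_of_id = {ids[i]: rank for rank, i in enumerate(sorted(first))}
        key = np.array([order_of_id[c] for c in ids])
        order = np.argsort(key, kind="stable")
        self.cluster_ids = ids[order]
        self.y = self.y[order]
        self.X = self.X[order]
        self.weights = self.weights[order]
        # cluster boundaries
        change = np.flatnonzero(np.diff(key[order])) + 1
        starts = np.concatenate([[0], change])
        stops = np.concatenate([change, [len(key)]])
        self.cluster_slices = [slice(a, b) for a, b in zip(starts, stops)]
        self.n_i = stops - starts
        self.N = len(self.n_i)

    @property
    def n_obs(self) -> int:
        return self.y.shape[0]

    @property
    def p(self) -> int:
        """Number of covariates (excluding the intercept)."""
        return self.X.shape[1] - 1

    def to_frame(self, cluster_col="cluster", outcome_col="y") -> pd.DataFrame:
        df = pd.DataFrame(self.X[:, 1:], columns=list(self.columns)[1:])
        df.insert(0, outcome_col, self.y.astype(int))
        df.insert(0, cluster_col, self.cluster_ids)
        if not np.all(self.weights == 1.0):
            df["weight"] = self.weights
        return df


@dataclass
class WorkingCorrelation:
    """Working correlation structure tag plus its parameter.

    ``alpha`` is a scalar for exchangeable/AR(1), a matrix for unstructured
    and ``None`` for independent.
    """

    structure: str
    alpha: object = None

    def __post_init__(self):
        if self.structure not in STRUCTURES:
            raise ValueError(f"unknown working correlation structure {self.structure!r}")

    def matrix(self, n: int) -> np.ndarray:
        return working_matrix(self.structure, self.alpha, n)


@dataclass
class GEEFit:
    """Result of a (possibly penalized or augmented) GEE fit."""

    beta: np.ndarray
    alpha: object
    converged: bool
    n_outer: int
    n_inner: int
    cov_sandwich: np.ndarray
    cov_morel: np.ndarray
    fitted: np.ndarray
    method: str
    reason: str = ""
    trace: list = None


def working_matrix(structure: str, alpha, n: int) -> np.ndarray:
    """Build the n x n working correlation matrix R(alpha).

    independent -> identity; exchangeable -> off-diagonals all alpha;
    ar1 -> alpha^|j-k|; unstructured -> alpha itself (upper-left block).

    Raises
    ------
    SingularCorrelationError
        if the resulting matrix is not positive definite (the failure mode of
        a working correlation structure approaching singularity).
    """
    if n < 1:
        raise ValueError("cluster size must be >= 1")
    if structure == "independent":
        return np.eye(n)
    if structure == "exchangeable":
        R = np.full((n, n), float(alpha))
        np.fill_diagonal(R, 1.0)
    elif structure == "ar1":
        idx = np.arange(n)
        R = float(alpha) ** np.abs(idx[:, None] - idx[None, :])
    elif structure == "unstructured":
        A = np.asarray(alpha, dtype=float)
        if A.shape[0] < n:
            raise ValueError("unstructured alpha matrix smaller than cluster size")
        R = A[:n, :n].copy()
        np.fill_diagonal(R, 1.0)
    else:  # pragma: no cover
        raise ValueError(structure)
    if n > 1:
        w = np.linalg.eigvalsh(R)
        if w.min() <= 1e-12:
            raise SingularCorrelationError(
                f"working correlation ({structure}, n={n}) is not positive definite"
            )
    return R


def read_clustered(
    path,
    cluster_col: str,
    outcome_col: str,
    covariate_cols: Sequence[str],
    weight_col: str = None,
) -> ClusteredDataset:
    """Read a long-format CSV/TSV file into a validated :class:`ClusteredDataset`.

    The file must have a header.  An intercept column of ones is prepended to
    the covariates.  Outcome values must be coercible to {0, 1}; offending
    rows are named in the error.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep)
    return from_frame(df, cluster_col, outcome_col, covariate_cols, weight_col)


def from_frame(
    df: pd.DataFrame,
    cluster_col: str,
    outcome_col: str,
    covariate_cols: Sequence[str],
    weight_col: str = None,
) -> ClusteredDataset:
    for col in [cluster_col, outcome_col, *covariate_cols]:
        if col not in df.columns:
            raise ValidationError(f"column {col!r} not found")
    ids = df[cluster_col].to_numpy()
    if pd.isna(df[cluster_col]).any() or any(str(c).strip() == "" for c in ids):
        raise ValidationError("empty or missing cluster id encountered")
    y = pd.to_numeric(df[outcome_col], errors="coerce").to_numpy(dtype=float)
    bad = ~np.isin(y, (0.0, 1.0))
    if np.any(bad):
        rows = np.flatnonzero(bad)
        raise ValidationError(
            f"outcome column {outcome_col!r} must be binary 0/1; "
            f"offending rows (0-based): {rows.tolist()[:20]}"
        )
    Xc = df[list(covariate_cols)].to_numpy(dtype=float)
    X = np.column_stack([np.ones(len(df)), Xc])
    w = df[weight_col].to_numpy(dtype=float) if weight_col else None
    return ClusteredDataset(
        cluster_ids=ids, y=y, X=X, weights=w,
        columns=["(Intercept)"] + list(covariate_cols),
    )


def write_clustered(data: ClusteredDataset, path, cluster_col="cluster", outcome_col="y"):
    """Write a dataset back to CSV (round-trips through :func:`read_clustered`)."""
    path = Path(path)
    df = data.to_frame(cluster_col=cluster_col, outcome_col=outcome_col)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df.to_csv(path, sep=sep, index=False)
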