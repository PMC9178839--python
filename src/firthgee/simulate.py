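"""Clustered binary-outcome data generator, separation detection and the
packaged dental-style fixture.

The generator emulates a factorial simulation design for marginal logistic
models: N in {20, 50, 100} clusters, truncated-Poisson cluster sizes
(small/moderate/large), five covariates obtained by transforming correlated
standard normals (two between-cluster binaries, one within-cluster binary,
one ordinal, one winsorized continuous), an intercept calibrated by Monte
Carlo to a marginal event rate of 0.1 or 0.3, and outcomes drawn from a
latent-threshold (Gaussian copula) model with exchangeable latent correlation
0.7 or 0.9.  The marginal model P(Y=1|x) = expit(x beta) holds exactly by
construction; the achieved correlation of the binary outcomes is smaller
than the latent correlation and depends on the event rate.

The default latent correlation matrix among the Z's, the transformation
thresholds and the true slopes beta_2..beta_5 are reconstructions of a
realistic epidemiological covariate mix (binary prevalences 0.5/0.3/0.2,
quartile-binned ordinal, log-normal-type continuous); all are configurable.
Only beta_1 = 0.69 is fixed by design as the effect of the binary variable
of interest.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .data import ClusteredDataset

__all__ = [
    "CovariateSpec",
    "ScenarioConfig",
    "CLUSTER_SIZE_PARAMS",
    "sample_cluster_sizes",
    "generate_covariates",
    "calibrate_intercept",
    "generate_outcomes",
    "generate_dataset",
    "detect_separation",
    "achieved_correlation",
    "make_dental_fixture",
]

#: truncated-Poisson parameters (mean, min, max) per cluster-size tag; "mean"
#: is the parameter of the untruncated Poisson that is rejection-sampled.
CLUSTER_SIZE_PARAMS = {
    "small": (5, 1, 10),
    "moderate": (10, 1, 20),
    "large": (20, 1, 40),
}

_DEFAULT_Z_CORR = np.array(
    [
        [1.0, 0.1, 0.1, 0.2, 0.1],
        [0.1, 1.0, 0.2, 0.1, 0.3],
        [0.1, 0.2, 1.0, 0.1, 0.2],
        [0.2, 0.1, 0.1, 1.0, 0.1],
        [0.1, 0.3, 0.2, 0.1, 1.0],
    ]
)


@dataclass
class CovariateSpec:
    """Latent correlation matrix and transformations Z -> X.

    X1, X2 are between-cluster (Z1, Z2 constant within cluster); X3 binary,
    X4 ordinal (quartile bins, 0-3), X5 continuous exp(Z5/2) winsorized at
    Q1 - 3 IQR and Q3 + 3 IQR, with the quartiles obtained by transforming
    the standard-normal quartiles.
    """

    z_corr: np.ndarray = field(default_factory=lambda: _DEFAULT_Z_CORR.copy())
    prevalences: tuple = (0.5, 0.3, 0.2)  # for X1, X2, X3

    def __post_init__(self):
        self.z_corr = np.asarray(self.z_corr, dtype=float)
        w = np.linalg.eigvalsh(self.z_corr)
        if w.min() <= 0:
            raise ValueError("latent covariate correlation matrix not positive definite")
        q = stats.norm.ppf(0.75)
        lo_t, hi_t = np.exp(-q / 2.0), np.exp(q / 2.0)
        iqr = hi_t - lo_t
        self.x5_bounds = (lo_t - 3.0 * iqr, hi_t + 3.0 * iqr)

    def transform(self, Z: np.ndarray) -> np.ndarray:
        """Map latent normals (n, 5) to covariates (n, 5)."""
        thr = stats.norm.ppf(1.0 - np.asarray(self.prevalences))
        X = np.empty_like(Z)
        X[:, 0] = (Z[:, 0] > thr[0]).astype(float)
        X[:, 1] = (Z[:, 1] > thr[1]).astype(float)
        X[:, 2] = (Z[:, 2] > thr[2]).astype(float)
        cuts = stats.norm.ppf([0.25, 0.5, 0.75])
        X[:, 3] = np.searchsorted(cuts, Z[:, 3]).astype(float)
        X[:, 4] = np.clip(np.exp(Z[:, 4] / 2.0), *self.x5_bounds)
        return X


@dataclass
class ScenarioConfig:
    """One cell of the factorial simulation design."""

    n_clusters: int = 20
    cluster_size: str = "small"
    latent_corr: float = 0.9
    event_rate: float = 0.1
    beta1: float = 0.69
    slopes_rest: tuple = (-0.5, 0.5, 0.25, 0.25)  # beta_2 .. beta_5
    beta0: float = None  # calibrated when None
    n_datasets: int = 1000
    seed: int = None
    covariates: CovariateSpec = field(default_factory=CovariateSpec)

    @property
    def slopes(self) -> np.ndarray:
        return np.array([self.beta1, *self.slopes_rest], dtype=float)

    def beta(self) -> np.ndarray:
        if self.beta0 is None:
            raise ValueError("intercept not calibrated yet; call calibrate_intercept")
        return np.concatenate([[self.beta0], self.slopes])


def sample_cluster_sizes(config: ScenarioConfig, rng: np.random.Generator) -> np.ndarray:
    """Truncated-Poisson cluster sizes by rejection sampling; the stated mean
    is the parameter of the untruncated Poisson."""
    mean, lo, hi = CLUSTER_SIZE_PARAMS[config.cluster_size]
    if lo == hi:
        return np.full(config.n_clusters, lo)
    sizes = np.empty(config.n_clusters, dtype=int)
    todo = np.arange(config.n_clusters)
    while todo.size:
        draw = rng.poisson(mean, size=todo.size)
        ok = (draw >= lo) & (draw <= hi)
        sizes[todo[ok]] = draw[ok]
        todo = todo[~ok]
    return sizes


def generate_covariates(
    n_clusters: int, sizes: np.ndarray, spec: CovariateSpec, rng: np.random.Generator
) -> np.ndarray:
    """Covariate matrix (n_obs, 5).  Z1, Z2 are drawn once per cluster and
    repeated within it; Z3-Z5 are drawn per observation from their
    conditional distribution given (Z1, Z2) so that the full latent
    correlation structure is preserved."""
    S = spec.z_corr
    S11, S12, S22 = S[:2, :2], S[:2, 2:], S[2:, 2:]
    L11 = np.linalg.cholesky(S11)
    A = np.linalg.solve(S11, S12)  # (2, 3): conditional-mean map
    Scond = S22 - S12.T @ A
    Lc = np.linalg.cholesky(Scond)
    z12_cl = rng.standard_normal((n_clusters, 2)) @ L11.T
    z12 = np.repeat(z12_cl, sizes, axis=0)
    n_obs = int(np.sum(sizes))
    z345 = z12 @ A + rng.standard_normal((n_obs, 3)) @ Lc.T
    Z = np.column_stack([z12, z345])
    return spec.transform(Z)


def calibrate_intercept(
    slopes,
    spec: CovariateSpec,
    target_rate: float,
    rng: np.random.Generator,
    n_mc: int = 400_000,
    tol: float = 0.002,
) -> float:
    """Monte-Carlo calibration of beta_0 so that E[expit(beta_0 + x'slopes)]
    equals the target marginal event rate (to within ``tol``).

    The marginal covariate distribution does not depend on the clustering,
    so an i.i.d. latent sample suffices.
    """
    if not 0.0 < target_rate < 1.0:
        raise ValueError("target rate must lie in (0, 1)")
    slopes = np.asarray(slopes, dtype=float)
    L = np.linalg.cholesky(spec.z_corr)
    Z = rng.standard_normal((n_mc, 5)) @ L.T
    eta = spec.transform(Z) @ slopes

    def f(b0):
        return float(np.mean(1.0 / (1.0 + np.exp(-(b0 + eta))))) - target_rate

    lo, hi = -10.0, 10.0
    for _ in range(6):
        if f(lo) < 0.0 < f(hi):
            break
        lo *= 2.0
        hi *= 2.0
    else:
        raise RuntimeError("could not bracket the intercept")
    b0 = optimize.brentq(f, lo, hi, xtol=1e-8)
    if abs(f(b0)) > tol:  # pragma: no cover
        raise RuntimeError("intercept calibration did not reach tolerance")
    return float(b0)


def generate_outcomes(
    X: np.ndarray,
    beta,
    sizes: np.ndarray,
    latent_corr: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Correlated binary outcomes from the latent-threshold construction.

    A latent exchangeable standard normal z_ij = sqrt(rho) a_i +
    sqrt(1-rho) b_ij is transformed to u_ij = Phi(z_ij); y_ij = 1 iff
    u_ij < pi_ij.  Marginally P(Y=1|x) = expit(x beta) exactly; the
    within-cluster dependence comes from the shared a_i.
    """
    rho = float(latent_corr)
    if not 0.0 <= rho <= 1.0:
        raise ValueError("latent correlation must lie in [0, 1]")
    X = np.asarray(X, dtype=float)
    eta = X @ np.asarray(beta, dtype=float)
    pi = 1.0 / (1.0 + np.exp(-eta))
    a = np.repeat(rng.standard_normal(len(sizes)), sizes)
    b = rng.standard_normal(len(a))
    z = np.sqrt(rho) * a + np.sqrt(1.0 - rho) * b
    u = stats.norm.cdf(z)
    return (u < pi).astype(float)


def generate_dataset(config: ScenarioConfig, rng: np.random.Generator):
    """One simulated dataset.  Returns (ClusteredDataset, true_beta,
    true_pi)."""
    if config.beta0 is None:
        raise ValueError("calibrate the intercept first (config.beta0 is None)")
    sizes = sample_cluster_sizes(config, rng)
    Xc = generate_covariates(config.n_clusters, sizes, config.covariates, rng)
    X = np.column_stack([np.ones(Xc.shape[0]), Xc])
    beta = config.beta()
    y = generate_outcomes(X, beta, sizes, config.latent_corr, rng)
    ids = np.repeat(np.arange(config.n_clusters), sizes)
    data = ClusteredDataset(
        cluster_ids=ids, y=y, X=X,
        columns=["(Intercept)", "x1", "x2", "x3", "x4", "x5"],
    )
    pi = 1.0 / (1.0 + np.exp(-(X @ beta)))
    return data, beta, pi


def detect_separation(X: np.ndarray, y: np.ndarray, tol: float = 1e-7):
    """Linear-program separation check.

    The data are separable iff a nonzero gamma exists with x_i gamma >= 0 for
    all events and <= 0 for all non-events, with strict inequality somewhere.
    Solved by maximizing the total slack sum_i a_i gamma subject to
    0 <= a_i gamma <= 1 (a_i = x_i for events, -x_i for non-events); a
    positive optimum certifies separation.

    Returns (separable, direction) where ``direction`` is the separating
    gamma (or None).  Raises on LP failure rather than silently reporting
    non-separation.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    sign = np.where(y == 1.0, 1.0, -1.0)
    A = sign[:, None] * X
    c = -A.sum(axis=0)
    A_ub = np.vstack([A, -A])
    b_ub = np.concatenate([np.ones(len(A)), np.zeros(len(A))])
    res = optimize.linprog(
        c, A_ub=A_ub, b_ub=b_ub, bounds=[(None, None)] * X.shape[1], method="highs"
    )
    if res.status not in (0,):
        raise RuntimeError(f"separation LP failed: {res.message}")
    if -res.fun > tol:
        return True, res.x
    return False, None


def achieved_correlation(
    latent_corr: float,
    event_rate: float,
    n_clusters: int = 100_000,
    cluster_size: str = "small",
    slopes=None,
    spec: CovariateSpec = None,
    beta0: float = None,
    rng: np.random.Generator = None,
    chunk: int = 20_000,
) -> float:
    """Empirical within-cluster pairwise correlation of the standardized
    binary outcomes under the generator, pooled over all pairs.

    Uses the true pi to standardize: e_ij = (y_ij - pi_ij)/sqrt(pi(1-pi));
    returns sum over clusters of the pairwise products divided by the total
    number of ordered pairs.
    """
    rng = np.random.default_rng() if rng is None else rng
    spec = CovariateSpec() if spec is None else spec
    cfg = ScenarioConfig(
        n_clusters=chunk, cluster_size=cluster_size, latent_corr=latent_corr,
        event_rate=event_rate, covariates=spec,
    )
    if slopes is not None:
        cfg.beta1 = float(slopes[0])
        cfg.slopes_rest = tuple(slopes[1:])
    cfg.beta0 = (
        calibrate_intercept(cfg.slopes, spec, event_rate, rng) if beta0 is None else beta0
    )
    num = 0.0
    den = 0.0
    done = 0
    while done < n_clusters:
        m = min(chunk, n_clusters - done)
        cfg.n_clusters = m
        data, beta, pi = generate_dataset(cfg, rng)
        e = (data.y - pi) / np.sqrt(pi * (1.0 - pi))
        for sl, n in zip(data.cluster_slices, data.n_i):
            if n < 2:
                continue
            es = e[sl]
            num += es.sum() ** 2 - (es**2).sum()
            den += n * (n - 1)
        done += m
    return num / den


def make_dental_fixture(rng: np.random.Generator = None) -> ClusteredDataset:
    """Deterministic synthetic dataset emulating the structural features of a
    multi-implant dentistry study: 134 patients (clusters), 533 implantations
    (observations), a rare event (~5%), a rare between-patient binary
    covariate whose carriers experienced no events (causing quasi-complete
    separation), a 3-level within-patient factor (two dummies) and a
    continuous covariate (age in decades).

    This is a synthetic stand-in built from the package's own generator —
    not real study data.
    """
    rng = np.random.default_rng(20220609) if rng is None else rng
    N, total = 134, 533
    sizes = np.clip(rng.poisson(4, size=N), 1, 10)
    # adjust to the exact observation count
    while sizes.sum() != total:
        i = rng.integers(N)
        if sizes.sum() > total and sizes[i] > 1:
            sizes[i] -= 1
        elif sizes.sum() < total and sizes[i] < 10:
            sizes[i] += 1
    # rare between-cluster covariate: carriers' implantations total 24
    order = rng.permutation(N)
    art = np.zeros(N)
    left = 24
    for i in order:
        if sizes[i] <= left:
            art[i] = 1.0
            left -= sizes[i]
        if left == 0:
            break
    diabetes = (rng.random(N) < 0.12).astype(float)
    age = rng.normal(6.2, 1.2, size=N)
    timing = rng.choice(3, size=total, p=(0.4, 0.35, 0.25))
    X = np.column_stack(
        [
            np.ones(total),
            (timing == 1).astype(float),
            (timing == 2).astype(float),
            np.repeat(diabetes, sizes),
            np.repeat(art, sizes),
            np.repeat(age, sizes),
        ]
    )
    beta = np.array([-4.0, 0.2, 0.3, 0.3, 0.0, 0.15])
    y = generate_outcomes(X, beta, sizes, 0.85, rng)
    y[X[:, 4] == 1.0] = 0.0  # carriers of the rare covariate: no events
    if y.sum() < 5:  # pragma: no cover - deterministic default seed has ~28 events
        y[:5] = 1.0
    ids = np.repeat(np.arange(N), sizes)
    return ClusteredDataset(
        cluster_ids=ids, y=y, X=X,
        columns=["(Intercept)", "timing_early", "timing_late", "diabetes",
                 "antiresorptive", "age_decades"],
    )
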