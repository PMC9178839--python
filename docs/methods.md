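# Methods

## The problem

Marginal logistic regression for clustered binary outcomes, fitted by
generalized estimating equations (GEE), frequently fails to converge on
sparse data: few clusters, rare events, rare binary covariates. For
independent data the analogous failure is *separation* — a hyperplane of
covariates perfectly discriminating events from non-events, which sends
maximum-likelihood coefficients to infinity — and Firth's penalized logistic
regression (FL) is the standard remedy. Separation appears to be sufficient
but not necessary for GEE non-convergence, so extensions of FL to GEE can
reduce, but not eliminate, the problem. This package implements ordinary GEE
plus three such extensions, a small-sample sandwich-covariance correction,
and a full simulation harness to quantify convergence and accuracy.

## Models and estimators

Notation: N clusters, n_i observations in cluster i, binary outcomes y_ij,
covariate rows x_ij (intercept first, p covariates), marginal model
P(Y_ij = 1 | x_ij) = expit(x_ij' β). W_i = diag(π_ij(1−π_ij)), working
correlation R_i(α) ∈ {independent, exchangeable, AR(1), unstructured}.

**Ordinary GEE** solves Σ_i X_i' W_i (W_i^{1/2} R_i(α) W_i^{1/2})^{-1}
(y_i − π_i) = 0 by alternating a moment update of α from Pearson residuals
with one Fisher-scoring step for β. With scale weights w_ij (the
scale-factor dialect of SAS PROC GEE and R's weighted-GEE implementations:
working variance π(1−π)/w), the estimating function
is Σ_i X_i' Δ_i V_i^{-1} (y_i − π_i) with Δ_i = diag(π(1−π)) and
V_i = A_i^{1/2} R_i A_i^{1/2}, A_i = Δ_i / w; under independence this is the
weighted logistic score. The scale parameter is fixed at 1.

**Penalized GEE** treats the GEE as score equations and adds the Firth
term: U*(β, α) = U(β, α) + ½ trace(I(β, α)^{-1} ∂I(β, α)/∂β) with
I = Σ_i X_i' W_i^{1/2} R_i^{-1} W_i^{1/2} X_i. The derivative ∂I/∂β_m is
computed analytically, holding α fixed, via
∂[π(1−π)]/∂β_m = π(1−π)(1−2π) x_m; a finite-difference oracle guards it in
the tests. Under independence the penalty reduces exactly to the classic
Firth modification, so penalized GEE reproduces FL.

**Augmented GEE** carries over FL's augmented-data representation: stack
three copies of the data — originals (weight 1), a copy with weight h/2 and
a copy with the outcome flipped and weight h/2 — and solve a weighted GEE on
the result. The leverages h are the diagonals of the generalized hat matrix
with blocks H_i = Ω_i^{1/2} X_i (Σ_j X_j' Ω_j X_j)^{-1} X_i' Ω_i^{1/2},
Ω_i = W_i^{1/2} R_i(α)^{-1} W_i^{1/2}. The inner inverse uses the whole-data
information sum: that is the choice under which trace(H) = p + 1 exactly,
so the pseudo data always carry total weight p + 1 and become negligible as
the sample grows (consistency). Each copy forms its own cluster (3N
clusters, the default; an N-cluster variant that merges the copies into
their source clusters is available behind `pseudo_clusters="N"`). The
*iterated* algorithm re-augments at each outer step with the generalized hat
at the current (β, α); the *single-step* algorithm augments once with the
ordinary independence hat from the FL fit and solves one weighted GEE,
warm-started at the FL estimate. Under independence both reproduce FL, and
the single-step variant with an independent working structure always returns
finite estimates — it serves as the fallback estimator in simulations.

**Variance estimation.** The sandwich S = I0^{-1} I1 I0^{-1} with
I0 = Σ X_i'Ŵ_iV̂_i^{-1}Ŵ_iX_i, I1 = Σ d_i d_i',
d_i = X_i'Ŵ_iV̂_i^{-1}(y_i − π̂_i), plus the Morel small-sample correction
S* = I0^{-1} I1* I0^{-1} + δφ I0^{-1}, where I1* is the centered meat
inflated by (N*−1)/(N*−p−1) · N/(N−1), δ = min(0.5, (p+1)/(N−p−1)) and
φ = max(1, trace(α I0^{-1} I1*)/(p+1)). Confidence intervals are
β̂_m ± t_{df=N} SE_m with N the number of clusters (not N − p). For the
augmented estimators the covariance is evaluated on the *original* data at
the final (β̂, α̂) — deliberately not on the augmented pseudo-data.

## Numerical choices

- Convergence: max_m |β̂_m^{k+1} − β̂_m^k| < 0.001 within 20 outer
  iterations; every GEE solve (stand-alone or inside the augmented
  algorithms) allows 30 iterations. The iteration cap for stand-alone
  ordinary GEE is not canonical; 30 is used everywhere for comparability.
- FL itself uses Newton–Raphson on the modified score with up to five
  step-halvings whenever the penalized likelihood would decrease, tolerance
  1e-6, 50 iterations.
- Starting values: FL coefficients for penalized and both augmented
  algorithms (α⁰ = 0, the identity working matrix); plain ML-logistic
  coefficients (IRLS capped at 25 iterations, tolerant of separation) for
  ordinary GEE, mimicking default GEE software.
- Alternation detail: ordinary GEE uses the freshly updated α in each β
  step; penalized GEE uses the previous iteration's α in the β step, which
  is the algorithm's printed form (step 2 computes α̂^{k+1}, step 3 applies
  α̂^k). The fixed points coincide; only the path differs.
- Moment estimator of α (exchangeable): average over clusters of the mean
  pairwise product of Pearson residuals. Clusters with a single observation
  contribute no pairs and are excluded from the averaging denominator
  (the printed formula divides by N; with singleton clusters admitted that
  would bias α̂ toward zero). AR(1) uses lag-one products, unstructured
  pairwise means per position pair. With scale weights the residuals carry
  the factor sqrt(w) while the pair-count denominators stay unweighted —
  deliberately: the flipped pseudo-observations are not mean-centered
  (mean 1 − 2π), and a weight-normalized estimator would let them inflate
  α̂ grossly; the damped dialect (also what weighted-GEE engines implement)
  keeps the pseudo contribution of order h. A side effect is that the
  augmented methods' α̂ is shrunk toward zero relative to ordinary GEE's.
- A fit is flagged non-convergent (never an exception) when the tolerance
  is not met in time, when the estimated α leaves (−1, 1) or the invertible
  range of R (exchangeable needs α > −1/(n_max−1)), or on a singular
  information matrix; fitted probabilities are clipped to
  [1e-10, 1 − 1e-10].
- φ's trace formula presumes a scalar α; for the unstructured structure the
  mean off-diagonal estimate is substituted (documented deviation), and
  α = 0 (φ = 1) is used under independence.
- Per-cluster linear algebra is batched by cluster size; the exchangeable
  R^{-1} uses its closed form (I − α/(1+(n−1)α) J)/(1−α), and Ω^{1/2} a
  batched symmetric eigendecomposition.

## The synthetic-data generator

One cell of a 36-scenario factorial design: N ∈ {20, 50, 100} clusters;
cluster sizes truncated-Poisson with (mean, min, max) = (5, 1, 10),
(10, 1, 20), (20, 1, 40) for small/moderate/large ("mean" is the parameter
of the untruncated Poisson, realized by rejection); latent exchangeable
correlation 0.7 or 0.9; marginal event rate 0.1 or 0.3.

Covariates come from five correlated standard normals Z1..Z5: Z1, Z2 are
drawn once per cluster (between-cluster covariates) and Z3–Z5 per
observation from their conditional distribution given (Z1, Z2), preserving
the joint correlation. Transformations: X1, X2, X3 binary with prevalences
0.5/0.3/0.2; X4 ordinal by quartile binning (0–3); X5 = exp(Z5/2)
winsorized at Q1 − 3·IQR and Q3 + 3·IQR, quartiles obtained by transforming
the standard-normal quartiles (fixed bounds, not per-sample). The latent
correlation matrix (entries 0.1–0.3) and the true slopes
β_2..β_5 = (−0.5, 0.5, 0.25, 0.25) are reconstructions of a realistic
covariate mix; only β_1 = 0.69 — the effect of the between-cluster binary
variable of interest — is fixed by design. The intercept is calibrated by
Monte Carlo (400,000 draws, Brent root-finding, tolerance 0.002) to hit the
target marginal rate.

Outcomes use the latent-threshold (Gaussian copula) construction:
z_ij = sqrt(ρ) a_i + sqrt(1−ρ) b_ij with standard-normal a_i, b_ij, and
y_ij = 1{Φ(z_ij) < expit(x_ij'β)}. The marginal logistic model holds
*exactly*; the achieved correlation of the binary outcomes is far below the
latent ρ and increases with the event rate (about 0.38 at ρ = 0.7, rate
0.1; about 0.66 at ρ = 0.9, rate 0.3).

What the generator does *not* emulate: covariate measurement error, missing
data, informative cluster sizes, non-exchangeable dependence, or real-world
covariate distributions beyond the transformed-normal family — so passing
tests certify the estimators' behavior under a clean marginal model, not
robustness to those violations.

`make_dental_fixture()` builds a deterministic *synthetic* stand-in for a
multi-implant dentistry study: 134 clusters, 533 observations, ~5% events, a
rare between-cluster binary covariate (24 rows) whose carriers have no
events (quasi-complete separation), a 3-level within-cluster factor and a
continuous covariate. On it, ordinary GEE diverges while the penalized and
augmented estimators return finite, plausible coefficients.

## Evaluation harness

A fit counts as non-convergent if the solver said so, if α̂ ∉ (−1, 1), or if
any slope is farther than 10 reference SEs from its true value; the
reference SE of coefficient j is the root of the scenario-averaged j-th
sandwich-variance diagonal evaluated at the true β and the true working
correlation. "True working correlation" is taken on the achieved
binary-outcome scale (estimated by Monte Carlo from the generator), not the
latent scale — the binary scale is what the sandwich formula consumes.
Non-convergent fits are replaced by single-step augmented GEE with
independent working structure before computing bias, RMSE of β̂_1, RMSE of
predicted probabilities (per-dataset MSE averaged across datasets, *then*
rooted), coverage and power of t-based 95% intervals. Rarely a generated
dataset is degenerate (a between-cluster binary constant across every
cluster, probability ≈ 0.7^20 per dataset at N = 20): it is skipped in the
reference-SE average, counted as non-convergent for every method and
excluded from accuracy averages when even the fallback cannot be fitted.
Per-dataset RNG substreams derive from (seed, scenario factors, dataset
index), so scenarios are reproducible and order-independent.

## Problem sizes used by the shipped checks

The acceptance script runs the hardest cell (N = 20, small clusters,
ρ = 0.9, rate 0.1) at 1000 datasets and estimates achieved correlations
from 100,000 clusters. The test suite runs the same cell at 500 datasets,
and the 36-scenario accuracy sweep at 200 datasets per scenario with the
full four-estimator set in the N = 100, rate-0.3 cells — sizes chosen to
keep the whole suite fast while leaving binomial Monte-Carlo error well
inside the asserted bands.

## Known limitations

- Logit link and binary outcomes only; no GEE2, no scale-parameter
  estimation, no FLAC-style added-covariate augmentation, no equal-weight
  pseudo-observations.
- Finite estimates are *not* guaranteed for penalized or augmented GEE
  under separation with non-independent working structures — that matches
  the methods' actual behavior; only the single-step variant under
  independence is guaranteed finite.
- The moment estimator's behavior for the unstructured structure with
  heavily unbalanced cluster sizes relies on per-position pair counts and
  is the least exercised code path.
- Supplementary-level details of the reference covariate design were not
  available; the generator's defaults are documented reconstructions, so
  quantities that depend on the covariate mix (e.g. the separable fraction
  in the hardest cell) carry extra uncertainty beyond Monte-Carlo error.
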