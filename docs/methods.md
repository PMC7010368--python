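# Methods

## Model and estimators

The package estimates high conditional quantiles Q_y(τ|**x**) = **x**ᵀβ(τ)
of a heavy-tailed response. Two regression-quantile estimators are
provided, both exact linear-programming solutions of the check-loss
problem:

* **regular**: minimize Σ ρ_τ(y_i − x_iᵀβ) with ρ_τ(u) = u(τ − 1{u<0});
* **weighted**: minimize Σ w_i ρ_τ(y_i − x_iᵀβ) for positive weights w_i
  that depend on the covariates and τ but not on y_i.

The LP uses the standard split of the residual into nonnegative slacks,
`min Σ w_i(τ u_i + (1−τ) v_i)` subject to `Xβ + u − v = y`, solved with
HiGHS through `scipy.optimize.linprog`. Weights enter the objective
multiplicatively, so the fit is invariant to rescaling the weight vector;
any optimal basic solution is accepted, and a residual of exactly zero
counts as nonnegative in the indicator. Objectives are recomputed from the
returned coefficients and validated against a 1e−9 solver tolerance; on
small problems the tests cross-check the LP optimum against exhaustive
enumeration of all p-point interpolating fits, and against the
statsmodels IRLS fitter where that converges.

The efficiency-motivated weight is the conditional density of the
response at the conditional quantile, w_i = f(ξ(τ|x_i)|x_i): observations
whose response is sharply concentrated near the target quantile carry the
most information about it. Under standard regularity conditions the
weighted estimator with this weight is asymptotically normal with
covariance τ(1−τ)D₀⁻¹, D₀ = lim n⁻¹Σ f_i² x_i x_iᵀ; a simulation test
verifies the empirical covariance at n = 2000 against this formula within
a factor of two.

A simpler comparison weight, w_i ∝ ‖x_i‖⁻¹ over the non-intercept
regressors (normalized to sum 1), is also provided. Note a degeneracy: in
a single-regressor design this is proportional to 1/x_i, which for the
simulation model below is exactly proportional to the oracle density
weight — scale invariance then makes the two weighted estimators
identical. An `include_intercept` option extends the norm to the constant
coordinate for users who want the weights bounded as a regressor
approaches zero.

## Simulation ground truth

The bivariate Pareto (Mardia type I) law with tail index α has joint cdf
F(x,y) = 1 − x^−α − y^−α + (x+y−1)^−α on (1,∞)², Pareto(α) margins, and
conditional density f(y|x) = (α+1)x^(α+1)/(x+y−1)^(α+2). Its conditional
quantile is exactly linear, ξ(τ|x) = 1 + x((1−τ)^(−1/(α+1)) − 1), and the
density at the quantile is (α+1)(1−τ)^((α+2)/(α+1))/x. (The sign of the
joint-cdf cross term is fixed by requiring a nonnegative mixed density;
the tests verify that the numeric mixed partial equals
α(α+1)(x+y−1)^−(α+2) and that the closed-form quantile inverts the
integral of the conditional density.) At α = 3 the 0.95- and 0.97-quantile
slopes are 1.114743 and 1.402811. Sampling is by inverse-cdf composition,
X = (1−U₁)^(−1/α), Y = 1 + X((1−U₂)^(−1/(α+1)) − 1), from one seeded
generator.

## Monte Carlo efficiency study

Default study conditions: m = 1000 replicates of size n = 300 at α = 3,
τ ∈ {0.95,…,0.99}, scoring each fitted line by the closed-form integral of
its squared deviation from the true line over x ∈ [1, N] with N = 1000
(quadrature is kept only as a test oracle). All estimators share each
replicate's sample (common random numbers), and per-replicate RNG
substreams are spawned from the master seed. SEFF is the ratio of the
regular estimator's SMSE to a candidate's.

A caveat the harness makes visible: because the design is heavy-tailed,
the integrated squared error has a heavy-tailed distribution across
replicates — at τ = 0.99 a single replicate can contribute ~20% of the
m = 1000 sum. SEFF estimates at the most extreme τ therefore carry
substantial seed-to-seed variability (a few tenths), and at τ = 0.99 the
weighted estimator's measured SEFF fluctuates around 1. The weighted
estimator's SMSE at τ = 0.95 agrees with its asymptotic variance limit to
a few percent, which is the sharper evidence that the implementation is
correct.

## Kernel weight estimation

On data, f(ξ(τ|x_i)|x_i) is estimated in three steps, all using the
whitened ("Fukunaga") multivariate normal-kernel estimator
f̂(z) = (det S)^(−1/2)(nh^d)⁻¹ Σ k((z−Z_j)ᵀS⁻¹(z−Z_j)/h²) with S the
sample covariance (ddof = 1) of the coordinates being smoothed and the
normal-reference bandwidth h = (4/(d+2))^(1/(d+4)) n^(−1/(d+4)):

1. ξ̂(τ|x_i) by inverting the Nadaraya–Watson conditional cdf
   F̂(y|x) = Σ K_h(x−x_j)1{y_j ≤ y}/Σ K_h(x−x_j) over the sorted observed
   responses (inf over the data grid);
2. the joint density f̂(y, x) in dimension k+1 and the marginal μ̂(x) in
   dimension k, each whitened by its own covariance and smoothed with the
   rule in its own dimension;
3. w_i = f̂(ξ̂_i, x_i)/μ̂(x_i).

Degenerate covariances (a constant column) raise rather than being
silently regularized; callers may jitter. A constant-bandwidth,
constant-whitening smoother of this kind assumes the covariate
distribution is reasonably compact. On a compact design the estimated
weights track the closed-form oracle (Spearman rank correlation ≈ 0.85 at
n = 500, improving with n — tested). On the α = 3 bivariate-Pareto design
they do not: the sample covariance used for whitening is itself
heavy-tailed (its variance is infinite at α = 3), and the inversion step
acquires an x-dependent bias — upward at the support edge, downward in the
sparse tail — which the steep density gradient near the extreme quantile
amplifies and which can invert the weight ranking. This is a genuine
limitation of constant-bandwidth kernel weighting under heavy-tailed
covariates, not a tuning accident; variants examined during development
(robust scatter matrices, leave-one-out kernels, smaller bandwidths,
internally consistent mixture inversion) mitigate but do not remove it.

## Peaks over threshold

Excesses over a user threshold (≥ by default, > optionally) are modelled
by the two-parameter GPD with shape γ > 0 and scale σ > 0:
F(x) = 1 − (1+γx/σ)^(−1/γ). The MLE uses the exact profile-likelihood
reduction to one dimension: with θ = γ/σ, the optimal shape for fixed θ is
γ(θ) = mean(log(1+θx)), and the profile is minimized by a bounded scalar
search in log θ (tolerance 1e−10). Samples whose unrestricted optimum
would have γ ≤ 0 return the restricted optimum at a tiny positive shape —
an exponential-like fit — rather than failing. Scale equivariance and
dominance over a moment-based start are tested.

Goodness of fit uses the Kolmogorov–Smirnov, Cramér–von Mises and
Anderson–Darling EDF statistics. Because the null parameters are
estimated, p-values come from a parametric bootstrap (default B = 1000,
seeded) with re-estimation in every replicate; p = (1 + #{boot ≥
obs})/(B+1). A size simulation (200 replicates of n = 100 with B = 199,
sizes chosen to keep the full check inside a few minutes) verifies the
bootstrap K–S test holds its nominal 0.05 level, and a power check
verifies it rejects log-normal data at n = 500.

## Relative R(τ)

On real data, where SMSE is unavailable, the weighted and regular fits are
compared by R(τ) = 1 − V_weighted/V_regular, with V_regular the mean check
loss of the regular fit and V_weighted the weight-multiplied check loss of
the weighted fit. As defined, R is not invariant to the overall scale of
the weights (V_weighted carries w_i where V_regular carries 1/n), so the
package reports the raw value by default and a variant with weights
normalized to mean 1/n alongside it; with unnormalized positive weights R
is bounded above by 1 but not below by −1.

## Synthetic fixtures

`make_fixtures` writes three kinds of CSV test data: bivariate-Pareto
samples (α = 3, n ∈ {300, 500}); pure GPD excesses at (γ, σ) =
(0.2636, 5.1552); and a "snowfall-like" set of 600 rows with covariate
t ~ U(−20, 15) (a maximum-temperature stand-in), response
max(0, 0.5 − 0.08t + 0.006t²) plus GPD(0.26, 5.2) noise, thresholded at 5
by the pipeline (~320 rows retained). The quadratic amplitude is kept
small relative to the noise scale so the threshold excesses remain
plausibly GPD — matching the situation the pipeline is designed for —
while still giving the quadratic design a real signal. The fixtures
emulate the shape of daily-extreme data (mild conditional structure,
heavy-tailed residual); they do not emulate serial dependence, seasonality
or measurement rounding of real records, so passing tests demonstrate the
pipeline's correctness, not calibration on any particular dataset.

## Numerical choices and limitations

* LP solver tolerance 1e−9 on the objective; degeneracy (more than p zero
  residuals) means coefficients may differ between optimal bases, so tests
  compare objectives in that case.
* Quantile levels are validated to lie strictly inside (0, 1); weights
  must be strictly positive and finite.
* The GPD branch γ ≤ 0 (bounded tails) and threshold-selection
  diagnostics are out of scope; no quantile-crossing correction is applied
  across τ values; no confidence intervals are provided for β̂(τ).
* All CLI commands and library entry points are deterministic given their
  seed; fixture files hash identically across runs.
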