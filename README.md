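# extremeqr

Density-weighted quantile regression for high conditional quantiles of
heavy-tailed responses — snowfall extremes, emission extremes, losses, and
other peaks-over-threshold data where the interesting question is not the
mean but the 95th–99th conditional percentile.

## The method

For observations (y_i, **x**_i), the τ-th regression quantile minimizes the
check (pinball) loss

```
β̂(τ) = argmin_β Σ_i ρ_τ(y_i − x_iᵀβ),    ρ_τ(u) = u(τ − 1{u<0}),
```

solved exactly as a linear program. At extreme τ the classical estimator is
inefficient; weighting each observation by the conditional density of the
response at the conditional quantile,

```
β̂_w(τ) = argmin_β Σ_i w_i ρ_τ(y_i − x_iᵀβ),    w_i = f(ξ(τ|x_i) | x_i),
```

downweights covariate regions where the response is diffuse near the target
quantile. On real data w_i is estimated by kernel smoothing: a whitened
multivariate normal-kernel density estimator for the joint and marginal
densities, `f̂(y|x) = f̂(y,x)/μ̂(x)`, evaluated at `ξ̂(τ|x) = inf{y :
F̂(y|x) ≥ τ}` from a Nadaraya–Watson conditional cdf. Threshold excesses of
the response are modelled by the generalized Pareto distribution GPD(γ, σ)
with maximum likelihood and bootstrap Kolmogorov–Smirnov /
Anderson–Darling / Cramér–von Mises goodness-of-fit tests.

A bivariate-Pareto (Mardia type I) simulation model with tail index α
provides closed-form ground truth — its conditional quantile is the line
`ξ(τ|x) = 1 + x((1−τ)^(−1/(α+1)) − 1)` and the oracle weight is
`(α+1)(1−τ)^((α+2)/(α+1))/x` — so the Monte Carlo harness can measure each
estimator's integrated squared error against the truth (SMSE) and the
efficiency ratio SEFF = SMSE(regular)/SMSE(weighted).

## Worked example

On any single sample either estimator can win — the gain is an average
property, so the natural demonstration is the Monte Carlo harness. Five
hundred replicates of size 300 from the α = 3 model, each fitted with and
without the oracle density weights:

```python
from extremeqr import BenchmarkConfig, run_benchmark

cfg = BenchmarkConfig(
    m=500, n=300, tau_grid=(0.95, 0.97),
    estimators=("regular", "weighted_oracle"), seed=42,
)
result = run_benchmark(cfg)
print(result.seff.round(3))
```

prints

```
      regular  weighted_oracle
tau
0.95      1.0            1.249
0.97      1.0            1.526
```

SEFF is the ratio of the unweighted estimator's simulation mean squared
error to the weighted one's, integrated against the true quantile line over
x ∈ [1, 1000]: values above 1 mean the density weighting delivered a more
accurate extreme-quantile line on average. SEFF estimates at these τ are
themselves noisy (the error integral is heavy-tailed across replicates), so
expect seed-to-seed variation of a few tenths.

The same workflow runs from the shell on CSV data:

```bash
extremeqr fixtures --out-dir fixtures --seed 0          # synthetic test data
extremeqr gpd-fit --input fixtures/snowfall_like.csv \
    --column snowfall --threshold 5 --boot 199 --seed 7
extremeqr benchmark --m 200 --n 300 --seed 11 --out results/
```

`extremeqr pipeline --input data.csv --config cfg.yaml` runs the full
threshold → GPD → quantile-regression analysis and writes a JSON report
with the fitted coefficients, goodness-of-fit p-values and the Relative
R(τ) comparison of the weighted vs the unweighted fit.

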