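# spatialnb

Bayesian spatial negative-binomial modeling of areal count data —
disease-mapping style analyses of per-cluster counts such as the number
of undernourished under-five children in survey clusters nested within
administrative regions.

The package is aimed at biostatisticians and epidemiologists who want a
self-contained, dependency-light workflow for small-area count data:
exploratory spatial statistics, an over-dispersion screen, a from-scratch
MCMC sampler for the standard hierarchy of count models, predictive model
comparison, and relative-risk mapping.

## The models

Counts `y_k` for clusters `k = 1..n` are negative binomial with a log
link and dispersion `γ` (`Var(y) = μ + γμ²`):

```
y_k ~ NB(μ_k, γ)
log μ_k = x_kᵀβ  [+ Φ_{r(k)}]  [+ u_k]
```

Four nested structures are fitted and compared:

| structure | spatial term | heterogeneity term |
|-----------|--------------|--------------------|
| `glm`     | —            | —                  |
| `glmm`    | exchangeable region intercepts | exchangeable cluster intercepts |
| `icar`    | intrinsic CAR field Φ on the region adjacency graph | — |
| `bym`     | ICAR field Φ (structured) | iid `u_k ~ N(0, τ²ᵤ)` (unstructured) |

plus the proper-CAR `leroux` variant with mixing parameter `ρ ∈ (0,1)`.
The ICAR prior is the pairwise-difference Gaussian Markov random field

```
p(Φ | W, τ²_Φ) ∝ exp( −1/(2τ²_Φ) Σ_{k<j} W_kj (Φ_k − Φ_j)² )
```

identified by a sum-to-zero constraint, with full conditionals
`Φ_k | Φ_{−k} ~ N( Σ_j W_kj Φ_j / Σ_j W_kj , τ²_Φ / Σ_j W_kj )`.
Variance components carry inverse-gamma hyperpriors (IG(1, 5·10⁻⁴) for
the random effects, IG(1, 10⁻⁴) for the coefficient scale); sampling is
Metropolis-within-Gibbs (see `docs/methods.md`).

Exploratory tools include global/local Moran's I, the Getis-Ord Gi*
hot-spot statistic, mean center / standard distance, queen-contiguity,
exponential (`w_ij = exp(−d_ij)`) and inverse-distance weight matrices,
and Pearson/deviance over-dispersion ratios from in-package ML Poisson
and NB fits. Model comparison uses WAIC and Pareto-smoothed
importance-sampling LOO; convergence is checked with rank-normalized
split R̂ and bulk/tail ESS. Fitted spatial effects map to relative
risks `RR = E[exp(Φ + u)]`, categorized low (RR < 1), moderate
(1 ≤ RR ≤ 1.5), high (RR > 1.5), and coefficients translate to percent
changes `100·(exp(β)−1)`.

## Worked example

Generate a synthetic survey-like study (10 regions × 10 clusters, known
truth, strong spatial field), fit the convolution model and the
non-spatial GLM, compare, and map risk:

```python
from spatialnb import synthetic, mcmc, evaluation, riskmap

params = synthetic.TrueParams(beta=(2.5, -0.2, 0.15), tau2_phi=1.0,
                              n_regions=10, clusters_per_region=10, seed=5008)
table, W, truth = synthetic.simulate_study(params)

bym = mcmc.sample_posterior(table, mcmc.ModelSpec("bym", ("x1", "x2"), W=W),
                            chains=2, iterations=1500, warmup=750, seed=0)
glm = mcmc.sample_posterior(table, mcmc.ModelSpec("glm", ("x1", "x2")),
                            chains=2, iterations=1500, warmup=750, seed=0)

print(mcmc.fit_summary(bym, params=["beta[1]", "gamma", "tau2_phi"]).round(2))
print(evaluation.compare_models({"bym": bym, "glm": glm})[["waic", "d_waic"]].round(1))
print(riskmap.relative_risk(bym, area_level="region").round(2).head())
```

prints (abridged)

```
           estimate    sd  ci_0.025  ci_0.975  rhat  bulk_ess  tail_ess
beta[1]        2.54  0.12      2.30      2.79   1.0    889.86   1180.37
gamma          0.46  0.08      0.32      0.62   1.0    715.49    812.12
tau2_phi       2.35  1.27      0.87      5.76   1.0    678.72    864.07

        waic  d_waic
bym    708.7     0.0
glm    798.2    89.4

   area_id    rr  rr_lo  rr_hi  exceedance  category
0        1  0.69   0.43   1.04        0.04       low
...
4        5  4.08   2.74   5.90        1.00      high
```

The intercept (true 2.5) and dispersion (true 0.5) are recovered, the
spatial model beats the GLM by ~90 WAIC points, and the two regions
generated with structured effects of +1.37 are flagged `high` with
exceedance probability 1.00 — exactly the pattern a risk map is for.

The same chain runs from the shell:

```
spatialnb pipeline --out run --seed 1
```

executing simulate → weights → ESDA → dispersion → four model fits →
WAIC/LOO comparison → risk map, with a provenance manifest.

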