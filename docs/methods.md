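# Methods

This note documents the statistical machinery in `spatialnb`: the data
model, the priors, the sampler, the diagnostics, the synthetic-data
generator, and the numerical choices that were genuinely open.

## Data model

The unit of analysis is a spatial cluster (survey enumeration area)
carrying a non-negative count `y_k` (e.g. undernourished children),
covariates `x_k` with a leading intercept, coordinates, and a region id
`r(k) ∈ 1..R`. Regions carry an adjacency graph encoded as a binary
queen-contiguity weight matrix `W`.

All likelihoods are negative binomial on the mean/dispersion scale:
`E(y) = μ`, `Var(y) = μ + γμ²`, i.e. size parameter `1/γ`. The linear
predictor is always on the log scale, `log μ = Xβ + Φ + u`; the
exponential link is what makes `exp(β)−1` a percent change and
`exp(Φ+u)` a relative risk, and it is used consistently in generation
and fitting.

Model structures: `glm` (fixed effects only), `glmm` (exchangeable
region + cluster intercepts; no graph), `icar` (region-level intrinsic
CAR field), `bym` (ICAR field + iid cluster effects `u`), and `leroux`
(proper CAR, `Q(ρ) = ρ(D−W) + (1−ρ)I`, `ρ ~ U(0,1)`). `stern_cressie`
is accepted as an alias for `leroux` with a warning: the two conditional
specifications given for them are typographically identical, and no
distinct Stern–Cressie form is recoverable, so only one proper-CAR
variant is implemented.

The ICAR density is the unique-pair quadratic form
`−Σ_{k<j} W_kj (Φ_k−Φ_j)² / (2τ²_Φ) = −ΦᵀQΦ/(2τ²_Φ)` with
`Q = diag(W1) − W`. A double-sum over ordered pairs would simply double
the quadratic form, equivalent to halving `τ²_Φ`; the unique-pair form is
the standard convention and is what the full conditionals
`N(ΣWΦ/ΣW, τ²/ΣW)` integrate to. Impropriety (rank `R−1` on a connected
graph) is handled by re-centering Φ to sum to zero after every sweep,
with the subtracted mean folded into the intercept so the likelihood is
untouched; disconnected graphs are rejected for ICAR/BYM fits.

## Priors

* `β_j ~ N(0, τ²_β)`, shared `τ²_β ~ IG(1, 10⁻⁴)` (an `IG(0.001, 0.001)`
  variant can be set through `PriorConfig`). The scale is learned, so
  the prior is effectively weakly informative at any covariate scaling.
* `τ²_Φ, τ²_u ~ IG(1, 5·10⁻⁴)`. Note these densities behave like
  `x⁻²` away from zero: at a few hundred observations they place
  substantial mass on very small variances, so weak spatial signals are
  shrunk toward zero — see "Known behavior" below.
* `ρ ~ Uniform(0, 1)` for the Leroux model.
* `γ ~ Gamma(2, 2)` (shape–rate; mean 1, sd ≈ 0.7). The dispersion
  prior is a genuine modeling choice here. A deliberately "vague"
  Gamma(0.01, 0.01) was tried first and rejected: its density diverges
  at 0, and the BYM convolution then has an attracting degenerate mode
  in which the cluster effects `u` interpolate every observation while
  `γ → 0` (a saturated pseudo-Poisson fit with runaway `τ²_u`). Any
  dispersion prior whose density vanishes at zero removes that funnel;
  Gamma(2, 2) is weakly informative over the range (0.05–3) that count
  data of this kind actually produce. The choice is exposed in
  `PriorConfig` and should be revisited for data with dispersion far
  from 1.

## Sampler

`sample_posterior` runs independent Metropolis-within-Gibbs chains
(defaults: 4 chains × 2000 iterations, first 1000 discarded as warmup;
chain seeds are spawned deterministically from one master seed, and
fixed seeds reproduce draws bit-for-bit).

Per sweep:

1. **β** — adaptive random-walk MH on each coordinate (target
   acceptance 0.44), plus a block proposal using the empirical
   covariance of the warmup draws (target 0.23), plus — after warmup —
   an independence proposal frozen at the warmup draws' mean and 1.5×
   covariance. The independence kernel yields near-iid β draws when the
   conditional is approximately Gaussian (ESS per draw ≈ 0.3–0.4) and
   is harmless otherwise; the random-walk kernels guarantee
   irreducibility regardless.
2. **Φ** — single-site adaptive random-walk MH; the acceptance ratio
   combines the likelihood of the site's clusters with the prior full
   conditional (ICAR, exchangeable, or Leroux as appropriate). Sites
   are visited in random order. Pure independence proposals drawn from
   the prior full conditional were tried and rejected: when the
   variance Gibbs step drifts small, such proposals can no longer move
   the field and the chain is effectively absorbed at the degenerate
   mode.
3. **u** — the cluster effects are conditionally independent given
   everything else, so all n random-walk proposals are
   accepted/rejected element-wise in one vectorized pass, with per-site
   adaptive scales.
4. **γ** — adaptive random-walk on `log γ` plus a frozen post-warmup
   independence kernel on the log scale (same rationale as for β).
5. **ρ** — adaptive random-walk on `logit ρ`; the acceptance includes
   the `½ log|Q(ρ)|` determinant term (dense `slogdet`, cheap at
   region-level dimensions).
6. **Variances** — conjugate inverse-gamma Gibbs draws
   `IG(a + rank/2, b + QF/2)` with rank `R−1` for a connected ICAR
   field, `R`/`n` for exchangeable effects, `p` for β.
7. **Translation moves** — the intercept trades off one-for-one against
   the mean of each exchangeable random-effect block. A
   generalized-Gibbs (location-sweep) draw of the shift `m` from its
   exact conditional, applying `u → u − m`, `β₀ → β₀ + m`, removes that
   ridge without altering the target. The ICAR field is instead
   deterministically re-centered (its prior is translation-invariant,
   so only β₀'s broad prior is touched).

All adaptation uses Robbins–Monro scale updates and stops at the end of
warmup, so the sampling-phase kernel is fixed and satisfies detailed
balance. The pointwise log-likelihood matrix is stored for every
retained draw. Non-finite states abort with a diagnostic dump.

## Diagnostics and model comparison

* **Split R̂ and ESS** follow the rank-normalization recipe: draws are
  rank-transformed through the normal quantile function, chains split in
  half; R̂ = √(((n−1)/n·W + B/n)/W). Bulk ESS uses Geyer's initial
  monotone sequence on the FFT autocovariance averaged across split
  chains; tail ESS is the minimum over the 5%/95% exceedance
  indicators. These match the `arviz` reference implementation to
  rounding error (asserted in the tests).
* **WAIC**: `elpd = Σ_k [log mean_d exp(ll) − var_d(ll)]` with stable
  log-sum-exp and the `ddof = 1` sample variance (the R `loo`
  convention; `arviz` uses `ddof = 0`, a difference of order `p/S`).
  Points with pointwise variance > 0.4 are reported as unstable.
* **PSIS-LOO**: importance ratios `1/p(y_k|θ_d)` are Pareto-smoothed —
  the top `min(0.2S, 3√S)` ratios are replaced by generalized-Pareto
  quantiles fitted with the Zhang–Stephens empirical-Bayes estimator —
  and truncated at the raw maximum. `k > 0.7` flags unreliable points;
  with too few draws for a tail fit the estimator falls back to
  truncated importance sampling and reports `k = ∞`. Matches `arviz`
  with `reff = 1` to 10⁻⁸.
* **Posterior predictive checks** replicate `y` from evenly spaced
  retained draws via the Poisson–gamma mixture and compare observed
  mean/max and the count histogram against the replicate distribution.

## Synthetic-data generator

The generator emulates a DHS-style survey: `R` regions (default 11)
with a connected adjacency graph (Delaunay triangulation of random
points by default — a reasonable stand-in for an administrative map —
or grid/cycle), a fixed number of clusters per region (defaults give
n ≈ 305 to match the survey scale), binary household/maternal
indicators with plausible national prevalences plus a continuous
mother's-age column on 15–49 years, a region-level ICAR field sampled
exactly from the restricted GMRF eigenbasis, iid cluster noise, and NB
counts via the Poisson–gamma mixture. Default effect scales —
`τ_Φ = 0.35`, `τ_u = 0.37`, `γ = 0.5`, intercept ≈ 2.5 (baseline count
≈ 12) — mirror the magnitudes reported for this kind of under-nutrition
analysis. Every stage draws from a substream spawned off one master
seed.

What the generator does *not* emulate: survey design weights and
two-stage sampling, covariate correlation structure (covariates are
independent), within-cluster anthropometry, or realistic geography.
Passing recovery tests therefore demonstrates correctness of the
machinery under the stated model, not robustness to design effects or
confounding in real survey data.

## Known behavior and limitations

* **Structured/unstructured confounding.** In the BYM convolution the
  regional mean of `u` is likelihood-equivalent to `Φ_r`, and NB
  overdispersion `γ` can absorb regional structure as unstructured
  noise. At the synthetic scale (≈100 clusters) with the IG(1, 5·10⁻⁴)
  variance hyperpriors, the posterior can legitimately shrink `τ²_Φ`
  and `τ²_u` toward zero when the spatial signal is weak; fixed-effect
  inference is unaffected (coverage is verified by simulation), but the
  Φ/u decomposition should be read with care on small data sets. With a
  strong field (`τ²_Φ ≈ 1`) the spatial mode dominates and WAIC
  separates the models decisively.
* **Scaled-down defaults.** Simulation-based tests and the acceptance
  script use 10 regions × 10 clusters and single short chains
  (600–1000 iterations) for replicate studies, and the full 4 × 2000
  protocol for the convergence check; these sizes were chosen as the
  smallest at which the respective phenomena are stable, keeping the
  whole suite in the minutes range on one core.
* **Distances** are planar Euclidean on raw coordinates by default,
  matching the `exp(−d)` / `1/d` weight definitions as printed in the
  disease-mapping literature this follows; a haversine option exists
  for real lat/lon.
* The sampler is random-walk based: for models far outside the tested
  regime (very large n, extreme dispersion) a gradient-based sampler
  would mix better. No spatio-temporal extension, no DIC, no k-fold CV,
  no survey weights.
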