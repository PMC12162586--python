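"""Bayesian negative-binomial spatial count models via Metropolis-within-Gibbs.

Implements the four competing model structures for areal counts —

* ``glm``   : log mu = X beta
* ``glmm``  : log mu = X beta + v_r + u_k   (exchangeable region and
  cluster intercepts, no spatial graph)
* ``icar``  : log mu = X beta + Phi_r       (intrinsic CAR field on the
  region adjacency graph)
* ``bym``   : log mu = X beta + Phi_r + u_k (convolution of a structured
  ICAR field and unstructured cluster noise)

plus the proper-CAR ``leroux`` variant (mixing parameter rho in (0,1);
``stern_cressie`` is accepted as an alias).  The likelihood is negative
binomial with dispersion gamma (Var = mu + gamma mu^2).

Priors: beta_j ~ N(0, tau2_beta) with tau2_beta ~ IG(1, 1e-4);
Phi an (I)CAR Gaussian Markov random field with tau2_phi ~ IG(1, 5e-4);
u_k ~ N(0, tau2_u) with tau2_u ~ IG(1, 5e-4); rho ~ Uniform(0, 1).
The dispersion prior is Gamma(2, 2) on gamma (mean 1): the model family
itself is silent on this choice, and a prior whose density vanishes at
gamma = 0 is needed because the convolution model has a degenerate mode
in which u absorbs every observation and gamma escapes to the Poisson
boundary; any prior with positive (or diverging) density at zero invites
the sampler into that funnel.  The choice is exposed in
:class:`PriorConfig`.

The sampler is Metropolis-within-Gibbs: adaptive random-walk MH on each
beta coordinate and on log gamma / logit rho, single-site adaptive MH
on Phi and u whose acceptance combines the likelihood of the affected
clusters with the prior full conditional (centered at the weighted
neighbor mean), and conjugate inverse-gamma Gibbs draws for the
variance components.  Proposal scales adapt during warmup only and are frozen
afterwards, preserving detailed balance in the sampling phase.  The
ICAR field is re-centered to sum to zero after every sweep, with the
subtracted mean folded into the intercept so the linear predictor is
unchanged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special

from .weights import WeightMatrix

__all__ = [
    "ModelSpec",
    "PriorConfig",
    "PosteriorSamples",
    "nb_loglik_pointwise",
    "log_prior_beta",
    "log_prior_icar",
    "icar_full_conditional",
    "leroux_full_conditional",
    "gibbs_update_variance",
    "sample_posterior",
    "fit_summary",
    "log_posterior",
]

STRUCTURES = ("glm", "glmm", "icar", "bym", "leroux", "stern_cressie")


@dataclass(frozen=True)
class ModelSpec:
    """Which model structure to fit and on which data columns.

    ``formula`` lists covariate column names (the intercept is implicit);
    ``W`` is the region-level weight matrix, required for the spatial
    structures; ``region_col`` maps clusters to 1-based region ids.
    """

    structure: str
    formula: tuple[str, ...] = ()
    W: WeightMatrix | None = None
    region_col: str = "region_id"

    def __post_init__(self):
        if self.structure not in STRUCTURES:
            raise ValueError(f"unknown structure {self.structure!r}; choose from {STRUCTURES}")
        if self.structure == "stern_cressie":
            warnings.warn(
                "stern_cressie is fitted as the Leroux proper-CAR model "
                "(the two conditional specifications coincide here)",
                stacklevel=2,
            )
        if self.structure in ("icar", "bym", "leroux", "stern_cressie") and self.W is None:
            raise ValueError(f"structure {self.structure!r} requires a weight matrix W")
        object.__setattr__(self, "formula", tuple(self.formula))

    @property
    def is_spatial(self) -> bool:
        return self.structure in ("icar", "bym", "leroux", "stern_cressie")

    @property
    def has_phi(self) -> bool:
        return self.structure != "glm"

    @property
    def has_u(self) -> bool:
        return self.structure in ("glmm", "bym")

    @property
    def has_rho(self) -> bool:
        return self.structure in ("leroux", "stern_cressie")


@dataclass(frozen=True)
class PriorConfig:
    """Hyperprior settings: (shape, scale) for the inverse-gamma variance
    priors and (shape, rate) for the gamma prior on the NB dispersion."""

    tau2_beta: tuple[float, float] = (1.0, 1e-4)
    tau2_phi: tuple[float, float] = (1.0, 5e-4)
    tau2_u: tuple[float, float] = (1.0, 5e-4)
    gamma_prior: tuple[float, float] = (2.0, 2.0)

    def __post_init__(self):
        for name in ("tau2_beta", "tau2_phi", "tau2_u", "gamma_prior"):
            a, b = getattr(self, name)
            if a <= 0 or b <= 0:
                raise ValueError(f"{name} hyperparameters must be positive")


class PosteriorSamples:
    """Retained MCMC draws: chains x iterations per parameter block, plus
    the pointwise log-likelihood matrix used by WAIC/LOO."""

    def __init__(self, draws: dict[str, np.ndarray], loglik: np.ndarray, meta: dict):
        self.draws = draws
        self.loglik = loglik
        self.meta = meta

    @property
    def chains(self) -> int:
        return self.loglik.shape[0]

    @property
    def n_retained(self) -> int:
        return self.loglik.shape[1]

    def parameter_names(self) -> list[str]:
        names = []
        for key, arr in self.draws.items():
            if arr.ndim == 2:
                names.append(key)
            else:
                names.extend(f"{key}[{i + 1}]" for i in range(arr.shape[2]))
        return names

    def get(self, name: str) -> np.ndarray:
        """(chains, iterations) array for a scalar parameter name."""
        if name in self.draws and self.draws[name].ndim == 2:
            return self.draws[name]
        if "[" in name:
            key, idx = name[:-1].split("[")
            return self.draws[key][:, :, int(idx) - 1]
        raise KeyError(name)

    def flat(self, name: str) -> np.ndarray:
        return self.get(name).reshape(-1)

    def loglik_matrix(self) -> np.ndarray:
        """(total draws, n) pointwise log-likelihood."""
        return self.loglik.reshape(-1, self.loglik.shape[2])

    def to_long_dataframe(self) -> pd.DataFrame:
        rows = []
        for name in self.parameter_names():
            arr = self.get(name)
            for c in range(arr.shape[0]):
                rows.append(
                    pd.DataFrame(
                        {
                            "chain": c + 1,
                            "iteration": np.arange(1, arr.shape[1] + 1),
                            "parameter": name,
                            "value": arr[c],
                        }
                    )
                )
        return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# densities


def nb_loglik_pointwise(y, mu, gamma: float) -> np.ndarray:
    """Pointwise NB log-likelihood, log p(y_k | mu_k, gamma).

    Mean/dispersion parameterization with size r = 1/gamma:
    p(y) = C(y + r - 1, y) (r/(r+mu))^r (mu/(r+mu))^y.  Stable via
    log-gamma functions for counts up to ~1e6.
    """
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    if (mu <= 0).any() or not np.isfinite(mu).all():
        bad = int(np.flatnonzero(~np.isfinite(mu) | (mu <= 0))[0])
        raise ValueError(f"invalid mean mu at index {bad}")
    r = 1.0 / gamma
    ll = (
        special.gammaln(y + r)
        - special.gammaln(r)
        - special.gammaln(y + 1)
        + r * (np.log(r) - np.log(r + mu))
        + y * (np.log(mu) - np.log(r + mu))
    )
    if not np.isfinite(ll).all():
        bad = int(np.flatnonzero(~np.isfinite(ll))[0])
        raise ValueError(f"non-finite log-likelihood at index {bad}")
    return ll


def log_prior_beta(beta, tau2_beta: float) -> float:
    """Sum of independent N(0, tau2_beta) log-densities over coefficients."""
    if tau2_beta <= 0:
        raise ValueError("tau2_beta must be positive")
    beta = np.asarray(beta, dtype=float)
    p = beta.size
    return float(-0.5 * p * np.log(2 * np.pi * tau2_beta) - 0.5 * np.sum(beta**2) / tau2_beta)


def log_prior_icar(phi, W: WeightMatrix, tau2_phi: float) -> float:
    """Unnormalized ICAR log-density, -QF/(2 tau2) with the unique-pair
    quadratic form QF = sum_{k<j} w_kj (phi_k - phi_j)^2 = phi' Q phi,
    Q = diag(rowsum) - W."""
    if tau2_phi <= 0:
        raise ValueError("tau2_phi must be positive")
    phi = np.asarray(phi, dtype=float)
    qf = icar_quadform(phi, W)
    return float(-0.5 * qf / tau2_phi)


def icar_quadform(phi, W: WeightMatrix) -> float:
    phi = np.asarray(phi, dtype=float)
    return float(phi @ (W.w.sum(axis=1) * phi) - phi @ W.w @ phi)


def icar_full_conditional(k: int, phi, W: WeightMatrix, tau2_phi: float) -> tuple[float, float]:
    """Full conditional of the ICAR field at site k:
    N(weighted neighbor mean, tau2 / sum of weights)."""
    row = W.w[k]
    s = row.sum()
    if s == 0:
        raise ValueError(f"site {k} is isolated: ICAR conditional undefined")
    phi = np.asarray(phi, dtype=float)
    return float(row @ phi / s), float(tau2_phi / s)


def leroux_full_conditional(k: int, phi, W: WeightMatrix, tau2: float, rho: float) -> tuple[float, float]:
    """Leroux proper-CAR full conditional at site k:
    N(rho * sum w phi / (rho * sum w + 1 - rho), tau2 / (rho * sum w + 1 - rho)).
    rho = 1 recovers the ICAR conditional; rho = 0 gives N(0, tau2)."""
    if not 0.0 <= rho <= 1.0:
        raise ValueError("rho must lie in [0, 1]")
    row = W.w[k]
    s = row.sum()
    denom = rho * s + 1.0 - rho
    phi = np.asarray(phi, dtype=float)
    return float(rho * (row @ phi) / denom), float(tau2 / denom)


def leroux_quadform(phi, W: WeightMatrix, rho: float) -> float:
    """phi' Q(rho) phi with Q(rho) = rho (D - W) + (1 - rho) I."""
    phi = np.asarray(phi, dtype=float)
    return float(rho * icar_quadform(phi, W) + (1.0 - rho) * np.sum(phi**2))


def _leroux_logdet(W: WeightMatrix, rho: float) -> float:
    q = rho * (np.diag(W.w.sum(axis=1)) - W.w) + (1.0 - rho) * np.eye(W.n)
    sign, logdet = np.linalg.slogdet(q)
    return float(logdet)


def gibbs_update_variance(quadratic_form: float, effective_rank: int,
                          prior: tuple[float, float], rng: np.random.Generator) -> float:
    """Conjugate draw tau2 ~ IG(a + rank/2, b + QF/2).

    ``effective_rank`` is n minus the number of connected components for
    an ICAR field, n for exchangeable effects, p for coefficients.
    """
    if quadratic_form < 0:
        raise ValueError("quadratic form must be non-negative")
    a, b = prior
    shape = a + 0.5 * effective_rank
    scale = b + 0.5 * quadratic_form
    return float(scale / rng.gamma(shape))


def _log_ig(x: float, a: float, b: float) -> float:
    return a * np.log(b) - special.gammaln(a) - (a + 1) * np.log(x) - b / x


def _log_gamma_pdf(x: float, shape: float, rate: float) -> float:
    return shape * np.log(rate) - special.gammaln(shape) + (shape - 1) * np.log(x) - rate * x


def log_posterior(y, X, spec: ModelSpec, priors: PriorConfig, beta, phi, u,
                  tau2_beta: float, tau2_phi: float | None, tau2_u: float | None,
                  gamma: float, rho: float | None, region_idx) -> float:
    """Joint unnormalized log-posterior assembled from the same component
    densities the sampler uses (likelihood x priors x hyperpriors)."""
    eta = np.asarray(X) @ np.asarray(beta)
    if phi is not None:
        eta = eta + np.asarray(phi)[region_idx]
    if u is not None:
        eta = eta + np.asarray(u)
    total = float(np.sum(nb_loglik_pointwise(y, np.exp(eta), gamma)))
    total += log_prior_beta(beta, tau2_beta)
    total += _log_ig(tau2_beta, *priors.tau2_beta)
    if phi is not None:
        R = len(phi)
        if spec.structure == "glmm":
            total += -0.5 * R * np.log(2 * np.pi * tau2_phi) - 0.5 * np.sum(np.asarray(phi) ** 2) / tau2_phi
        elif spec.has_rho:
            total += (
                0.5 * _leroux_logdet(spec.W, rho)
                - 0.5 * R * np.log(2 * np.pi * tau2_phi)
                - 0.5 * leroux_quadform(phi, spec.W, rho) / tau2_phi
            )
        else:
            total += log_prior_icar(phi, spec.W, tau2_phi)
        total += _log_ig(tau2_phi, *priors.tau2_phi)
    if u is not None:
        n = len(u)
        total += -0.5 * n * np.log(2 * np.pi * tau2_u) - 0.5 * np.sum(np.asarray(u) ** 2) / tau2_u
        total += _log_ig(tau2_u, *priors.tau2_u)
    total += _log_gamma_pdf(gamma, *priors.gamma_prior)
    # rho prior is Uniform(0,1): contributes 0 on its support
    return total


# ---------------------------------------------------------------------------
# the sampler


def build_design(data: pd.DataFrame, spec: ModelSpec) -> tuple[np.ndarray, list[str]]:
    missing = [c for c in spec.formula if c not in data.columns]
    if missing:
        raise ValueError(f"formula names not in data: {missing}")
    cols = ["intercept"] + [c for c in spec.formula if c != "intercept"]
    X = np.column_stack(
        [np.ones(len(data))] + [data[c].to_numpy(dtype=float) for c in cols[1:]]
    )
    return X, cols


def sample_posterior(data: pd.DataFrame, spec: ModelSpec, priors: PriorConfig | None = None,
                     chains: int = 4, iterations: int = 2000, warmup: int = 1000,
                     seed: int = 0) -> PosteriorSamples:
    """Draw from the posterior by Metropolis-within-Gibbs.

    ``iterations`` counts total sweeps per chain; the first ``warmup``
    are discarded (and are the only phase in which proposal scales
    adapt).  Chain c uses the substream spawned at offset c from the
    master seed, so runs are reproducible draw-for-draw.
    """
    if priors is None:
        priors = PriorConfig()
    if warmup >= iterations:
        raise ValueError("iterations must exceed warmup")
    y = data["y"].to_numpy(dtype=float)
    if (y < 0).any():
        raise ValueError("counts must be non-negative")
    X, colnames = build_design(data, spec)
    n, p = X.shape

    region_idx = None
    R = 0
    if spec.has_phi:
        region_idx = data[spec.region_col].to_numpy(dtype=int) - 1
        R = int(region_idx.max()) + 1
        if spec.is_spatial:
            if spec.W.n != R:
                raise ValueError(f"W has order {spec.W.n} but data references {R} regions")
            ncomp = spec.W.n_components()
            if spec.structure in ("icar", "bym") and ncomp != 1:
                raise ValueError(f"disconnected W ({ncomp} components): ICAR prior improper")
            if spec.W.islands.any():
                raise ValueError("W contains islands: CAR prior undefined on isolated nodes")

    retained = iterations - warmup
    master = np.random.SeedSequence(seed)
    chain_seeds = master.spawn(chains)

    draws: dict[str, np.ndarray] = {"beta": np.empty((chains, retained, p)), "gamma": np.empty((chains, retained)),
                                    "tau2_beta": np.empty((chains, retained))}
    if spec.has_phi:
        draws["phi"] = np.empty((chains, retained, R))
        draws["tau2_phi"] = np.empty((chains, retained))
    if spec.has_u:
        draws["u"] = np.empty((chains, retained, n))
        draws["tau2_u"] = np.empty((chains, retained))
    if spec.has_rho:
        draws["rho"] = np.empty((chains, retained))
    loglik = np.empty((chains, retained, n))
    accept_meta = []

    for c in range(chains):
        _run_chain(
            c, y, X, spec, priors, region_idx, R, iterations, warmup,
            np.random.default_rng(chain_seeds[c]), draws, loglik, accept_meta,
        )

    meta = {
        "structure": spec.structure,
        "columns": colnames,
        "chains": chains,
        "iterations": iterations,
        "warmup": warmup,
        "seed": seed,
        "acceptance": accept_meta,
        "n": n,
    }
    return PosteriorSamples(draws, loglik, meta)


def _run_chain(c, y, X, spec, priors, region_idx, R, iterations, warmup, rng,
               draws, loglik, accept_meta):
    n, p = X.shape
    has_phi, has_u, has_rho = spec.has_phi, spec.has_u, spec.has_rho
    exchangeable_phi = spec.structure == "glmm"
    icar_phi = spec.structure in ("icar", "bym")

    # initialize at a crude GLM fit so the random effects and their
    # variances start at the scale the data support (starting the field
    # at zero can trap the variance Gibbs step near the degenerate mode)
    from .dispersion import _irls

    try:
        beta, mu0, _, _ = _irls(y, X, lambda m: m, 50, 1e-6)
    except Exception:
        beta = np.zeros(p)
        beta[0] = np.log(y.mean() + 0.5)
        mu0 = np.exp(X @ beta)
    beta = beta + 0.05 * rng.standard_normal(p)
    resid = np.log((y + 0.5) / mu0)
    if has_phi:
        members = [np.flatnonzero(region_idx == r) for r in range(R)]
        phi = np.array([resid[idx].mean() if idx.size else 0.0 for idx in members])
        phi = phi - phi.mean() + 0.02 * rng.standard_normal(R)
        tau2_phi = max(float(phi.var()), 0.02)
    else:
        phi, tau2_phi = None, None
    if has_u:
        u = 0.5 * (resid - phi[region_idx])
        u = u + 0.02 * rng.standard_normal(n)
        tau2_u = max(float(u.var()), 0.02)
    else:
        u, tau2_u = None, None
    tau2_beta = 1.0
    ybar = y.mean()
    gamma = max(float((y.var() - ybar) / ybar**2), 0.05) * np.exp(0.2 * rng.standard_normal())
    rho = 0.5 if has_rho else None

    eta = X @ beta
    if has_phi:
        eta = eta + phi[region_idx]
    if has_u:
        eta = eta + u
    ll = nb_loglik_pointwise(y, np.exp(eta), gamma)

    step_beta = np.full(p, 0.1)
    step_phi = np.full(R, 0.3) if has_phi else None
    step_u = np.full(n, 0.5) if has_u else None
    step_gamma = 0.3
    step_rho = 0.8
    acc_beta = np.zeros(p)
    acc_gamma = acc_rho = 0.0
    n_adapt = 0

    # empirical-covariance block proposal for beta, adapted during warmup
    beta_hist = []
    block_scale = 2.38**2 / p
    block_chol = None
    acc_block = 0.0
    n_block = 0
    # independence kernels from the warmup draws' moments, frozen after
    # warmup (near-iid draws when the conditional is Gaussian-like)
    ind_mu = ind_chol = ind_prec = None
    lg_hist = []
    lg_mu = lg_sd = None

    warm = warmup
    for it in range(iterations):
        adapting = it < warm
        if adapting:
            n_adapt += 1
            lr = 1.0 / np.sqrt(n_adapt + 10)

        # --- beta, coordinate-wise random walk -----------------------------
        for j in range(p):
            prop = rng.normal(0.0, step_beta[j])
            eta_new = eta + X[:, j] * prop
            ll_new = nb_loglik_pointwise(y, np.exp(np.clip(eta_new, -700, 700)), gamma)
            bj = beta[j] + prop
            lp_diff = (ll_new.sum() - ll.sum()) + (beta[j] ** 2 - bj**2) / (2 * tau2_beta)
            if np.log(rng.uniform()) < lp_diff:
                beta[j] = bj
                eta, ll = eta_new, ll_new
                acc = 1.0
            else:
                acc = 0.0
            if adapting:
                step_beta[j] = float(np.clip(step_beta[j] * np.exp(lr * (acc - 0.44)), 1e-4, 10.0))
            acc_beta[j] += acc

        # --- beta, joint block proposal from the adapted covariance --------
        if adapting:
            beta_hist.append(beta.copy())
            if it >= max(50, warm // 4) and it % 25 == 0 and len(beta_hist) > 2 * p + 10:
                cov = np.cov(np.asarray(beta_hist[len(beta_hist) // 2:]).T)
                cov = np.atleast_2d(cov) + 1e-8 * np.eye(p)
                block_chol = np.linalg.cholesky(cov)
        if block_chol is not None:
            prop = beta + np.sqrt(block_scale) * (block_chol @ rng.standard_normal(p))
            eta_new = eta + X @ (prop - beta)
            ll_new = nb_loglik_pointwise(y, np.exp(np.clip(eta_new, -700, 700)), gamma)
            lp_diff = (ll_new.sum() - ll.sum()) + (beta @ beta - prop @ prop) / (2 * tau2_beta)
            acc = 0.0
            if np.log(rng.uniform()) < lp_diff:
                beta, eta, ll = prop, eta_new, ll_new
                acc = 1.0
            if adapting:
                block_scale = float(np.clip(block_scale * np.exp(lr * (acc - 0.23)), 1e-6, 100.0))
            acc_block += acc
            n_block += 1

        # --- beta, frozen independence proposal (post-warmup only) ---------
        if it == warm and len(beta_hist) > 2 * p + 10:
            hist = np.asarray(beta_hist[len(beta_hist) // 2:])
            ind_mu = hist.mean(axis=0)
            cov = np.atleast_2d(np.cov(hist.T)) * 1.5 + 1e-9 * np.eye(p)
            ind_chol = np.linalg.cholesky(cov)
            ind_prec = np.linalg.inv(cov)
        if ind_chol is not None:
            prop = ind_mu + ind_chol @ rng.standard_normal(p)
            eta_new = eta + X @ (prop - beta)
            ll_new = nb_loglik_pointwise(y, np.exp(np.clip(eta_new, -700, 700)), gamma)
            dq = 0.5 * ((prop - ind_mu) @ ind_prec @ (prop - ind_mu)
                        - (beta - ind_mu) @ ind_prec @ (beta - ind_mu))
            lp_diff = (ll_new.sum() - ll.sum()) + (beta @ beta - prop @ prop) / (2 * tau2_beta) + dq
            if np.log(rng.uniform()) < lp_diff:
                beta, eta, ll = prop, eta_new, ll_new

        # --- phi, single-site adaptive random-walk MH ----------------------
        # target = likelihood of the site's clusters x the prior full
        # conditional (centered at the weighted neighbor mean)
        if has_phi:
            for r in rng.permutation(R):
                if exchangeable_phi:
                    m, v = 0.0, tau2_phi
                elif has_rho:
                    m, v = leroux_full_conditional(r, phi, spec.W, tau2_phi, rho)
                else:
                    m, v = icar_full_conditional(r, phi, spec.W, tau2_phi)
                prop = phi[r] + rng.normal(0.0, step_phi[r])
                lp_diff = ((phi[r] - m) ** 2 - (prop - m) ** 2) / (2 * v)
                idx = members[r]
                if idx.size:
                    eta_r = eta[idx] + (prop - phi[r])
                    ll_r = nb_loglik_pointwise(y[idx], np.exp(np.clip(eta_r, -700, 700)), gamma)
                    lp_diff += ll_r.sum() - ll[idx].sum()
                acc = 0.0
                if np.log(rng.uniform()) < lp_diff:
                    if idx.size:
                        eta[idx], ll[idx] = eta_r, ll_r
                    phi[r] = prop
                    acc = 1.0
                if adapting:
                    step_phi[r] = float(np.clip(step_phi[r] * np.exp(lr * (acc - 0.44)), 1e-3, 10.0))

        # --- u, vectorized per-site adaptive random-walk MH ----------------
        # sites are conditionally independent given beta, phi, so all n
        # proposals can be accepted/rejected elementwise in one pass
        if has_u:
            prop = u + step_u * rng.standard_normal(n)
            eta_new = eta + (prop - u)
            ll_new = nb_loglik_pointwise(y, np.exp(np.clip(eta_new, -700, 700)), gamma)
            lp_diff = (ll_new - ll) + (u**2 - prop**2) / (2 * tau2_u)
            accept = np.log(rng.uniform(size=n)) < lp_diff
            u = np.where(accept, prop, u)
            eta = np.where(accept, eta_new, eta)
            ll = np.where(accept, ll_new, ll)
            if adapting:
                step_u = np.clip(step_u * np.exp(lr * (accept - 0.44)), 1e-3, 10.0)

        # --- gamma, random walk on the log scale ---------------------------
        g_shape, g_rate = priors.gamma_prior
        lg_new = np.log(gamma) + rng.normal(0.0, step_gamma)
        g_new = float(np.exp(lg_new))
        ll_new = nb_loglik_pointwise(y, np.exp(eta), g_new)
        lp_diff = (
            ll_new.sum() - ll.sum()
            + _log_gamma_pdf(g_new, g_shape, g_rate) - _log_gamma_pdf(gamma, g_shape, g_rate)
            + lg_new - np.log(gamma)  # log-scale proposal Jacobian
        )
        if np.log(rng.uniform()) < lp_diff:
            gamma, ll = g_new, ll_new
            acc = 1.0
        else:
            acc = 0.0
        if adapting:
            step_gamma = float(np.clip(step_gamma * np.exp(lr * (acc - 0.44)), 1e-4, 10.0))
            lg_hist.append(np.log(gamma))
        acc_gamma += acc

        # --- gamma, frozen independence proposal on the log scale ----------
        if it == warm and len(lg_hist) > 50:
            tail_hist = np.asarray(lg_hist[len(lg_hist) // 2:])
            lg_mu, lg_sd = float(tail_hist.mean()), float(tail_hist.std() * 1.3 + 1e-6)
        if lg_sd is not None:
            lg_new = rng.normal(lg_mu, lg_sd)
            g_new = float(np.exp(lg_new))
            ll_new = nb_loglik_pointwise(y, np.exp(eta), g_new)
            lg_cur = np.log(gamma)
            dq = ((lg_new - lg_mu) ** 2 - (lg_cur - lg_mu) ** 2) / (2 * lg_sd**2)
            lp_diff = (
                ll_new.sum() - ll.sum()
                + _log_gamma_pdf(g_new, g_shape, g_rate) - _log_gamma_pdf(gamma, g_shape, g_rate)
                + lg_new - lg_cur  # Jacobian of the log parameterization
                + dq
            )
            if np.log(rng.uniform()) < lp_diff:
                gamma, ll = g_new, ll_new

        # --- rho (Leroux), random walk on the logit scale ------------------
        if has_rho:
            logit = np.log(rho) - np.log1p(-rho)
            logit_new = logit + rng.normal(0.0, step_rho)
            rho_new = float(1.0 / (1.0 + np.exp(-logit_new)))
            lp_old = 0.5 * _leroux_logdet(spec.W, rho) - 0.5 * leroux_quadform(phi, spec.W, rho) / tau2_phi
            lp_new = 0.5 * _leroux_logdet(spec.W, rho_new) - 0.5 * leroux_quadform(phi, spec.W, rho_new) / tau2_phi
            jac = np.log(rho_new * (1 - rho_new)) - np.log(rho * (1 - rho))
            if np.log(rng.uniform()) < lp_new - lp_old + jac:
                rho = rho_new
                acc = 1.0
            else:
                acc = 0.0
            if adapting:
                step_rho = float(np.clip(step_rho * np.exp(lr * (acc - 0.44)), 1e-3, 10.0))
            acc_rho += acc

        # --- conjugate variance updates ------------------------------------
        tau2_beta = gibbs_update_variance(float(np.sum(beta**2)), p, priors.tau2_beta, rng)
        if has_phi:
            if exchangeable_phi:
                qf, rank = float(np.sum(phi**2)), R
            elif has_rho:
                qf, rank = leroux_quadform(phi, spec.W, rho), R
            else:
                qf, rank = icar_quadform(phi, spec.W), R - 1
            tau2_phi = gibbs_update_variance(qf, rank, priors.tau2_phi, rng)
        if has_u:
            tau2_u = gibbs_update_variance(float(np.sum(u**2)), n, priors.tau2_u, rng)

        # --- translation moves along likelihood-invariant directions -------
        # the intercept trades off one-for-one against the mean of each
        # exchangeable random-effect block; a generalized-Gibbs draw of the
        # shift m (u -> u - m, beta0 -> beta0 + m) from its conditional
        # removes that ridge without changing the target
        if has_u:
            prec = n / tau2_u + 1.0 / tau2_beta
            m = rng.normal((n * u.mean() / tau2_u - beta[0] / tau2_beta) / prec,
                           1.0 / np.sqrt(prec))
            u -= m
            beta[0] += m  # eta unchanged
        if has_phi and exchangeable_phi:
            prec = R / tau2_phi + 1.0 / tau2_beta
            m = rng.normal((R * phi.mean() / tau2_phi - beta[0] / tau2_beta) / prec,
                           1.0 / np.sqrt(prec))
            phi -= m
            beta[0] += m

        # --- re-center the ICAR field (soft sum-to-zero constraint) --------
        if has_phi and icar_phi:
            shift = phi.mean()
            phi -= shift
            beta[0] += shift  # eta unchanged

        if not np.isfinite(ll).all():
            raise RuntimeError(
                f"divergent log-posterior at iteration {it}: "
                f"beta={beta}, gamma={gamma}"
            )

        if it >= warm:
            k = it - warm
            draws["beta"][c, k] = beta
            draws["gamma"][c, k] = gamma
            draws["tau2_beta"][c, k] = tau2_beta
            if has_phi:
                draws["phi"][c, k] = phi
                draws["tau2_phi"][c, k] = tau2_phi
            if has_u:
                draws["u"][c, k] = u
                draws["tau2_u"][c, k] = tau2_u
            if has_rho:
                draws["rho"][c, k] = rho
            loglik[c, k] = ll

    accept_meta.append(
        {
            "chain": c + 1,
            "beta": (acc_beta / iterations).round(3).tolist(),
            "gamma": round(acc_gamma / iterations, 3),
            "rho": round(acc_rho / iterations, 3) if has_rho else None,
            "step_beta": step_beta.round(4).tolist(),
            "step_gamma": round(step_gamma, 4),
        }
    )


def fit_summary(samples: PosteriorSamples, prob: float = 0.95,
                params: list[str] | None = None) -> pd.DataFrame:
    """Posterior summary table: mean, sd, equal-tailed CI, split-Rhat and
    bulk/tail ESS per scalar parameter."""
    from .evaluation import split_rhat, ess_bulk_tail

    names = params if params is not None else samples.parameter_names()
    lo_q, hi_q = (1 - prob) / 2, 1 - (1 - prob) / 2
    rows = []
    for name in names:
        arr = samples.get(name)
        flat = arr.reshape(-1)
        if arr.shape[0] >= 2 and np.ptp(flat) > 0:
            rhat = split_rhat(arr)
            bulk, tail = ess_bulk_tail(arr)
        else:
            rhat, bulk, tail = np.nan, np.nan, np.nan
        rows.append(
            {
                "parameter": name,
                "estimate": flat.mean(),
                "sd": flat.std(ddof=1),
                f"ci_{lo_q:g}": np.quantile(flat, lo_q),
                f"ci_{hi_q:g}": np.quantile(flat, hi_q),
                "rhat": rhat,
                "bulk_ess": bulk,
                "tail_ess": tail,
            }
        )
    return pd.DataFrame(rows).set_index("parameter")
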