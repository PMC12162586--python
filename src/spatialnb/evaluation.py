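"""Model comparison and MCMC convergence diagnostics.

WAIC and Pareto-smoothed importance-sampling LOO are computed from the
pointwise posterior log-likelihood matrix; convergence is assessed with
rank-normalized split R-hat and bulk/tail effective sample sizes
(Geyer initial-monotone-sequence autocorrelation estimator), plus
posterior predictive replication of the observed counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

__all__ = [
    "WAICResult",
    "LOOResult",
    "waic",
    "loo_psis",
    "split_rhat",
    "ess_bulk_tail",
    "posterior_predictive",
    "compare_models",
]


@dataclass(frozen=True)
class WAICResult:
    elpd_waic: float
    p_waic: float
    waic: float
    se: float
    pointwise: np.ndarray
    unstable: np.ndarray  # indices with pointwise variance > 0.4


@dataclass(frozen=True)
class LOOResult:
    elpd_loo: float
    p_loo: float
    looic: float
    se: float
    pointwise: np.ndarray
    pareto_k: np.ndarray


def _as_loglik(loglik) -> np.ndarray:
    ll = np.asarray(loglik, dtype=float)
    if ll.ndim == 3:  # chains x draws x n
        ll = ll.reshape(-1, ll.shape[2])
    if ll.ndim != 2:
        raise ValueError("loglik must be (draws, n) or (chains, draws, n)")
    if ll.shape[0] < 2:
        raise ValueError("need at least two draws")
    if not np.isfinite(ll).all():
        raise ValueError("loglik contains non-finite entries")
    return ll


def waic(loglik) -> WAICResult:
    """Widely applicable information criterion from pointwise log-likelihood.

    elpd_waic = sum_k [lpd_k - p_k] with lpd_k = log mean_d exp(ll_dk)
    (computed stably) and p_k = var_d(ll_dk); waic = -2 elpd_waic;
    SE = sqrt(n * var_k(pointwise elpd)).  Points whose pointwise
    variance exceeds 0.4 are reported as unstable.
    """
    ll = _as_loglik(loglik)
    s, n = ll.shape
    lpd = special.logsumexp(ll, axis=0) - np.log(s)
    p = ll.var(axis=0, ddof=1)
    pointwise = lpd - p
    unstable = np.flatnonzero(p > 0.4)
    if unstable.size:
        warnings.warn(
            f"waic: {unstable.size} observations with pointwise variance > 0.4; "
            "estimate may be unstable",
            stacklevel=2,
        )
    elpd = float(pointwise.sum())
    se = float(np.sqrt(n * pointwise.var(ddof=1)))
    return WAICResult(elpd, float(p.sum()), -2 * elpd, se, pointwise, unstable)


def _gpd_fit(x: np.ndarray) -> tuple[float, float]:
    """Zhang-Stephens empirical-Bayes fit of the generalized Pareto
    (shape k, scale sigma) to exceedances ``x`` (sorted ascending)."""
    n = x.size
    m = 30 + int(np.sqrt(n))
    b = 1.0 - np.sqrt(m / (np.arange(1, m + 1) - 0.5))
    b = b / (3.0 * x[int(n / 4 + 0.5) - 1]) + 1.0 / x[-1]
    k_cand = np.log1p(-b[:, None] * x[None, :]).mean(axis=1)
    log_lik = n * (np.log(-b / k_cand) - k_cand - 1.0)
    wts = 1.0 / np.exp(log_lik - log_lik[:, None]).sum(axis=1)
    wts[wts < 10 * np.finfo(float).eps] = 0.0
    wts /= wts.sum()
    b_post = float(np.sum(b * wts))
    k_post = float(np.log1p(-b_post * x).mean())
    sigma = -k_post / b_post
    k_post = (n * k_post + 5.0) / (n + 10.0)  # weak prior pulling k toward 0.5
    return k_post, sigma


def _psis_smooth(lw: np.ndarray) -> tuple[np.ndarray, float]:
    """Pareto-smooth one vector of log importance ratios (in place safe)."""
    s = lw.size
    lw = lw - lw.max()
    m = int(min(np.ceil(0.2 * s), np.ceil(3 * np.sqrt(s))))
    if m < 5:
        return lw, np.inf
    order = np.argsort(lw)
    tail_idx = order[-m:]
    cutoff = lw[order[-m - 1]]
    exp_cutoff = np.exp(cutoff)
    x = np.exp(lw[tail_idx]) - exp_cutoff
    x = np.sort(x)
    if x[-1] <= 0 or np.ptp(x) == 0:
        return lw, np.inf
    k, sigma = _gpd_fit(x)
    if np.isfinite(k):
        q = (np.arange(1, m + 1) - 0.5) / m
        if abs(k) < 1e-12:
            quant = -sigma * np.log1p(-q)
        else:
            quant = sigma / k * ((1 - q) ** (-k) - 1.0)
        # tail_idx is already ordered by increasing lw, matching the
        # ascending GPD quantiles
        lw[tail_idx] = np.log(quant + exp_cutoff)
    lw = np.minimum(lw, 0.0)  # truncate at the raw maximum
    return lw, k


def loo_psis(loglik, k_threshold: float = 0.7) -> LOOResult:
    """Pareto-smoothed importance-sampling leave-one-out cross-validation.

    Raw importance ratios 1/p(y_k | theta_d) have their upper 20% tail
    replaced by generalized-Pareto quantiles (Zhang-Stephens fit) and
    are truncated at the raw maximum; points with Pareto k above
    ``k_threshold`` are unreliable and reported.  Very short draw
    sequences fall back to truncated importance sampling (k = inf).
    """
    ll = _as_loglik(loglik)
    s, n = ll.shape
    lpd = special.logsumexp(ll, axis=0) - np.log(s)
    pointwise = np.empty(n)
    ks = np.empty(n)
    for j in range(n):
        lw, k = _psis_smooth(-ll[:, j].copy())
        lw = lw - special.logsumexp(lw)
        pointwise[j] = special.logsumexp(lw + ll[:, j])
        ks[j] = k
    bad = np.flatnonzero(ks > k_threshold)
    if np.isinf(ks).all():
        warnings.warn("loo: degenerate importance weights; truncated-IS fallback used", stacklevel=2)
    elif bad.size:
        warnings.warn(f"loo: {bad.size} observations with Pareto k > {k_threshold}", stacklevel=2)
    elpd = float(pointwise.sum())
    se = float(np.sqrt(n * pointwise.var(ddof=1)))
    return LOOResult(elpd, float((lpd - pointwise).sum()), -2 * elpd, se, pointwise, ks)


# ---------------------------------------------------------------------------
# convergence diagnostics


def _rank_normalize(draws: np.ndarray) -> np.ndarray:
    flat = draws.reshape(-1)
    ranks = stats.rankdata(flat, method="average")
    z = stats.norm.ppf((ranks - 0.375) / (flat.size + 0.25))
    return z.reshape(draws.shape)


def _split_chains(draws: np.ndarray) -> np.ndarray:
    m, n = draws.shape
    half = n // 2
    return np.vstack([draws[:, :half], draws[:, half: 2 * half]])


def split_rhat(draws) -> float:
    """Rank-normalized split-R-hat.

    Chains are split in half, draws are rank-normalized, and
    R-hat = sqrt(((n-1)/n * W + B/n) / W) with W the mean within-chain
    variance and B the between-chain variance of the split halves.
    Values near 1 indicate the chains agree; > 1.01 suggests
    non-convergence.
    """
    draws = np.atleast_2d(np.asarray(draws, dtype=float))
    if draws.shape[0] < 2:
        raise ValueError("split_rhat needs at least 2 chains")
    if draws.shape[1] < 4:
        raise ValueError("split_rhat needs at least 4 iterations per chain")
    if np.ptp(draws) == 0:
        return np.nan
    z = _split_chains(_rank_normalize(draws))
    m, n = z.shape
    w = z.var(axis=1, ddof=1).mean()
    b = n * z.mean(axis=1).var(ddof=1)
    var_plus = (n - 1) / n * w + b / n
    return float(np.sqrt(var_plus / w))


def _geyer_ess(z: np.ndarray) -> float:
    """ESS of (already normalized) split chains via Geyer's initial
    monotone sequence on the chain-averaged autocorrelation."""
    m, n = z.shape
    chain_var = z.var(axis=1, ddof=1)
    w = chain_var.mean()
    b = n * z.mean(axis=1).var(ddof=1) if m > 1 else 0.0
    var_plus = (n - 1) / n * w + (b / n if m > 1 else 0.0)
    if var_plus == 0:
        return np.nan

    # per-chain autocovariance via FFT
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    centered = z - z.mean(axis=1, keepdims=True)
    f = np.fft.rfft(centered, nfft, axis=1)
    acov = np.fft.irfft(f * np.conj(f), nfft, axis=1)[:, :n].real / n
    mean_acov = acov.mean(axis=0)

    rho = 1.0 - (w - mean_acov) / var_plus
    rho[0] = 1.0
    # Geyer: sum pairs rho_{2t} + rho_{2t+1} while positive, enforce
    # monotone decrease
    max_t = (n - 2) // 2
    pair = rho[2 * np.arange(max_t + 1)] + rho[2 * np.arange(max_t + 1) + 1]
    s = 0.0
    prev = np.inf
    for t in range(max_t + 1):
        p = pair[t]
        if p < 0:
            break
        p = min(p, prev)
        prev = p
        s += p
    tau = max(2.0 * s - 1.0, 1.0 / np.log10(m * n + 10))
    ess = m * n / tau
    return float(min(ess, m * n * np.log10(m * n)))


def ess_bulk_tail(draws) -> tuple[float, float]:
    """Bulk and tail effective sample sizes.

    Bulk ESS is the Geyer autocorrelation ESS of the rank-normalized
    split chains; tail ESS is the smaller of the ESS of the 5% and 95%
    exceedance indicators.  Constant draws give (nan, nan).
    """
    draws = np.atleast_2d(np.asarray(draws, dtype=float))
    if draws.shape[0] < 1 or draws.shape[1] < 4:
        raise ValueError("need at least 4 iterations")
    if np.ptp(draws) == 0:
        return np.nan, np.nan
    z = _split_chains(_rank_normalize(draws)) if draws.shape[1] >= 8 else _rank_normalize(draws)
    bulk = _geyer_ess(z)

    tails = []
    for q in (0.05, 0.95):
        thr = np.quantile(draws, q)
        ind = (draws <= thr).astype(float)
        if np.ptp(ind) == 0:
            tails.append(np.nan)
            continue
        zi = _split_chains(ind) if draws.shape[1] >= 8 else ind
        tails.append(_geyer_ess(zi))
    tail = np.nanmin(tails) if not all(np.isnan(t) for t in tails) else np.nan
    return bulk, float(tail) if np.isfinite(tail) else np.nan


# ---------------------------------------------------------------------------
# posterior predictive checks


def posterior_predictive(samples, data: pd.DataFrame, spec, n_rep: int = 100,
                         seed: int = 0) -> dict:
    """Replicate the observed counts from ``n_rep`` retained draws.

    For each selected draw, y_rep ~ NB(mu(draw), gamma(draw)) via the
    Poisson-gamma mixture.  Returns the replicate matrix and scalar
    check statistics (observed vs replicated mean and max) for a
    density-overlay style comparison.
    """
    from .mcmc import build_design

    y = data["y"].to_numpy(dtype=float)
    X, _ = build_design(data, spec)
    n = len(y)
    total = samples.chains * samples.n_retained
    n_rep = min(n_rep, total)
    pick = np.linspace(0, total - 1, n_rep).astype(int)
    beta = samples.draws["beta"].reshape(total, -1)[pick]
    gamma = samples.draws["gamma"].reshape(total)[pick]
    eta = beta @ X.T
    if spec.has_phi:
        region_idx = data[spec.region_col].to_numpy(dtype=int) - 1
        eta += samples.draws["phi"].reshape(total, -1)[pick][:, region_idx]
    if spec.has_u:
        eta += samples.draws["u"].reshape(total, -1)[pick]
    mu = np.exp(eta)
    rng = np.random.default_rng(seed)
    g = rng.gamma(shape=1.0 / gamma[:, None], scale=gamma[:, None], size=(n_rep, n))
    y_rep = rng.poisson(mu * g)
    rep_means = y_rep.mean(axis=1)
    return {
        "y_rep": y_rep,
        "observed_mean": float(y.mean()),
        "observed_max": float(y.max()),
        "replicated_means": rep_means,
        "replicated_maxes": y_rep.max(axis=1).astype(float),
        "mean_in_central_95": bool(
            np.quantile(rep_means, 0.025) <= y.mean() <= np.quantile(rep_means, 0.975)
        ),
    }


def ppc_density_export(ppc: dict, y, path) -> None:
    """Write observed vs replicated histogram densities to CSV."""
    y = np.asarray(y, dtype=float)
    hi = max(y.max(), ppc["y_rep"].max()) + 1
    bins = np.arange(0, hi + 1)
    obs, _ = np.histogram(y, bins=bins, density=True)
    rep, _ = np.histogram(ppc["y_rep"].ravel(), bins=bins, density=True)
    pd.DataFrame({"count": bins[:-1], "observed": obs, "replicated": rep}).to_csv(path, index=False)


def compare_models(fits: dict[str, "np.ndarray | object"]) -> pd.DataFrame:
    """WAIC/LOO comparison table across models fitted to the same data.

    Accepts a mapping from model name to a pointwise log-likelihood
    matrix (or any object with a ``loglik_matrix()`` method).  Rows are
    sorted by WAIC ascending, with differences to the best model and
    the SE of each pairwise pointwise difference.
    """
    if not fits:
        raise ValueError("no fits to compare")
    lls = {}
    n_ref = None
    for name, obj in fits.items():
        ll = obj.loglik_matrix() if hasattr(obj, "loglik_matrix") else _as_loglik(obj)
        if n_ref is None:
            n_ref = ll.shape[1]
        elif ll.shape[1] != n_ref:
            raise ValueError("all fits must be on identical data (same n)")
        lls[name] = ll
    rows = {}
    for name, ll in lls.items():
        w = waic(ll)
        lo = loo_psis(ll)
        rows[name] = {
            "elpd_waic": w.elpd_waic, "p_waic": w.p_waic, "waic": w.waic, "se_waic": w.se,
            "elpd_loo": lo.elpd_loo, "p_loo": lo.p_loo, "looic": lo.looic, "se_loo": lo.se,
            "_pw": w.pointwise,
        }
    table = pd.DataFrame({k: {kk: vv for kk, vv in v.items() if kk != "_pw"} for k, v in rows.items()}).T
    table = table.sort_values("waic")
    best = table.index[0]
    best_pw = rows[best]["_pw"]
    table["d_waic"] = table["waic"] - table.loc[best, "waic"]
    table["d_looic"] = table["looic"] - table.loc[best, "looic"]
    n = best_pw.size
    table["d_se"] = [
        float(np.sqrt(n * (rows[name]["_pw"] - best_pw).var(ddof=1))) if name != best else 0.0
        for name in table.index
    ]
    table.index.name = "model"
    return table
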