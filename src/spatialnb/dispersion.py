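"""Over-dispersion diagnostics for count regressions.

Count data often show variance well above the Poisson mean-variance
identity.  The standard screen fits maximum-likelihood Poisson and
negative-binomial log-linear models and divides the Pearson chi-squared
and the residual deviance by the residual degrees of freedom: ratios
far above one flag over-dispersion and argue for the NB family.

The GLM fits here are plain IRLS/Newton on the log link; the NB
dispersion gamma (Var = mu + gamma mu^2) is profiled by univariate
maximum likelihood.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, special

__all__ = [
    "GLMFit",
    "DispersionReport",
    "fit_count_glm",
    "deviance_lr",
    "overdispersion_ratios",
]


@dataclass(frozen=True)
class GLMFit:
    family: str
    beta: np.ndarray
    mu: np.ndarray
    loglik: float
    gamma: float | None  # NB dispersion; None for Poisson
    n_iter: int
    converged: bool


@dataclass(frozen=True)
class DispersionReport:
    """Pearson chi2 and residual deviance divided by df, per Table-style
    over-dispersion screening; ``flag`` marks ratio > threshold."""

    family: str
    pearson_chi2: float
    deviance: float
    df: int
    ratio_pearson: float
    ratio_deviance: float
    threshold: float
    flag: bool

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "pearson_chi2": self.pearson_chi2,
            "deviance": self.deviance,
            "df": self.df,
            "ratio_pearson": self.ratio_pearson,
            "ratio_deviance": self.ratio_deviance,
            "overdispersed": self.flag,
        }


def _validate(y, X):
    y = np.asarray(y, dtype=float).ravel()
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] != y.size:
        raise ValueError("X must be (n, p) matching y")
    if (y < 0).any() or not np.allclose(y, np.round(y)):
        raise ValueError("y must contain non-negative integers")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")
    return y, X


def poisson_loglik(y, mu):
    return float(np.sum(y * np.log(mu) - mu - special.gammaln(y + 1)))


def nb_loglik(y, mu, gamma):
    """NB log-likelihood, mean/dispersion parameterization (size r = 1/gamma)."""
    r = 1.0 / gamma
    return float(
        np.sum(
            special.gammaln(y + r)
            - special.gammaln(r)
            - special.gammaln(y + 1)
            + r * np.log(r / (r + mu))
            + y * np.log(mu / (r + mu))
        )
    )


def _irls(y, X, weights_fn, max_iter, tol, beta0=None):
    """IRLS for a log-link count GLM; weights_fn(mu) gives working weights."""
    n, p = X.shape
    beta = beta0 if beta0 is not None else np.zeros(p)
    if beta0 is None:
        beta[0] = np.log(max(y.mean(), 0.1)) if np.allclose(X[:, 0], 1) else 0.0
    eta = X @ beta
    for it in range(1, max_iter + 1):
        mu = np.exp(np.clip(eta, -30, 30))
        wt = weights_fn(mu)
        z = eta + (y - mu) / mu  # working response for log link
        WX = X * wt[:, None]
        try:
            beta_new = np.linalg.solve(X.T @ WX, WX.T @ z)
        except np.linalg.LinAlgError as exc:
            raise RuntimeError("IRLS normal equations singular (separation?)") from exc
        step = beta_new - beta
        beta, eta = beta_new, X @ beta_new
        if np.max(np.abs(step)) < tol:
            return beta, np.exp(np.clip(eta, -30, 30)), it, True
    return beta, np.exp(np.clip(eta, -30, 30)), max_iter, False


def fit_count_glm(y, X, family: str = "poisson", max_iter: int = 100, tol: float = 1e-9) -> GLMFit:
    """Maximum-likelihood log-linear Poisson or NB fit.

    Poisson uses canonical IRLS.  For ``negbin``, beta and gamma are
    estimated by alternating IRLS (working weights mu/(1+gamma*mu)) with
    univariate ML for gamma on the log scale, iterated to joint
    convergence.
    """
    y, X = _validate(y, X)
    if family == "poisson":
        beta, mu, it, conv = _irls(y, X, lambda m: m, max_iter, tol)
        if not conv:
            raise RuntimeError(f"Poisson IRLS failed to converge in {max_iter} iterations")
        return GLMFit("poisson", beta, mu, poisson_loglik(y, mu), None, it, conv)
    if family != "negbin":
        raise ValueError(f"unknown family: {family!r}")

    # initialize from the Poisson fit; method-of-moments start for gamma
    beta, mu, _, _ = _irls(y, X, lambda m: m, max_iter, tol)
    resid2 = (y - mu) ** 2
    gamma = max(float(np.sum(resid2 - mu) / np.sum(mu**2)), 1e-4)
    ll_prev = -np.inf
    it_total = 0
    for outer in range(100):
        def neg_prof(log_g):
            return -nb_loglik(y, mu, np.exp(log_g))

        res = optimize.minimize_scalar(
            neg_prof, bracket=None, bounds=(np.log(1e-8), np.log(1e4)), method="bounded",
            options={"xatol": 1e-10},
        )
        gamma = float(np.exp(res.x))
        beta, mu, it, conv = _irls(
            y, X, lambda m: m / (1.0 + gamma * m), max_iter, tol, beta0=beta
        )
        it_total += it
        ll = nb_loglik(y, mu, gamma)
        scale = max(1.0, abs(ll))
        # near the Poisson boundary the profile is flat in log(gamma) and
        # the optimizer jitters among negligible gammas; accept a slightly
        # looser likelihood tolerance there
        if abs(ll - ll_prev) < 1e-9 * scale or (gamma < 1e-6 and abs(ll - ll_prev) < 1e-7 * scale):
            return GLMFit("negbin", beta, mu, ll, gamma, it_total, True)
        ll_prev = ll
    raise RuntimeError("NB alternating maximization failed to converge")


def deviance_lr(loglik_null: float, loglik_model: float) -> float:
    """Likelihood-ratio deviance D = -2 (log L_null - log L_model) >= 0."""
    d = -2.0 * (loglik_null - loglik_model)
    if d < -1e-8:
        raise ValueError("nesting violated: model log-likelihood below the null's")
    return max(d, 0.0)


def _residual_deviance(y, mu, family: str, gamma: float | None) -> float:
    """Deviance against the saturated model (mu_hat = y), >= 0."""
    with np.errstate(divide="ignore", invalid="ignore"):
        if family == "poisson":
            term = np.where(y > 0, y * np.log(y / mu), 0.0)
            return float(2.0 * np.sum(term - (y - mu)))
        r = 1.0 / gamma
        term = np.where(y > 0, y * np.log(y / mu), 0.0)
        return float(2.0 * np.sum(term - (y + r) * np.log((y + r) / (mu + r))))


def overdispersion_ratios(y, X, family: str = "poisson", threshold: float = 1.5,
                          fit: GLMFit | None = None) -> DispersionReport:
    """Pearson and deviance over-dispersion ratios from an ML fit.

    Pearson chi2 = sum (y - mu)^2 / V(mu) with V = mu (Poisson) or
    mu + gamma mu^2 (NB); the deviance is residual deviance against the
    saturated model (for NB, evaluated with the fitted gamma held
    fixed).  Ratios above ``threshold`` flag over-dispersion.
    """
    y, X = _validate(y, X)
    df = y.size - X.shape[1]
    if family == "negbin":
        df -= 1  # gamma is estimated too
    if df <= 0:
        raise ValueError("non-positive residual degrees of freedom")
    if fit is None:
        fit = fit_count_glm(y, X, family=family)
    mu = fit.mu
    if family == "poisson":
        v = mu
    else:
        v = mu + fit.gamma * mu**2
    pearson = float(np.sum((y - mu) ** 2 / v))
    dev = _residual_deviance(y, mu, family, fit.gamma)
    rp, rd = pearson / df, dev / df
    return DispersionReport(
        family=family,
        pearson_chi2=pearson,
        deviance=dev,
        df=df,
        ratio_pearson=rp,
        ratio_deviance=rd,
        threshold=threshold,
        flag=max(rp, rd) > threshold,
    )
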