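"""Exploratory spatial data analysis for areal counts.

Global and local Moran's I, the Getis-Ord Gi* hot/cold-spot statistic,
and the mean center / standard distance of a point pattern.  Inference
for the global statistics is available both under the normality
assumption (Cliff-Ord closed-form moments) and by random permutation of
the observations over locations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .weights import WeightMatrix

__all__ = [
    "ESDAResult",
    "morans_i",
    "morans_i_permutation",
    "local_morans_i",
    "getis_ord_gstar",
    "mean_center_and_standard_distance",
]


@dataclass(frozen=True)
class ESDAResult:
    """A spatial statistic with its null moments and p-value."""

    statistic: float
    expected: float
    variance: float
    z: float
    p_value: float
    per_unit: pd.DataFrame | None = None
    method: str = ""


def _check_y(y, min_n: int = 2) -> np.ndarray:
    y = np.asarray(y, dtype=float).ravel()
    if y.size < min_n:
        raise ValueError(f"need at least {min_n} observations")
    if not np.isfinite(y).all():
        raise ValueError("y must be finite")
    if np.ptp(y) == 0:
        raise ValueError("zero variance: y is constant, statistic undefined")
    return y


def _moran_stat(y: np.ndarray, w: np.ndarray) -> float:
    z = y - y.mean()
    s0 = w.sum()
    return y.size / s0 * (z @ w @ z) / (z @ z)


def morans_i(y, W: WeightMatrix, two_sided: bool = True) -> ESDAResult:
    """Global Moran's I with normality-assumption inference.

    I = n * sum_ij w_ij (y_i - ybar)(y_j - ybar) /
        (sum_ij w_ij * sum_i (y_i - ybar)^2),

    with null expectation E(I) = -1/(n-1) and the Cliff-Ord
    normality-assumption variance built from the weight sums
    S0 = sum_ij w_ij, S1 = (1/2) sum_ij (w_ij + w_ji)^2 and
    S2 = sum_i (w_i. + w_.i)^2.
    """
    y = _check_y(y, min_n=2)
    w = W.w
    n = y.size
    if w.shape[0] != n:
        raise ValueError("dimension mismatch between y and W")
    if n < 3:
        # statistic is defined but the normality variance needs n >= 3
        i_obs = _moran_stat(y, w)
        e_i = -1.0 / (n - 1)
        return ESDAResult(i_obs, e_i, np.nan, np.nan, np.nan, method="normality")

    i_obs = _moran_stat(y, w)
    e_i = -1.0 / (n - 1)
    s0 = w.sum()
    s1 = 0.5 * ((w + w.T) ** 2).sum()
    s2 = ((w.sum(axis=1) + w.sum(axis=0)) ** 2).sum()
    var = (n * n * s1 - n * s2 + 3 * s0 * s0) / ((n * n - 1) * s0 * s0) - e_i**2
    z = (i_obs - e_i) / np.sqrt(var) if var > 0 else np.nan
    if two_sided:
        p = 2 * stats.norm.sf(abs(z))
    else:
        p = stats.norm.sf(z)
    return ESDAResult(i_obs, e_i, var, z, p, method="normality")


def morans_i_permutation(y, W: WeightMatrix, n_perm: int = 999, seed: int = 0) -> ESDAResult:
    """Moran's I with a one-sided (clustering) permutation test.

    p = (1 + #{permuted I >= observed I}) / (n_perm + 1).
    """
    if n_perm < 99:
        raise ValueError("use at least 99 permutations")
    y = _check_y(y, min_n=2)
    w = W.w
    if w.shape[0] != y.size:
        raise ValueError("dimension mismatch between y and W")
    i_obs = _moran_stat(y, w)
    rng = np.random.default_rng(seed)
    count = 0
    perm_vals = np.empty(n_perm)
    for b in range(n_perm):
        perm = rng.permutation(y)
        perm_vals[b] = _moran_stat(perm, w)
    count = int((perm_vals >= i_obs).sum())
    p = (1 + count) / (n_perm + 1)
    e_i = perm_vals.mean()
    var = perm_vals.var(ddof=1)
    z = (i_obs - e_i) / np.sqrt(var) if var > 0 else np.nan
    return ESDAResult(i_obs, e_i, var, z, p, method=f"permutation({n_perm})")


def local_morans_i(y, W: WeightMatrix, n_perm: int = 999, seed: int = 0,
                   alpha: float = 0.05) -> pd.DataFrame:
    """Local Moran's I per unit with hot/cold quadrant labels.

    I_i = z_i * sum_j w_ij z_j with z the population-sd standardized
    deviations.  Conditional permutation (holding unit i fixed,
    permuting the rest) gives per-unit p-values; labels: ``hot`` for
    significant high-high units, ``cold`` for significant low-low,
    ``other`` otherwise.
    """
    y = _check_y(y, min_n=2)
    w = W.w
    n = y.size
    if w.shape[0] != n:
        raise ValueError("dimension mismatch between y and W")
    z = (y - y.mean()) / y.std()  # population sd
    lag = w @ z
    local = z * lag

    rng = np.random.default_rng(seed)
    p = np.ones(n)
    others = [np.delete(np.arange(n), i) for i in range(n)]
    for i in range(n):
        wi = w[i, others[i]]
        nz = np.flatnonzero(wi)
        if nz.size == 0:
            p[i] = np.nan
            continue
        zo = z[others[i]]
        sims = np.empty(n_perm)
        for b in range(n_perm):
            sims[b] = z[i] * (wi @ rng.permutation(zo))
        # one-sided toward the observed sign of the local statistic
        if local[i] >= 0:
            p[i] = (1 + (sims >= local[i]).sum()) / (n_perm + 1)
        else:
            p[i] = (1 + (sims <= local[i]).sum()) / (n_perm + 1)

    label = np.full(n, "other", dtype=object)
    sig = p < alpha
    label[sig & (z > 0) & (lag > 0)] = "hot"   # high surrounded by high
    label[sig & (z < 0) & (lag < 0)] = "cold"  # low surrounded by low
    return pd.DataFrame(
        {"local_i": local, "z_value": z, "spatial_lag": lag, "p_value": p, "label": label},
        index=pd.Index(W.node_ids, name="node_id"),
    )


def getis_ord_gstar(y, W: WeightMatrix, star: bool = True) -> pd.DataFrame:
    """Getis-Ord Gi* z-scores per unit.

    Gi* = (sum_j w_ij y_j - ybar sum_j w_ij) /
          (S sqrt[(n sum_j w_ij^2 - (sum_j w_ij)^2) / (n-1)]),

    with S = sqrt(sum_j y_j^2 / n - ybar^2) and, for the starred
    statistic, self-weight w_ii = 1.  Values are asymptotically standard
    normal; large positive = hot spot, large negative = cold spot.
    """
    y = _check_y(y, min_n=2)
    w = W.w.copy()
    n = y.size
    if w.shape[0] != n:
        raise ValueError("dimension mismatch between y and W")
    if star:
        np.fill_diagonal(w, 1.0)
    ybar = y.mean()
    s = np.sqrt((y**2).sum() / n - ybar**2)
    wsum = w.sum(axis=1)
    w2sum = (w**2).sum(axis=1)
    num = w @ y - ybar * wsum
    inner = (n * w2sum - wsum**2) / (n - 1)
    denom = s * np.sqrt(np.maximum(inner, 0.0))
    g = np.full(n, np.nan)
    ok = denom > 0
    g[ok] = num[ok] / denom[ok]
    return pd.DataFrame(
        {"g_star": g, "defined": ok},
        index=pd.Index(W.node_ids, name="node_id"),
    )


def mean_center_and_standard_distance(coords, weights=None) -> tuple[np.ndarray, float]:
    """Mean center and standard distance of a (possibly weighted) point set.

    The mean center is the (weighted) arithmetic mean of the
    coordinates; the standard distance is the root mean squared
    (weighted) Euclidean distance of the points to that center.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim == 1:
        coords = coords.reshape(1, -1)
    n = coords.shape[0]
    if n < 1:
        raise ValueError("need at least one point")
    if weights is None:
        wts = np.ones(n)
    else:
        wts = np.asarray(weights, dtype=float)
        if wts.shape != (n,) or (wts < 0).any() or wts.sum() == 0:
            raise ValueError("weights must be non-negative with positive sum")
    wts = wts / wts.sum()
    center = wts @ coords
    d2 = ((coords - center) ** 2).sum(axis=1)
    sd = float(np.sqrt(wts @ d2))
    return center, sd
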