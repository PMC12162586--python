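"""Interpretable outputs from fitted spatial count models.

Log-scale coefficients are translated to percent changes in the
expected count, 100*(exp(c) - 1); the intercept exponentiates to the
baseline expected count at reference covariate levels; and per-area
relative risks RR = E[exp(structured + unstructured effects)] are
categorized as low (RR < 1), moderate (1 <= RR <= 1.5) or high
(RR > 1.5) for choropleth mapping.
"""

from __future__ import annotations

import json
import warnings

import numpy as np
import pandas as pd

__all__ = [
    "percent_change",
    "baseline_count",
    "relative_risk",
    "effect_table",
    "export_map",
    "categorize_rr",
]

RR_CATEGORIES = ("low", "moderate", "high")


def percent_change(coefficient: float) -> float:
    """Percent change in the expected count per unit of a log-scale
    coefficient: 100 * (exp(c) - 1).  Note the asymmetry: a coefficient
    of +c does not undo -c in percent terms."""
    c = float(coefficient)
    if not np.isfinite(c):
        raise ValueError("coefficient must be finite")
    return 100.0 * (np.exp(c) - 1.0)


def baseline_count(intercept: float) -> float:
    """Expected count at reference covariate levels, exp(intercept)."""
    b = float(intercept)
    if not np.isfinite(b):
        raise ValueError("intercept must be finite")
    return float(np.exp(b))


def categorize_rr(rr) -> np.ndarray:
    """low iff RR < 1; moderate iff 1 <= RR <= 1.5; high iff RR > 1.5."""
    rr = np.asarray(rr, dtype=float)
    out = np.full(rr.shape, "moderate", dtype=object)
    out[rr < 1.0] = "low"
    out[rr > 1.5] = "high"
    return out


def relative_risk(samples, area_level: str = "region", prob: float = 0.95,
                  region_idx=None) -> pd.DataFrame:
    """Posterior relative risk per area from a fitted spatial model.

    RR is the posterior mean of exp(spatial effects): exp(Phi_r) at
    region level, exp(Phi_{r(k)} + u_k) at cluster level (requires the
    convolution model).  Credible intervals are equal-tailed draw
    quantiles; ``exceedance`` is P(RR > 1), an alternative display
    robust to skew.
    """
    if "phi" not in samples.draws:
        raise ValueError("relative_risk requires a fit with a spatial/structured effect")
    phi = samples.draws["phi"]
    total = phi.shape[0] * phi.shape[1]
    phi = phi.reshape(total, -1)
    if area_level == "region":
        eff = phi
    elif area_level == "cluster":
        if "u" not in samples.draws:
            raise ValueError("cluster-level RR requires an unstructured effect u")
        u = samples.draws["u"].reshape(total, -1)
        if region_idx is None:
            raise ValueError("cluster-level RR requires region_idx mapping clusters to regions")
        region_idx = np.asarray(region_idx, dtype=int)
        eff = phi[:, region_idx] + u
    else:
        raise ValueError("area_level must be 'region' or 'cluster'")
    rr_draws = np.exp(eff)
    lo, hi = (1 - prob) / 2, 1 - (1 - prob) / 2
    rr = rr_draws.mean(axis=0)
    out = pd.DataFrame(
        {
            "area_id": np.arange(1, eff.shape[1] + 1),
            "rr": rr,
            "rr_lo": np.quantile(rr_draws, lo, axis=0),
            "rr_hi": np.quantile(rr_draws, hi, axis=0),
            "exceedance": (rr_draws > 1.0).mean(axis=0),
            "category": categorize_rr(rr),
        }
    )
    return out


def effect_table(samples, covariate_names: list[str] | None = None, prob: float = 0.95) -> pd.DataFrame:
    """Posterior coefficient table on log and percent-change scales.

    The percent transform is applied to the posterior mean and to each
    CI bound (exp is monotone, so the interval order is preserved).
    """
    names = covariate_names if covariate_names is not None else samples.meta.get("columns")
    beta = samples.draws["beta"]
    beta = beta.reshape(-1, beta.shape[2])
    if names is None or len(names) != beta.shape[1]:
        raise ValueError("covariate_names must match the fitted coefficient block")
    lo, hi = (1 - prob) / 2, 1 - (1 - prob) / 2
    mean = beta.mean(axis=0)
    qlo = np.quantile(beta, lo, axis=0)
    qhi = np.quantile(beta, hi, axis=0)
    return pd.DataFrame(
        {
            "coefficient": mean,
            "ci_lo": qlo,
            "ci_hi": qhi,
            "percent_change": [percent_change(c) for c in mean],
            "percent_lo": [percent_change(c) for c in qlo],
            "percent_hi": [percent_change(c) for c in qhi],
        },
        index=pd.Index(names, name="covariate"),
    )


def export_map(risk: pd.DataFrame, geometry: dict | None = None, out_prefix: str = "risk") -> list[str]:
    """Write choropleth-ready outputs: CSV always, GeoJSON when geometry
    features (matched on ``region_id``/``area_id`` property) are given.

    Returns the list of paths written; unmatched area ids are an error.
    """
    written = []
    csv_path = f"{out_prefix}.csv"
    risk.to_csv(csv_path, index=False)
    written.append(csv_path)
    if geometry is None:
        warnings.warn("no geometry supplied: CSV only", stacklevel=2)
        return written
    feats = geometry.get("features", [])
    by_id = {}
    for f in feats:
        props = f.get("properties", {}) or {}
        fid = props.get("region_id", props.get("area_id"))
        if fid is not None:
            by_id[int(fid)] = f
    missing = [int(a) for a in risk["area_id"] if int(a) not in by_id]
    if missing:
        raise ValueError(f"geometry missing features for area ids: {missing}")
    out_feats = []
    for _, row in risk.iterrows():
        f = json.loads(json.dumps(by_id[int(row["area_id"])]))  # deep copy
        f.setdefault("properties", {})
        f["properties"].update(
            {
                "rr": float(row["rr"]),
                "rr_lo": float(row["rr_lo"]),
                "rr_hi": float(row["rr_hi"]),
                "category": str(row["category"]),
            }
        )
        out_feats.append(f)
    geo_path = f"{out_prefix}.geojson"
    with open(geo_path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": out_feats}, fh)
    written.append(geo_path)
    return written
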