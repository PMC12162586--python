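"""Synthetic DHS-like spatial count data with known ground truth.

The generator emulates the structure of a national household survey with
~305 spatial clusters nested in 11 regions: a per-cluster count of
undernourished under-five children, cluster-level covariates (binary
indicators plus a continuous mother's-age column on 15-49 years),
cluster coordinates, and a region adjacency graph.  Counts are negative
binomial on a log link,

    y_k ~ NB(mu_k, gamma),   log mu_k = x_k' beta + Phi_{r(k)} + u_k,

with a structured region-level ICAR field Phi (clusters inherit their
region's value) and unstructured cluster-level noise u ~ N(0, tau_u^2).
The NB is parameterized by mean and dispersion: Var(y) = mu + gamma mu^2.

Every stage draws from a substream spawned off one master seed, so each
stage is independently reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .weights import WeightMatrix, queen_contiguity

__all__ = [
    "TrueParams",
    "make_region_graph",
    "simulate_covariates",
    "simulate_icar_field",
    "simulate_counts",
    "simulate_study",
    "default_covariate_scheme",
    "write_study_table",
    "read_study_table",
]

# Emulates the survey codebook: binary indicator covariates (reference
# level omitted) and one continuous age column.  Probabilities are the
# generator's fixed study conditions, chosen as plausible national
# household-survey prevalences.
DEFAULT_BINARY_COVARIATES: dict[str, float] = {
    "mass_media_yes": 0.45,
    "breastfeed_yes": 0.55,
    "water_unimproved": 0.35,
    "toilet_unimproved": 0.40,
    "cooking_traditional": 0.60,
    "residence_urban": 0.25,
    "edu_primary": 0.30,
    "edu_secondary": 0.15,
    "edu_higher": 0.08,
    "wealth_poorer": 0.20,
    "wealth_middle": 0.20,
    "wealth_richer": 0.20,
    "wealth_richest": 0.18,
}

MOTHER_AGE_RANGE = (15.0, 49.0)


def default_covariate_scheme() -> dict:
    """Full covariate scheme: intercept, all binary indicators, mother's age."""
    return {
        "binary": dict(DEFAULT_BINARY_COVARIATES),
        "mother_age": True,
    }


@dataclass(frozen=True)
class TrueParams:
    """Ground-truth generator parameters for recovery tests.

    ``beta`` is on the log scale with a leading intercept.  ``tau2_phi``
    and ``tau2_u`` are the structured (region) and unstructured
    (cluster) random-effect variances; ``gamma`` is the NB dispersion in
    the Var = mu + gamma mu^2 parameterization.
    """

    beta: tuple[float, ...] = (2.5, -0.2, 0.15)
    tau2_phi: float = 0.35**2
    tau2_u: float = 0.37**2
    gamma: float = 0.5
    n_regions: int = 11
    clusters_per_region: int = 28
    seed: int = 0
    topology: str = "random_planar"
    covariates: dict = field(default_factory=lambda: {"binary": {"x1": 0.5, "x2": 0.4}, "mother_age": False})

    def __post_init__(self):
        if self.tau2_phi <= 0 or self.tau2_u <= 0:
            raise ValueError("variance components must be positive")
        if self.gamma <= 0:
            raise ValueError("dispersion gamma must be positive")
        if self.n_regions < 1:
            raise ValueError("need at least one region")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "TrueParams":
        with open(path) as fh:
            d = json.load(fh)
        d["beta"] = tuple(d["beta"])
        return cls(**d)


def make_region_graph(n_regions: int, topology: str = "random_planar", seed: int = 0) -> list[tuple[int, int]]:
    """Symmetric edge list (1-based, no self-loops) for the region graph.

    Topologies: ``grid`` (near-square lattice), ``cycle``, and
    ``random_planar`` (a Delaunay triangulation of random points — a
    connected planar graph resembling an administrative-region
    adjacency).  A single region yields an empty edge list.
    """
    import networkx as nx

    if n_regions < 1:
        raise ValueError("n_regions must be >= 1")
    if topology not in {"grid", "cycle", "random_planar"}:
        raise ValueError(f"unknown topology: {topology!r}")
    if n_regions == 1:
        return []
    if n_regions == 2:
        return [(1, 2)]

    if topology == "cycle":
        return [(i, i + 1) for i in range(1, n_regions)] + [(n_regions, 1)]

    if topology == "grid":
        ncol = int(np.ceil(np.sqrt(n_regions)))
        edges = []
        for v in range(n_regions):
            r, c = divmod(v, ncol)
            if c + 1 < ncol and v + 1 < n_regions:
                edges.append((v + 1, v + 2))
            if v + ncol < n_regions:
                edges.append((v + 1, v + ncol + 1))
        g = nx.Graph(edges)
        g.add_nodes_from(range(1, n_regions + 1))
        # a ragged last row can strand nodes; chain any stray components
        comps = [sorted(c) for c in nx.connected_components(g)]
        for a, b in zip(comps, comps[1:]):
            edges.append((a[-1], b[0]))
        return sorted(set(tuple(sorted(e)) for e in edges))

    # random_planar: Delaunay triangulation of uniform points
    from scipy.spatial import Delaunay

    rng = np.random.default_rng(seed)
    pts = rng.uniform(size=(n_regions, 2))
    tri = Delaunay(pts)
    edges = set()
    for simplex in tri.simplices:
        for i in range(3):
            a, b = int(simplex[i]), int(simplex[(i + 1) % 3])
            edges.add((min(a, b) + 1, max(a, b) + 1))
    return sorted(edges)


def region_positions(n_regions: int, topology: str, seed: int) -> np.ndarray:
    """Representative (lat, lon)-like positions for each region, matching
    the layout used by :func:`make_region_graph`."""
    rng = np.random.default_rng(seed)
    if topology == "random_planar":
        return rng.uniform(size=(n_regions, 2))
    if topology == "cycle":
        ang = 2 * np.pi * np.arange(n_regions) / max(n_regions, 1)
        return 0.5 + 0.4 * np.column_stack([np.sin(ang), np.cos(ang)])
    ncol = int(np.ceil(np.sqrt(n_regions)))
    r, c = np.divmod(np.arange(n_regions), ncol)
    return np.column_stack([r, c]).astype(float)


def simulate_covariates(n_clusters: int, scheme: dict | None = None, seed: int = 0) -> pd.DataFrame:
    """Simulate the cluster-level design matrix.

    Returns a DataFrame with a leading ``intercept`` column of ones,
    one Bernoulli indicator per binary covariate (reference level
    omitted), and — if requested — a continuous ``mother_age`` column
    uniform on 15-49 years.
    """
    if n_clusters < 1:
        raise ValueError("n_clusters must be >= 1")
    scheme = scheme if scheme is not None else {"binary": {}, "mother_age": False}
    rng = np.random.default_rng(seed)
    cols = {"intercept": np.ones(n_clusters)}
    for name, p in scheme.get("binary", {}).items():
        cols[name] = (rng.uniform(size=n_clusters) < p).astype(float)
    if scheme.get("mother_age", False):
        lo, hi = MOTHER_AGE_RANGE
        cols["mother_age"] = rng.uniform(lo, hi, size=n_clusters)
    return pd.DataFrame(cols)


def simulate_icar_field(W: WeightMatrix, tau2_phi: float, seed: int = 0,
                        size: int | None = None) -> np.ndarray:
    """Sample a zero-mean intrinsic-CAR (GMRF) field on the graph of ``W``.

    The improper precision is Q = (diag(rowsum) - W)/tau2; sampling uses
    the eigendecomposition of Q restricted to its non-null eigenspace
    (the null space of an ICAR on a connected graph is the constant
    vector), and the draw is re-centered to sum exactly to zero.
    """
    if tau2_phi <= 0:
        raise ValueError("tau2_phi must be positive")
    n = W.n
    if n == 1:
        out = np.zeros((1,) if size is None else (size, 1))
        return out[0] if size is None else out
    ncomp = W.n_components()
    if ncomp > 1:
        import networkx as nx

        comps = list(nx.connected_components(nx.from_numpy_array(W.w)))
        sizes = sorted(len(c) for c in comps)
        raise ValueError(
            f"ICAR field requires a connected graph; got {ncomp} components of sizes {sizes}"
        )
    q = np.diag(W.w.sum(axis=1)) - W.w
    evals, evecs = np.linalg.eigh(q)
    keep = evals > evals[-1] * 1e-10
    rng = np.random.default_rng(seed)
    k = int(keep.sum())
    nsamp = 1 if size is None else size
    z = rng.standard_normal((nsamp, k))
    phi = (z * np.sqrt(tau2_phi / evals[keep])) @ evecs[:, keep].T
    phi -= phi.mean(axis=1, keepdims=True)
    return phi[0] if size is None else phi


def simulate_counts(X, beta, phi, u, gamma: float, seed: int = 0) -> np.ndarray:
    """Draw y_k ~ NB(mu_k, gamma) with log mu = X beta + phi + u.

    ``phi`` must already be expanded to cluster length (clusters inherit
    their region's structured effect).  Uses the Poisson-gamma mixture:
    y ~ Poisson(mu * g), g ~ Gamma(1/gamma, scale=gamma), which has
    mean mu and variance mu + gamma mu^2.
    """
    X = np.asarray(X, dtype=float)
    beta = np.asarray(beta, dtype=float)
    phi = np.asarray(phi, dtype=float)
    u = np.asarray(u, dtype=float)
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    eta = X @ beta + phi + u
    if not np.isfinite(eta).all():
        raise ValueError("non-finite linear predictor")
    mu = np.exp(eta)
    if not np.isfinite(mu).all():
        raise ValueError("non-finite mean: linear predictor too large")
    rng = np.random.default_rng(seed)
    g = rng.gamma(shape=1.0 / gamma, scale=gamma, size=mu.shape)
    return rng.poisson(mu * g)


def simulate_study(params: TrueParams) -> tuple[pd.DataFrame, WeightMatrix, dict]:
    """Generate a complete synthetic study: table, region weights, truth.

    Returns ``(study_table, region_W, truth)`` where ``truth`` records
    the realized phi/u fields alongside the parameters.
    """
    p = params
    edges = make_region_graph(p.n_regions, p.topology, _seed_for(p.seed, 0))
    W = queen_contiguity(edge_list=edges, node_ids=range(1, p.n_regions + 1))

    n = p.n_regions * p.clusters_per_region
    region_id = np.repeat(np.arange(1, p.n_regions + 1), p.clusters_per_region)

    Xdf = simulate_covariates(n, p.covariates, seed=_seed_for(p.seed, 1))
    X = Xdf.to_numpy()
    if len(p.beta) != X.shape[1]:
        raise ValueError(f"beta has {len(p.beta)} entries but design has {X.shape[1]} columns")

    if p.n_regions > 1:
        phi_r = simulate_icar_field(W, p.tau2_phi, seed=_seed_for(p.seed, 2))
    else:
        phi_r = np.zeros(1)
    rng_u = np.random.default_rng(_seed_for(p.seed, 3))
    u = rng_u.normal(0.0, np.sqrt(p.tau2_u), size=n)
    phi = phi_r[region_id - 1]

    y = simulate_counts(X, p.beta, phi, u, p.gamma, seed=_seed_for(p.seed, 4))

    centers = region_positions(p.n_regions, p.topology, _seed_for(p.seed, 0))
    rng_c = np.random.default_rng(_seed_for(p.seed, 5))
    jitter = rng_c.normal(scale=0.08, size=(n, 2))
    coords = centers[region_id - 1] + jitter

    table = pd.DataFrame(
        {
            "cluster_id": np.arange(1, n + 1),
            "region_id": region_id,
            "lat": coords[:, 0],
            "lon": coords[:, 1],
            "y": y,
        }
    )
    table = pd.concat([table, Xdf], axis=1)
    truth = {
        "params": p,
        "phi_region": phi_r,
        "u": u,
        "edges": edges,
        "columns": list(Xdf.columns),
    }
    return table, W, truth


def _seed_for(master: int, stage: int) -> int:
    """Deterministic per-stage substream seed below 2**31."""
    ss = np.random.SeedSequence(master).spawn(stage + 1)[stage]
    return int(ss.generate_state(1)[0] % (2**31 - 1))


def write_study_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


def read_study_table(path) -> pd.DataFrame:
    table = pd.read_csv(path)
    required = {"cluster_id", "region_id", "lat", "lon", "y"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"study table missing columns: {sorted(missing)}")
    return table
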