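"""Spatial weight matrices for areal count analysis.

Three weighting schemes are supported: queen contiguity (binary adjacency
from polygons or an edge list, counting shared edges *and* corners),
exponential distance decay ``w_ij = exp(-d_ij)`` and inverse distance
``w_ij = 1/d_ij``.  Distances are planar Euclidean on the raw coordinates
by default; a haversine (great-circle, km) option is available.

Binary, unstandardized weights are what the CAR/ICAR priors consume
(their conditionals divide by the row sum, so standardizing is a no-op
there); row-standardized weights are the convention for Moran's I.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "WeightMatrix",
    "queen_contiguity",
    "exponential_weights",
    "inverse_distance_weights",
    "row_standardize",
    "select_weighting",
    "read_edge_list",
    "write_edge_list",
]

_EARTH_RADIUS_KM = 6371.0088


@dataclass(frozen=True)
class WeightMatrix:
    """A non-negative n x n spatial weight matrix with scheme metadata.

    ``w`` is dense; the graphs this package targets (tens to a few
    hundred areas) do not warrant sparse storage.  ``node_ids`` are the
    1-based area labels, in matrix order.
    """

    w: np.ndarray
    scheme: str
    standardized: bool = False
    node_ids: tuple[int, ...] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        w = np.asarray(self.w, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("weight matrix must be square")
        if (w < 0).any():
            raise ValueError("weights must be non-negative")
        if np.diagonal(w).any():
            raise ValueError("weight matrix must have a zero diagonal")
        if not self.standardized and not np.allclose(w, w.T):
            raise ValueError("weight matrix must be symmetric before standardization")
        object.__setattr__(self, "w", w)
        if self.node_ids is None:
            object.__setattr__(self, "node_ids", tuple(range(1, w.shape[0] + 1)))
        elif len(self.node_ids) != w.shape[0]:
            raise ValueError("node_ids length does not match matrix order")

    @property
    def n(self) -> int:
        return self.w.shape[0]

    @property
    def islands(self) -> np.ndarray:
        """Boolean mask of areas with no neighbors (zero row sum)."""
        return self.w.sum(axis=1) == 0

    def neighbor_lists(self) -> list[np.ndarray]:
        """Indices of positive-weight neighbors per area."""
        return [np.flatnonzero(row) for row in self.w]

    def n_components(self) -> int:
        """Number of connected components of the positive-weight graph."""
        import networkx as nx

        g = nx.from_numpy_array(self.w)
        return nx.number_connected_components(g)

    def is_connected(self) -> bool:
        return self.n_components() == 1


def _pairwise_distances(coords: np.ndarray, metric: str = "euclidean") -> np.ndarray:
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 2:
        raise ValueError("coords must be an (n, 2) array of (lat, lon)")
    if not np.isfinite(coords).all():
        raise ValueError("coordinates must be finite")
    if metric == "euclidean":
        diff = coords[:, None, :] - coords[None, :, :]
        return np.sqrt((diff**2).sum(axis=-1))
    if metric == "haversine":
        lat = np.radians(coords[:, 0])
        lon = np.radians(coords[:, 1])
        dlat = lat[:, None] - lat[None, :]
        dlon = lon[:, None] - lon[None, :]
        a = np.sin(dlat / 2) ** 2 + np.cos(lat)[:, None] * np.cos(lat)[None, :] * np.sin(dlon / 2) ** 2
        return 2 * _EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0, 1)))
    raise ValueError(f"unknown distance metric: {metric!r}")


def queen_contiguity(polygons=None, edge_list=None, node_ids=None) -> WeightMatrix:
    """Binary queen-contiguity weights: ``w_ij = 1`` iff areas i and j touch.

    Queen contiguity counts any shared boundary point, so corner-only
    neighbors (as on a checkerboard) are adjacent.  Supply either
    ``polygons`` (a sequence of shapely geometries, or a GeoJSON-style
    FeatureCollection dict) or ``edge_list`` (pairs of 1-based node ids,
    symmetrized automatically).
    """
    if (polygons is None) == (edge_list is None):
        raise ValueError("supply exactly one of polygons or edge_list")

    if polygons is not None:
        geoms, ids = _coerce_polygons(polygons, node_ids)
        n = len(geoms)
        w = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                if geoms[i].touches(geoms[j]) or geoms[i].intersects(geoms[j]):
                    # intersects() also catches overlapping (invalid tiling)
                    # geometries; any shared point makes a queen neighbor
                    if not geoms[i].disjoint(geoms[j]):
                        w[i, j] = w[j, i] = 1.0
        return WeightMatrix(w, scheme="queen", node_ids=tuple(ids))

    edges = [(int(a), int(b)) for a, b in edge_list]
    if node_ids is None:
        nodes = sorted({v for e in edges for v in e}) if edges else []
        if not nodes:
            raise ValueError("empty edge list requires explicit node_ids")
    else:
        nodes = list(node_ids)
        known = set(nodes)
        for a, b in edges:
            if a not in known or b not in known:
                raise ValueError(f"edge ({a}, {b}) references unknown node")
    index = {v: i for i, v in enumerate(nodes)}
    w = np.zeros((len(nodes), len(nodes)))
    for a, b in edges:
        if a == b:
            raise ValueError(f"self-loop ({a}, {a}) not allowed")
        w[index[a], index[b]] = w[index[b], index[a]] = 1.0
    return WeightMatrix(w, scheme="queen", node_ids=tuple(nodes))


def _coerce_polygons(polygons, node_ids):
    from shapely.geometry import shape

    if isinstance(polygons, dict):  # GeoJSON FeatureCollection
        feats = polygons.get("features", [])
        geoms = [shape(f["geometry"]) for f in feats]
        ids = [f.get("properties", {}).get("region_id", i + 1) for i, f in enumerate(feats)]
    else:
        geoms = list(polygons)
        ids = list(node_ids) if node_ids is not None else list(range(1, len(geoms) + 1))
    for g in geoms:
        if not g.is_valid:
            raise ValueError("invalid geometry in polygon input")
    return geoms, ids


def exponential_weights(coords, node_ids=None, metric: str = "euclidean") -> WeightMatrix:
    """Exponential distance-decay weights ``w_ij = exp(-d_ij)``."""
    d = _pairwise_distances(coords, metric)
    if d.shape[0] < 2:
        raise ValueError("need at least two locations")
    offdiag = d[~np.eye(d.shape[0], dtype=bool)]
    if (offdiag == 0).any():
        warnings.warn("duplicate coordinates: some off-diagonal weights equal 1", stacklevel=2)
    w = np.exp(-d)
    np.fill_diagonal(w, 0.0)
    return WeightMatrix(w, scheme="exponential", node_ids=node_ids if node_ids is None else tuple(node_ids))


def inverse_distance_weights(coords, node_ids=None, metric: str = "euclidean") -> WeightMatrix:
    """Inverse-distance weights ``w_ij = 1/d_ij``; coincident points are an error."""
    d = _pairwise_distances(coords, metric)
    if d.shape[0] < 2:
        raise ValueError("need at least two locations")
    n = d.shape[0]
    zero = np.argwhere((d == 0) & ~np.eye(n, dtype=bool))
    if len(zero):
        i, j = zero[0]
        raise ValueError(f"coincident coordinates for locations {i + 1} and {j + 1}: inverse distance undefined")
    with np.errstate(divide="ignore"):
        w = 1.0 / d
    np.fill_diagonal(w, 0.0)
    return WeightMatrix(w, scheme="inverse_distance", node_ids=node_ids if node_ids is None else tuple(node_ids))


def row_standardize(wm: WeightMatrix) -> WeightMatrix:
    """Divide each row by its sum; island (all-zero) rows are left as zeros."""
    sums = wm.w.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        w = np.where(sums > 0, wm.w / sums, 0.0)
    return replace(wm, w=w, standardized=True)


def select_weighting(y, candidates: dict[str, WeightMatrix], n_perm: int = 999, seed: int = 0,
                     standardize: bool = True) -> pd.DataFrame:
    """Rank candidate weight matrices by the Moran's I they yield for ``y``.

    A larger, significant I indicates the scheme captures the spatial
    dependence in the outcome; candidates are returned sorted by I
    descending with one-sided permutation p-values attached.
    """
    from .esda import morans_i_permutation

    if not candidates:
        raise ValueError("need at least one candidate weight matrix")
    y = np.asarray(y, dtype=float)
    rows = []
    for name, wm in candidates.items():
        use = row_standardize(wm) if (standardize and not wm.standardized) else wm
        res = morans_i_permutation(y, use, n_perm=n_perm, seed=seed)
        rows.append({"scheme": name, "morans_i": res.statistic, "p_value": res.p_value})
    out = pd.DataFrame(rows).sort_values("morans_i", ascending=False, kind="mergesort")
    out.index = range(1, len(out) + 1)
    out.index.name = "rank"
    return out


def threshold_weights(wm: WeightMatrix, coords, max_distance: float,
                      metric: str = "euclidean") -> WeightMatrix:
    """Zero out weights between locations farther apart than ``max_distance``.

    This turns any distance-based weight matrix into the threshold-band
    form used by the distance-d Getis-Ord statistic: pass the result to
    :func:`spatialnb.esda.getis_ord_gstar` rather than using a separate
    estimator.
    """
    if max_distance <= 0:
        raise ValueError("max_distance must be positive")
    d = _pairwise_distances(coords, metric)
    if d.shape != wm.w.shape:
        raise ValueError("coords do not match the weight matrix order")
    w = np.where(d <= max_distance, wm.w, 0.0)
    np.fill_diagonal(w, 0.0)
    return replace(wm, w=w)


def read_edge_list(path) -> list[tuple[int, int]]:
    """Read a two-column whitespace- or comma-separated edge list (1-based ids)."""
    edges = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.replace(",", " ").split()
            if len(parts) < 2:
                raise ValueError(f"malformed edge-list line: {line!r}")
            edges.append((int(parts[0]), int(parts[1])))
    return edges


def write_edge_list(edges, path) -> None:
    with open(path, "w") as fh:
        for a, b in edges:
            fh.write(f"{a} {b}\n")


def write_weight_matrix(wm: WeightMatrix, triplet_path=None, csv_path=None) -> None:
    """Write W as an ``i j w`` triplet text file and/or a dense CSV."""
    if triplet_path is not None:
        with open(triplet_path, "w") as fh:
            for i in range(wm.n):
                for j in range(wm.n):
                    if wm.w[i, j] != 0:
                        fh.write(f"{wm.node_ids[i]} {wm.node_ids[j]} {wm.w[i, j]:.12g}\n")
    if csv_path is not None:
        pd.DataFrame(wm.w, index=wm.node_ids, columns=wm.node_ids).to_csv(csv_path)


def read_weight_matrix(triplet_path, scheme: str = "custom", standardized: bool = False) -> WeightMatrix:
    """Read an ``i j w`` triplet file back into a dense :class:`WeightMatrix`."""
    entries = []
    with open(triplet_path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            i, j, v = line.replace(",", " ").split()[:3]
            entries.append((int(i), int(j), float(v)))
    nodes = sorted({e[0] for e in entries} | {e[1] for e in entries})
    index = {v: i for i, v in enumerate(nodes)}
    w = np.zeros((len(nodes), len(nodes)))
    for i, j, v in entries:
        w[index[i], index[j]] = v
    return WeightMatrix(w, scheme=scheme, standardized=standardized, node_ids=tuple(nodes))
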