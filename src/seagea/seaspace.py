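"""Oceanic least-cost distances and distance-based Moran's eigenvector maps.

Distances are shortest over-water paths on the 8-connected graph of water
raster cells, with edge weights equal to great-circle distances between cell
centers (km).  The dbMEM basis is the classical construction: truncate the
distance matrix at t (default: the longest minimum-spanning-tree edge),
replace off-neighborhood distances by 4t, double-center -0.5 d^2, and
eigendecompose; eigenvectors with positive eigenvalues are spatial
covariates ordered from broad- to fine-scale pattern.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra, minimum_spanning_tree

from ._forward import ForwardSelection, forward_select
from .simgen import WaterMask

logger = logging.getLogger(__name__)

__all__ = [
    "OceanDistanceMatrix",
    "MEMBasis",
    "great_circle_km",
    "oceanic_distances",
    "build_dbmem",
    "morans_i",
    "expand_to_individuals",
    "forward_select_mems",
]

EARTH_RADIUS_KM = 6371.0


def great_circle_km(lon1, lat1, lon2, lat2) -> np.ndarray:
    """Haversine great-circle distance in km (array-aware)."""
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(v, dtype=float)) for v in (lon1, lat1, lon2, lat2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    h = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0, 1)))


@dataclass
class OceanDistanceMatrix:
    distances: np.ndarray  # symmetric, km, zero diagonal
    labels: list

    def __post_init__(self) -> None:
        D = np.asarray(self.distances, dtype=float)
        if D.ndim != 2 or D.shape[0] != D.shape[1]:
            raise ValueError("distance matrix must be square")
        if not np.allclose(D, D.T, atol=1e-8):
            raise ValueError("distance matrix must be symmetric")
        self.distances = D


@dataclass
class MEMBasis:
    """Unit-norm spatial eigenvectors (columns) with descending eigenvalues."""

    vectors: np.ndarray
    eigenvalues: np.ndarray
    truncation_distance: float


def _water_graph(mask: WaterMask):
    water = np.argwhere(mask.grid)
    index = -np.ones(mask.grid.shape, dtype=int)
    index[water[:, 0], water[:, 1]] = np.arange(len(water))
    lons = mask.origin_lon + (water[:, 1] + 0.5) * mask.cell_size
    lats = mask.origin_lat + (mask.nrows - water[:, 0] - 0.5) * mask.cell_size
    src, dst, w = [], [], []
    for dr, dc in ((0, 1), (1, 0), (1, 1), (1, -1)):
        r2, c2 = water[:, 0] + dr, water[:, 1] + dc
        ok = (r2 >= 0) & (r2 < mask.nrows) & (c2 >= 0) & (c2 < mask.ncols)
        ok[ok] &= mask.grid[r2[ok], c2[ok]]
        a = index[water[ok, 0], water[ok, 1]]
        b = index[r2[ok], c2[ok]]
        src.extend(a)
        dst.extend(b)
        w.extend(great_circle_km(lons[a], lats[a], lons[b], lats[b]))
    n = len(water)
    graph = coo_matrix((w, (src, dst)), shape=(n, n)).tocsr()
    return graph, lons, lats


def oceanic_distances(
    coords, mask: WaterMask, labels=None, snap_radius_km: float = 50.0
) -> OceanDistanceMatrix:
    """Pairwise least-cost over-water distances between coordinates.

    ``coords`` is an iterable of (lon, lat).  Each point is snapped to the
    nearest water cell center within ``snap_radius_km``; unsnappable points
    and disconnected pairs raise with the offending labels named.
    """
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    labels = list(labels) if labels is not None else [f"p{i}" for i in range(n)]
    graph, lons, lats = _water_graph(mask)
    nodes = np.empty(n, dtype=int)
    for i, (lon, lat) in enumerate(coords):
        d = great_circle_km(lon, lat, lons, lats)
        j = int(np.argmin(d))
        if d[j] > snap_radius_km:
            raise ValueError(
                f"sample {labels[i]!r} at ({lon:.4f}, {lat:.4f}) is "
                f"{d[j]:.1f} km from the nearest water cell (> {snap_radius_km} km)"
            )
        nodes[i] = j
    uniq, inv = np.unique(nodes, return_inverse=True)
    dist_sub = dijkstra(graph, directed=False, indices=uniq)
    D = dist_sub[np.ix_(inv, uniq)][:, inv]
    if not np.isfinite(D).all():
        bad = np.argwhere(~np.isfinite(D))
        i, j = bad[0]
        raise ValueError(
            f"no over-water path between {labels[i]!r} and {labels[j]!r} "
            "(disconnected water components)"
        )
    np.fill_diagonal(D, 0.0)
    return OceanDistanceMatrix(distances=(D + D.T) / 2.0, labels=labels)


def build_dbmem(
    D: OceanDistanceMatrix | np.ndarray,
    truncation: float | None = None,
    keep: str = "positive",
    tol: float = 1e-9,
) -> MEMBasis:
    """Classical dbMEM basis from a distance matrix.

    ``truncation=None`` uses the longest minimum-spanning-tree edge.
    ``keep`` selects "positive" eigenvalues (positive spatial
    autocorrelation, the default used for selection) or "all" nonzero ones.
    """
    Dm = D.distances if isinstance(D, OceanDistanceMatrix) else np.asarray(D, dtype=float)
    n = Dm.shape[0]
    if n < 3:
        raise ValueError("dbMEM needs at least 3 points")
    if truncation is None:
        mst = minimum_spanning_tree(Dm).toarray()
        truncation = float(mst.max())
    t = float(truncation)
    W = Dm.copy()
    W[W > t] = 4.0 * t
    np.fill_diagonal(W, 0.0)
    A = -0.5 * W**2
    H = np.eye(n) - np.ones((n, n)) / n
    Omega = H @ A @ H
    vals, vecs = np.linalg.eigh(Omega)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    scale = max(np.abs(vals).max(), 1.0)
    if keep == "positive":
        sel = vals > tol * scale
    elif keep == "all":
        sel = np.abs(vals) > tol * scale
    else:
        raise ValueError("keep must be 'positive' or 'all'")
    vecs = vecs[:, sel]
    vecs /= np.linalg.norm(vecs, axis=0, keepdims=True)
    # deterministic sign: largest-magnitude element positive
    for j in range(vecs.shape[1]):
        i = np.argmax(np.abs(vecs[:, j]))
        if vecs[i, j] < 0:
            vecs[:, j] = -vecs[:, j]
    return MEMBasis(vectors=vecs, eigenvalues=vals[sel], truncation_distance=t)


def morans_i(u: np.ndarray, W: np.ndarray) -> float:
    """Moran's I of a vector under weight matrix W (diagonal ignored)."""
    u = np.asarray(u, dtype=float)
    z = u - u.mean()
    W = np.asarray(W, dtype=float).copy()
    np.fill_diagonal(W, 0.0)
    s0 = W.sum()
    return float(len(u) / s0 * (z @ W @ z) / (z @ z))


def truncated_weights(D: np.ndarray, t: float) -> np.ndarray:
    """Similarity weights 1 - (d/4t)^2 within the truncation neighborhood."""
    W = np.where((D > 0) & (D <= t), 1.0 - (D / (4.0 * t)) ** 2, 0.0)
    np.fill_diagonal(W, 0.0)
    return W


def expand_to_individuals(site_vectors: np.ndarray, site_index) -> np.ndarray:
    """Broadcast site-level vectors to individuals via their site index."""
    return np.asarray(site_vectors)[np.asarray(site_index, dtype=int)]


def forward_select_mems(
    Y: np.ndarray,
    basis: MEMBasis,
    site_index=None,
    alpha: float = 0.05,
    n_perm: int = 100,
    seed: int | None = 0,
) -> ForwardSelection:
    """Forward-select MEMs against the genotype response.

    ``Y`` is the (imputed) individuals x loci dosage matrix; if the basis is
    site-level, ``site_index`` expands it to individuals.  Selection uses the
    shared engine (global pre-test, per-step permutation p <= alpha, adjusted
    R^2 double stopping rule).
    """
    V = basis.vectors
    if site_index is not None:
        V = expand_to_individuals(V, site_index)
    if V.shape[0] != np.asarray(Y).shape[0]:
        raise ValueError("MEM rows do not align with individuals")
    names = [f"MEM{i + 1}" for i in range(V.shape[1])]
    return forward_select(Y, V, alpha=alpha, n_perm=n_perm, seed=seed, names=names)
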