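"""Expression / spatial connectivity graphs, weighted fusion and Leiden.

The expression graph uses a UMAP-style fuzzy kernel on kNN distances in a
PCA latent space; the spatial graph is a unit-weight kNN graph on spot
coordinates (k=6 matching hex geometry). The two are fused as a convex
combination (default 0.8 expression / 0.2 spatial) and partitioned with
Leiden at a configurable resolution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import igraph as ig
import leidenalg
import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.neighbors import NearestNeighbors

from txflow.data import ConfigError, EmptyDatasetError
from txflow.qc import NormalizedMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "FusionWeights",
    "latent_embed",
    "expression_connectivities",
    "spatial_adjacency",
    "fuse_graphs",
    "leiden_cluster",
    "assign_inhibitory_subtypes",
    "check_graph",
]


@dataclass(frozen=True)
class FusionWeights:
    """Convex weights for graph fusion; spatial weight is 1 - alpha_expr."""

    alpha_expr: float = 0.8

    def __post_init__(self) -> None:
        if not 0 <= self.alpha_expr <= 1:
            raise ConfigError("alpha_expr must be in [0, 1]")

    @property
    def alpha_spatial(self) -> float:
        return 1.0 - self.alpha_expr


def check_graph(g: sp.spmatrix, tol: float = 1e-12) -> None:
    """Assert graph invariants: symmetry, zero diagonal, weights in [0,1]."""
    g = sp.csr_matrix(g)
    if abs(g - g.T).max() > tol:
        raise AssertionError("graph is not symmetric")
    if np.abs(g.diagonal()).max() > 0:
        raise AssertionError("graph has self-loops")
    if g.nnz and (g.data.min() < -tol or g.data.max() > 1 + tol):
        raise AssertionError("graph weights outside [0, 1]")


def latent_embed(norm: NormalizedMatrix, hvgs, d: int = 30) -> np.ndarray:
    """PCA embedding of the HVG-restricted, per-gene standardized
    normalized matrix. Sign convention: the largest-|loading| entry of
    each component is positive, so the embedding is deterministic."""
    hvgs = pd.Index(hvgs)
    missing = hvgs.difference(norm.gene_ids)
    if len(missing):
        raise ConfigError(f"HVGs not in matrix: {list(missing)[:5]}")
    cols = norm.gene_ids.get_indexer(hvgs)
    X = np.asarray(norm.values[:, cols].todense())
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    X = (X - mu) / sd
    if d > min(X.shape):
        raise ConfigError(f"d={d} exceeds matrix rank bound {min(X.shape)}")
    # full SVD on the centered matrix; deterministic up to sign
    U, S, Vt = np.linalg.svd(X - X.mean(axis=0), full_matrices=False)
    rank = int((S > S[0] * 1e-12).sum()) if S.size else 0
    if d > rank:
        raise ConfigError(f"d={d} exceeds matrix rank {rank}")
    flip = np.sign(Vt[np.arange(d), np.abs(Vt[:d]).argmax(axis=1)])
    flip[flip == 0] = 1.0
    return (U[:, :d] * S[:d]) * flip


def _knn(X: np.ndarray, k: int):
    nn = NearestNeighbors(n_neighbors=k + 1).fit(X)
    dist, idx = nn.kneighbors(X)
    return dist[:, 1:], idx[:, 1:]  # drop self


def expression_connectivities(emb: np.ndarray, k: int = 15) -> sp.csr_matrix:
    """Fuzzy kNN graph in latent space: directed weight
    ``a_ij = exp(-max(0, d_ij - d_i1) / sigma_i)`` (sigma_i = mean neighbor
    distance), symmetrized by the fuzzy union ``a + a' - a*a'``."""
    n = emb.shape[0]
    if k <= 0:
        raise ConfigError("k must be positive")
    if k >= n:
        raise ConfigError(f"k={k} must be < n_observations={n}")
    dist, idx = _knn(emb, k)
    d1 = dist[:, 0][:, None]
    sigma = dist.mean(axis=1)[:, None]
    sigma[sigma == 0] = 1.0
    a = np.exp(-np.maximum(0.0, dist - d1) / sigma)
    rows = np.repeat(np.arange(n), k)
    A = sp.csr_matrix((a.ravel(), (rows, idx.ravel())), shape=(n, n))
    A.setdiag(0)
    A.eliminate_zeros()
    At = A.T.tocsr()
    W = A + At - A.multiply(At)
    W = sp.csr_matrix(W)
    W.setdiag(0)
    W.eliminate_zeros()
    check_graph(W)
    return W


def spatial_adjacency(coords: np.ndarray, k: int = 6) -> sp.csr_matrix:
    """Unit-weight k-nearest-neighbor graph on coordinates, symmetrized
    by max (an edge exists if either endpoint selects the other)."""
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] < 2:
        raise ConfigError("coordinates must be an (n, 2) array")
    n = coords.shape[0]
    if k <= 0 or k >= n:
        raise ConfigError(f"k={k} out of range for n={n}")
    _, idx = _knn(coords, k)
    rows = np.repeat(np.arange(n), k)
    A = sp.csr_matrix((np.ones(n * k), (rows, idx.ravel())), shape=(n, n))
    W = A.maximum(A.T).tocsr()
    W.setdiag(0)
    W.eliminate_zeros()
    check_graph(W)
    return W


def fuse_graphs(g_expr: sp.spmatrix, g_spatial: sp.spmatrix,
                w: FusionWeights = FusionWeights()) -> sp.csr_matrix:
    """Convex combination ``alpha_expr * W_expr + alpha_spatial * W_spatial``."""
    if g_expr.shape != g_spatial.shape:
        raise ConfigError(f"graph shapes differ: {g_expr.shape} vs "
                          f"{g_spatial.shape}")
    W = (w.alpha_expr * sp.csr_matrix(g_expr, dtype=float)
         + w.alpha_spatial * sp.csr_matrix(g_spatial, dtype=float))
    W = sp.csr_matrix(W)
    check_graph(W)
    return W


def leiden_cluster(g: sp.spmatrix, resolution: float = 0.8,
                   seed: int = 0) -> np.ndarray:
    """Leiden partition of a weighted graph (RB-modularity objective).
    Labels are integers renumbered by decreasing cluster size."""
    g = sp.csr_matrix(g)
    n = g.shape[0]
    if n == 0:
        raise EmptyDatasetError("empty graph")
    triu = sp.triu(g, k=1).tocoo()
    graph = ig.Graph(
        n=n,
        edges=list(zip(triu.row.tolist(), triu.col.tolist())),
        edge_attrs={"weight": triu.data.tolist()},
    )
    part = leidenalg.find_partition(
        graph,
        leidenalg.RBConfigurationVertexPartition,
        weights="weight",
        resolution_parameter=resolution,
        seed=seed,
        n_iterations=2,
    )
    labels = np.asarray(part.membership)
    # stable relabel by decreasing size (ties: smaller original label first)
    sizes = np.bincount(labels)
    order = np.lexsort((np.arange(sizes.size), -sizes))
    remap = np.empty(sizes.size, dtype=int)
    remap[order] = np.arange(sizes.size)
    logger.info("leiden: resolution=%s seed=%s clusters=%d", resolution,
                seed, sizes.size)
    return remap[labels]


def assign_inhibitory_subtypes(
    norm: NormalizedMatrix,
    labels: np.ndarray,
    markers: dict[str, str],
) -> tuple[pd.Series, dict[int, str]]:
    """Assign each cluster the subtype whose marker has the highest mean
    normalized expression in the cluster.

    ``markers`` maps subtype name -> marker gene id; ties are broken by
    the mapping's iteration order. Clusters where every marker mean is
    zero become ``"unassigned"``. Returns (per-observation subtype
    labels, cluster -> subtype map).
    """
    missing = [g for g in markers.values() if g not in norm.gene_ids]
    if missing:
        raise ConfigError(f"marker genes not in matrix: {missing}")
    cols = norm.gene_ids.get_indexer(pd.Index(markers.values()))
    M = np.asarray(norm.values[:, cols].todense())
    labels = np.asarray(labels)
    names = list(markers)
    cluster_map: dict[int, str] = {}
    for c in np.unique(labels):
        means = M[labels == c].mean(axis=0)
        if means.max() <= 0:
            cluster_map[int(c)] = "unassigned"
        else:
            cluster_map[int(c)] = names[int(means.argmax())]
    per_obs = pd.Series([cluster_map[int(c)] for c in labels],
                        index=norm.obs_ids, name="subtype")
    return per_obs, cluster_map
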