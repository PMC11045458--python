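"""Graph-based clustering of the integrated data and partition comparison.

Cells become nodes of a shared-nearest-neighbour (SNN) graph: edges join cells
whose k-nearest-neighbour sets overlap, weighted by the Jaccard index of those
sets and pruned below a floor.  Louvain modularity optimisation on that graph
yields the clusters; partitions are compared with the Adjusted Rand Index.

The ARI for two partitions with contingency counts n_ij, row sums a_i, column
sums b_j and total n is

          sum_ij C(n_ij,2) - [sum_i C(a_i,2) sum_j C(b_j,2)] / C(n,2)
    ARI = --------------------------------------------------------------
          (1/2)[sum_i C(a_i,2) + sum_j C(b_j,2)] - [...same product...] / C(n,2)

evaluated here in exact integer arithmetic.  When the denominator is zero
(both partitions all-singletons or all-one-cluster) the convention is 1.0 for
identical partitions and 0.0 otherwise.
"""

from __future__ import annotations

import random as _pyrandom
from dataclasses import dataclass
from math import comb

import igraph as ig
import numpy as np
import pandas as pd
from scipy import sparse
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from .integrate import IntegratedData

__all__ = [
    "ClusterResult",
    "contingency_table",
    "knn_graph",
    "louvain_cluster",
    "ari",
    "resolution_scan",
    "umap_embed",
]


@dataclass
class ClusterResult:
    labels: np.ndarray  # contiguous integer ids from 0
    k_neighbors: int
    resolution: float
    seed: int
    modularity: float


def _data_values(data) -> np.ndarray:
    if isinstance(data, IntegratedData):
        return data.values
    return np.asarray(data, dtype=float)


def knn_graph(
    data,
    k: int = 20,
    n_pcs: int | None = None,
    prune: float = 1 / 15,
) -> ig.Graph:
    """Shared-nearest-neighbour graph from Euclidean k-NN.

    Neighbours are found in PCA space when ``n_pcs`` is set, otherwise on the
    raw columns.  Edge (i, j) carries the Jaccard overlap of the two
    neighbourhoods (each including the cell itself); weights below ``prune``
    are dropped.
    """
    X = _data_values(data)
    n = X.shape[0]
    if k >= n:
        raise ValueError(f"k = {k} must be smaller than the number of observations {n}")
    if n_pcs is not None:
        if n_pcs > min(n - 1, X.shape[1]):
            raise ValueError(f"n_pcs = {n_pcs} exceeds min(n - 1, n_columns)")
        X = PCA(n_components=n_pcs, svd_solver="full" if n < 1000 else "randomized",
                random_state=0).fit_transform(X)

    nn = NearestNeighbors(n_neighbors=k + 1).fit(X)
    A = nn.kneighbors_graph(X, mode="connectivity")  # includes self, k+1 per row
    # SNN: shared neighbour counts between all pairs that share at least one
    shared = A @ A.T
    shared = sparse.csr_matrix(shared)
    shared.setdiag(0)
    shared.eliminate_zeros()
    # Jaccard: |N_i & N_j| / |N_i | N_j|, neighbourhood size k+1 each
    rows, cols = shared.nonzero()
    inter = shared.data.astype(float)
    union = 2.0 * (k + 1) - inter
    jac = inter / union
    keep = jac >= prune
    rows, cols, jac = rows[keep], cols[keep], jac[keep]
    upper = rows < cols
    edges = np.column_stack([rows[upper], cols[upper]])
    weights = jac[upper]

    g = ig.Graph(n=n, edges=edges.tolist(), directed=False)
    g.es["weight"] = weights.tolist()
    return g


def louvain_cluster(graph: ig.Graph, resolution: float = 0.8, seed: int = 0) -> ClusterResult:
    """Louvain community detection at the given resolution, seeded."""
    if graph.vcount() == 0:
        raise ValueError("empty graph")
    weights = graph.es["weight"] if "weight" in graph.es.attributes() else None
    # python-igraph draws from Python's random module
    state = _pyrandom.getstate()
    try:
        _pyrandom.seed(seed)
        part = graph.community_multilevel(weights=weights, resolution=resolution)
    finally:
        _pyrandom.setstate(state)
    labels = np.asarray(part.membership)
    # contiguous relabel in order of first appearance
    _, labels = np.unique(labels, return_inverse=True)
    first = pd.Series(labels).drop_duplicates().to_numpy()
    remap = np.empty(first.size, dtype=int)
    remap[first] = np.arange(first.size)
    labels = remap[labels]
    modularity = graph.modularity(labels, weights=weights)
    return ClusterResult(
        labels=labels,
        k_neighbors=-1,
        resolution=resolution,
        seed=seed,
        modularity=modularity,
    )


def contingency_table(labels_a, labels_b) -> tuple[np.ndarray, np.ndarray, np.ndarray, int]:
    """Contingency counts n_ij with marginals a_i, b_j and total n."""
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape:
        raise ValueError(f"label vectors differ in length: {a.shape} vs {b.shape}")
    _, ai = np.unique(a, return_inverse=True)
    _, bi = np.unique(b, return_inverse=True)
    r, s = ai.max() + 1, bi.max() + 1
    counts = np.zeros((r, s), dtype=np.int64)
    np.add.at(counts, (ai, bi), 1)
    return counts, counts.sum(axis=1), counts.sum(axis=0), a.size


def ari(labels_a, labels_b) -> float:
    """Adjusted Rand Index between two partitions (exact integer arithmetic)."""
    counts, a_sums, b_sums, n = contingency_table(labels_a, labels_b)
    sum_nij = sum(comb(int(x), 2) for x in counts.ravel())
    sum_a = sum(comb(int(x), 2) for x in a_sums)
    sum_b = sum(comb(int(x), 2) for x in b_sums)
    total = comb(n, 2)
    if total == 0:
        return 1.0
    # multiply numerator and denominator through by 2 * C(n,2) to stay integral
    num = 2 * (sum_nij * total - sum_a * sum_b)
    den = (sum_a + sum_b) * total - 2 * sum_a * sum_b
    if den == 0:
        # only possible when both partitions are all-singletons or both are a
        # single cluster, i.e. the partitions coincide
        return 1.0
    return num / den


def resolution_scan(
    data,
    reference_labels,
    grid,
    k: int = 20,
    seed: int = 0,
    n_pcs: int | None = None,
) -> tuple[float, ClusterResult, pd.DataFrame]:
    """Cluster at each resolution and keep the one maximising ARI vs reference.

    Ties resolve to the smallest resolution.  Returns the winning resolution,
    its ClusterResult, and the full (resolution, ari, n_clusters) table.  Only
    meaningful when trustworthy reference labels exist.
    """
    grid = list(grid)
    if not grid:
        raise ValueError("resolution grid is empty")
    reference_labels = np.asarray(reference_labels)
    graph = knn_graph(data, k=k, n_pcs=n_pcs)
    rows = []
    best = None
    for res in sorted(grid):
        result = louvain_cluster(graph, resolution=res, seed=seed)
        result.k_neighbors = k
        score = ari(result.labels, reference_labels)
        rows.append({"resolution": res, "ari": score, "n_clusters": result.labels.max() + 1})
        if best is None or score > best[1]:
            best = (res, score, result)
    table = pd.DataFrame(rows)
    return best[0], best[2], table


def umap_embed(data, seed: int = 0, n_neighbors: int = 15, min_dist: float = 0.5) -> np.ndarray:
    """2-D UMAP embedding (plumbing around umap-learn), seeded."""
    import umap  # deferred: numba compilation is slow at import time

    X = _data_values(data)
    n_neighbors = min(n_neighbors, X.shape[0] - 1)
    reducer = umap.UMAP(
        n_components=2,
        n_neighbors=max(n_neighbors, 2),
        min_dist=min_dist,
        random_state=seed,
        # spectral initialisation needs more points than components
        init="random" if X.shape[0] < 10 else "spectral",
    )
    return reducer.fit_transform(X)
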