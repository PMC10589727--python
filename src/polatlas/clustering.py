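"""Three-step hierarchical ordering and SNN-Leiden consensus clustering.

Ward hierarchical clustering does not scale to hundreds of thousands of
items and is restricted to Euclidean space, so heatmap ordering uses a
three-step scheme: (1) a 10-dimensional neighborhood-embedding (UMAP)
reduction under the requested metric, which moves any metric into Euclidean
space; (2) k-means compression to at most ``kmeans_cap`` centroids, applied
only above the cap; (3) Ward linkage on the centroids, with items ordered by
dendrogram leaf order and sorted within centroid groups.

Cluster discovery uses a shared-nearest-neighbor graph (edge weight = number
of shared k-nearest neighbors) partitioned with the Leiden algorithm, so the
number of clusters is data-driven.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import KMeans
from sklearn.neighbors import NearestNeighbors

_METRICS = {
    "yule": "yule",
    "sorensen-dice": "dice",
    "dice": "dice",
    "pearson-correlation": "correlation",
    "correlation": "correlation",
    "euclidean": "euclidean",
}

EXACT_KNN_MAX = 5000


def _resolve_metric(metric: str) -> str:
    try:
        return _METRICS[metric]
    except KeyError:
        raise ValueError(f"unknown metric {metric!r}; choose from "
                         f"{sorted(set(_METRICS))}") from None


def three_step_hc(data, metric: str = "euclidean", kmeans_cap: int = 50000,
                  n_embed: int = 10, seed: int = 0):
    """Order items for heatmap display; see module docstring.

    Returns ``(order, linkage, centroid_labels)`` where ``order`` indexes the
    rows of ``data``, ``linkage`` is the scipy linkage over centroids and
    ``centroid_labels`` assigns each item to a centroid (identity when the
    k-means step is skipped).
    """
    X = np.asarray(data, dtype=float)
    scipy_metric = _resolve_metric(metric)
    n = len(X)
    if n < 3:
        return np.arange(n), None, np.arange(n)

    import umap  # deferred: numba compilation is slow at import

    n_embed = min(n_embed, max(n - 2, 2))
    reducer = umap.UMAP(n_components=n_embed, metric=scipy_metric,
                        random_state=seed, n_neighbors=min(15, n - 1))
    emb = reducer.fit_transform(X)

    if n > kmeans_cap:
        km = KMeans(n_clusters=kmeans_cap, random_state=seed, n_init=3)
        centroid_labels = km.fit_predict(emb)
        centroids = km.cluster_centers_
    else:
        centroid_labels = np.arange(n)
        centroids = emb

    Z = hierarchy.ward(centroids)
    leaf_order = hierarchy.leaves_list(Z)
    rank = np.empty(len(centroids), dtype=int)
    rank[leaf_order] = np.arange(len(centroids))
    order = np.lexsort((np.arange(n), rank[centroid_labels]))
    return order, Z, centroid_labels


def linkage_to_newick(Z, labels=None) -> str:
    """Render a scipy linkage matrix as a Newick string (branch lengths =
    merge heights) for text inspection of dendrograms."""
    tree = hierarchy.to_tree(Z)
    labels = list(labels) if labels is not None else None

    def rec(node, parent_height):
        name = (labels[node.id] if labels and node.is_leaf() else
                (f"item{node.id}" if node.is_leaf() else ""))
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{name}:{length:.6g}"
        left = rec(node.left, node.dist)
        right = rec(node.right, node.dist)
        return f"({left},{right}){name}:{length:.6g}"

    return f"({rec(tree.left, tree.dist)},{rec(tree.right, tree.dist)});"


def _knn_indices(X: np.ndarray, metric: str, k: int, seed: int) -> np.ndarray:
    """k nearest neighbors (excluding self) — exact below EXACT_KNN_MAX,
    approximate (pynndescent) above when available."""
    n = len(X)
    if n > EXACT_KNN_MAX:
        try:
            from pynndescent import NNDescent
            index = NNDescent(X, metric=metric, n_neighbors=k + 1,
                              random_state=seed)
            idx, _ = index.neighbor_graph
            return idx[:, 1:k + 1]
        except ImportError:
            pass
    algo = "brute" if metric in ("yule", "dice", "correlation") else "auto"
    nn = NearestNeighbors(n_neighbors=k + 1, metric=metric, algorithm=algo)
    nn.fit(X)
    idx = nn.kneighbors(return_distance=False)
    return idx[:, :k]


def snn_leiden(data, metric: str = "euclidean", k_neighbors: int = 30,
               resolution: float = 1.0, seed: int = 0) -> np.ndarray:
    """SNN-graph Leiden clustering; returns labels 0..C-1.

    Edge weights are shared-neighbor counts between each item and its k
    nearest neighbors; zero-weight edges are dropped. Items disconnected
    from the graph become singleton clusters. The Leiden objective is
    modularity (RBConfiguration with the given resolution), seeded.
    """
    import igraph
    import leidenalg

    X = np.asarray(data, dtype=float)
    n = len(X)
    if n < k_neighbors + 1:
        raise ValueError("need at least k_neighbors + 1 items")
    scipy_metric = _resolve_metric(metric)
    knn = _knn_indices(X, scipy_metric, k_neighbors, seed)

    neighbor_sets = [set(int(j) for j in row) | {i} for i, row in enumerate(knn)]
    edge_weights: dict[tuple[int, int], int] = {}
    for i in range(n):
        for j in knn[i]:
            j = int(j)
            if j == i:
                continue
            key = (i, j) if i < j else (j, i)
            if key in edge_weights:
                continue
            shared = len(neighbor_sets[i] & neighbor_sets[j])
            if shared > 0:
                edge_weights[key] = shared
    edges = list(edge_weights)
    weights = [edge_weights[e] for e in edges]
    g = igraph.Graph(n=n, edges=edges)
    g.es["weight"] = weights
    part = leidenalg.find_partition(
        g, leidenalg.RBConfigurationVertexPartition,
        weights="weight", resolution_parameter=resolution, seed=seed)
    return np.asarray(part.membership)


class SNNLeiden(ClusterMixin, BaseEstimator):
    """sklearn-style wrapper for SNN-Leiden clustering (``fit_predict``)."""

    def __init__(self, metric="euclidean", k_neighbors=30, resolution=1.0,
                 random_state=0):
        self.metric = metric
        self.k_neighbors = k_neighbors
        self.resolution = resolution
        self.random_state = random_state

    def fit(self, X, y=None):
        self.labels_ = snn_leiden(X, metric=self.metric,
                                  k_neighbors=self.k_neighbors,
                                  resolution=self.resolution,
                                  seed=self.random_state)
        return self
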