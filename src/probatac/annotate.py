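"""Cell-type annotation: Louvain communities on a KNN graph of cell embeddings.

Cells are nodes; edges connect k-nearest neighbours under Euclidean
distance (directed KNN symmetrised by union, so every node keeps degree
>= k).  Louvain greedy modularity optimisation assigns a community to
every cell, and agreement with ground-truth labels is scored by ARI, AMI
and the v-score (harmonic mean of homogeneity and completeness).
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
from networkx.algorithms.community import louvain_communities, modularity
from sklearn.metrics import (adjusted_mutual_info_score, adjusted_rand_score,
                             v_measure_score)
from sklearn.neighbors import NearestNeighbors

from .model import CellEmbedding

__all__ = [
    "NeighborGraph",
    "ClusterAssignment",
    "ClusteringMetrics",
    "build_knn_graph",
    "louvain_cluster",
    "clustering_metrics",
    "umap_projection",
    "plot_embedding",
]


@dataclass
class NeighborGraph:
    graph: nx.Graph
    k: int

    @property
    def n_cells(self) -> int:
        return self.graph.number_of_nodes()


@dataclass
class ClusterAssignment:
    labels: np.ndarray           # per-cell community id, contiguous from 0
    modularity: float
    resolution: float
    seed: int

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max()) + 1 if self.labels.size else 0


@dataclass
class ClusteringMetrics:
    ari: float
    ami: float
    v_score: float


def build_knn_graph(embedding: CellEmbedding | np.ndarray, k: int = 15
                    ) -> NeighborGraph:
    """Union-symmetrised k-nearest-neighbour graph (Euclidean), no self-loops;
    edge attribute ``distance`` holds the Euclidean distance."""
    X = embedding.matrix if isinstance(embedding, CellEmbedding) else np.asarray(embedding)
    n = X.shape[0]
    if not np.all(np.isfinite(X)):
        raise ValueError("embedding contains non-finite coordinates")
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the number of cells {n}")
    nn = NearestNeighbors(n_neighbors=k + 1).fit(X)
    dist, idx = nn.kneighbors(X)
    g = nx.Graph()
    g.add_nodes_from(range(n))
    for i in range(n):
        for d, j in zip(dist[i, 1:], idx[i, 1:]):   # skip self
            g.add_edge(i, int(j), distance=float(d))
    return NeighborGraph(g, k)


def louvain_cluster(graph: NeighborGraph, resolution: float = 1.0,
                    seed: int = 0, weighted: bool = False) -> ClusterAssignment:
    """Louvain community detection; deterministic under a fixed seed.

    Edges are unweighted by default (``weighted=True`` uses 1/(1+distance)
    similarities).  Community ids are contiguous from 0, ordered by each
    community's smallest member index.
    """
    g = graph.graph
    if g.number_of_nodes() == 0:
        raise ValueError("empty graph")
    weight = None
    if weighted:
        for u, v, data in g.edges(data=True):
            data["similarity"] = 1.0 / (1.0 + data.get("distance", 0.0))
        weight = "similarity"
    comms = louvain_communities(g, weight=weight, resolution=resolution,
                                seed=int(seed))
    comms = sorted((sorted(c) for c in comms), key=lambda c: c[0])
    labels = np.empty(g.number_of_nodes(), dtype=int)
    for cid, members in enumerate(comms):
        labels[members] = cid
    mod = modularity(g, [set(c) for c in comms], weight=weight,
                     resolution=resolution)
    return ClusterAssignment(labels, float(mod), float(resolution), int(seed))


def umap_projection(embedding: CellEmbedding | np.ndarray, seed: int = 0
                    ) -> np.ndarray:
    """Optional 2-D UMAP projection of the cell embedding (visualisation
    only; not part of the annotation contract)."""
    import umap

    X = embedding.matrix if isinstance(embedding, CellEmbedding) else np.asarray(embedding)
    return umap.UMAP(n_components=2, random_state=seed).fit_transform(X)


def plot_embedding(embedding: CellEmbedding | np.ndarray, labels=None,
                   seed: int = 0, ax=None):
    """Scatter the UMAP projection, coloured by ``labels`` when given."""
    import matplotlib.pyplot as plt

    proj = umap_projection(embedding, seed=seed)
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    if labels is None:
        ax.scatter(proj[:, 0], proj[:, 1], s=6)
    else:
        labels = np.asarray(labels)
        for lab in np.unique(labels):
            sel = labels == lab
            ax.scatter(proj[sel, 0], proj[sel, 1], s=6, label=str(lab))
        ax.legend(markerscale=2, frameon=False)
    ax.set_xlabel("UMAP1")
    ax.set_ylabel("UMAP2")
    return ax


def clustering_metrics(pred: ClusterAssignment | np.ndarray,
                       truth: np.ndarray | list) -> ClusteringMetrics:
    """ARI (permutation-adjusted), AMI (expected-MI corrected) and v-score."""
    labels = pred.labels if isinstance(pred, ClusterAssignment) else np.asarray(pred)
    truth = np.asarray(truth)
    if labels.shape[0] != truth.shape[0]:
        raise ValueError("prediction / truth length mismatch")
    return ClusteringMetrics(
        ari=float(adjusted_rand_score(truth, labels)),
        ami=float(adjusted_mutual_info_score(truth, labels)),
        v_score=float(v_measure_score(truth, labels)),
    )
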