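"""Single-cell-style clustering of simulated transcriptomes.

Mirrors the standard scRNA-seq workflow at tiny gene counts: library-size
log-normalisation, per-gene scaling, PCA with one component fewer than the
number of genes, a shared-nearest-neighbour (SNN) graph with Jaccard edge
weights, and Louvain community detection at resolution 1. The resulting
cluster count is the model's lower-bound proxy for the number of cell types
in a simulated population (distinct-transcriptome diversity being the upper
bound).

With <= 10 genes, variable-feature selection is vacuous, so all genes are
used. Because simulated matrices contain massive numbers of exactly
duplicated cells, the pipeline finally reassigns every set of identical
input rows to its modal label, guaranteeing that the cluster count never
exceeds the number of distinct transcriptomes.
"""

from __future__ import annotations

import random
from dataclasses import dataclass

import igraph as ig
import numpy as np
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

__all__ = [
    "ClusterResult",
    "normalize_log",
    "reduce_pca",
    "cluster_snn_louvain",
    "cluster_pipeline",
]


@dataclass(frozen=True)
class ClusterResult:
    """Per-cell cluster labels plus the parameters that produced them."""

    labels: np.ndarray
    n_clusters: int
    n_pcs: int | None
    k_neighbors: int
    resolution: float
    seed: int

    def __post_init__(self) -> None:
        assert self.n_clusters == len(np.unique(self.labels))


def normalize_log(matrix: np.ndarray, scale_total: float = 1e4) -> np.ndarray:
    """Log-normalise counts and z-score genes.

    Per cell: counts are scaled to a common library size ``scale_total``
    then transformed with log(1 + x); all-zero cells pass through as zero
    rows. Per gene: centred and scaled to unit variance (constant genes
    become zero columns).
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2:
        raise ValueError("expected a cells x genes 2-D matrix")
    libsize = X.sum(axis=1, keepdims=True)
    safe = np.where(libsize > 0, libsize, 1.0)
    X = np.log1p(X / safe * scale_total)
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    return (X - mu) / sd


def reduce_pca(matrix: np.ndarray, n_components: int | None = None) -> np.ndarray:
    """PCA embedding with (by default) one component fewer than genes.

    Uses the deterministic full SVD solver; the default component count
    follows the convention of taking the maximum informative dimensionality,
    genes - 1, when gene counts are tiny.
    """
    X = np.asarray(matrix, dtype=float)
    n_cells, n_genes = X.shape
    if n_components is None:
        n_components = n_genes - 1
    if n_components >= n_genes:
        raise ValueError(
            f"n_components ({n_components}) must be < number of genes ({n_genes})"
        )
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    pca = PCA(n_components=min(n_components, n_cells), svd_solver="full")
    # fit then project: the projection is a row-wise map, so identical cells
    # land on bit-identical embedding coordinates (fit_transform's U*S does not
    # guarantee that)
    pca.fit(X)
    return pca.transform(X)


def _snn_graph(
    embedding: np.ndarray, k_neighbors: int, prune: float
) -> tuple[ig.Graph, np.ndarray]:
    n = embedding.shape[0]
    nn = NearestNeighbors(n_neighbors=k_neighbors).fit(embedding)
    knn = nn.kneighbors(embedding, return_distance=False)  # includes self
    neighbor_sets = [set(row.tolist()) for row in knn]
    edges: list[tuple[int, int]] = []
    weights: list[float] = []
    seen = set()
    for i in range(n):
        for j in knn[i]:
            j = int(j)
            if i == j:
                continue
            key = (i, j) if i < j else (j, i)
            if key in seen:
                continue
            seen.add(key)
            inter = len(neighbor_sets[i] & neighbor_sets[j])
            union = len(neighbor_sets[i] | neighbor_sets[j])
            w = inter / union
            if w >= prune:
                edges.append(key)
                weights.append(w)
    g = ig.Graph(n=n, edges=edges)
    return g, np.asarray(weights, dtype=float)


def cluster_snn_louvain(
    embedding: np.ndarray,
    k_neighbors: int = 20,
    resolution: float = 1.0,
    seed: int = 0,
    *,
    prune: float = 1 / 15,
    method: str = "louvain",
    consolidate_duplicates: bool = True,
) -> ClusterResult:
    """SNN-graph community detection on an embedding.

    Builds the k-nearest-neighbour graph (self included among neighbours),
    weights each kNN edge by the Jaccard overlap of the two endpoint
    neighbourhoods, prunes edges below ``prune``, and optimises modularity
    with Louvain (or Leiden with ``method="leiden"``) at the given
    resolution under a fixed seed. Identical embedding rows are finally
    assigned a common (modal) label. An embedding where all points coincide
    yields a single cluster.
    """
    embedding = np.asarray(embedding, dtype=float)
    n = embedding.shape[0]
    if n == 0:
        raise ValueError("empty embedding")
    k = min(k_neighbors, n)
    graph, weights = _snn_graph(embedding, k, prune)
    w = weights.tolist() if len(weights) else None

    if method == "louvain":
        ig.set_random_number_generator(random.Random(seed))
        membership = graph.community_multilevel(weights=w, resolution=resolution).membership
        ig.set_random_number_generator(random)
    elif method == "leiden":
        import leidenalg

        part = leidenalg.find_partition(
            graph,
            leidenalg.RBConfigurationVertexPartition,
            weights=w,
            resolution_parameter=resolution,
            seed=seed,
        )
        membership = part.membership
    else:
        raise ValueError(f"unknown method {method!r}")
    labels = np.asarray(membership, dtype=np.int64)

    if consolidate_duplicates:
        _, inverse = np.unique(embedding, axis=0, return_inverse=True)
        for u in np.unique(inverse):
            mask = inverse == u
            vals, cnts = np.unique(labels[mask], return_counts=True)
            labels[mask] = vals[np.argmax(cnts)]

    # relabel to 0..k-1 in order of first appearance (stable across runs)
    _, first = np.unique(labels, return_index=True)
    order = {labels[i]: rank for rank, i in enumerate(np.sort(first))}
    labels = np.array([order[v] for v in labels], dtype=np.int64)
    return ClusterResult(
        labels=labels,
        n_clusters=len(order),
        n_pcs=embedding.shape[1],
        k_neighbors=k,
        resolution=resolution,
        seed=seed,
    )


def cluster_pipeline(
    matrix: np.ndarray,
    *,
    scale_total: float = 1e4,
    n_components: int | None = None,
    k_neighbors: int = 20,
    resolution: float = 1.0,
    seed: int = 0,
    method: str = "louvain",
) -> ClusterResult:
    """Full pipeline: log-normalise, scale, PCA (genes - 1), SNN-Louvain."""
    X = normalize_log(matrix, scale_total=scale_total)
    emb = reduce_pca(X, n_components=n_components)
    return cluster_snn_louvain(
        emb, k_neighbors=k_neighbors, resolution=resolution, seed=seed, method=method
    )
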