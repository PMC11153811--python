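"""Consensus clustering with silhouette-based selection of the cluster
count, a graph-based cross-check, and agreement metrics.

The consensus ensemble follows the SC3-style recipe at desk scale: for
each candidate k, cells are embedded via the leading eigenvectors of three
cell-cell distance matrices (Euclidean, Pearson, Spearman) at several
spectral dimensions d in [ceil(0.04 n), ceil(0.07 n)], k-means is run on
each embedding, and the consensus matrix records how often each cell pair
is co-assigned.  Final labels cut an average-linkage tree of
(1 - consensus); the average silhouette width on the same distances guides
the choice of k (largest width wins; ties prefer smaller k).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import rankdata
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.manifold import TSNE
from sklearn.metrics import adjusted_rand_score, silhouette_score
from sklearn.neighbors import kneighbors_graph

__all__ = [
    "ConsensusMatrix",
    "ClusteringResult",
    "consensus_cluster",
    "select_k",
    "graph_cluster",
    "cluster_agreement",
    "pca_embed",
    "tsne_embed",
]


@dataclass
class ConsensusMatrix:
    matrix: np.ndarray  # cells x cells co-assignment frequency
    k: int

    def __post_init__(self) -> None:
        m = self.matrix
        if not np.allclose(m, m.T):
            raise ValueError("consensus matrix must be symmetric")
        if not np.allclose(np.diag(m), 1.0):
            raise ValueError("consensus diagonal must be 1")
        if m.min() < -1e-12 or m.max() > 1 + 1e-12:
            raise ValueError("consensus entries must lie in [0, 1]")


@dataclass
class ClusteringResult:
    labels: np.ndarray  # in 1..k_selected
    k_selected: int
    silhouette_by_k: dict[int, float]
    method: str
    consensus: dict[int, ConsensusMatrix] = field(default_factory=dict)
    labels_by_k: dict[int, np.ndarray] = field(default_factory=dict)


def _distance_matrices(x: np.ndarray) -> dict[str, np.ndarray]:
    """Euclidean, Pearson and Spearman cell-cell distances (cells x genes)."""
    from scipy.spatial.distance import pdist

    d_eucl = squareform(pdist(x, metric="euclidean"))
    c = np.corrcoef(x)
    d_pear = 1.0 - c
    ranks = rankdata(x, axis=1)
    d_spear = 1.0 - np.corrcoef(ranks)
    for d in (d_pear, d_spear):
        np.fill_diagonal(d, 0.0)
    return {"euclidean": d_eucl, "pearson": d_pear, "spearman": d_spear}


def _spectral_embeddings(dist: np.ndarray, dims: list[int]) -> dict[int, np.ndarray]:
    """Leading eigenvectors (by |eigenvalue|) of the distance matrix."""
    evals, evecs = np.linalg.eigh(dist)
    order = np.argsort(np.abs(evals))[::-1]
    evecs = evecs[:, order]
    return {d: evecs[:, :d] for d in dims}


def consensus_cluster(
    x: np.ndarray,
    k_range: range = range(2, 11),
    seed: int = 0,
    n_restarts: int = 10,
) -> ClusteringResult:
    """Ensemble consensus clustering over distances x spectral dimensions.

    ``x`` is cells x features (normalized log2 expression restricted to
    HVGs).  Returns the per-k consensus matrices, per-k labels, average
    silhouette widths on (1 - consensus) distances, and the selected k.
    """
    n = x.shape[0]
    k_range = [k for k in k_range]
    if any(k >= n for k in k_range):
        raise ValueError("k must be smaller than the number of cells")
    if n < max(k_range) + 2:
        raise ValueError("need at least k_max + 2 cells")

    d_lo, d_hi = int(np.ceil(0.04 * n)), int(np.ceil(0.07 * n))
    dims = list(range(max(d_lo, 2), max(d_hi, 2) + 1))
    dists = _distance_matrices(x)
    embeddings = [
        emb
        for dmat in dists.values()
        for emb in _spectral_embeddings(dmat, dims).values()
    ]

    consensus: dict[int, ConsensusMatrix] = {}
    labels_by_k: dict[int, np.ndarray] = {}
    sil_by_k: dict[int, float] = {}
    for k in k_range:
        co = np.zeros((n, n))
        for j, emb in enumerate(embeddings):
            km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed + 97 * j)
            lab = km.fit_predict(emb)
            co += (lab[:, None] == lab[None, :]).astype(float)
        co /= len(embeddings)
        np.fill_diagonal(co, 1.0)
        cons = ConsensusMatrix(matrix=co, k=k)
        dist = 1.0 - co
        np.fill_diagonal(dist, 0.0)
        z = linkage(squareform(dist, checks=False), method="average")
        lab = fcluster(z, t=k, criterion="maxclust")
        consensus[k] = cons
        labels_by_k[k] = lab
        if len(np.unique(lab)) > 1:
            sil_by_k[k] = float(silhouette_score(dist, lab, metric="precomputed"))
        else:
            sil_by_k[k] = float("nan")

    k_sel = select_k_from_table(sil_by_k)
    return ClusteringResult(
        labels=labels_by_k[k_sel],
        k_selected=k_sel,
        silhouette_by_k=sil_by_k,
        method="consensus",
        consensus=consensus,
        labels_by_k=labels_by_k,
    )


def select_k_from_table(silhouette_by_k: dict[int, float]) -> int:
    """argmax of average silhouette width; ties broken toward smaller k."""
    valid = {k: s for k, s in silhouette_by_k.items() if np.isfinite(s)}
    if not valid:
        raise ValueError("no defined silhouette widths")
    best = max(valid.values())
    return min(k for k, s in valid.items() if s == best)


def select_k(result: ClusteringResult) -> int:
    return select_k_from_table(result.silhouette_by_k)


def graph_cluster(
    x: np.ndarray,
    seed: int = 0,
    n_neighbors: int = 15,
    n_components: int = 10,
    resolution: float = 0.5,
) -> np.ndarray:
    """Leiden community detection on a kNN graph of top principal components.

    The cross-check method: PCA to ``n_components``, symmetrized
    ``n_neighbors``-NN graph, modularity (RB configuration) optimization.
    """
    import igraph
    import leidenalg

    n = x.shape[0]
    if n < 10:
        raise ValueError("graph clustering needs at least 10 cells")
    n_comp = min(n_components, n - 1, x.shape[1])
    scores = PCA(n_components=n_comp, random_state=seed).fit_transform(x)
    adj = kneighbors_graph(scores, n_neighbors=min(n_neighbors, n - 1), mode="connectivity")
    adj = adj.maximum(adj.T).tocoo()
    g = igraph.Graph(n=n, edges=list(zip(adj.row, adj.col)), directed=False)
    g.simplify()
    part = leidenalg.find_partition(
        g,
        leidenalg.RBConfigurationVertexPartition,
        resolution_parameter=resolution,
        seed=seed,
    )
    return np.asarray(part.membership) + 1


def cluster_agreement(
    labels_a: np.ndarray, labels_b: np.ndarray
) -> tuple[np.ndarray, float, dict]:
    """Contingency table, adjusted Rand index, and matched overlap counts.

    Overlaps pair clusters of the two labelings by maximum matching on the
    contingency table (Hungarian algorithm) and report the shared count per
    matched pair.
    """
    from scipy.optimize import linear_sum_assignment

    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape:
        raise ValueError("labelings must cover the same cells")
    ua, ub = np.unique(a), np.unique(b)
    table = np.zeros((ua.size, ub.size), dtype=int)
    for i, va in enumerate(ua):
        for j, vb in enumerate(ub):
            table[i, j] = int(np.sum((a == va) & (b == vb)))
    ari = float(adjusted_rand_score(a, b))
    ri, ci = linear_sum_assignment(-table)
    overlaps = {
        (ua[i], ub[j]): int(table[i, j]) for i, j in zip(ri, ci)
    }
    return table, ari, overlaps


def pca_embed(x: np.ndarray, n_components: int = 10, seed: int = 0):
    """Centered PCA; returns (scores, loadings, explained variance ratios)."""
    n_comp = min(n_components, *x.shape)
    pca = PCA(n_components=n_comp, random_state=seed)
    scores = pca.fit_transform(x)
    return scores, pca.components_, pca.explained_variance_ratio_


def tsne_embed(scores: np.ndarray, seed: int = 0, perplexity: float | None = None) -> np.ndarray:
    """Seeded 2-D t-SNE of PCA scores (visualization only)."""
    n = scores.shape[0]
    if n < 5:
        raise ValueError("t-SNE needs at least 5 cells")
    if perplexity is None:
        perplexity = min(30.0, max((n - 1) / 3.0, 2.0))
    ts = TSNE(n_components=2, random_state=seed, perplexity=perplexity, init="pca")
    return ts.fit_transform(scores)
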