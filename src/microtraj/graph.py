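"""Cell kNN graph construction, Louvain partitioning and cluster typing.

The graph is the substrate for both clustering and the Moran's I
autocorrelation screen: a union-symmetrized, binary-weighted k-nearest-
neighbor graph in PCA space.  Community detection is Louvain modularity
optimization with a resolution parameter gamma; the final modularity
Q = sum_c [e_c/m - gamma (d_c/2m)^2] is reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import sparse
from sklearn.neighbors import NearestNeighbors

from .containers import Embedding, ExpressionMatrix
from .preprocess import scale_center

__all__ = ["CellGraph", "Partition", "knn_graph", "louvain_partition",
           "modularity", "classify_clusters"]


@dataclass
class CellGraph:
    """Symmetric weighted adjacency over cells; w_ii = 0.

    ``W`` is the total weight sum_ij w_ij (both directions counted), the
    normalizer of Moran's I.
    """

    adjacency: sparse.csr_matrix
    cell_ids: list
    construction: dict = field(default_factory=dict)

    def __post_init__(self):
        a = sparse.csr_matrix(self.adjacency)
        if a.shape[0] != a.shape[1]:
            raise ValueError("adjacency must be square")
        if (abs(a - a.T)).sum() > 1e-9:
            raise ValueError("adjacency must be symmetric")
        if a.diagonal().sum() != 0:
            raise ValueError("self-loops are not allowed")
        if a.data.size and a.data.min() < 0:
            raise ValueError("edge weights must be nonnegative")
        self.adjacency = a
        self.cell_ids = list(map(str, self.cell_ids))
        if len(self.cell_ids) != a.shape[0]:
            raise ValueError("cell id count does not match adjacency size")

    @property
    def n(self) -> int:
        return self.adjacency.shape[0]

    @property
    def W(self) -> float:
        return float(self.adjacency.sum())

    def n_components(self) -> int:
        ncomp, _ = sparse.csgraph.connected_components(self.adjacency, directed=False)
        return int(ncomp)

    def to_networkx(self) -> nx.Graph:
        return nx.from_scipy_sparse_array(self.adjacency)

    def edge_list(self) -> np.ndarray:
        coo = sparse.triu(self.adjacency, k=1).tocoo()
        return np.stack([coo.row, coo.col, coo.data], axis=1)


@dataclass
class Partition:
    """Cell -> community labels from modularity optimization."""

    labels: np.ndarray
    resolution: float
    modularity: float
    seed: int
    modularity_trace: list = field(default_factory=list)

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=int)
        uniq = np.unique(self.labels)
        if not np.array_equal(uniq, np.arange(uniq.size)):
            raise ValueError("labels must be contiguous 0..C-1")

    @property
    def n_communities(self) -> int:
        return int(self.labels.max()) + 1


def knn_graph(emb: Embedding, k: int = 15) -> CellGraph:
    """Union-symmetrized k-nearest-neighbor graph with binary weights.

    Edge i-j exists iff j is among i's k Euclidean nearest neighbors or
    vice versa.  Ties in distance are broken by index (the stable order
    returned by the neighbor search).
    """
    n = emb.n_cells
    if not (0 < k < n):
        raise ValueError(f"k must satisfy 0 < k < n (got k={k}, n={n})")
    nn = NearestNeighbors(n_neighbors=k + 1, algorithm="auto")
    nn.fit(emb.coords)
    _, idx = nn.kneighbors(emb.coords)
    rows = np.repeat(np.arange(n), k)
    cols = idx[:, 1:].ravel()  # drop self (first neighbor)
    a = sparse.coo_matrix((np.ones(rows.size), (rows, cols)), shape=(n, n))
    a = a.maximum(a.T).tocsr()  # union symmetrization, binary weights
    a.setdiag(0)
    a.eliminate_zeros()
    return CellGraph(
        adjacency=a,
        cell_ids=emb.cell_ids,
        construction={"k": k, "metric": "euclidean", "space": "embedding"},
    )


def modularity(g: CellGraph, labels: np.ndarray, resolution: float = 1.0) -> float:
    """Q = sum_c [e_c / m - resolution * (d_c / 2m)^2].

    e_c is the weight of intra-community edges (each undirected edge once),
    d_c the total degree of the community, m the total edge weight.
    """
    a = g.adjacency
    two_m = a.sum()  # = 2m for a symmetric matrix
    if two_m == 0:
        raise ValueError("graph has no edges")
    labels = np.asarray(labels)
    deg = np.asarray(a.sum(axis=1)).ravel()
    q = 0.0
    for c in np.unique(labels):
        mask = labels == c
        e_c2 = a[mask][:, mask].sum()          # 2 * intra-community weight
        d_c = deg[mask].sum()
        q += e_c2 / two_m - resolution * (d_c / two_m) ** 2
    return float(q)


def louvain_partition(g: CellGraph, resolution: float = 1.0, seed: int = 0) -> Partition:
    """Louvain modularity optimization at resolution gamma.

    Deterministic given *seed* (which shuffles the node sweep order).  The
    per-level modularity trace is recorded; it is non-decreasing by
    construction of the algorithm.
    """
    if g.n == 0:
        raise ValueError("graph is empty")
    nxg = g.to_networkx()
    trace = []
    communities = None
    for level in nx.community.louvain_partitions(
        nxg, resolution=resolution, seed=seed
    ):
        communities = level
        labels = np.empty(g.n, dtype=int)
        for ci, nodes in enumerate(level):
            for node in nodes:
                labels[node] = ci
        trace.append(modularity(g, labels, resolution))
    if communities is None:  # graph with no edges: every node its own community
        labels = np.arange(g.n)
        return Partition(labels=labels, resolution=resolution,
                         modularity=0.0, seed=seed, modularity_trace=[0.0])
    labels = np.empty(g.n, dtype=int)
    for ci, nodes in enumerate(communities):
        for node in nodes:
            labels[node] = ci
    # relabel contiguous by first occurrence for determinism
    _, labels = np.unique(labels, return_inverse=True)
    return Partition(
        labels=labels,
        resolution=resolution,
        modularity=modularity(g, labels, resolution),
        seed=seed,
        modularity_trace=trace,
    )


def classify_clusters(
    em: ExpressionMatrix,
    part: Partition,
    marker_sets: dict[str, list[str]],
) -> tuple[dict[int, str], dict]:
    """Label each cluster by the marker set with highest mean scaled
    expression; ties broken alphabetically by label.

    Markers absent from the matrix are dropped with a warning; a marker
    set losing all its genes scores -inf.  Returns (cluster -> label,
    per-cluster score table).
    """
    import logging
    log = logging.getLogger(__name__)
    if not any(marker_sets.values()):
        raise ValueError("all marker sets are empty")
    present_sets = {}
    for label, genes in marker_sets.items():
        present = [gx for gx in genes if gx in em.gene_ids]
        missing = sorted(set(genes) - set(present))
        if missing:
            log.warning("markers missing for %s: %s", label, missing)
        present_sets[label] = present
    all_genes = sorted({gx for genes in present_sets.values() for gx in genes})
    if not all_genes:
        raise ValueError("no marker genes present in the matrix")
    scaled, order = scale_center(em, all_genes)
    col = {gx: j for j, gx in enumerate(order)}
    scores: dict = {}
    assignment: dict[int, str] = {}
    for c in range(part.n_communities):
        mask = part.labels == c
        scores[c] = {}
        for label in sorted(present_sets):
            genes = present_sets[label]
            if not genes:
                scores[c][label] = float("-inf")
                continue
            scores[c][label] = float(
                scaled[np.ix_(mask, [col[gx] for gx in genes])].mean()
            )
        assignment[c] = max(sorted(scores[c]), key=lambda lb: scores[c][lb])
    return assignment, scores
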