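"""Cell clustering on the final transformer cell embeddings.

A shared-nearest-neighbor (SNN) graph is built from Euclidean k-nearest
neighbors in embedding space (Jaccard edge weights), then partitioned by
modularity optimization (Louvain by default, Leiden behind a flag) at a
configurable resolution (default 0.4).
"""

from __future__ import annotations

import random
from dataclasses import dataclass

import igraph as ig
import numpy as np
from sklearn.neighbors import NearestNeighbors

from .preprocess import NamedMatrix


@dataclass
class ClusterLabeling:
    assignment: dict[str, int]  # cell -> cluster id in {1..Z}
    Z: int
    resolution: float

    def __post_init__(self) -> None:
        labels = set(self.assignment.values())
        if labels != set(range(1, self.Z + 1)):
            raise ValueError("cluster ids must be contiguous 1..Z and non-empty")

    def cells_of(self, z: int) -> list[str]:
        return [c for c, lab in self.assignment.items() if lab == z]

    def labels_for(self, cells: list[str]) -> np.ndarray:
        return np.array([self.assignment[c] for c in cells])


def knn_graph(cell_emb: np.ndarray, k: int = 20) -> ig.Graph:
    """Symmetric SNN graph: kNN by Euclidean distance, edges weighted by the
    Jaccard overlap of the two cells' neighbor sets (self included)."""
    n = cell_emb.shape[0]
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the number of cells {n}")
    nn = NearestNeighbors(n_neighbors=k + 1).fit(cell_emb)
    _, idx = nn.kneighbors(cell_emb)
    neigh = [set(row) | {i} for i, row in enumerate(idx)]
    edges, weights = [], []
    for i in range(n):
        for j in idx[i]:
            j = int(j)
            if j == i:
                continue
            a, b = (i, j) if i < j else (j, i)
            inter = len(neigh[a] & neigh[b])
            union = len(neigh[a] | neigh[b])
            w = inter / union
            if w > 0:
                edges.append((a, b))
                weights.append(w)
    g = ig.Graph(n=n, edges=edges)
    g.es["weight"] = weights
    g.simplify(combine_edges="max")
    return g


def louvain_cluster(graph: ig.Graph, resolution: float = 0.4,
                    seed: int = 0, method: str = "louvain") -> ClusterLabeling:
    """Modularity-optimizing partition; cluster ids sorted by descending
    size so numbering is reproducible."""
    if method == "louvain":
        random.seed(seed)
        ig.set_random_number_generator(random)
        part = graph.community_multilevel(weights="weight",
                                          resolution=resolution)
        membership = np.array(part.membership)
    elif method == "leiden":
        import leidenalg
        part = leidenalg.find_partition(
            graph, leidenalg.RBConfigurationVertexPartition,
            weights="weight", resolution_parameter=resolution, seed=seed)
        membership = np.array(part.membership)
    else:
        raise ValueError(f"unknown clustering method {method!r}")
    # renumber by descending size (ties by smallest member index)
    ids, counts = np.unique(membership, return_counts=True)
    first = [int(np.argmax(membership == i)) for i in ids]
    order = sorted(range(len(ids)), key=lambda t: (-counts[t], first[t]))
    remap = {ids[t]: rank + 1 for rank, t in enumerate(order)}
    names = graph.vs["name"] if "name" in graph.vs.attributes() else \
        [str(i) for i in range(graph.vcount())]
    assignment = {names[i]: remap[m] for i, m in enumerate(membership)}
    return ClusterLabeling(assignment, len(ids), resolution)


def pca_reduce(cell_emb: np.ndarray, n_pcs: int = 10) -> np.ndarray:
    """Top principal components of the embedding (deterministic SVD)."""
    x = cell_emb - cell_emb.mean(axis=0)
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    n = min(n_pcs, s.size)
    return u[:, :n] * s[:n]


def cluster_cells(cell_emb: np.ndarray, cell_names: list[str], k: int = 20,
                  resolution: float = 0.4, seed: int = 0,
                  method: str = "louvain", n_pcs: int | None = 10) -> ClusterLabeling:
    """SNN + Louvain on the embedding, mirroring the Seurat v3 defaults the
    reference clustering protocol names: neighbors are found in a
    PCA-reduced space (10 components by default; ``n_pcs=None`` uses the
    raw embedding)."""
    emb = cell_emb if n_pcs is None else pca_reduce(cell_emb, n_pcs)
    g = knn_graph(emb, k=k)
    g.vs["name"] = cell_names
    return louvain_cluster(g, resolution=resolution, seed=seed, method=method)


def leave_out_cluster(matrices: list[NamedMatrix], labels: ClusterLabeling,
                      z: int) -> tuple[list[NamedMatrix], ClusterLabeling]:
    """Remove every cell of cluster z from all aligned matrices and re-index
    the remaining cluster labels contiguously."""
    if z not in set(labels.assignment.values()):
        raise ValueError(f"cluster {z} does not exist")
    removed = set(labels.cells_of(z))
    if all(len(set(m.col_names) - removed) == 0 for m in matrices):
        raise ValueError("removing cluster would empty the data")
    out = []
    for m in matrices:
        keep = [j for j, c in enumerate(m.col_names) if c not in removed]
        out.append(m.subset(cols=keep))
    kept = {c: lab for c, lab in labels.assignment.items() if c not in removed}
    old_ids = sorted(set(kept.values()))
    remap = {o: i + 1 for i, o in enumerate(old_ids)}
    new_labels = ClusterLabeling({c: remap[v] for c, v in kept.items()},
                                 len(old_ids), labels.resolution)
    return out, new_labels


def iterate_leave_outs(matrices: list[NamedMatrix], labels: ClusterLabeling):
    """Yield (z, reduced matrices, reduced labels) for every cluster."""
    for z in range(1, labels.Z + 1):
        yield z, *leave_out_cluster(matrices, labels, z)
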