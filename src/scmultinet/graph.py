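"""Bipartite cell-gene heterogeneous graph and initial node embeddings.

The graph has two node types (gene, cell), one edge type, and therefore two
directed meta-relations (gene->cell, cell->gene).  An unweighted edge exists
exactly where the integrated matrix is positive.  Initial 256-dimensional
embeddings come from two dense autoencoders (input -> 512 -> 256 -> 512 ->
input, ReLU hidden, linear output, MSE loss, Adam), one over cell columns of
X and one over gene columns of X^T; the bottleneck activation is the layer-0
embedding.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Adam, Tensor
from .preprocess import IntegratedMatrix

GENE, CELL = "gene", "cell"
META_RELATIONS = ((GENE, "gene-cell", CELL), (CELL, "gene-cell", GENE))


@dataclass
class HeteroGraph:
    gene_nodes: list[str]
    cell_nodes: list[str]
    edges: np.ndarray  # (n_edges, 2) int array of (gene_idx, cell_idx)
    x: np.ndarray      # integrated matrix values, genes x cells
    meta_relations: tuple = META_RELATIONS

    def __post_init__(self) -> None:
        self.edges = np.asarray(self.edges, dtype=int)
        if self.edges.size and (self.edges[:, 0].max() >= len(self.gene_nodes)
                                or self.edges[:, 1].max() >= len(self.cell_nodes)):
            raise ValueError("edge index out of range")

    @property
    def n_genes(self) -> int:
        return len(self.gene_nodes)

    @property
    def n_cells(self) -> int:
        return len(self.cell_nodes)

    @property
    def n_edges(self) -> int:
        return self.edges.shape[0]

    def adjacency_mask(self) -> np.ndarray:
        """Boolean genes x cells mask of edges."""
        mask = np.zeros((self.n_genes, self.n_cells), dtype=bool)
        mask[self.edges[:, 0], self.edges[:, 1]] = True
        return mask

    def node_type(self, idx: int) -> str:
        return GENE if idx < self.n_genes else CELL


@dataclass
class EmbeddingTable:
    """Stacked (genes+cells) x d embeddings for one layer."""

    embedding: np.ndarray
    n_genes: int
    layer_tag: int = 0

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.embedding)):
            raise ValueError("non-finite embedding entries")

    @property
    def genes(self) -> np.ndarray:
        return self.embedding[: self.n_genes]

    @property
    def cells(self) -> np.ndarray:
        return self.embedding[self.n_genes:]


def build_graph(X: IntegratedMatrix) -> HeteroGraph:
    """One edge per strictly positive entry of the integrated matrix."""
    if X.values.size == 0:
        raise ValueError("empty integrated matrix")
    gi, cj = np.nonzero(X.values > 0)
    return HeteroGraph(list(X.row_names), list(X.col_names),
                       np.column_stack([gi, cj]), X.values)


# ---------------------------------------------------------------------------
# autoencoder initial embeddings


def _init_weight(rng: np.random.Generator, n_in: int, n_out: int) -> Tensor:
    scale = np.sqrt(2.0 / n_in)
    return Tensor(rng.normal(0.0, scale, size=(n_in, n_out)), requires_grad=True)


@dataclass
class _AE:
    weights: list[Tensor]
    biases: list[Tensor]

    def params(self) -> list[Tensor]:
        return self.weights + self.biases

    def encode(self, x: Tensor) -> Tensor:
        h = (x @ self.weights[0] + self.biases[0]).relu()
        return h @ self.weights[1] + self.biases[1]

    def forward(self, x: Tensor) -> tuple[Tensor, Tensor]:
        z = self.encode(x)
        h = (z @ self.weights[2] + self.biases[2]).relu()
        out = h @ self.weights[3] + self.biases[3]
        return z, out


def _make_ae(rng, n_in: int, d_hidden: int, d_out: int) -> _AE:
    dims = [n_in, d_hidden, d_out, d_hidden, n_in]
    ws = [_init_weight(rng, dims[i], dims[i + 1]) for i in range(4)]
    bs = [Tensor(np.zeros(dims[i + 1]), requires_grad=True) for i in range(4)]
    return _AE(ws, bs)


def _train_ae(mat: np.ndarray, d_hidden: int, d_out: int, epochs: int,
              lr: float, rng) -> tuple[np.ndarray, list[float]]:
    """Full-batch MSE training; rows of `mat` are samples.

    Features are centered before training (a numerical choice that speeds
    Adam convergence markedly); the bottleneck therefore embeds the
    centered profiles.
    """
    mat = mat - mat.mean(axis=0, keepdims=True)
    ae = _make_ae(rng, mat.shape[1], d_hidden, d_out)
    opt = Adam(ae.params(), lr=lr)
    x = Tensor(mat)
    trace: list[float] = []
    for _ in range(epochs):
        opt.zero_grad()
        _, recon = ae.forward(x)
        loss = ((recon - x) ** 2).mean()
        loss.backward()
        opt.step()
        trace.append(float(loss.data))
    z, _ = ae.forward(x)
    return z.data, trace


def _rescale(e: np.ndarray) -> np.ndarray:
    # center and divide by the global coordinate scale: keeps attention
    # logits and inner products numerically benign while preserving the
    # relative variance structure of the bottleneck
    e = e - e.mean(axis=0)
    sd = e.std()
    return e / sd if sd > 0 else e


def init_embeddings(X: IntegratedMatrix, d_hidden: int = 512, d_out: int = 256,
                    epochs: int = 100, lr: float = 1e-3,
                    seed: int = 0, n_restarts: int = 3) -> EmbeddingTable:
    """Layer-0 embeddings from two seeded dense autoencoders.

    The cell autoencoder reconstructs the columns of X (each cell's gene
    profile); the gene autoencoder reconstructs the columns of X^T.
    Training is full-batch and deterministic for a given seed.

    A single random restart leaves noticeable init-dependent noise in the
    bottleneck's local neighborhoods, so `n_restarts` independently seeded
    autoencoders are trained per node set and their rescaled bottlenecks
    concatenated, then reduced back to d_out by SVD.  With ``n_restarts=1``
    the raw bottleneck is returned.
    """
    vals = X.values
    I, J = vals.shape
    if d_out >= min(I, J):
        import warnings
        warnings.warn(f"d_out={d_out} >= min(I={I}, J={J}); embeddings will "
                      "be over-complete")

    def ensemble(mat):
        zs, traces = [], []
        for r in range(n_restarts):
            rng = np.random.default_rng(np.random.SeedSequence([seed, r]))
            z, trace = _train_ae(mat, d_hidden, d_out, epochs, lr, rng)
            zs.append(_rescale(z))
            traces.append(trace)
        if n_restarts == 1:
            return zs[0], traces
        cat = np.hstack(zs)
        u, s, _ = np.linalg.svd(cat - cat.mean(axis=0), full_matrices=False)
        k = min(d_out, s.size)
        red = u[:, :k] * s[:k]
        if k < d_out:  # rank-limited small inputs: pad to the declared width
            red = np.hstack([red, np.zeros((red.shape[0], d_out - k))])
        return _rescale(red), traces

    gene_emb, gene_traces = ensemble(vals)
    cell_emb, cell_traces = ensemble(vals.T)
    table = EmbeddingTable(np.vstack([gene_emb, cell_emb]), I, layer_tag=0)
    table.gene_loss_trace = gene_traces[0]  # type: ignore[attr-defined]
    table.cell_loss_trace = cell_traces[0]  # type: ignore[attr-defined]
    return table
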