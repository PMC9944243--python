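"""Heterogeneous graph transformer (HGT) trained as a graph autoencoder.

Per node type (gene, cell) there are Q/K/V linear projections split into H
heads; per meta-relation (gene->cell, cell->gene) there are an attention
transform W_att, a message transform W_msg and a trainable prior scalar mu.
Attention between a target and its neighborhood is a per-head softmax of
scaled key-query bilinear scores; messages are value vectors transformed by
W_msg; aggregation is attention-weighted message summation followed by a
gated residual update H^l = theta*ReLU(H~) + (1-theta)*H^(l-1) (the
`standard` convention; the `paper` convention uses (theta-1) on the
residual).

Training: subgraphs are sampled to cover a fraction of nodes, the HGT is the
encoder of a graph autoencoder whose decoder is the embedding inner product,
and the loss is the KL divergence between column-softmaxed reconstruction
and input.  Parameters and optimizer state are inherited sequentially across
subgraphs; the trained model is finally applied to the whole graph.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .autodiff import Adam, Tensor, concat, masked_log_softmax, softmax_np
from .graph import CELL, GENE, EmbeddingTable, HeteroGraph

REL_G2C = (GENE, "gene-cell", CELL)
REL_C2G = (CELL, "gene-cell", GENE)


class ConfigError(ValueError):
    pass


@dataclass
class HGTConfig:
    n_layers: int = 2
    n_heads: int = 16
    d: int = 112
    learning_rate: float = 1e-4
    epochs_per_subgraph: int = 100
    n_subgraphs: int = 50
    coverage_fraction: float = 0.30
    seed: int = 0
    residual_convention: str = "standard"  # or "paper"
    tol: float = 1e-4
    patience: int = 5

    def __post_init__(self) -> None:
        if self.d % self.n_heads != 0:
            raise ConfigError(f"d={self.d} not divisible by n_heads={self.n_heads}")
        if self.n_layers < 1:
            raise ConfigError("n_layers must be >= 1")
        if self.residual_convention not in ("standard", "paper"):
            raise ConfigError("residual_convention must be standard|paper")

    @property
    def d_head(self) -> int:
        return self.d // self.n_heads


@dataclass
class HGTParameters:
    """Trainable parameter tensors keyed by node type / meta-relation."""

    wq: dict
    wk: dict
    wv: dict
    w_att: dict
    w_msg: dict
    mu: dict
    theta: Tensor
    w_in: dict  # optional input projections (d_in != d)
    cfg: HGTConfig

    def all_params(self) -> list[Tensor]:
        out = []
        for d in (self.wq, self.wk, self.wv, self.w_att, self.w_msg, self.mu,
                  self.w_in):
            out.extend(d.values())
        out.append(self.theta)
        return out

    def state_dict(self) -> dict:
        def pack(d):
            return {str(k): v.data.copy() for k, v in d.items()}
        return {"wq": pack(self.wq), "wk": pack(self.wk), "wv": pack(self.wv),
                "w_att": pack(self.w_att), "w_msg": pack(self.w_msg),
                "mu": pack(self.mu), "w_in": pack(self.w_in),
                "theta": self.theta.data.copy()}


def init_parameters(cfg: HGTConfig, d_in: int | None = None,
                    seed: int | None = None) -> HGTParameters:
    """Seeded initialization: Q/K/V He-scaled, W_att/W_msg identity plus
    small Gaussian noise (sigma=0.01), mu=1, theta=0.5."""
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    d, dh = cfg.d, cfg.d_head

    def proj():
        return Tensor(rng.normal(0, np.sqrt(1.0 / d), (d, d)), requires_grad=True)

    def rel():
        return Tensor(np.eye(dh) + rng.normal(0, 0.01, (dh, dh)),
                      requires_grad=True)

    wq = {t: proj() for t in (GENE, CELL)}
    wk = {t: proj() for t in (GENE, CELL)}
    wv = {t: proj() for t in (GENE, CELL)}
    w_att = {r: rel() for r in (REL_G2C, REL_C2G)}
    w_msg = {r: rel() for r in (REL_G2C, REL_C2G)}
    mu = {r: Tensor(np.array(1.0), requires_grad=True) for r in (REL_G2C, REL_C2G)}
    theta = Tensor(np.array(0.5), requires_grad=True)
    w_in = {}
    if d_in is not None and d_in != d:
        for t in (GENE, CELL):
            w_in[t] = Tensor(rng.normal(0, np.sqrt(1.0 / d_in), (d_in, d)),
                             requires_grad=True)
    return HGTParameters(wq, wk, wv, w_att, w_msg, mu, theta, w_in, cfg)


# ---------------------------------------------------------------------------
# single-node operations (numpy; the batched forward reproduces these)


def project_qkv(emb: np.ndarray, params: HGTParameters, node_type: str,
                role: str) -> np.ndarray:
    """Split a node embedding into H per-head Q (target) or K/V (source)
    vectors of dimension d/H via the node-type-specific projection."""
    cfg = params.cfg
    if role == "target":
        w = params.wq[node_type].data
    elif role in ("source_k",):
        w = params.wk[node_type].data
    elif role in ("source_v",):
        w = params.wv[node_type].data
    else:
        raise ValueError(f"unknown role {role!r}")
    return (emb @ w).reshape(cfg.n_heads, cfg.d_head)


def attention_logits(q_heads: np.ndarray, k_heads: np.ndarray,
                     params: HGTParameters, rel: tuple) -> np.ndarray:
    """Per-head bilinear attention score K W_att Q^T * mu / sqrt(d)."""
    cfg = params.cfg
    w = params.w_att[rel].data
    mu = float(params.mu[rel].data)
    return np.array([k_heads[h] @ w @ q_heads[h] for h in range(cfg.n_heads)]
                    ) * mu / math.sqrt(cfg.d)


def mutual_attention(target_emb: np.ndarray, source_embs: np.ndarray,
                     params: HGTParameters, rel: tuple) -> np.ndarray:
    """Softmax attention of each source to the target, per head.

    Returns an (n_sources, H) array whose columns each sum to 1.  With no
    sources the result is empty.
    """
    n_src = source_embs.shape[0]
    cfg = params.cfg
    if n_src == 0:
        return np.zeros((0, cfg.n_heads))
    src_type, _, tgt_type = rel
    q = project_qkv(target_emb, params, tgt_type, "target")
    logits = np.zeros((n_src, cfg.n_heads))
    for s in range(n_src):
        k = project_qkv(source_embs[s], params, src_type, "source_k")
        logits[s] = attention_logits(q, k, params, rel)
    return softmax_np(logits, axis=0)


def message_passing(source_embs: np.ndarray, params: HGTParameters,
                    rel: tuple) -> np.ndarray:
    """Per-source, per-head message vectors V(v_s) W_msg, shape (n, H, d/H)."""
    cfg = params.cfg
    src_type = rel[0]
    out = np.zeros((source_embs.shape[0], cfg.n_heads, cfg.d_head))
    for s in range(source_embs.shape[0]):
        v = project_qkv(source_embs[s], params, src_type, "source_v")
        for h in range(cfg.n_heads):
            out[s, h] = v[h] @ params.w_msg[rel].data
    return out


def aggregate(attention: np.ndarray, messages: np.ndarray,
              prev_emb: np.ndarray, theta: float,
              convention: str = "standard") -> np.ndarray:
    """Gated residual update of one target embedding."""
    if attention.shape[0] == 0:
        agg = np.zeros_like(prev_emb)
    else:
        h_parts = [(attention[:, h][:, None] * messages[:, h]).sum(axis=0)
                   for h in range(attention.shape[1])]
        agg = np.concatenate(h_parts)
    act = np.maximum(agg, 0.0)
    if convention == "standard":
        return theta * act + (1.0 - theta) * prev_emb
    return theta * act + (theta - 1.0) * prev_emb


# ---------------------------------------------------------------------------
# batched dense forward (autodiff)


def _heads(t: Tensor, cfg: HGTConfig) -> list[Tensor]:
    return [t[:, h * cfg.d_head:(h + 1) * cfg.d_head]
            for h in range(cfg.n_heads)]


def _layer(hg: Tensor, hc: Tensor, mask: np.ndarray, params: HGTParameters
           ) -> tuple[Tensor, Tensor, np.ndarray]:
    """One HGT layer over the dense edge mask (genes x cells).

    Returns updated gene and cell embeddings plus the per-head gene->cell
    attention array (H, I, J) for attention extraction.
    """
    cfg = params.cfg
    scale = 1.0 / math.sqrt(cfg.d)
    maskT = mask.T

    def attend(src_h, tgt_h, rel, m):
        """Per-head attention of sources (rows of m) to targets (cols)."""
        atts, logs = [], []
        for h in range(cfg.n_heads):
            logit = (src_h[h] @ params.w_att[rel]) @ tgt_h[h].T
            logit = logit * (params.mu[rel] * scale)
            att = masked_log_softmax(logit, m, axis=0).exp() * Tensor(m.astype(float))
            atts.append(att)
        return atts

    kg = _heads(hg @ params.wk[GENE], cfg)
    vg = _heads(hg @ params.wv[GENE], cfg)
    qc = _heads(hc @ params.wq[CELL], cfg)
    kc = _heads(hc @ params.wk[CELL], cfg)
    vc = _heads(hc @ params.wv[CELL], cfg)
    qg = _heads(hg @ params.wq[GENE], cfg)

    # cells as targets, genes as sources
    att_g2c = attend(kg, qc, REL_G2C, mask)
    msg_g = [vg[h] @ params.w_msg[REL_G2C] for h in range(cfg.n_heads)]
    agg_c = concat([att_g2c[h].T @ msg_g[h] for h in range(cfg.n_heads)], axis=1)

    # genes as targets, cells as sources
    att_c2g = attend(kc, qg, REL_C2G, maskT)
    msg_c = [vc[h] @ params.w_msg[REL_C2G] for h in range(cfg.n_heads)]
    agg_g = concat([att_c2g[h].T @ msg_c[h] for h in range(cfg.n_heads)], axis=1)

    theta = params.theta
    if cfg.residual_convention == "standard":
        res = (1.0 - theta)
    else:
        res = (theta - 1.0)
    hg_new = agg_g.relu() * theta + hg * res
    hc_new = agg_c.relu() * theta + hc * res
    att_stack = np.stack([a.data for a in att_g2c])
    return hg_new, hc_new, att_stack


def hgt_forward(graph_or_mask, emb0: EmbeddingTable, params: HGTParameters,
                return_tensors: bool = False):
    """Apply L HGT layers to every node; deterministic given parameters.

    Accepts a HeteroGraph or a boolean genes x cells mask.  Returns
    (EmbeddingTable at layer L, per-head gene->cell attention of the last
    layer with shape (H, I, J)); with ``return_tensors`` the raw autodiff
    tensors are returned instead of the table (used during training).
    """
    cfg = params.cfg
    mask = (graph_or_mask.adjacency_mask()
            if isinstance(graph_or_mask, HeteroGraph) else graph_or_mask)
    n_genes = mask.shape[0]
    hg = Tensor(emb0.genes)
    hc = Tensor(emb0.cells)
    if params.w_in:
        hg = hg @ params.w_in[GENE]
        hc = hc @ params.w_in[CELL]
    att_last = None
    for _ in range(cfg.n_layers):
        hg, hc, att_last = _layer(hg, hc, mask, params)
    if return_tensors:
        return hg, hc, att_last
    table = EmbeddingTable(np.vstack([hg.data, hc.data]), n_genes,
                           layer_tag=cfg.n_layers)
    return table, att_last


@dataclass
class AttentionMatrix:
    """Final gene-to-cell importance a_ij, defined on graph edges only."""

    scores: np.ndarray  # genes x cells, 0 off-edges
    support: np.ndarray  # boolean mask of edges

    def __post_init__(self) -> None:
        if np.any(self.scores < 0):
            raise ValueError("attention scores must be non-negative")
        if np.any(self.scores[~self.support] != 0):
            raise ValueError("scores outside edge support")


def final_attention(per_head_att: np.ndarray, mask: np.ndarray) -> AttentionMatrix:
    """a_ij = sqrt(sum_h att_h(i,j)^2), the per-head L2 norm on each edge."""
    scores = np.sqrt((per_head_att ** 2).sum(axis=0))
    scores = np.where(mask, scores, 0.0)
    return AttentionMatrix(scores, mask)


# ---------------------------------------------------------------------------
# subgraph sampling


def neighbor_probabilities(graph: HeteroGraph, cell_idx: int) -> tuple[np.ndarray, np.ndarray]:
    """Genes adjacent to a cell and their sampling probabilities
    x(v_s, v_t) / sum over neighbors."""
    col = graph.x[:, cell_idx]
    nbr = np.where(col > 0)[0]
    w = col[nbr]
    return nbr, w / w.sum()


def schedule_length(cfg: HGTConfig) -> int:
    """Total training iterations of the subgraph scheduler."""
    return cfg.n_subgraphs * cfg.epochs_per_subgraph


def sample_subgraphs(graph: HeteroGraph, cfg: HGTConfig,
                     seed: int | None = None,
                     max_attempts: int = 10) -> list[tuple[np.ndarray, np.ndarray]]:
    """Sample n_subgraphs (gene_idx, cell_idx) pairs.

    Each subgraph holds ceil(a*I/n) genes and ceil(a*J/n) cells; cells are
    taken from a cycling random permutation (guaranteeing cell coverage) and
    each target cell draws neighbor genes without replacement with
    probability proportional to x_ij.  Sampling is repeated (up to
    `max_attempts`) until the union covers the requested fraction of both
    node sets.
    """
    I, J = graph.n_genes, graph.n_cells
    a, n = cfg.coverage_fraction, cfg.n_subgraphs
    if a * I / n < 1 or a * J / n < 1:
        raise ValueError(
            f"coverage_fraction*(I or J)/n_subgraphs < 1; use n_subgraphs <= "
            f"{max(1, int(a * min(I, J)))}")
    n_g = math.ceil(a * I / n)
    n_c = math.ceil(a * J / n)
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    need_g, need_c = math.ceil(a * I), math.ceil(a * J)
    best = None
    for _ in range(max_attempts):
        perm = rng.permutation(J)
        pos = 0
        subs = []
        seen_genes: set[int] = set()
        for _s in range(n):
            cells = []
            while len(cells) < n_c:
                if pos >= J:
                    perm = rng.permutation(J)
                    pos = 0
                cells.append(perm[pos])
                pos += 1
            cells = np.array(sorted(set(cells)))
            genes: set[int] = set()
            per_cell = max(1, math.ceil(n_g / len(cells)))
            for c in cells:
                nbr, p = neighbor_probabilities(graph, int(c))
                k = min(per_cell, len(nbr))
                if k:
                    genes.update(rng.choice(nbr, size=k, replace=False, p=p))
            # top up from pooled neighbors if short, preferring genes the
            # subgraph union has not covered yet
            cand = np.unique(graph.edges[np.isin(graph.edges[:, 1], cells), 0])
            extra = [int(g) for g in cand if g not in genes]
            rng.shuffle(extra)
            extra.sort(key=lambda g: g in seen_genes)  # stable: unseen first
            for g in extra:
                if len(genes) >= n_g:
                    break
                genes.add(g)
            seen_genes |= genes
            subs.append((np.array(sorted(genes)), cells))
        cov_g = len(set().union(*(set(s[0]) for s in subs)))
        cov_c = len(set().union(*(set(s[1]) for s in subs)))
        if cov_g >= need_g and cov_c >= need_c:
            return subs
        if best is None or cov_g + cov_c > best[0]:
            best = (cov_g + cov_c, subs)
    warnings.warn("subgraph sampling did not reach requested coverage "
                  f"after {max_attempts} attempts")
    return best[1]


# ---------------------------------------------------------------------------
# graph autoencoder training


def kl_reconstruction_loss(hg: Tensor, hc: Tensor, x: np.ndarray) -> Tensor:
    """KL divergence between the reconstruction and the input, softmaxed
    per cell column; X_hat is the inner-product decoding of gene and cell
    embeddings.

    The divergence is taken with the data as the reference distribution,
    KL(softmax(X) || softmax(X_hat)) — the cross-entropy-style direction
    every deep-learning KL-divergence loss computes, which forces the
    reconstruction to cover the full gene profile of each cell (the
    reverse direction is mode-seeking and degenerates to reconstructing
    only each cell's top gene).
    """
    xhat = hg @ hc.T
    full = np.ones_like(x, dtype=bool)
    logq = masked_log_softmax(xhat, full, axis=0)
    p = softmax_np(x, axis=0)
    logp = np.log(p + 1e-300)
    return (Tensor(p * logp) - Tensor(p) * logq).sum()


@dataclass
class TrainResult:
    params: HGTParameters
    embedding: EmbeddingTable
    attention: AttentionMatrix
    loss_trace: list[float] = field(default_factory=list)


def train_gae(graph: HeteroGraph, emb0: EmbeddingTable, cfg: HGTConfig,
              subgraphs: list | None = None) -> TrainResult:
    """Train the HGT graph autoencoder on sampled subgraphs.

    Per subgraph, up to `epochs_per_subgraph` full-batch Adam steps with
    early stop once the relative loss change stays below `tol` for
    `patience` consecutive epochs.  Parameters and optimizer state persist
    across subgraphs.  The trained model is then applied to the whole graph
    to produce final embeddings and the gene-to-cell attention.
    """
    d_in = emb0.embedding.shape[1]
    params = init_parameters(cfg, d_in=d_in)
    opt = Adam(params.all_params(), lr=cfg.learning_rate)
    if subgraphs is None:
        subgraphs = sample_subgraphs(graph, cfg)
    mask_full = graph.adjacency_mask()
    trace: list[float] = []
    for genes, cells in subgraphs:
        sub_emb = EmbeddingTable(
            np.vstack([emb0.genes[genes], emb0.cells[cells]]), len(genes))
        sub_mask = mask_full[np.ix_(genes, cells)]
        x_sub = graph.x[np.ix_(genes, cells)]
        calm = 0
        prev = None
        for _ in range(cfg.epochs_per_subgraph):
            opt.zero_grad()
            hg, hc, _ = hgt_forward(sub_mask, sub_emb, params,
                                    return_tensors=True)
            loss = kl_reconstruction_loss(hg, hc, x_sub)
            val = float(loss.data)
            if not np.isfinite(val):
                raise RuntimeError(
                    f"NaN/inf GAE loss at iteration {len(trace)}; "
                    f"subgraph {len(genes)}x{len(cells)}, lr={cfg.learning_rate}")
            loss.backward()
            opt.step()
            trace.append(val)
            if prev is not None:
                rel = abs(prev - val) / max(abs(prev), 1e-12)
                calm = calm + 1 if rel < cfg.tol else 0
                if calm >= cfg.patience:
                    break
            prev = val
    table, att = hgt_forward(graph, emb0, params)
    attention = final_attention(att, mask_full)
    return TrainResult(params, table, attention, trace)
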