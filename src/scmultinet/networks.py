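"""Cell-cluster-active gene association networks via a Steiner Forest model.

For one cell cluster an augmented graph is built: gene-gene edges weighted
by the Pearson correlation of the transformer gene embeddings (kept when
r > 0.5) and gene-cell edges weighted by the final attention scores (kept
when a_ij exceeds mean + sd of the attention incident to the cluster's
cells).  Surviving weights are inverted max-min normalized (largest weight
-> 0, smallest -> 1) and a minimum-weight forest connecting every pair of
cluster cells through gene-internal paths is extracted with a
metric-closure 2-approximation.  The gene nodes of the solution form the
cluster-active gene association network.
"""

from __future__ import annotations

import heapq
import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .cluster import ClusterLabeling
from .graph import EmbeddingTable
from .hgt import AttentionMatrix


class EmptyGraphError(ValueError):
    pass


@dataclass
class AugmentedGraph:
    genes: list[str]
    cells: list[str]  # cluster cells only
    gene_gene: dict[tuple[int, int], float]  # original weights (correlation)
    gene_cell: dict[tuple[int, int], float]  # original weights (attention)
    norm_gene_gene: dict[tuple[int, int], float] = field(default_factory=dict)
    norm_gene_cell: dict[tuple[int, int], float] = field(default_factory=dict)
    attention_threshold: float = 0.0


def invert_normalize(weights: list[float]) -> list[float]:
    """Map weights so the maximum becomes 0 and the minimum becomes 1."""
    w = np.asarray(weights, dtype=float)
    if w.size == 0:
        return []
    lo, hi = w.min(), w.max()
    if hi == lo:
        return [0.0] * len(weights)
    return list((hi - w) / (hi - lo))


def build_augmented_graph(gene_emb: EmbeddingTable | np.ndarray,
                          gene_names: list[str],
                          attention: AttentionMatrix,
                          cell_names: list[str],
                          labels: ClusterLabeling, z: int,
                          corr_threshold: float = 0.5,
                          threshold_scope: str = "cell") -> AugmentedGraph:
    """Augmented gene/cell graph for cluster z.

    The attention cutoff mean+sd is computed per cell over that cell's
    incident edge scores (``threshold_scope="cell"``, the default, which
    keeps every cell attached to its own most-attended genes) or pooled
    over all edges incident to cluster-z cells (``"cluster"``).  Gene-gene candidate edges are evaluated among the genes
    passing the attention filter only.
    """
    emb = gene_emb.genes if isinstance(gene_emb, EmbeddingTable) else gene_emb
    cluster_cells = [c for c in cell_names if labels.assignment.get(c) == z]
    if not cluster_cells:
        raise EmptyGraphError(f"cluster {z} has no cells")
    cell_pos = {c: j for j, c in enumerate(cell_names)}
    cols = np.array([cell_pos[c] for c in cluster_cells])
    sub_scores = attention.scores[:, cols]
    sub_support = attention.support[:, cols]

    gene_cell: dict[tuple[int, int], float] = {}
    if threshold_scope == "cluster":
        vals = sub_scores[sub_support]
        if vals.size == 0:
            raise EmptyGraphError("no attention edges into the cluster")
        thr = float(vals.mean() + vals.std())
        keep = sub_support & (sub_scores > thr)
    elif threshold_scope == "cell":
        keep = np.zeros_like(sub_support)
        thr = float("nan")
        for jj in range(sub_scores.shape[1]):
            v = sub_scores[sub_support[:, jj], jj]
            if v.size:
                keep[:, jj] = sub_support[:, jj] & (
                    sub_scores[:, jj] > v.mean() + v.std())
    else:
        raise ValueError("threshold_scope must be cluster|cell")
    gi, cj = np.nonzero(keep)
    kept_genes = sorted(set(gi.tolist()))
    if not kept_genes:
        raise EmptyGraphError(
            f"no gene-cell edge above threshold {thr:.4g} for cluster {z}")
    g_local = {g: t for t, g in enumerate(kept_genes)}
    for g, c in zip(gi, cj):
        gene_cell[(g_local[g], int(c))] = float(sub_scores[g, c])

    # gene-gene correlations among the filtered genes
    gene_gene: dict[tuple[int, int], float] = {}
    if len(kept_genes) > 1:
        sub_emb = emb[kept_genes]
        with np.errstate(invalid="ignore"):
            corr = np.corrcoef(sub_emb)
        corr = np.nan_to_num(corr, nan=0.0)
        for a, b in combinations(range(len(kept_genes)), 2):
            if corr[a, b] > corr_threshold:
                gene_gene[(a, b)] = float(corr[a, b])

    g = AugmentedGraph(
        genes=[gene_names[i] for i in kept_genes],
        cells=cluster_cells,
        gene_gene=gene_gene,
        gene_cell=gene_cell,
        attention_threshold=thr,
    )
    all_edges = list(gene_gene.items()) + list(gene_cell.items())
    if not all_edges:
        raise EmptyGraphError(f"no surviving edges for cluster {z} "
                              f"(attention threshold {thr:.4g})")
    norm = invert_normalize([w for _, w in all_edges])
    for (key, _), nw in zip(gene_gene.items(), norm[: len(gene_gene)]):
        g.norm_gene_gene[key] = nw
    for (key, _), nw in zip(gene_cell.items(), norm[len(gene_gene):]):
        g.norm_gene_cell[key] = nw
    return g


# ---------------------------------------------------------------------------
# Steiner forest solver


def _gene_graph(g: AugmentedGraph):
    """networkx gene-only graph on normalized weights."""
    import networkx as nx

    G = nx.Graph()
    G.add_nodes_from(range(len(g.genes)))
    for (a, b), _ in g.gene_gene.items():
        w = g.norm_gene_gene[(a, b)]
        if not G.has_edge(a, b) or G[a][b]["weight"] > w:
            G.add_edge(a, b, weight=w)
    return G


def _attachments(g: AugmentedGraph) -> dict[int, dict[int, float]]:
    """terminal j -> {gene i: normalized weight}."""
    out: dict[int, dict[int, float]] = {}
    for (i, j), _ in g.gene_cell.items():
        w = g.norm_gene_cell[(i, j)]
        d = out.setdefault(j, {})
        d[i] = min(w, d.get(i, np.inf))
    return out


def terminal_groups(g: AugmentedGraph):
    """Partition terminals over gene-graph components.

    Because cells may only be path endpoints, two cluster cells can be
    connected exactly when one connected component of the gene-gene graph
    is adjacent to both.  Components are claimed greedily by the number of
    still-unassigned terminals they can host (ties: smaller total
    attachment cost), each terminal joining one component.

    Returns (groups, unreachable) with groups = list of
    (component_gene_set, terminal_list).
    """
    import networkx as nx

    G = _gene_graph(g)
    att = _attachments(g)
    comp_sets = [set(c) for c in nx.connected_components(G)]
    unassigned = set(att)
    unreachable = sorted(set(range(len(g.cells))) - unassigned)
    groups = []
    while unassigned:
        best = None
        for comp in comp_sets:
            hosted = [t for t in unassigned if set(att[t]) & comp]
            if not hosted:
                continue
            cost = sum(min(att[t][i] for i in set(att[t]) & comp)
                       for t in hosted)
            key = (-len(hosted), cost)
            if best is None or key < best[0]:
                best = (key, comp, hosted)
        if best is None:
            break
        _, comp, hosted = best
        groups.append((comp, sorted(hosted)))
        unassigned -= set(hosted)
    return groups, unreachable


@dataclass
class SFPSolution:
    edges: set  # ((kind,i),(kind,j)) canonical-ordered node-key pairs
    steiner_genes: list[int]  # local gene indices used
    cost: float
    unreachable: list[int] = field(default_factory=list)


def _group_cost_edges(g, comp, terms, tree_edges, att):
    """Final edge set for one group given a gene tree; terminals attach to
    the cheapest tree gene; unused tree leaves are pruned."""
    tree_genes = set()
    for a, b in tree_edges:
        tree_genes.update((a, b))
    if not tree_genes:
        # single-gene (or empty) tree: all terminals share one gene
        counts: dict[int, float] = {}
        for i in comp:
            if all(i in att[t] for t in terms):
                counts[i] = sum(att[t][i] for t in terms)
        if counts:
            hub = min(counts, key=lambda i: (counts[i], i))
            tree_genes = {hub}
        else:
            tree_genes = set(comp)
    attach_edges = set()
    used_genes = set()
    for t in terms:
        cands = [(att[t][i], i) for i in att[t] if i in tree_genes]
        if not cands:
            cands = [(att[t][i], i) for i in att[t] if i in comp]
        w, i = min(cands)
        attach_edges.add((("c", t), ("g", i)))
        used_genes.add(i)
    # prune tree leaves that serve no terminal
    edges = {tuple(sorted((("g", a), ("g", b)))) for a, b in tree_edges}
    changed = True
    while changed:
        changed = False
        deg: dict = {}
        for u, v in edges:
            deg[u] = deg.get(u, 0) + 1
            deg[v] = deg.get(v, 0) + 1
        for e in sorted(edges):
            for node in e:
                if (node[0] == "g" and deg.get(node, 0) == 1
                        and node[1] not in used_genes):
                    edges.discard(e)
                    changed = True
                    break
            if changed:
                break
    return edges | {tuple(sorted(e)) for e in attach_edges}


def _edge_cost(g, edges) -> float:
    total = 0.0
    for u, v in edges:
        if u[0] == "g" and v[0] == "g":
            a, b = sorted((u[1], v[1]))
            total += g.norm_gene_gene[(a, b)]
        else:
            cell = u if u[0] == "c" else v
            gene = v if u[0] == "c" else u
            total += g.norm_gene_cell[(gene[1], cell[1])]
    return total


def solve_sfp(g: AugmentedGraph) -> SFPSolution:
    """Approximate minimum-weight forest connecting the cluster cells.

    Per terminal group (see :func:`terminal_groups`): each terminal picks
    its cheapest attachment gene, the attachment genes are joined by the
    Kou/Mehlhorn 2-approximate Steiner tree on the gene-gene graph, and
    attachments are then re-chosen against the tree.  Cells are leaves by
    construction.  Terminals without any surviving edge are reported
    unreachable.
    """
    import networkx as nx
    from networkx.algorithms.approximation import steiner_tree

    att = _attachments(g)
    groups, unreachable = terminal_groups(g)
    if unreachable:
        warnings.warn(f"{len(unreachable)} terminal cell(s) have no "
                      "surviving edges; excluded from the forest")
    G = _gene_graph(g)
    solution: set = set()
    for comp, terms in groups:
        if len(terms) <= 1:
            # a lone terminal needs no connection (and no edges)
            continue
        candidates = []

        def tree_for(s_genes):
            if len(s_genes) > 1:
                sub = G.subgraph(comp)
                tree = steiner_tree(sub, list(s_genes), weight="weight",
                                    method="mehlhorn")
                return list(tree.edges())
            return []

        # (a) greedy attachment + Steiner tree, refined up to 3 rounds
        s_cur = {min(((att[t][i], i) for i in set(att[t]) & comp))[1]
                 for t in terms}
        for _ in range(3):
            edges = _group_cost_edges(g, comp, terms, tree_for(s_cur), att)
            candidates.append(edges)
            s_next = {v[1] for e in edges for v in e
                      if v[0] == "g" and any(u[0] == "c" for u in e)}
            if s_next == s_cur:
                break
            s_cur = s_next
        # (b) best single shared hub, when one gene reaches every terminal
        hubs = [i for i in comp if all(i in att[t] for t in terms)]
        if hubs:
            hub = min(hubs, key=lambda i: (sum(att[t][i] for t in terms), i))
            candidates.append({tuple(sorted((("c", t), ("g", hub))))
                               for t in terms})
        # (c) leave-one-out: greedy attachment can anchor on a gene that is
        # expensive to wire into the tree; retry with each greedy anchor
        # gene forbidden for attachment
        s_greedy = {min(((att[t][i], i) for i in set(att[t]) & comp))[1]
                    for t in terms}
        for banned in sorted(s_greedy):
            att2 = {t: {i: w for i, w in att[t].items() if i != banned}
                    for t in terms}
            if any(not (set(att2[t]) & comp) for t in terms):
                continue
            s_alt = {min(((att2[t][i], i) for i in set(att2[t]) & comp))[1]
                     for t in terms}
            candidates.append(
                _group_cost_edges(g, comp, terms, tree_for(s_alt), att2))
        best = min(candidates, key=lambda e: _edge_cost(g, e))
        solution |= best
    genes = sorted({k[1] for e in solution for k in e if k[0] == "g"})
    return SFPSolution(solution, genes, _edge_cost(g, solution), unreachable)


def solve_sfp_exact(g: AugmentedGraph) -> SFPSolution:
    """Exhaustive oracle for toy graphs: for each terminal group, enumerate
    connected gene subsets S hosting every terminal; cost(S) = MST of the
    S-induced gene graph + each terminal's cheapest attachment into S.
    Exponential in the component size; intended for <= ~14 genes."""
    import networkx as nx

    att = _attachments(g)
    groups, unreachable = terminal_groups(g)
    G = _gene_graph(g)
    solution: set = set()
    for comp, terms in groups:
        if len(terms) <= 1:
            continue
        comp = sorted(comp)
        best = None
        for mask in range(1, 1 << len(comp)):
            S = [comp[i] for i in range(len(comp)) if mask >> i & 1]
            sub = G.subgraph(S)
            if not nx.is_connected(sub):
                continue
            cost = 0.0
            attach = []
            ok = True
            for t in terms:
                cands = [(att[t][i], i) for i in att[t] if i in set(S)]
                if not cands:
                    ok = False
                    break
                w, i = min(cands)
                cost += w
                attach.append((t, i))
            if not ok:
                continue
            mst = nx.minimum_spanning_tree(sub, weight="weight")
            cost += sum(d["weight"] for _, _, d in mst.edges(data=True))
            if best is None or cost < best[0]:
                edges = {tuple(sorted((("g", a), ("g", b))))
                         for a, b in mst.edges()}
                edges |= {tuple(sorted((("c", t), ("g", i))))
                          for t, i in attach}
                best = (cost, edges)
        if best is not None:
            solution |= best[1]
    genes = sorted({k[1] for e in solution for k in e if k[0] == "g"})
    return SFPSolution(solution, genes, _edge_cost(g, solution), unreachable)


@dataclass
class GeneNetwork:
    """Cluster-active gene association network (original weights)."""

    cluster: int
    genes: list[str]
    edges: list[tuple[str, str, float]]  # gene-gene, correlation weights
    gene_attention: dict[str, float]  # summed attention to cluster cells


def extract_network(g: AugmentedGraph, sol: SFPSolution, z: int) -> GeneNetwork:
    """Gene-gene edges of the solution with their original correlation
    weights; node attribute is the gene's summed attention to the cluster."""
    genes = [g.genes[i] for i in sol.steiner_genes]
    name_of = {i: g.genes[i] for i in sol.steiner_genes}
    edges = []
    for u, v in sorted(sol.edges):
        if u[0] == "g" and v[0] == "g":
            a, b = sorted((u[1], v[1]))
            w = g.gene_gene.get((a, b), g.gene_gene.get((b, a)))
            edges.append((name_of[a], name_of[b], float(w)))
    att_sum: dict[str, float] = {name: 0.0 for name in genes}
    for (i, j), w in g.gene_cell.items():
        if i in name_of:
            att_sum[name_of[i]] += w
    return GeneNetwork(z, genes, edges, att_sum)
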