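"""Gene regulatory networks: regulons, RI/RAS scores and cell-type
specificity.

TF binding sites (JASPAR-convention scores, -log10(p) x 100) are filtered
at score >= 500, intersected with ATAC peaks, and divided by 100 to give
binding affinities in (0, 10].  The regulatory intensity (RI) of TF q on
gene i in cell j sums affinity x regulatory potential over shared peaks.
A regulon is the set of cluster-network genes with positive RI for a TF;
its regulon activity score (RAS) averages GAS x RI over regulon genes and
cluster cells.  Cell-type-specific regulons (CTSR) are called by a
one-vs-rest Wilcoxon rank-sum test on per-cell activities with BH
correction (adjusted p < 0.05 and log2 fold change > 0.10).  Master TFs
are ranked by eigenvector centrality of the merged cluster GRN.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.stats import mannwhitneyu
from statsmodels.stats.multitest import multipletests

from .cluster import ClusterLabeling
from .io import GenomicInterval, NamedMatrix
from .networks import GeneNetwork
from .preprocess import IntegratedMatrix


@dataclass
class BindingAffinityTable:
    """(tf, peak index) -> affinity in (0, 10]."""

    entries: dict[tuple[str, int], float]

    def __post_init__(self) -> None:
        for (tf, k), b in self.entries.items():
            if not (0.0 < b <= 10.0):
                raise ValueError(f"affinity {b} for ({tf},{k}) outside (0,10]")

    def tfs(self) -> list[str]:
        return sorted({tf for tf, _ in self.entries})

    def peaks_of(self, tf: str) -> dict[int, float]:
        return {k: b for (t, k), b in self.entries.items() if t == tf}


def binding_affinity(sites: list[GenomicInterval],
                     peaks: list[GenomicInterval],
                     min_score: float = 500.0) -> BindingAffinityTable:
    """Filter TF binding sites and intersect them with ATAC peaks.

    Site names carry the TF identifier; scores follow the JASPAR
    convention (0..1000 = -log10 p x 100).  Sites scoring below
    `min_score` are dropped (strict "less than"), out-of-range scores are
    clamped with a warning, and a site overlapping several peaks
    contributes its affinity to each.  When a TF hits the same peak through
    several sites the strongest affinity is kept.
    """
    entries: dict[tuple[str, int], float] = {}
    by_chrom: dict[str, list[tuple[int, GenomicInterval]]] = {}
    for k, p in enumerate(peaks):
        by_chrom.setdefault(p.chrom, []).append((k, p))
    for s in sites:
        score = s.score if s.score is not None else 0.0
        if score < 0 or score > 1000:
            warnings.warn(f"site {s.name} score {score} outside [0,1000]; clamped")
            score = min(max(score, 0.0), 1000.0)
        if score < min_score:
            continue
        for k, p in by_chrom.get(s.chrom, []):
            if s.overlaps(p):
                key = (s.name, k)
                aff = score / 100.0
                entries[key] = max(aff, entries.get(key, 0.0))
    return BindingAffinityTable(entries)


def ri_score(affinity: BindingAffinityTable, w: sp.spmatrix,
             atac: NamedMatrix) -> dict[str, np.ndarray]:
    """RI s_ij|q = sum_k b_qk * w_ik * x^A_kj per TF (genes x cells).

    `w` is the peak->gene regulatory-potential weight map (genes x peaks)
    from preprocessing, so the inner product runs over peaks both bound by
    the TF and assigned to the gene.
    """
    w = sp.csr_matrix(w)
    out: dict[str, np.ndarray] = {}
    for tf in affinity.tfs():
        bound = affinity.peaks_of(tf)
        b = np.zeros(w.shape[1])
        for k, aff in bound.items():
            b[k] = aff
        weighted = w.multiply(b[None, :])  # genes x peaks
        out[tf] = np.asarray(weighted @ atac.values)
    return out


@dataclass
class Regulon:
    tf: str
    cluster: int
    targets: list[str]
    ras: float = np.nan
    ctsr: bool = False
    adj_p: float = np.nan
    logfc: float = np.nan


def assemble_regulons(networks: dict[int, GeneNetwork],
                      ri: dict[str, np.ndarray],
                      gene_names: list[str],
                      labels: ClusterLabeling,
                      cell_names: list[str],
                      min_targets: int = 2) -> list[Regulon]:
    """Per cluster, a TF's regulon is the set of cluster-network genes with
    positive RI in at least one cluster cell; regulons with fewer than
    `min_targets` targets are dropped."""
    gene_pos = {g: i for i, g in enumerate(gene_names)}
    cell_pos = {c: j for j, c in enumerate(cell_names)}
    out: list[Regulon] = []
    for z, net in sorted(networks.items()):
        cols = np.array([cell_pos[c] for c in labels.cells_of(z)
                         if c in cell_pos])
        net_idx = [gene_pos[g] for g in net.genes if g in gene_pos]
        if not net_idx or cols.size == 0:
            continue
        for tf in sorted(ri):
            s = ri[tf]
            targets = [gene_names[i] for i in net_idx
                       if cols.size and s[i, cols].max() > 0]
            if len(targets) >= min_targets:
                out.append(Regulon(tf, z, targets))
    if not out:
        warnings.warn("no TF could be assigned to any cluster network")
    return out


def ras(regulon: Regulon, X: IntegratedMatrix, ri: dict[str, np.ndarray],
        labels: ClusterLabeling, denominator: str = "subset") -> float:
    """Regulon activity score r(q, z).

    With ``denominator="subset"`` (default) the double sum of GAS x RI is
    divided by |I_q| * |C[z]|; ``"global"`` divides by I * J (the full
    matrix size), which scales with the dataset.
    """
    if not regulon.targets:
        raise ValueError("empty regulon")
    gene_pos = {g: i for i, g in enumerate(X.row_names)}
    cell_pos = {c: j for j, c in enumerate(X.col_names)}
    rows = np.array([gene_pos[g] for g in regulon.targets])
    cols = np.array([cell_pos[c] for c in labels.cells_of(regulon.cluster)
                     if c in cell_pos])
    s = ri[regulon.tf]
    num = float((X.values[np.ix_(rows, cols)] * s[np.ix_(rows, cols)]).sum())
    if denominator == "subset":
        den = len(rows) * len(cols)
    elif denominator == "global":
        den = X.values.shape[0] * X.values.shape[1]
    else:
        raise ValueError("denominator must be subset|global")
    return num / den


def per_cell_activity(regulon: Regulon, X: IntegratedMatrix,
                      ri: dict[str, np.ndarray]) -> np.ndarray:
    """r_j(q) = sum_{i in I_q} x_ij * s_ij|q / |I_q| for every cell."""
    gene_pos = {g: i for i, g in enumerate(X.row_names)}
    rows = np.array([gene_pos[g] for g in regulon.targets])
    s = ri[regulon.tf]
    return (X.values[rows] * s[rows]).sum(axis=0) / len(rows)


def ctsr_test(regulons: list[Regulon], X: IntegratedMatrix,
              ri: dict[str, np.ndarray], labels: ClusterLabeling,
              alpha: float = 0.05, min_logfc: float = 0.10,
              min_cells: int = 3) -> list[Regulon]:
    """One-vs-rest Wilcoxon rank-sum CTSR test with BH correction.

    Per (TF, cluster) regulon the per-cell activities of cluster cells are
    compared against all other cells; p-values are BH-adjusted across all
    tests, and a regulon is cell-type-specific iff adjusted p < alpha and
    log2(mean_in / mean_out) > `min_logfc` (both strict).  Clusters with
    fewer than `min_cells` cells are skipped (flagged NA).
    """
    cell_pos = {c: j for j, c in enumerate(X.col_names)}
    pvals, tested = [], []
    for reg in regulons:
        act = per_cell_activity(reg, X, ri)
        in_cols = np.array([cell_pos[c] for c in labels.cells_of(reg.cluster)
                            if c in cell_pos])
        out_cols = np.setdiff1d(np.arange(len(X.col_names)), in_cols)
        if len(in_cols) < min_cells or len(out_cols) < min_cells:
            reg.adj_p = np.nan
            reg.ctsr = False
            continue
        a, b = act[in_cols], act[out_cols]
        eps = 1e-9
        reg.logfc = float(np.log2((a.mean() + eps) / (b.mean() + eps)))
        if np.all(a == a[0]) and np.all(b == b[0]) and a[0] == b[0]:
            p = 1.0
        else:
            p = float(mannwhitneyu(a, b, alternative="greater").pvalue)
        pvals.append(p)
        tested.append(reg)
    if pvals:
        rejected, adj, *_ = multipletests(pvals, alpha=alpha, method="fdr_bh")
        for reg, padj in zip(tested, adj):
            reg.adj_p = float(padj)
            reg.ctsr = bool(padj < alpha and reg.logfc > min_logfc)
    for reg in regulons:
        reg.ras = ras(reg, X, ri, labels)
    return regulons


def master_tfs(regulons: list[Regulon], ri: dict[str, np.ndarray],
               X: IntegratedMatrix, labels: ClusterLabeling, z: int,
               top_n: int = 10) -> list[tuple[str, float]]:
    """Rank TFs of cluster z's merged GRN by eigenvector centrality.

    The GRN unions the cluster's regulons (TF -> target edges weighted by
    the mean RI over cluster cells); centrality is computed on the
    symmetrized weighted adjacency, ties broken lexicographically.
    """
    from .metrics import eigenvector_centrality

    cluster_regs = [r for r in regulons if r.cluster == z]
    if not cluster_regs:
        return []
    gene_pos = {g: i for i, g in enumerate(X.row_names)}
    cell_pos = {c: j for j, c in enumerate(X.col_names)}
    cols = np.array([cell_pos[c] for c in labels.cells_of(z) if c in cell_pos])
    nodes: list[str] = []
    edges: list[tuple[str, str, float]] = []
    for reg in cluster_regs:
        tf_node = f"TF:{reg.tf}"
        if tf_node not in nodes:
            nodes.append(tf_node)
        for g in reg.targets:
            if g not in nodes:
                nodes.append(g)
            w = float(ri[reg.tf][gene_pos[g], cols].mean()) if cols.size else 0.0
            edges.append((tf_node, g, w))
    if not edges:
        return []
    scores = eigenvector_centrality(nodes, edges)
    tf_scores = [(n[3:], s) for n, s in scores.items() if n.startswith("TF:")]
    tf_scores.sort(key=lambda t: (-t[1], t[0]))
    return tf_scores[:top_n]
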