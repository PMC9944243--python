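"""Quality control, normalization and modality integration.

Three integration paths produce the single features x cells matrix ``X`` that
all downstream stages consume:

* multiple scRNA-seq: log-normalize, select highly variable genes, align
  batches with a basic CCA and concatenate;
* CITE-seq: log-normalize, vertically concatenate genes and proteins, apply a
  per-cell centered log-ratio (CLR) transform;
* paired scRNA/scATAC-seq: turn peak accessibility into per-gene regulatory
  potential with an exponential TSS-distance decay, discretize expression with
  a mixture model, derive rank-based RNA-velocity weights, and combine
  expression with regulatory potential into a gene activity score (GAS).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from sklearn.cluster import KMeans
from sklearn.mixture import GaussianMixture

from .io import GeneAnnotation, GenomicInterval, NamedMatrix


class EmptyResultError(ValueError):
    """All rows or all columns were removed by a filtering step."""


@dataclass
class QCParams:
    min_nonzero_fraction: float = 0.001
    max_mito_fraction: float = 1.0  # 1.0 disables the mito filter
    min_counts: int = 0
    mito_prefix: str = "MT-"

    def __post_init__(self) -> None:
        if not (0.0 <= self.min_nonzero_fraction <= 1.0):
            raise ValueError("min_nonzero_fraction must be in [0, 1]")
        if not (0.0 <= self.max_mito_fraction <= 1.0):
            raise ValueError("max_mito_fraction must be in [0, 1]")


@dataclass
class LTMGLabels:
    """Per-gene discrete regulatory-state labels in {1..G_i}."""

    labels: np.ndarray  # genes x cells, int
    n_components: np.ndarray  # per gene G_i

    def __post_init__(self) -> None:
        if np.any(self.n_components < 1):
            raise ValueError("G_i must be >= 1")
        if np.any(self.labels < 1) or np.any(self.labels > self.n_components[:, None]):
            raise ValueError("labels out of per-gene range")


@dataclass
class VelocityWeights:
    beta: np.ndarray  # genes x cells, >= 0
    sign: np.ndarray  # genes x cells, in {-1, 0, +1}

    def __post_init__(self) -> None:
        if np.any(self.beta < 0):
            raise ValueError("beta must be non-negative")
        if np.any(self.beta[self.sign == 0] != 0):
            raise ValueError("beta must be 0 where sign is 0")


@dataclass
class IntegratedMatrix:
    """The integrated features x cells matrix X consumed by the graph."""

    values: np.ndarray
    row_names: list[str]
    col_names: list[str]
    feature_kind: list[str] = field(default_factory=list)  # gene | protein
    source: str = "multi_rna"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not self.feature_kind:
            self.feature_kind = ["gene"] * self.values.shape[0]
        if np.any(self.values < 0):
            # only the unclipped (literal) GAS path can produce negatives;
            # downstream edge construction treats them as absent
            warnings.warn("integrated matrix contains negative entries")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


# ---------------------------------------------------------------------------
# QC and normalization


def qc_filter(m: NamedMatrix, p: QCParams | None = None) -> NamedMatrix:
    """Iteratively remove rows/columns with < min_nonzero_fraction non-zeros.

    The threshold is a strict "less than": a row non-zero in exactly the
    threshold fraction of columns is retained.  Filtering repeats until a
    fixed point, so the result is idempotent under re-filtering.
    """
    p = p or QCParams()
    vals = m.values
    rows = np.arange(vals.shape[0])
    cols = np.arange(vals.shape[1])

    if p.min_counts > 0:
        keep = vals.sum(axis=0) >= p.min_counts
        cols = cols[keep]
        vals = vals[:, keep]
    if p.max_mito_fraction < 1.0:
        mito = np.array([n.upper().startswith(p.mito_prefix.upper())
                         for n in m.row_names])[rows]
        totals = vals.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(totals > 0, vals[mito].sum(axis=0) / totals, 0.0)
        keep = frac <= p.max_mito_fraction
        cols = cols[keep]
        vals = vals[:, keep]

    while True:
        if vals.shape[0] == 0 or vals.shape[1] == 0:
            raise EmptyResultError("QC removed all rows or all columns")
        row_frac = (vals != 0).mean(axis=1)
        keep_r = row_frac >= p.min_nonzero_fraction
        # strict "less than" removal, but all-zero rows always go
        keep_r &= (vals != 0).any(axis=1)
        vals = vals[keep_r]
        rows = rows[keep_r]
        if vals.shape[0] == 0:
            raise EmptyResultError("QC removed all rows")
        col_frac = (vals != 0).mean(axis=0)
        keep_c = col_frac >= p.min_nonzero_fraction
        keep_c &= (vals != 0).any(axis=0)
        vals = vals[:, keep_c]
        cols = cols[keep_c]
        if keep_r.all() and keep_c.all():
            break
    return NamedMatrix(vals, [m.row_names[i] for i in rows],
                       [m.col_names[j] for j in cols], m.modality)


def log_normalize(m: NamedMatrix, scale: float = 10000.0) -> NamedMatrix:
    """Depth-normalize each cell to `scale` total counts, then log1p."""
    totals = m.values.sum(axis=0)
    if np.any(totals == 0):
        raise EmptyResultError("all-zero cell column; run qc_filter first")
    out = np.log1p(m.values / totals[None, :] * scale)
    return NamedMatrix(out, m.row_names, m.col_names, m.modality)


def select_hvg(m: NamedMatrix, n: int = 2000) -> NamedMatrix:
    """Keep the top-n genes by variance-stabilized dispersion.

    Genes are binned by mean expression (20 bins) and dispersion
    (variance/mean) is z-scored within bins, the classical highly-variable
    gene ranking.  If the matrix has fewer than n genes, all are kept.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if m.shape[0] <= n:
        return m
    means = m.values.mean(axis=1)
    var = m.values.var(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        disp = np.where(means > 0, var / means, 0.0)
    order = np.argsort(means)
    n_bins = min(20, max(1, m.shape[0] // 10))
    bins = np.array_split(order, n_bins)
    z = np.zeros_like(disp)
    for b in bins:
        mu, sd = disp[b].mean(), disp[b].std()
        z[b] = (disp[b] - mu) / sd if sd > 0 else 0.0
    # stable ranking: dispersion z-score, ties broken by raw variance
    keep = np.lexsort((-var, -z))[:n]
    keep = np.sort(keep)
    return m.subset(rows=keep)


# ---------------------------------------------------------------------------
# multiple scRNA-seq: CCA alignment


def _cca_cell_embeddings(za: np.ndarray, zb: np.ndarray,
                         k: int) -> tuple[np.ndarray, np.ndarray]:
    """Canonical correlation cell embeddings from the SVD of Za^T Zb."""
    u, _, vt = np.linalg.svd(za.T @ zb, full_matrices=False)
    ea, eb = u[:, :k], vt[:k].T
    # L2-normalize rows so embedding scale is comparable across batches
    ea = ea / np.maximum(np.linalg.norm(ea, axis=1, keepdims=True), 1e-12)
    eb = eb / np.maximum(np.linalg.norm(eb, axis=1, keepdims=True), 1e-12)
    return ea, eb


def cca_align(matrices: list[NamedMatrix], n_components: int = 20,
              n_groups: int = 5, seed: int = 0,
              min_shared_genes: int = 30) -> IntegratedMatrix:
    """Align log-normalized batches into one genes x cells matrix.

    Batches are reduced to a shared canonical-correlation space (SVD of the
    standardized cross-batch product against the largest batch), pooled cells
    are grouped by k-means in that space, and each batch's per-group,
    per-gene mean offset from the pooled group mean is removed.  Corrected
    values are clipped at 0.  With a single input the matrix passes through
    unchanged; identical batches incur no correction.
    """
    if not matrices:
        raise ValueError("no matrices supplied")
    if len(matrices) == 1:
        m = matrices[0]
        return IntegratedMatrix(np.maximum(m.values, 0.0), list(m.row_names),
                                list(m.col_names), source="multi_rna")
    shared = set(matrices[0].row_names)
    for m in matrices[1:]:
        shared &= set(m.row_names)
    genes = sorted(shared)
    if len(genes) < min_shared_genes:
        raise ValueError(f"only {len(genes)} shared genes (< {min_shared_genes})")
    mats = []
    for m in matrices:
        idx = [m.row_index()[g] for g in genes]
        mats.append(m.values[idx, :])

    ref = int(np.argmax([x.shape[1] for x in mats]))

    def standardize(x):
        mu = x.mean(axis=1, keepdims=True)
        sd = x.std(axis=1, keepdims=True)
        return (x - mu) / np.where(sd > 0, sd, 1.0)

    k = min(n_components, *(x.shape[1] - 1 for x in mats), len(genes))
    k = max(k, 1)
    zref = standardize(mats[ref])
    embeds: list[np.ndarray] = [None] * len(mats)  # type: ignore[list-item]
    for b, x in enumerate(mats):
        if b == ref:
            continue
        ea, eb = _cca_cell_embeddings(zref, standardize(x), k)
        embeds[b] = eb
        if embeds[ref] is None:
            embeds[ref] = ea
    if embeds[ref] is None:  # single non-ref batch edge case
        embeds[ref] = np.zeros((mats[ref].shape[1], k))

    pooled = np.vstack(embeds)
    ng = min(n_groups, pooled.shape[0])
    km = KMeans(n_clusters=ng, n_init=5, random_state=seed)
    groups = km.fit_predict(pooled)
    batch_of = np.concatenate([np.full(x.shape[1], b) for b, x in enumerate(mats)])

    corrected = [x.copy() for x in mats]
    offsets = np.cumsum([0] + [x.shape[1] for x in mats])
    for g in range(ng):
        in_g = groups == g
        if not in_g.any():
            continue
        pooled_mean = np.hstack(mats)[:, in_g].mean(axis=1, keepdims=True)
        for b, x in enumerate(mats):
            cells_b = in_g[offsets[b]:offsets[b + 1]]
            if not cells_b.any():
                continue
            batch_mean = x[:, cells_b].mean(axis=1, keepdims=True)
            corrected[b][:, cells_b] -= batch_mean - pooled_mean
    values = np.maximum(np.hstack(corrected), 0.0)
    col_names = []
    for b, m in enumerate(matrices):
        col_names.extend(f"{c}" if col_unique(matrices, b, c) else f"{c}.b{b}"
                         for c in m.col_names)
    return IntegratedMatrix(values, genes, col_names, source="multi_rna")


def col_unique(matrices: list[NamedMatrix], b: int, name: str) -> bool:
    return sum(name in m.col_names for m in matrices) == 1


# ---------------------------------------------------------------------------
# CITE-seq: CLR


def clr_transform(m: NamedMatrix) -> NamedMatrix:
    """Per-cell centered log-ratio against the geometric mean of 1+x over the
    cell's non-zero features; zeros map exactly to zero."""
    vals = m.values
    nz = vals != 0
    if np.any(~nz.any(axis=0)):
        raise EmptyResultError("cell with no non-zero features")
    logs = np.log1p(vals)
    denom = np.exp((logs * nz).sum(axis=0) / nz.sum(axis=0))  # per cell
    out = np.log1p(vals / denom[None, :])
    out[~nz] = 0.0
    return NamedMatrix(out, m.row_names, m.col_names, m.modality)


def integrate_cite(rna: NamedMatrix, protein: NamedMatrix,
                   n_hvg: int = 2000) -> IntegratedMatrix:
    """Log-normalize both modalities, select HVGs, stack vertically, CLR."""
    rna_n = select_hvg(log_normalize(rna), n_hvg)
    prot_n = log_normalize(protein)
    rows = rna_n.row_names + [f"prot:{p}" for p in prot_n.row_names]
    stacked = NamedMatrix(np.vstack([rna_n.values, prot_n.values]),
                          rows, rna_n.col_names, "rna")
    out = clr_transform(stacked)
    kinds = ["gene"] * rna_n.shape[0] + ["protein"] * prot_n.shape[0]
    return IntegratedMatrix(np.maximum(out.values, 0.0), rows,
                            list(out.col_names), kinds, source="cite")


# ---------------------------------------------------------------------------
# scRNA/scATAC: regulatory potential


def peak_gene_weights(peaks: list[GenomicInterval],
                      genes: list[GeneAnnotation],
                      d0: float = 10_000.0,
                      dmax: float = 150_000.0) -> sp.csr_matrix:
    """Regulatory-potential weight w_ik of peak k for gene i.

    w = 0 beyond `dmax` from the TSS or when the peak center sits inside
    another gene's transcript body; w = 1/exon_length when the peak overlaps
    an exon of gene i; otherwise w = 2^(-d/d0) with d the unsigned distance
    from the peak center to the TSS (d0 = 10 kb half-decay).
    """
    for g in genes:
        if g.exon_length() <= 0:
            raise ValueError(f"gene {g.gene_id} has zero exon length")
    n_g, n_p = len(genes), len(peaks)
    rows, cols, data = [], [], []
    spans = [(g.chrom, *g.span) for g in genes]
    for k, pk in enumerate(peaks):
        center = pk.center
        for i, g in enumerate(genes):
            if g.chrom != pk.chrom:
                continue
            d = abs(center - g.tss)
            if d > dmax:
                continue
            exonic = any(pk.overlaps(e) for e in g.exons)
            if not exonic:
                # inside a *different* gene's body -> no distal contribution
                inside_other = any(
                    spans[i2][0] == pk.chrom and spans[i2][1] <= center < spans[i2][2]
                    for i2 in range(n_g) if i2 != i)
                if inside_other:
                    continue
                w = 2.0 ** (-d / d0)
            else:
                w = 1.0 / g.exon_length()
            rows.append(i)
            cols.append(k)
            data.append(w)
    return sp.csr_matrix((data, (rows, cols)), shape=(n_g, n_p))


def regulatory_potential(atac: NamedMatrix, w: sp.spmatrix,
                         gene_ids: list[str]) -> NamedMatrix:
    """Sum peak accessibility into per-gene regulatory potential X^A'."""
    if w.nnz == 0:
        raise EmptyResultError("no peak maps to any gene")
    if w.shape[1] != atac.shape[0]:
        raise ValueError("weight map does not match ATAC peak count")
    vals = np.asarray(w @ atac.values)
    return NamedMatrix(vals, list(gene_ids), atac.col_names, "gas")


# ---------------------------------------------------------------------------
# LTMG discretization


def ltmg_discretize(rna: NamedMatrix, max_components: int = 5,
                    seed: int = 0, min_cells: int = 5) -> LTMGLabels:
    """Discretize each gene's log expression into mixture-component labels.

    Per gene, a Gaussian mixture (EM, BIC-selected G_i <= max_components) is
    fitted on the non-zero log expression values; the zero observations are
    treated as left-censored at the detection limit and assigned the
    lowest-mean component.  Genes detected in fewer than `min_cells` cells
    get G_i = 1 without fitting.
    """
    I, J = rna.shape
    labels = np.ones((I, J), dtype=int)
    n_comp = np.ones(I, dtype=int)
    for i in range(I):
        x = rna.values[i]
        nz = x > 0
        xs = x[nz].reshape(-1, 1)
        if nz.sum() < min_cells or np.allclose(xs, xs[0]):
            continue
        best_bic, best_gm, best_g = np.inf, None, 1
        for g in range(1, max_components + 1):
            if g > len(xs):
                break
            gm = GaussianMixture(n_components=g, tol=1e-4, max_iter=200,
                                 random_state=seed, reg_covar=1e-4)
            gm.fit(xs)
            bic = gm.bic(xs)
            if bic < best_bic - 1e-9:
                best_bic, best_gm, best_g = bic, gm, g
        if best_gm is None:
            continue
        n_comp[i] = best_g
        order = np.argsort(best_gm.means_.ravel())  # relabel by mean
        rank = np.empty_like(order)
        rank[order] = np.arange(best_g)
        comp = best_gm.predict(xs)
        labels[i, nz] = rank[comp] + 1
        labels[i, ~nz] = 1  # censored zeros -> lowest state
    return LTMGLabels(labels, n_comp)


# ---------------------------------------------------------------------------
# velocity weights and GAS


def steady_state_velocity(spliced: NamedMatrix, unspliced: NamedMatrix,
                          quantile: float = 0.95) -> NamedMatrix:
    """Steady-state velocity estimate v = u - gamma * s.

    gamma is fitted per gene by least squares through the origin on the
    cells in the upper `quantile` of s + u (the near-steady-state cells).
    """
    s, u = spliced.values, unspliced.values
    I, J = s.shape
    vel = np.zeros_like(s)
    for i in range(I):
        tot = s[i] + u[i]
        if tot.max() <= 0:
            continue
        thr = np.quantile(tot, quantile)
        top = tot >= thr
        ss, uu = s[i][top], u[i][top]
        denom = (ss * ss).sum()
        gamma = (ss * uu).sum() / denom if denom > 0 else 0.0
        vel[i] = u[i] - gamma * s[i]
    return NamedMatrix(vel, spliced.row_names, spliced.col_names, "velocity")


def _descending_ranks(values: np.ndarray, start: int) -> np.ndarray:
    """Ordinal ranks of `values` sorted descending, starting at `start`."""
    order = np.argsort(-values, kind="stable")
    ranks = np.empty(len(values), dtype=float)
    ranks[order] = np.arange(start, start + len(values))
    return ranks


def velocity_weights(vel: NamedMatrix, ltmg: LTMGLabels,
                     normalize: bool = True) -> VelocityWeights:
    """Rank-based velocity weights beta per (gene, cell).

    Velocities are first smoothed to the mean within each (gene,
    discretization-label) cell group.  For positive entries, a is the
    descending rank (from 1) of the entry among the gene's positive
    velocities and b the analogous rank among the cell's positive
    velocities; beta+ = sqrt((|P_i|-a-1)^2 + (|P_j|-b-1)^2).  Negative
    entries are ranked (from 0) by descending |velocity| with a symmetric
    formula.  With ``normalize`` (the default) beta is divided by
    sqrt(|S_i|^2 + |S_j|^2), bounding it by sqrt(2).
    """
    v = vel.values.copy()
    I, J = v.shape
    if ltmg.labels.shape != (I, J):
        raise ValueError("LTMG labels do not match velocity matrix shape")
    for i in range(I):
        for g in range(1, ltmg.n_components[i] + 1):
            grp = ltmg.labels[i] == g
            if grp.any():
                v[i, grp] = v[i, grp].mean()

    beta = np.zeros((I, J))
    sign = np.sign(v).astype(int)

    pos = v > 0
    neg = v < 0
    # per-gene and per-cell ranks for positive entries (descending, from 1)
    a_pos = np.zeros((I, J))
    b_pos = np.zeros((I, J))
    a_neg = np.zeros((I, J))
    b_neg = np.zeros((I, J))
    for i in range(I):
        if pos[i].any():
            a_pos[i, pos[i]] = _descending_ranks(v[i, pos[i]], 1)
        if neg[i].any():
            a_neg[i, neg[i]] = _descending_ranks(np.abs(v[i, neg[i]]), 0)
    for j in range(J):
        if pos[:, j].any():
            b_pos[pos[:, j], j] = _descending_ranks(v[pos[:, j], j], 1)
        if neg[:, j].any():
            b_neg[neg[:, j], j] = _descending_ranks(np.abs(v[neg[:, j], j]), 0)

    n_pos_gene = pos.sum(axis=1, keepdims=True).astype(float)
    n_pos_cell = pos.sum(axis=0, keepdims=True).astype(float)
    n_neg_gene = neg.sum(axis=1, keepdims=True).astype(float)
    n_neg_cell = neg.sum(axis=0, keepdims=True).astype(float)

    bp = np.sqrt((n_pos_gene - a_pos - 1) ** 2 + (n_pos_cell - b_pos - 1) ** 2)
    bn = np.sqrt((n_neg_gene - a_neg - 1) ** 2 + (n_neg_cell - b_neg - 1) ** 2)
    if normalize:
        with np.errstate(invalid="ignore", divide="ignore"):
            den_p = np.sqrt(n_pos_gene ** 2 + n_pos_cell ** 2)
            den_n = np.sqrt(n_neg_gene ** 2 + n_neg_cell ** 2)
            bp = np.where(den_p > 0, bp / den_p, 0.0)
            bn = np.where(den_n > 0, bn / den_n, 0.0)
    beta[pos] = bp[pos]
    beta[neg] = bn[neg]
    return VelocityWeights(beta, sign)


def gas_matrix(rna: NamedMatrix, regpot: NamedMatrix, vw: VelocityWeights,
               clip_negative: bool = True) -> IntegratedMatrix:
    """Gene activity score combining expression and regulatory potential.

    GAS = x^R + (1+beta)x^A' for positive velocity, x^R + (1-beta)x^A' for
    negative velocity, and x^R + x^A' where velocity is 0.  Negative scores
    are clipped at 0 by default (edges downstream require x_ij > 0).
    """
    if rna.shape != regpot.shape or rna.shape != vw.beta.shape:
        raise ValueError("rna, regulatory potential and velocity weights "
                         "must share shape")
    factor = np.ones_like(vw.beta)
    factor[vw.sign > 0] = 1.0 + vw.beta[vw.sign > 0]
    factor[vw.sign < 0] = 1.0 - vw.beta[vw.sign < 0]
    gas = rna.values + factor * regpot.values
    if clip_negative:
        gas = np.maximum(gas, 0.0)
    return IntegratedMatrix(gas, list(rna.row_names), list(rna.col_names),
                            source="rna_atac")


def joint_gene_filter(rna: NamedMatrix, regpot: NamedMatrix,
                      vel: NamedMatrix, ltmg: LTMGLabels
                      ) -> tuple[NamedMatrix, NamedMatrix, NamedMatrix, LTMGLabels]:
    """Drop genes whose regulatory-potential or velocity row is all zero,
    simultaneously from every aligned matrix."""
    keep = ~(np.all(regpot.values == 0, axis=1) | np.all(vel.values == 0, axis=1))
    idx = np.where(keep)[0]
    if idx.size == 0:
        raise EmptyResultError("joint filter removed all genes")
    return (rna.subset(rows=idx), regpot.subset(rows=idx), vel.subset(rows=idx),
            LTMGLabels(ltmg.labels[idx], ltmg.n_components[idx]))
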