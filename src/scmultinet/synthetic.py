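"""Synthetic multi-omic datasets with known ground truth.

Counts follow a negative binomial with gene-wise Gamma dispersion and
Bernoulli dropout, the standard structure of scRNA-seq simulators.  Cluster
structure is planted by up-shifting a fraction of genes per cluster;
CITE-seq protein counts are correlated with designated coding genes; the
paired RNA/ATAC generator lays genes on a synthetic chromosome, places
peaks at controlled TSS distances (exonic, 10 kb, beyond the 150 kb
truncation), plants TF regulons whose target peaks are accessible only in
the active cluster, and encodes velocity signs in spliced/unspliced ratios.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .io import GeneAnnotation, GenomicInterval, NamedMatrix


@dataclass
class FixtureSpec:
    n_cells: int = 300
    n_genes: int = 500
    n_clusters: int = 3
    n_proteins: int = 30
    n_peaks: int = 140
    n_tfs: int = 3
    n_null_tfs: int = 20
    de_fraction: float = 0.10
    de_fold: float = 8.0
    dropout: float = 0.3
    protein_rho: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_cells, self.n_genes, self.n_clusters) <= 0:
            raise ValueError("sizes must be positive")
        for f in (self.de_fraction, self.dropout):
            if not (0.0 <= f <= 1.0):
                raise ValueError("fractions must be in [0, 1]")


@dataclass
class FixtureTruth:
    cell_labels: dict[str, int] = field(default_factory=dict)
    regulon_map: dict[str, dict] = field(default_factory=dict)
    peak_gene_map: dict[str, str] = field(default_factory=dict)
    velocity_sign_map: dict[str, int] = field(default_factory=dict)
    de_genes: dict[int, list[str]] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)


def _nb_counts(rng: np.random.Generator, mean: np.ndarray,
               dispersion: np.ndarray) -> np.ndarray:
    """Negative binomial via Gamma-Poisson; `dispersion` is 1/size."""
    shape = 1.0 / dispersion
    lam = rng.gamma(shape[:, None] * np.ones_like(mean),
                    mean / shape[:, None])
    return rng.poisson(lam).astype(float)


def _cluster_sizes(n_cells: int, n_clusters: int) -> list[int]:
    base = n_cells // n_clusters
    sizes = [base] * n_clusters
    for i in range(n_cells - base * n_clusters):
        sizes[i] += 1
    return sizes


def make_rna(spec: FixtureSpec) -> tuple[NamedMatrix, FixtureTruth]:
    """Negative-binomial counts with planted clusters.

    Per cluster, `de_fraction` of the genes are up-shifted by `de_fold`;
    dropout is Bernoulli thinning.  de_fold = 1 yields a null dataset with
    no cluster signal.
    """
    if spec.n_clusters < 2:
        raise ValueError("need at least 2 clusters")
    n_de = int(spec.de_fraction * spec.n_genes)
    if n_de < 1:
        raise ValueError("de_fraction * n_genes must be >= 1")
    rng = np.random.default_rng(spec.seed)
    genes = [f"gene{i:04d}" for i in range(spec.n_genes)]
    cells = [f"cell{j:04d}" for j in range(spec.n_cells)]
    base_mean = rng.gamma(2.0, 1.5, size=spec.n_genes)  # skewed baseline
    dispersion = rng.gamma(2.0, 0.15, size=spec.n_genes) + 0.05

    sizes = _cluster_sizes(spec.n_cells, spec.n_clusters)
    labels = np.repeat(np.arange(1, spec.n_clusters + 1), sizes)
    truth = FixtureTruth(cell_labels=dict(zip(cells, labels.tolist())))

    mean = np.tile(base_mean[:, None], (1, spec.n_cells))
    for z in range(1, spec.n_clusters + 1):
        de = rng.choice(spec.n_genes, size=n_de, replace=False)
        truth.de_genes[z] = [genes[i] for i in sorted(de)]
        cols = labels == z
        mean[np.ix_(de, np.where(cols)[0])] *= spec.de_fold
    counts = _nb_counts(rng, mean, dispersion)
    if spec.dropout > 0:
        keep = rng.random(counts.shape) >= spec.dropout
        counts = counts * keep
    return NamedMatrix(counts, genes, cells, "rna"), truth


def make_multi_rna(spec: FixtureSpec, n_batches: int = 2,
                   batch_shift: float = 0.5
                   ) -> tuple[list[NamedMatrix], FixtureTruth]:
    """Split one planted-cluster dataset into batches with an additive
    per-gene log-scale shift, emulating multiple scRNA-seq runs."""
    m, truth = make_rna(spec)
    rng = np.random.default_rng(spec.seed + 1)
    perm = rng.permutation(spec.n_cells)
    parts = np.array_split(perm, n_batches)
    out = []
    for b, idx in enumerate(parts):
        idx = np.sort(idx)
        vals = m.values[:, idx].copy()
        if b > 0:
            shift = rng.gamma(1.0, batch_shift, size=spec.n_genes)
            vals = vals * np.exp(shift)[:, None]
        out.append(NamedMatrix(vals, m.row_names,
                               [m.col_names[j] for j in idx], "rna"))
    return out, truth


def make_cite(spec: FixtureSpec) -> tuple[NamedMatrix, NamedMatrix, FixtureTruth]:
    """Paired gene + surface-protein counts; protein p tracks a designated
    coding gene with correlation ~`protein_rho` plus NB background."""
    rna, truth = make_rna(spec)
    rng = np.random.default_rng(spec.seed + 2)
    coding = rng.choice(spec.n_genes, size=spec.n_proteins, replace=False)
    prots = [f"ADT{p:03d}" for p in range(spec.n_proteins)]
    rho = spec.protein_rho
    signal = rna.values[coding]
    # calibrated correlation: mix the standardized gene signal with
    # independent noise at weight rho / sqrt(1-rho^2), then map back to a
    # count-like non-negative scale
    mu = signal.mean(axis=1, keepdims=True)
    sd = signal.std(axis=1, keepdims=True)
    sd = np.where(sd > 0, sd, 1.0)
    z_s = (signal - mu) / sd
    z_n = rng.normal(0.0, 1.0, size=signal.shape)
    z_p = rho * z_s + np.sqrt(max(1.0 - rho ** 2, 0.0)) * z_n
    vals = np.round(np.maximum(mu + sd * z_p, 0.0))
    truth.regulon_map["protein_coding"] = {
        prots[p]: rna.row_names[coding[p]] for p in range(spec.n_proteins)}
    return rna, NamedMatrix(vals, prots, rna.col_names, "protein"), truth


# ---------------------------------------------------------------------------
# paired RNA + ATAC


GENE_SPACING = 400_000  # bp between TSSs; keeps peak-gene assignment unique
EXON_LEN = 1_500


@dataclass
class RnaAtacFixture:
    rna: NamedMatrix
    atac: NamedMatrix
    peaks: list[GenomicInterval]
    genes: list[GeneAnnotation]
    motif_sites: list[GenomicInterval]
    spliced: NamedMatrix
    unspliced: NamedMatrix
    truth: FixtureTruth


def make_rna_atac(spec: FixtureSpec) -> RnaAtacFixture:
    """Paired scRNA/scATAC data with planted regulons and velocity signs.

    Layout: gene g sits at TSS = g * 400 kb on one chromosome with a single
    1.5 kb exon; every gene has a promoter peak 2 kb upstream of its TSS.
    Gene 0 additionally carries an exonic peak, gene 1 a peak exactly 10 kb
    from the TSS, and gene 2 a peak beyond the 150 kb truncation (weight 0
    by construction).  Each planted TF is active in one cluster: its target
    genes' promoter peaks are accessible (and the genes expressed) mainly
    in that cluster, and high-scoring motif sites overlap those peaks.
    Null TFs get sites on uniformly accessible housekeeping peaks.
    Spliced/unspliced ratios encode a +1/-1 velocity sign per planted gene.
    """
    if spec.n_peaks < spec.n_genes:
        raise ValueError("need n_peaks >= n_genes")
    rng = np.random.default_rng(spec.seed + 3)
    n_g, n_c, n_z = spec.n_genes, spec.n_cells, spec.n_clusters
    gene_names = [f"gene{i:04d}" for i in range(n_g)]
    cells = [f"cell{j:04d}" for j in range(n_c)]
    sizes = _cluster_sizes(n_c, n_z)
    labels = np.repeat(np.arange(1, n_z + 1), sizes)
    truth = FixtureTruth(cell_labels=dict(zip(cells, labels.tolist())))

    # --- annotation: one exon per gene, a few minus-strand genes
    genes: list[GeneAnnotation] = []
    for i in range(n_g):
        tss = 10_000 + i * GENE_SPACING
        strand = "-" if i % 10 == 9 else "+"
        if strand == "+":
            exon = GenomicInterval("chr1", tss, tss + EXON_LEN)
            g = GeneAnnotation(gene_names[i], "chr1", tss, [exon], "+")
        else:
            exon = GenomicInterval("chr1", tss - EXON_LEN, tss)
            g = GeneAnnotation(gene_names[i], "chr1", tss, [exon], "-")
        genes.append(g)

    # --- peaks: promoter peak per gene + controlled special cases
    peaks: list[GenomicInterval] = []
    peak_owner: list[int] = []  # gene index a peak belongs to (-1: none)
    for i, g in enumerate(genes):
        lo = g.tss - 2_250 if g.strand == "+" else g.tss + 1_750
        peaks.append(GenomicInterval("chr1", lo, lo + 500,
                                     f"chr1:{lo}-{lo + 500}"))
        peak_owner.append(i)
    special = []
    if n_g > 3:
        e0 = genes[0].exons[0]
        special.append((GenomicInterval("chr1", e0.start + 100, e0.start + 600), 0))
        t1 = genes[1].tss
        special.append((GenomicInterval("chr1", t1 + 9_750, t1 + 10_250), 1))
        t2 = genes[2].tss
        special.append((GenomicInterval("chr1", t2 + 150_500, t2 + 151_000), 2))
    for iv, owner in special:
        iv.name = f"chr1:{iv.start}-{iv.end}"
        peaks.append(iv)
        peak_owner.append(owner)
    while len(peaks) < spec.n_peaks:  # intergenic filler peaks
        pos = int(rng.integers(n_g * GENE_SPACING + 500_000,
                               n_g * GENE_SPACING + 5_000_000))
        iv = GenomicInterval("chr1", pos, pos + 500, f"chr1:{pos}-{pos + 500}")
        peaks.append(iv)
        peak_owner.append(-1)
    for k, iv in enumerate(peaks):
        if peak_owner[k] >= 0:
            truth.peak_gene_map[iv.name] = gene_names[peak_owner[k]]

    # --- planted regulons: TF z active in cluster z with 6 target genes
    n_per_tf = 10
    planted: dict[str, dict] = {}
    used: set[int] = set()
    for t in range(spec.n_tfs):
        z = (t % n_z) + 1
        targets = [t * n_per_tf + u + 4 for u in range(n_per_tf)]  # skip 0-3
        targets = [g for g in targets if g < n_g]
        used.update(targets)
        planted[f"TF{t:02d}"] = {"cluster": z,
                                 "targets": [gene_names[g] for g in targets]}
    truth.regulon_map = planted

    # --- expression: baseline + cluster activation of planted targets;
    # regulon targets are silent outside their active cluster (the regulon
    # is switched on by its TF only there)
    base_mean = rng.gamma(2.0, 1.5, size=n_g)
    dispersion = rng.gamma(2.0, 0.15, size=n_g) + 0.05
    mean = np.tile(base_mean[:, None], (1, n_c))
    n_de = max(1, int(spec.de_fraction * n_g))
    tf_clusters = {info["cluster"] for info in planted.values()}
    all_de: set[int] = set()
    for z in range(1, n_z + 1):
        # every cluster carries a background of moderately differential
        # genes (half fold) for cluster identity; in clusters with a
        # planted TF the strongly differential program is the regulon
        de = sorted(rng.choice([i for i in range(n_g) if i not in used],
                               size=n_de, replace=False))
        all_de.update(de)
        cols = np.where(labels == z)[0]
        fold = spec.de_fold / 2 if z in tf_clusters else spec.de_fold
        mean[np.ix_(de, cols)] *= fold
        regulon = sorted(g for tf, info in planted.items()
                         if info["cluster"] == z for g in info["targets"])
        truth.de_genes[z] = sorted(set([gene_names[i] for i in de] + regulon))
    # regulon activity is bursty per cell but coordinated across the
    # regulon: the TF switches its whole target set on in ~60% of the
    # active-cluster cells, with 10% per-gene noise.  The shared mask keeps
    # target profiles strongly correlated (they are one regulatory unit)
    # while no single target covers every cluster cell.
    target_mask: dict[int, np.ndarray] = {}
    for tf, info in planted.items():
        cols = np.where(labels == info["cluster"])[0]
        other = np.where(labels != info["cluster"])[0]
        tf_on = rng.random(cols.size) < 0.6
        for gname in info["targets"]:
            i = gene_names.index(gname)
            on = tf_on ^ (rng.random(cols.size) < 0.1)
            target_mask[i] = np.zeros(n_c, dtype=bool)
            target_mask[i][cols[on]] = True
            # burst-off cells keep baseline expression; true silence only
            # outside the active cluster
            mean[i, cols] = np.where(on, base_mean[i] * spec.de_fold,
                                     base_mean[i])
            mean[i, other] = 0.02
    rna_counts = _nb_counts(rng, mean, dispersion)
    if spec.dropout > 0:
        rna_counts *= rng.random(rna_counts.shape) >= spec.dropout

    # --- accessibility: promoter peaks mirror their gene's activity
    atac_mean = np.full((len(peaks), n_c), 0.5)
    for k, owner in enumerate(peak_owner):
        if owner >= 0:
            atac_mean[k] = 0.3 + 0.4 * mean[owner] / mean[owner].max()
    for tf, info in planted.items():
        cluster_cells = np.isin(labels, [info["cluster"]])
        for gname in info["targets"]:
            k = gene_names.index(gname)  # promoter peak index == gene index
            on = target_mask[k]
            # regulon promoters stay poised (half-open) in burst-off cells
            # of the active cluster and close outside it
            atac_mean[k, on] = 4.0
            atac_mean[k, cluster_cells & ~on] = 2.0
            atac_mean[k, ~cluster_cells] = 0.05
    atac_disp = np.full(len(peaks), 0.3)
    atac_counts = _nb_counts(rng, atac_mean, atac_disp)

    # --- motif sites
    sites: list[GenomicInterval] = []
    for tf, info in planted.items():
        for gname in info["targets"]:
            pk = peaks[gene_names.index(gname)]
            sites.append(GenomicInterval(pk.chrom, pk.start + 100,
                                         pk.start + 115, tf, 999.0))
    # null TFs bind disjoint housekeeping peak sets so their specificity
    # tests are statistically independent of one another
    housekeeping = [k for k, o in enumerate(peak_owner)
                    if o >= 0 and o not in used and o not in all_de]
    rng.shuffle(housekeeping)
    per_null = max(2, len(housekeeping) // max(spec.n_null_tfs, 1))
    for t in range(spec.n_null_tfs):
        tf = f"NULLTF{t:02d}"
        picks = housekeeping[t * per_null:(t + 1) * per_null]
        if len(picks) < 2:  # wrap around only if the pool is exhausted
            picks = (housekeeping * 2)[t * 2:t * 2 + 2]
        for k in picks:
            pk = peaks[int(k)]
            off = 120 + 20 * (t % 10)
            sites.append(GenomicInterval(pk.chrom, pk.start + off,
                                         pk.start + off + 15, tf, 900.0))

    # --- velocity signs via spliced/unspliced (steady-state gamma = 0.5)
    spliced = rna_counts.copy()
    unspliced = 0.5 * spliced
    for i in range(3, min(n_g, 3 + 40)):
        sign = +1 if i % 2 else -1
        truth.velocity_sign_map[gene_names[i]] = sign
        if sign > 0:
            unspliced[i] = 0.5 * spliced[i] + 2.0
        else:
            unspliced[i] = np.maximum(0.5 * spliced[i] - 2.0, 0.0)
    unspliced = np.round(unspliced)

    peak_names = [p.name for p in peaks]
    return RnaAtacFixture(
        rna=NamedMatrix(rna_counts, gene_names, cells, "rna"),
        atac=NamedMatrix(atac_counts, peak_names, cells, "atac_peak"),
        peaks=peaks,
        genes=genes,
        motif_sites=sites,
        spliced=NamedMatrix(spliced, gene_names, cells, "rna"),
        unspliced=NamedMatrix(unspliced, gene_names, cells, "rna"),
        truth=truth,
    )


def write_fixture_dir(fix: RnaAtacFixture, outdir: str | Path) -> None:
    """Write a complete rna_atac input directory (MTX + BED + GTF + JSON)."""
    from .io import write_bed, write_mtx

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_mtx(fix.rna, outdir / "rna")
    write_mtx(fix.atac, outdir / "atac")
    write_mtx(fix.spliced, outdir / "spliced")
    write_mtx(fix.unspliced, outdir / "unspliced")
    write_bed(fix.peaks, outdir / "peaks.bed")
    write_bed(fix.motif_sites, outdir / "motifs.bed")
    with open(outdir / "genes.gtf", "w") as fh:
        for g in fix.genes:
            span = g.span
            attrs = f'gene_id "{g.gene_id}";'
            fh.write("\t".join(["chr1", "synthetic", "gene", str(span[0] + 1),
                                str(span[1]), ".", g.strand, ".", attrs]) + "\n")
            for e in g.exons:
                fh.write("\t".join(["chr1", "synthetic", "exon",
                                    str(e.start + 1), str(e.end), ".",
                                    g.strand, ".", attrs]) + "\n")
    fix.truth.to_json(outdir / "truth.json")
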