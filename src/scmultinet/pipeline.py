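"""End-to-end pipeline orchestration.

``run_pipeline`` executes preprocess -> graph -> transformer -> clustering
-> gene networks (-> GRN for paired RNA/ATAC) and writes labels,
embeddings, attention, networks, regulons, metrics and a run manifest.
Stage seeds fan out deterministically from the master seed.
"""

from __future__ import annotations

import json
import time
import warnings
from dataclasses import asdict, dataclass, field
from itertools import product
from pathlib import Path

import numpy as np

from . import cluster as cl
from . import grn as grnmod
from . import hgt as hgtmod
from . import io as iomod
from . import metrics as metricsmod
from . import networks as netmod
from . import preprocess as pp
from .graph import build_graph, init_embeddings

DATA_TYPES = ("multi_rna", "cite", "rna_atac")


@dataclass
class RunConfig:
    data_type: str = "multi_rna"
    seed: int = 0
    output_dir: str | None = None
    # preprocessing
    qc_min_nonzero_fraction: float = 0.001
    hvg_n: int = 2000
    cca_n_components: int = 20
    ltmg_max_components: int = 5
    gas_beta_mode: str = "normalized"  # normalized | literal
    gas_clip_negative: bool = True
    # embeddings / HGT
    ae_hidden: int = 512
    ae_dim: int = 256
    ae_epochs: int = 100
    n_layers: int = 2
    n_heads: int = 16
    hgt_dim: int = 256
    learning_rate: float = 1e-4
    epochs_per_subgraph: int = 100
    n_subgraphs: int = 50
    coverage_fraction: float = 0.30
    residual_convention: str = "standard"
    # clustering
    knn_k: int = 20
    resolution: float = 0.4
    cluster_method: str = "louvain"
    # stage toggles
    run_networks: bool = True
    run_grn: bool = True

    def __post_init__(self) -> None:
        if self.data_type not in DATA_TYPES:
            raise ValueError(f"data_type must be one of {DATA_TYPES}")

    def stage_seed(self, k: int) -> int:
        return int(np.random.SeedSequence([self.seed, k]).generate_state(1)[0]
                   % (2 ** 31))

    def hgt_config(self) -> hgtmod.HGTConfig:
        return hgtmod.HGTConfig(
            n_layers=self.n_layers, n_heads=self.n_heads, d=self.hgt_dim,
            learning_rate=self.learning_rate,
            epochs_per_subgraph=self.epochs_per_subgraph,
            n_subgraphs=self.n_subgraphs,
            coverage_fraction=self.coverage_fraction,
            seed=self.stage_seed(3),
            residual_convention=self.residual_convention)


@dataclass
class PipelineResult:
    X: pp.IntegratedMatrix
    labels: cl.ClusterLabeling
    embedding: np.ndarray  # stacked genes+cells
    n_genes: int
    attention: hgtmod.AttentionMatrix
    loss_trace: list[float]
    networks: dict[int, netmod.GeneNetwork] = field(default_factory=dict)
    regulons: list = field(default_factory=list)
    master_tfs: dict[int, list] = field(default_factory=dict)
    metrics: dict = field(default_factory=dict)
    manifest: dict = field(default_factory=dict)

    @property
    def cell_embedding(self) -> np.ndarray:
        return self.embedding[self.n_genes:]

    @property
    def gene_embedding(self) -> np.ndarray:
        return self.embedding[: self.n_genes]


def integrate(config: RunConfig, **inputs) -> pp.IntegratedMatrix:
    """Dispatch the data-type-specific integration path."""
    qc = pp.QCParams(min_nonzero_fraction=config.qc_min_nonzero_fraction)
    if config.data_type == "multi_rna":
        mats = inputs["matrices"]
        prepped = [pp.select_hvg(pp.log_normalize(pp.qc_filter(m, qc)),
                                 config.hvg_n) for m in mats]
        return pp.cca_align(prepped, n_components=config.cca_n_components,
                            seed=config.stage_seed(1))
    if config.data_type == "cite":
        rna = pp.qc_filter(inputs["rna"], qc)
        protein = inputs["protein"]
        common = [c for c in rna.col_names if c in set(protein.col_names)]
        rna = rna.subset(cols=[rna.col_index()[c] for c in common])
        protein = protein.subset(
            cols=[protein.col_index()[c] for c in common])
        return pp.integrate_cite(rna, protein, n_hvg=config.hvg_n)
    return _integrate_rna_atac(config, **inputs)


def _integrate_rna_atac(config: RunConfig, *, rna, atac, peaks, genes,
                        velocity=None, spliced=None, unspliced=None,
                        **_ignored):
    qc = pp.QCParams(min_nonzero_fraction=config.qc_min_nonzero_fraction)
    rna_q = pp.qc_filter(rna, qc)
    atac_q = pp.qc_filter(atac, qc)
    common = [c for c in rna_q.col_names if c in set(atac_q.col_names)]
    rna_q = rna_q.subset(cols=[rna_q.col_index()[c] for c in common])
    atac_q = atac_q.subset(cols=[atac_q.col_index()[c] for c in common])
    rna_n = pp.log_normalize(rna_q)

    gene_ann = [g for g in genes if g.gene_id in set(rna_n.row_names)]
    peak_by_name = {p.name: p for p in peaks}
    kept_peaks = [peak_by_name.get(n) or iomod.parse_peak_name(n)
                  for n in atac_q.row_names]
    w = pp.peak_gene_weights(kept_peaks, gene_ann)
    regpot = pp.regulatory_potential(atac_q, w, [g.gene_id for g in gene_ann])

    ridx = [rna_n.row_index()[g.gene_id] for g in gene_ann]
    rna_al = rna_n.subset(rows=ridx)
    ltmg = pp.ltmg_discretize(rna_al, config.ltmg_max_components,
                              seed=config.stage_seed(2))
    if velocity is None:
        if spliced is None or unspliced is None:
            raise ValueError("need velocity or spliced+unspliced matrices")
        sidx = [spliced.row_index()[g.gene_id] for g in gene_ann]
        cidx = [spliced.col_index()[c] for c in rna_al.col_names]
        velocity = pp.steady_state_velocity(
            spliced.subset(rows=sidx, cols=cidx),
            unspliced.subset(rows=sidx, cols=cidx))
    else:
        vidx = [velocity.row_index()[g.gene_id] for g in gene_ann]
        cidx = [velocity.col_index()[c] for c in rna_al.col_names]
        velocity = velocity.subset(rows=vidx, cols=cidx)

    rna_f, regpot_f, vel_f, ltmg_f = pp.joint_gene_filter(
        rna_al, regpot, velocity, ltmg)
    vw = pp.velocity_weights(vel_f, ltmg_f,
                             normalize=config.gas_beta_mode == "normalized")
    X = pp.gas_matrix(rna_f, regpot_f, vw,
                      clip_negative=config.gas_clip_negative)
    # stash the aligned pieces the GRN stage needs
    kept = [i for i, g in enumerate(gene_ann)
            if g.gene_id in set(X.row_names)]
    X.grn_inputs = {  # type: ignore[attr-defined]
        "w": w[kept, :], "atac": atac_q, "peaks": kept_peaks}
    return X


def run_pipeline(config: RunConfig, benchmark_labels: dict[str, int] | None = None,
                 motif_sites=None, **inputs) -> PipelineResult:
    """Execute the full pipeline for one data type.

    Stage failures after clustering degrade gracefully: partial results are
    retained and the manifest records the failure point.
    """
    manifest: dict = {"config": asdict(config), "stages": {}, "versions": {
        "numpy": np.__version__}}
    t0 = time.time()

    def mark(stage):
        manifest["stages"][stage] = round(time.time() - t0, 3)

    X = integrate(config, **inputs)
    mark("integrate")

    graph = build_graph(X)
    emb0 = init_embeddings(X, d_hidden=config.ae_hidden, d_out=config.ae_dim,
                           epochs=config.ae_epochs,
                           seed=config.stage_seed(0))
    mark("init_embeddings")

    result = hgtmod.train_gae(graph, emb0, config.hgt_config())
    mark("train")

    labels = cl.cluster_cells(result.embedding.cells, graph.cell_nodes,
                              k=min(config.knn_k, graph.n_cells - 1),
                              resolution=config.resolution,
                              seed=config.stage_seed(4),
                              method=config.cluster_method)
    mark("cluster")

    out = PipelineResult(
        X=X, labels=labels, embedding=result.embedding.embedding,
        n_genes=graph.n_genes, attention=result.attention,
        loss_trace=result.loss_trace, manifest=manifest)

    out.metrics = _clustering_metrics(out, benchmark_labels)
    mark("metrics")

    if config.run_networks:
        for z in range(1, labels.Z + 1):
            try:
                aug = netmod.build_augmented_graph(
                    result.embedding.genes, graph.gene_nodes,
                    result.attention, graph.cell_nodes, labels, z)
                sol = netmod.solve_sfp(aug)
                out.networks[z] = netmod.extract_network(aug, sol, z)
            except netmod.EmptyGraphError as exc:
                warnings.warn(f"cluster {z}: {exc}")
                manifest.setdefault("failures", []).append(
                    {"stage": "networks", "cluster": z, "error": str(exc)})
        mark("networks")

    if config.run_grn and config.data_type == "rna_atac" and motif_sites:
        grn_in = getattr(X, "grn_inputs", None)
        if grn_in is None:
            manifest.setdefault("failures", []).append(
                {"stage": "grn", "error": "missing GRN inputs"})
        else:
            affinity = grnmod.binding_affinity(motif_sites, grn_in["peaks"])
            ri = grnmod.ri_score(affinity, grn_in["w"], grn_in["atac"])
            regs = grnmod.assemble_regulons(out.networks, ri, X.row_names,
                                            labels, X.col_names)
            out.regulons = grnmod.ctsr_test(regs, X, ri, labels)
            for z in range(1, labels.Z + 1):
                out.master_tfs[z] = grnmod.master_tfs(out.regulons, ri, X,
                                                      labels, z)
        mark("grn")

    if config.output_dir:
        _write_outputs(out, config)
        mark("write")
    return out


def _clustering_metrics(res: PipelineResult,
                        benchmark: dict[str, int] | None) -> dict:
    emb = res.cell_embedding
    cells = res.X.col_names
    pred = res.labels.labels_for(cells)
    out: dict = {"n_clusters": int(res.labels.Z)}
    if res.labels.Z >= 2:
        out["asw"] = metricsmod.asw(emb, pred)
        out["ch"] = metricsmod.calinski_harabasz(emb, pred)
        out["dbi"] = metricsmod.davies_bouldin(emb, pred)
    if benchmark is not None:
        truth = np.array([benchmark[c] for c in cells])
        out["ari"] = metricsmod.ari(pred, truth)
    return out


def _write_outputs(res: PipelineResult, config: RunConfig) -> None:
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    iomod.write_labels(res.labels.assignment, outdir / "labels.tsv")
    names = res.X.row_names + res.X.col_names
    with open(outdir / "embeddings.tsv", "w") as fh:
        for name, row in zip(names, res.embedding):
            fh.write(name + "\t" + "\t".join(f"{v:.6g}" for v in row) + "\n")
    att = iomod.NamedMatrix(res.attention.scores, res.X.row_names,
                            res.X.col_names, "gas")
    iomod.write_mtx(att, outdir / "attention")
    with open(outdir / "loss_trace.tsv", "w") as fh:
        fh.write("iteration\tloss\n")
        for i, v in enumerate(res.loss_trace):
            fh.write(f"{i}\t{v:.8g}\n")
    for z, net in res.networks.items():
        iomod.write_edge_list(net.edges, outdir / f"network_cluster{z}.tsv",
                              header=("gene1", "gene2", "weight"))
    if res.regulons:
        with open(outdir / "regulons.tsv", "w") as fh:
            fh.write("cluster\ttf\tn_targets\tras\tadj_p\tlogfc\tctsr\n")
            for r in res.regulons:
                fh.write(f"{r.cluster}\t{r.tf}\t{len(r.targets)}\t"
                         f"{r.ras:.6g}\t{r.adj_p:.6g}\t{r.logfc:.6g}\t"
                         f"{int(r.ctsr)}\n")
    res.manifest["metrics"] = {k: float(v) if np.isscalar(v) else v
                               for k, v in res.metrics.items()}
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(res.manifest, fh, indent=1, default=str)


def enumerate_grid(embed_head_pairs=((91, 13), (104, 13), (112, 16), (128, 16)),
                   learning_rates=(1e-4, 1e-3, 1e-2),
                   epoch_settings=(50, 75, 100)) -> list[dict]:
    """Cartesian product of tuning axes in deterministic order."""
    if not (embed_head_pairs and learning_rates and epoch_settings):
        raise ValueError("grid axes must be non-empty")
    grid = []
    for (d, h), lr, ep in product(embed_head_pairs, learning_rates,
                                  epoch_settings):
        grid.append({"d": d, "n_heads": h, "learning_rate": lr,
                     "epochs_per_subgraph": ep})
    return grid
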