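# scmultinet

Cell-type-specific biological network inference from single-cell
multi-omics data with a heterogeneous graph transformer.

Single-cell multi-omics assays (multiple scRNA-seq runs, CITE-seq, paired
scRNA+scATAC-seq) measure several molecular layers of the same cells, but
most integration tools stop at cell clustering. `scmultinet` models the
integrated data as a bipartite **cell–gene heterogeneous graph** and learns
joint cell/gene embeddings plus explicit gene-to-cell attention scores, from
which it derives (i) cell clusters, (ii) cell-cluster-active gene
association networks via a Steiner Forest model, and (iii) cell-type-specific
gene regulatory networks (regulons with regulatory-intensity and
regulon-activity scores).

## Model

**Integration.** Each data type gets its own path to a features × cells
matrix `X`:

- multiple scRNA-seq: log-normalization, top-2000 highly variable genes,
  canonical-correlation alignment of batches;
- CITE-seq: log-normalization of genes and surface proteins, vertical
  concatenation, per-cell centered log-ratio transform
  `CLR(x_ij) = log(1 + x_ij / exp(Σ_{i∈Z_j} log(1+x_ij)/|Z_j|))`;
- paired RNA+ATAC: peak accessibility is turned into per-gene regulatory
  potential with the MAESTRO-style distance decay
  `w_ik = 2^(−d_ik/d₀)` (`d₀` = 10 kb, truncation at 150 kb, exonic peaks
  weighted `1/exon length`), and combined with expression through
  rank-based RNA-velocity weights into a gene activity score (GAS):
  `x^G = x^R + (1±β^±)·x^{A'}`.

**Graph and embeddings.** An edge connects gene *i* and cell *j* whenever
`x_ij > 0`. Initial 256-dimensional node embeddings come from two dense
autoencoders (cells over gene profiles, genes over cell profiles). A
two-layer heterogeneous graph transformer (HGT) — per-node-type Q/K/V
projections, per-meta-relation attention/message transforms with a prior
scalar μ, multi-head softmax attention over each target's neighborhood, and
a gated residual update `H^l = θ·ReLU(H̃^l) + (1−θ)·H^{l−1}` — is trained
as a graph autoencoder: the decoder is the embedding inner product and the
loss is the KL divergence between the column-softmaxed input and its
reconstruction, optimized on sampled subgraphs covering ≥30% of nodes.

**Downstream.** Cells are clustered by Louvain on an SNN graph of the final
cell embeddings (resolution 0.4). Per cluster, an augmented graph keeps
gene–gene edges with embedding correlation > 0.5 and gene–cell edges with
attention above mean+sd; a 2-approximate Steiner Forest over the
inverted-normalized weights yields the cluster-active gene association
network. TF binding sites (JASPAR convention, score ≥ 500) intersected with
peaks give binding affinities `b = score/100`; regulatory intensity
`s_ij|q = Σ_k b_qk·w_ik·x^A_kj` defines per-cluster regulons, scored by the
regulon activity score (RAS) and tested for cell-type specificity
(one-vs-rest Wilcoxon, BH-adjusted p < 0.05, log₂ fold change > 0.10).
Master TFs are ranked by eigenvector centrality of the merged cluster GRN.

The evaluation-metric suite (ARI, average silhouette width,
Calinski–Harabasz, Davies–Bouldin, closeness and eigenvector centrality) is
implemented from the definitions and cross-checked against independent
oracles in the test suite.

## Worked example

Simulate a paired RNA+ATAC dataset with 3 planted cell clusters and 3
planted regulons (plus 20 inactive decoy TFs), then run the full pipeline:

```bash
scmultinet simulate --data-type rna_atac --out demo/input \
    --n-cells 300 --n-genes 120 --n-clusters 3 --seed 11
scmultinet run --data-type rna_atac --input-dir demo/input \
    --out demo/out --seed 11 --n-subgraphs 1 --epochs-per-subgraph 100
```

The run prints the clustering metrics against the planted labels:

```json
{
 "n_clusters": 3.0,
 "asw": 0.1757,
 "ch": 54.6093,
 "dbi": 1.9683,
 "ari": 1.0
}
```

ARI 1.0 means every cell was assigned to its planted cluster; ASW/CH/DBI
describe the compactness of the learned embedding. `demo/out/regulons.tsv`
holds the regulon table:

```
cluster	tf	n_targets	ras	adj_p	logfc	ctsr
1	TF00	5	339.134	7.41424e-53	9.24682	1
2	TF01	6	255.002	4.30178e-51	8.90575	1
3	TF02	7	209.904	4.30178e-51	8.7249	1
```

Each planted TF is recovered as a cell-type-specific regulon (`ctsr = 1`)
in exactly its planted cluster, with strongly positive activity fold
changes; none of the 20 decoy TFs is called. The output directory also
contains the cell labels, node embeddings, the gene-to-cell attention
matrix (MatrixMarket), per-cluster gene association networks and a
manifest sufficient to reproduce the run bit-identically.

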