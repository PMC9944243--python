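# Methods

This note documents the models, the numerical choices behind them, what the
synthetic test bed does and does not emulate, and known limitations.

## Integration paths

All three paths end in a non-negative features × cells matrix `X`; one
edge of the heterogeneous graph exists per strictly positive entry.

**Quality control.** A row or column is removed when strictly less than
0.1% of its entries are non-zero (`qc.min_nonzero_fraction`, default
0.001); filtering iterates to a fixed point so it is idempotent. Total-count
and mitochondrial-fraction thresholds exist but are off by default — they
are named by the protocol this package follows without published cutoffs.

**Multiple scRNA-seq.** Per batch: depth normalization to 10,000 counts,
log1p, top-2000 genes by bin-standardized dispersion (all genes when fewer
exist). Alignment is a basic anchor-free CCA: cell embeddings from the SVD
of the standardized cross-batch product against the largest batch, k-means
grouping (default 5 groups) in that shared space, and removal of each
batch's per-group per-gene mean offset, clipped at zero. Identical batches
pass through unchanged; a constant additive batch shift is removed
entirely. This deliberately does not re-implement anchor weighting or
mutual-nearest-neighbor matching.

**CITE-seq.** Genes and proteins are log-normalized, stacked, and CLR-
transformed per cell against the geometric mean of `1+x` over the cell's
non-zero features; zeros map exactly to zero so sparsity is preserved.

**Paired RNA+ATAC.** Peaks map to genes with the exponential
regulatory-potential decay (half-decay 10 kb, hard zero beyond 150 kb from
the TSS, weight `1/exon_length` for exon-overlapping peaks, zero when the
peak center falls in a different gene's transcript span — the only reading
that distinguishes this case from the exon case). Distances are unsigned;
strand affects only TSS placement. Expression is discretized per gene by a
BIC-selected Gaussian mixture (≤5 components, tol 1e-4, ≤200 EM
iterations, seeded) on the non-zero log values; zero observations are
treated as left-censored and assigned the lowest-mean component, and genes
detected in fewer than 5 cells are not fitted. Velocity (supplied, or
estimated as `v = u − γs` with γ fitted through the origin on the top-5%
cells by `s+u`) is smoothed to the mean within each (gene,
discretization-label) group, then converted to rank-based weights:
for positive entries `β⁺ = sqrt((|P_i|−a−1)² + (|P_j|−b−1)²)` with
descending ranks from 1; negative entries use the symmetric form with
ranks from 0 over |velocity| (the printed form of the negative branch is
corrupted in the source description; the symmetric completion is used).
Because β grows with matrix size, the default mode normalizes it by
`sqrt(|P_i|² + |P_j|²)` into [0, √2] and clips negative GAS at zero so the
edge rule `x_ij > 0` stays meaningful; `beta_mode="literal"` reproduces
the unnormalized formula.

## Graph transformer

**Initial embeddings.** Two dense autoencoders (input → 512 → 256 → 512 →
input, ReLU hidden, linear output, MSE, Adam 1e-3, 100 epochs full-batch,
seeded) embed cells (over gene profiles) and genes (over cell profiles).
Inputs are centered per feature (markedly faster Adam convergence). A
single random restart leaves init-dependent noise in the bottleneck's
local neighborhoods — enough to perturb kNN graphs — so three seeded
restarts are trained and their rescaled bottlenecks concatenated and
SVD-reduced back to the target width; the result is centered and divided
by its global coordinate scale so downstream attention logits and inner
products stay in a benign range.

**HGT layer.** Per node type: Q/K/V projections (no bias) split into H
heads; per meta-relation (gene→cell, cell→gene): a d/H × d/H attention
transform, a message transform (both initialized as identity plus N(0,
0.01²) noise) and a trainable prior scalar μ (init 1). Attention logits
`K W_att Qᵀ · μ/√d` are softmaxed over each target's neighbors
independently per head (the standard contract that makes per-neighborhood
weights meaningful). Aggregation is attention-weighted message summation
with the gated residual `H^l = θ·ReLU(H̃) + (1−θ)·H^{l−1}` (θ trainable,
init 0.5). The printed source formula carries a (θ−1) residual
coefficient, which makes the residual negative; the `standard` convention
above is the default and `aggregation.residual_convention="paper"`
reproduces the printed sign. Two layers are used.

**Training.** Subgraphs of ⌈0.3·I/n⌉ genes × ⌈0.3·J/n⌉ cells are sampled
(cells from a cycling permutation, neighbor genes per target cell without
replacement with probability `x_ij/Σx`), resampling up to 10 times until
the union covers 30% of both node sets. The graph autoencoder decodes
`X̂ = H[genes]·H[cells]ᵀ` and minimizes the KL divergence between the
per-cell-column softmax of `X` and of `X̂`, with the data as the reference
distribution — the cross-entropy-style direction every deep-learning
KL-divergence loss computes. The reverse direction is mode-seeking: it can
be minimized by reconstructing only each cell's top gene, and in practice
collapses the embedding geometry. Optimizer state persists across
subgraphs; early stop per subgraph when the relative loss change stays
below 1e-4 for 5 epochs ("loss restrained"); the trained model is then
applied to the whole graph. Default schedule: 50 subgraphs × 100 epochs
(5,000 iterations); the pipeline default learning rate is 1e-4, the most
conservative value of the method's own grid {1e-4, 1e-3, 1e-2} — at small
problem sizes larger rates trade embedding geometry for reconstruction
well before the epoch cap. The pipeline-level embedding width defaults to
256 to match the autoencoder bottleneck (no lossy input projection);
`HGTConfig` itself defaults to the 112/16 width/heads grid pair.

**Attention extraction.** The final gene-to-cell score is
`a_ij = sqrt(Σ_h att_h(i,j)²)`, the per-head L2 norm of the last layer's
softmax-normalized gene→cell attention, defined only on graph edges.

Determinism holds per device: identical seed and configuration give
bit-identical parameters, embeddings and labels across reruns on one
machine.

## Clustering

Shared-nearest-neighbor graph (k = 20 Euclidean neighbors, Jaccard
weights) built in a 10-component PCA reduction of the cell embeddings —
mirroring the Seurat v3 defaults the reference clustering protocol names —
then Louvain at resolution 0.4 (Leiden behind `method="leiden"`). Cluster
ids are renumbered by descending size. A leave-out utility removes one
cluster from every aligned matrix and re-indexes labels contiguously.

## Gene association networks

Per cluster z: gene–gene edges keep Pearson correlations of gene
embeddings strictly above 0.5; gene–cell edges keep attention scores
strictly above mean+sd. The cutoff is computed **per cell** over that
cell's incident scores (default): pooling over the whole cluster lets a
few globally high-attention genes absorb the tail, leaving most cells
edgeless and collapsing the forest to one or two hubs; the per-cell scope
keeps every cell attached to its own most-attended genes.
`threshold_scope="cluster"` restores pooled behavior. Surviving weights
are inverted max-min normalized (largest → 0, smallest → 1).

The Steiner Forest connects every pair of cluster cells through paths with
gene–cell edges at both ends and gene–gene edges inside — cells are path
endpoints only, so two cells are connectable exactly when one connected
component of the gene–gene graph is adjacent to both. Terminals are
grouped accordingly (components claimed greedily by hosted-terminal count,
ties by attachment cost). Within a group the solver takes the cheapest of:
greedy per-terminal attachment plus a Kou/Mehlhorn 2-approximate Steiner
tree over the attachment genes (refined by re-attachment, up to 3 rounds);
the best single shared hub; and leave-one-out variants that forbid each
greedy anchor gene in turn (greedy anchors can be expensive to wire into a
tree). An exhaustive subset-enumeration oracle (connected gene subsets +
cheapest attachments + MST) verifies the heuristic within twice the
optimum on toy graphs; over 1,200 random toys the worst observed ratio was
1.65. The network exported per cluster is the solution's gene set with
original correlation weights and summed cluster attention per gene.

## Gene regulatory networks

Binding sites scoring below 500 on the 0–1000 scale (−log10 p × 100) are
dropped, out-of-range scores clamped with a warning; any base-pair overlap
with a peak contributes `score/100 ∈ [5, 10]` to that (TF, peak) pair, the
strongest site winning per pair. Regulatory intensity multiplies affinity
by the peak→gene weight and accessibility, summed over shared peaks. A
regulon needs at least two targets (singletons are not a module and break
centrality). RAS divides the GAS × RI double sum by |regulon| × |cluster|
by default — the literal all-genes × all-cells denominator (available as
`denominator="global"`) makes the score shrink with dataset size. The
specificity test needs per-cell values, so per-cell activity is the RI-
weighted GAS mean over regulon genes; one-vs-rest Wilcoxon rank-sum
p-values are BH-adjusted across all (TF, cluster) tests and a regulon is
cell-type-specific iff adjusted p < 0.05 and log2 fold change (pseudo-count
1e-9) strictly exceeds 0.10. Clusters under 3 cells are skipped (NA).
Master TFs are the top 10 by eigenvector centrality on the symmetrized
merged GRN (TF→target direction is kept in exports).

## Metrics

ARI is the standard Hubert–Arabie pair-counting form (the printed source
formula is treated as shorthand); CH uses the standard between/within
scatter ratio (the printed between-scatter term contains an obvious typo);
the silhouette uses the signed (n−m)/max(m,n) form. Closeness centrality
substitutes the vertex count for unreachable pairs; eigenvector centrality
is a power iteration with a positive diagonal shift (same eigenvectors;
plain iteration oscillates on bipartite components), L2-normalized.
Every metric is tested against an independent brute-force or library
oracle to 1e-8.

## Synthetic test bed

Counts are negative binomial (Gamma–Poisson with gene-wise Gamma
dispersion) with Bernoulli dropout. The expression fixture plants clusters
by up-shifting a fraction of genes (`de_fraction` 0.10, `de_fold` 8,
dropout 0.3 by default); `de_fold = 1` is an exact null. CITE-seq protein
counts mix the standardized coding-gene signal with independent noise at
the weight that yields the requested correlation. The paired RNA+ATAC
fixture lays one gene per 400 kb with a single exon and a promoter peak
2 kb upstream, plus dedicated exonic, exactly-10-kb and beyond-150-kb
peaks for the weight-function edge cases. Planted regulons behave as
regulatory units: each TF switches its whole target set on in ~60% of its
active cluster's cells (10% per-gene noise), giving strongly correlated
target profiles while no single target covers every cell; burst-off cells
keep baseline expression and poised (half-open) promoters, and outside the
active cluster targets are silent and closed. Null TFs bind disjoint
housekeeping peak sets (owner genes neither targets nor differential) so
their specificity tests are independent. Spliced/unspliced ratios encode
planted velocity signs around a steady-state ratio of 0.5.

What passing tests show — and do not. The generator captures planted
cluster structure, distance-decaying peak–gene geometry, regulon logic and
velocity signs at desk scale (hundreds of cells); it does not model batch
effects, doublets, ambient RNA, trajectory-shaped manifolds, or the
0.8–0.96 zero rates and 10⁴-cell scale of real assays. Recovery on these
fixtures demonstrates that the implementation is faithful and internally
consistent, not that the method attains any particular accuracy on real
tissue.

Problem sizes used by the test suite and the acceptance script — 300
cells × 500 genes for cluster recovery, 300 cells × 120 genes × 145 peaks
with 3 planted and 20 null TFs for regulon recovery, one 30%-coverage
subgraph × 100 epochs for training — are the package's own choices for a
complete, deterministic desk-scale demonstration.

## Known limitations

- The attention scores' ranking of genes within a cell is only weakly
  concentrated at desk scale; the per-cell threshold scope compensates.
  On large graphs trained for the full 5,000-iteration schedule the
  ordering is expected to sharpen.
- Longer GAE training slowly trades cluster geometry for reconstruction
  fidelity; the conservative default learning rate and the per-subgraph
  epoch cap are the operating point, not a converged optimum.
- The CCA alignment removes group-wise mean shifts only; strong nonlinear
  batch effects are out of scope.
- The left-truncated mixture is approximated by censoring zeros rather
  than integrating the truncated likelihood; for genes with high detection
  rates the two agree closely.
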