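import warnings

import numpy as np
import pytest

from scmultinet import pipeline as pl
from scmultinet import synthetic as syn

warnings.filterwarnings("ignore", category=UserWarning)


@pytest.fixture(scope="session")
def rna_fixture():
    """Small planted 3-cluster RNA dataset for unit tests."""
    spec = syn.FixtureSpec(n_cells=120, n_genes=150, n_clusters=3,
                           de_fold=8.0, seed=11)
    return syn.make_rna(spec)


@pytest.fixture(scope="session")
def atac_fixture():
    """Small paired RNA/ATAC fixture with planted regulons."""
    spec = syn.FixtureSpec(n_cells=150, n_genes=60, n_peaks=80, n_clusters=3,
                           de_fold=8.0, n_tfs=2, n_null_tfs=5, seed=7)
    return syn.make_rna_atac(spec)


@pytest.fixture(scope="session")
def integrated_small(rna_fixture):
    m, truth = rna_fixture
    cfg = pl.RunConfig(data_type="multi_rna", seed=11)
    return pl.integrate(cfg, matrices=[m]), truth


@pytest.fixture(scope="session")
def trained_small(integrated_small):
    """One seeded mini HGT training run shared by downstream tests."""
    from scmultinet import hgt as hgtmod
    from scmultinet.graph import build_graph, init_embeddings

    X, truth = integrated_small
    graph = build_graph(X)
    emb0 = init_embeddings(X, d_hidden=128, d_out=64, epochs=60, seed=3)
    cfg = hgtmod.HGTConfig(d=64, n_heads=8, n_subgraphs=1,
                           epochs_per_subgraph=40, seed=3)
    result = hgtmod.train_gae(graph, emb0, cfg)
    return graph, emb0, result, truth


def truth_labels(truth, cells):
    return np.array([truth.cell_labels[c] for c in cells])
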