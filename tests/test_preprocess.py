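import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from scmultinet import preprocess as pp
from scmultinet.io import GeneAnnotation, GenomicInterval, NamedMatrix
from scmultinet.preprocess import (EmptyResultError, LTMGLabels, QCParams,
                                   clr_transform, gas_matrix, log_normalize,
                                   ltmg_discretize, peak_gene_weights,
                                   qc_filter, regulatory_potential,
                                   select_hvg, steady_state_velocity,
                                   velocity_weights)


def nm(vals, modality="rna"):
    vals = np.asarray(vals, dtype=float)
    return NamedMatrix(vals,
                       [f"g{i}" for i in range(vals.shape[0])],
                       [f"c{j}" for j in range(vals.shape[1])], modality)


class TestQC:
    def test_all_zero_gene_removed(self):
        rng = np.random.default_rng(0)
        vals = rng.poisson(2.0, (5, 1000)).astype(float) + 1
        vals[2] = 0.0
        out = qc_filter(nm(vals))
        assert "g2" not in out.row_names
        assert out.shape == (4, 1000)

    def test_threshold_is_strict_less_than(self):
        # gene non-zero in exactly 0.1% of 1000 cells -> retained
        vals = np.ones((3, 1000))
        vals[0] = 0.0
        vals[0, 0] = 5.0  # exactly 1/1000 non-zero
        out = qc_filter(nm(vals), QCParams(min_nonzero_fraction=0.001))
        assert "g0" in out.row_names

    def test_idempotent(self):
        rng = np.random.default_rng(1)
        vals = rng.poisson(0.5, (40, 60)).astype(float)
        once = qc_filter(nm(vals), QCParams(min_nonzero_fraction=0.2))
        twice = qc_filter(once, QCParams(min_nonzero_fraction=0.2))
        np.testing.assert_array_equal(once.values, twice.values)
        assert once.row_names == twice.row_names

    def test_empty_result_error(self):
        with pytest.raises(EmptyResultError):
            qc_filter(nm(np.zeros((3, 3))))


class TestLogNormalize:
    def test_hand_example(self):
        out = log_normalize(nm([[10.0], [0.0]]), scale=10)
        assert out.values[0, 0] == pytest.approx(np.log(11))
        assert out.values[1, 0] == 0.0

    def test_depth_invariance(self):
        base = np.array([[1.0, 2.0], [3.0, 4.0]])
        a = log_normalize(nm(base))
        b = log_normalize(nm(base * np.array([2.0, 5.0])))  # per-cell scaling
        np.testing.assert_allclose(a.values, b.values)

    def test_column_sums_restored(self):
        rng = np.random.default_rng(2)
        out = log_normalize(nm(rng.poisson(3.0, (20, 10)) + 1.0), scale=1e4)
        np.testing.assert_allclose(np.expm1(out.values).sum(axis=0),
                                   1e4, rtol=1e-10)

    def test_zero_column_error(self):
        with pytest.raises(EmptyResultError):
            log_normalize(nm([[0.0, 1.0], [0.0, 1.0]]))


class TestHvg:
    def test_fewer_genes_than_n_keeps_all(self):
        m = nm(np.random.default_rng(0).random((50, 20)))
        assert select_hvg(m, 2000).shape == (50, 20)

    def test_constant_gene_ranks_last(self):
        rng = np.random.default_rng(3)
        vals = rng.random((30, 40)) * 5
        vals[7] = 2.0  # constant
        out = select_hvg(nm(vals), 29)
        assert "g7" not in out.row_names

    def test_single_spike_gene_selected_at_n1(self):
        rng = np.random.default_rng(4)
        vals = np.abs(rng.normal(1.0, 0.01, (20, 50)))
        vals[5] = rng.choice([0.0, 9.0], size=50)  # huge dispersion
        out = select_hvg(nm(vals), 1)
        assert out.row_names == ["g5"]

    def test_invalid_n(self):
        with pytest.raises(ValueError):
            select_hvg(nm(np.ones((3, 3))), 0)


class TestCCA:
    def test_identical_batches_pass_through(self):
        rng = np.random.default_rng(5)
        vals = rng.random((40, 25)) + 0.1
        m1 = nm(vals)
        m2 = NamedMatrix(vals.copy(), m1.row_names,
                         [f"d{j}" for j in range(25)], "rna")
        out = pp.cca_align([m1, m2], seed=0)
        order = [out.row_names.index(g) for g in m1.row_names]
        np.testing.assert_allclose(out.values[order][:, :25], vals, atol=1e-6)
        np.testing.assert_allclose(out.values[order][:, 25:], vals, atol=1e-6)

    def test_additive_shift_reduced(self):
        rng = np.random.default_rng(6)
        base = rng.random((50, 40)) + 0.5
        shift = rng.random((50, 1)) * 2.0
        m1 = nm(base)
        m2 = NamedMatrix(base + shift, m1.row_names,
                         [f"d{j}" for j in range(40)], "rna")
        out = pp.cca_align([m1, m2], seed=0)
        naive = np.abs((base + shift).mean(axis=1) - base.mean(axis=1)).mean()
        corrected = np.abs(out.values[:, 40:].mean(axis=1)
                           - out.values[:, :40].mean(axis=1)).mean()
        assert corrected <= 0.5 * naive

    def test_single_matrix_pass_through(self):
        m = nm(np.random.default_rng(7).random((30, 10)))
        out = pp.cca_align([m])
        np.testing.assert_array_equal(out.values, m.values)

    def test_too_few_shared_genes(self):
        m1 = nm(np.ones((5, 4)) * 2)
        m2 = nm(np.ones((5, 4)) * 2)
        with pytest.raises(ValueError, match="shared genes"):
            pp.cca_align([m1, m2], min_shared_genes=30)


class TestCLR:
    def test_zero_stays_zero(self):
        out = clr_transform(nm([[0.0, 1.0], [2.0, 3.0]]))
        assert out.values[0, 0] == 0.0

    def test_all_ones_cell(self):
        # geometric mean of (1+1) over non-zero features = 2
        out = clr_transform(nm(np.ones((4, 1))))
        np.testing.assert_allclose(out.values[:, 0], np.log(1.5))

    def test_per_cell_locality(self):
        vals = np.array([[1.0, 2.0], [3.0, 4.0]])
        a = clr_transform(nm(vals))
        scaled = vals.copy()
        scaled[:, 1] *= 7
        b = clr_transform(nm(scaled))
        np.testing.assert_allclose(a.values[:, 0], b.values[:, 0])
        assert not np.allclose(a.values[:, 1], b.values[:, 1])

    def test_empty_cell_error(self):
        with pytest.raises(EmptyResultError):
            clr_transform(nm([[0.0, 1.0], [0.0, 1.0]]))


def make_gene(gid="gA", tss=1_000_000, exon_len=1500, strand="+"):
    return GeneAnnotation(gid, "chr1", tss,
                          [GenomicInterval("chr1", tss, tss + exon_len)],
                          strand)


class TestPeakGeneWeights:
    def test_peak_at_tss_not_exonic(self):
        g = make_gene()
        peak = GenomicInterval("chr1", g.tss - 250, g.tss - 150)  # center -200
        w = peak_gene_weights([peak], [g]).toarray()
        assert w[0, 0] == pytest.approx(2 ** (-200 / 10000))

    def test_half_decay_at_10kb(self):
        g = make_gene()
        peak = GenomicInterval("chr1", g.tss - 10_250, g.tss - 9_750)
        w = peak_gene_weights([peak], [g]).toarray()
        assert w[0, 0] == pytest.approx(0.5)

    def test_truncation_beyond_150kb(self):
        g = make_gene()
        peak = GenomicInterval("chr1", g.tss + 150_001 - 250,
                               g.tss + 150_001 + 250)
        w = peak_gene_weights([peak], [g]).toarray()
        assert w[0, 0] == 0.0

    def test_exonic_peak_weight(self):
        g = make_gene(exon_len=1500)
        peak = GenomicInterval("chr1", g.tss + 100, g.tss + 200)
        w = peak_gene_weights([peak], [g]).toarray()
        assert w[0, 0] == pytest.approx(1 / 1500)

    def test_peak_in_other_gene_body_zeroed(self):
        ga = make_gene("gA", tss=1_000_000)
        gb = make_gene("gB", tss=1_030_000, exon_len=5000)
        peak = GenomicInterval("chr1", 1_031_000, 1_031_200)  # inside gB
        w = peak_gene_weights([peak], [ga, gb]).toarray()
        assert w[0, 0] == 0.0  # gA distal contribution suppressed
        assert w[1, 0] > 0  # gB exon case

    def test_monotone_in_distance(self):
        g = make_gene()
        dists = [2_000, 20_000, 60_000, 120_000]
        peaks = [GenomicInterval("chr1", g.tss + d - 100, g.tss + d + 100)
                 for d in dists]
        w = peak_gene_weights(peaks, [g]).toarray()[0]
        assert all(a > b for a, b in zip(w, w[1:]))


class TestRegulatoryPotential:
    def test_hand_sum(self):
        import scipy.sparse as sp
        w = sp.csr_matrix(np.array([[1.0, 0.5]]))
        atac = nm([[2.0], [4.0]], "atac_peak")
        out = regulatory_potential(atac, w, ["gA"])
        assert out.values[0, 0] == pytest.approx(4.0)

    def test_zero_atac_gives_zero(self):
        import scipy.sparse as sp
        w = sp.csr_matrix(np.ones((2, 3)))
        out = regulatory_potential(nm(np.zeros((3, 4)), "atac_peak"), w,
                                   ["gA", "gB"])
        assert not out.values.any()

    def test_no_mapping_error(self):
        import scipy.sparse as sp
        with pytest.raises(EmptyResultError):
            regulatory_potential(nm(np.ones((2, 2)), "atac_peak"),
                                 sp.csr_matrix((1, 2)), ["gA"])


class TestLTMG:
    def test_single_gaussian_mostly_one_component(self):
        # input contract: log-normalized expression, one regulatory state
        rng = np.random.default_rng(0)
        vals = np.abs(rng.normal(2.0, 0.3, (200, 80)))
        labels = ltmg_discretize(nm(vals), seed=0)
        assert (labels.n_components == 1).mean() >= 0.9

    def test_two_separated_components_recovered(self):
        rng = np.random.default_rng(1)
        lo = rng.normal(1.0, 0.2, (1, 50))
        hi = rng.normal(4.0, 0.2, (1, 50))  # 5+ sigma apart in log space
        vals = np.exp(np.hstack([lo, hi]))
        labels = ltmg_discretize(nm(vals), seed=0)
        assert labels.n_components[0] == 2
        truth = np.array([1] * 50 + [2] * 50)
        agree = (labels.labels[0] == truth).mean()
        assert max(agree, 1 - agree) >= 0.95

    def test_constant_gene(self):
        labels = ltmg_discretize(nm(np.full((1, 30), 2.0)), seed=0)
        assert labels.n_components[0] == 1
        assert (labels.labels[0] == 1).all()

    def test_sparse_gene_skipped(self):
        vals = np.zeros((1, 50))
        vals[0, :3] = [1.0, 2.0, 3.0]
        labels = ltmg_discretize(nm(vals), seed=0, min_cells=5)
        assert labels.n_components[0] == 1


class TestVelocityWeights:
    def _ltmg_identity(self, shape):
        return LTMGLabels(np.ones(shape, dtype=int), np.ones(shape[0], int))

    def test_single_positive_entry_literal_beta(self):
        vel = nm(np.array([[3.0]]), "velocity")
        vw = velocity_weights(vel, self._ltmg_identity((1, 1)),
                              normalize=False)
        assert vw.beta[0, 0] == pytest.approx(np.sqrt(2.0))
        assert vw.sign[0, 0] == 1

    def _ltmg_distinct(self, shape):
        # one label per cell: the group-mean smoothing leaves values as-is
        labels = np.tile(np.arange(1, shape[1] + 1), (shape[0], 1))
        return LTMGLabels(labels, np.full(shape[0], shape[1], int))

    def test_zero_velocity_gives_zero_beta(self):
        vel = nm(np.array([[0.0, 1.0], [2.0, 0.0]]), "velocity")
        vw = velocity_weights(vel, self._ltmg_distinct((2, 2)))
        assert vw.beta[0, 0] == 0.0
        assert vw.sign[0, 0] == 0

    def test_normalized_beta_bounded(self):
        rng = np.random.default_rng(2)
        vel = nm(rng.normal(0, 1, (20, 30)), "velocity")
        ltmg = LTMGLabels(np.ones((20, 30), int), np.ones(20, int))
        vw = velocity_weights(vel, ltmg, normalize=True)
        assert vw.beta.max() <= np.sqrt(2.0) + 1e-12

    def test_permutation_invariance(self):
        rng = np.random.default_rng(3)
        vals = rng.normal(0, 1, (6, 8))
        ltmg = self._ltmg_distinct((6, 8))
        vw = velocity_weights(nm(vals, "velocity"), ltmg)
        perm = rng.permutation(8)
        vw_p = velocity_weights(nm(vals[:, perm], "velocity"), ltmg)
        np.testing.assert_allclose(vw_p.beta, vw.beta[:, perm])

    def test_group_mean_replacement(self):
        # two cells sharing an LTMG label share the smoothed velocity
        vel = nm(np.array([[1.0, 3.0]]), "velocity")
        ltmg = LTMGLabels(np.array([[1, 1]]), np.array([1]))
        vw = velocity_weights(vel, ltmg, normalize=False)
        # both entries become mean 2.0 > 0; within-gene ranks tie-broken stably
        assert (vw.sign == 1).all()


class TestGas:
    def _vw(self, beta, sign):
        from scmultinet.preprocess import VelocityWeights
        return VelocityWeights(np.asarray(beta, float), np.asarray(sign, int))

    def test_zero_velocity_case(self):
        out = gas_matrix(nm([[1.0]]), nm([[2.0]], "gas"),
                         self._vw([[0.0]], [[0]]))
        assert out.values[0, 0] == pytest.approx(3.0)

    def test_positive_velocity_case(self):
        b = np.sqrt(2.0)
        out = gas_matrix(nm([[1.0]]), nm([[1.0]], "gas"),
                         self._vw([[b]], [[1]]))
        assert out.values[0, 0] == pytest.approx(1 + (1 + b))

    def test_negative_clipped(self):
        out = gas_matrix(nm([[0.0]]), nm([[2.0]], "gas"),
                         self._vw([[5.0]], [[-1]]), clip_negative=True)
        assert out.values[0, 0] == 0.0

    def test_gas_dominates_expression_for_nonnegative_velocity(self):
        rng = np.random.default_rng(4)
        r = np.abs(rng.normal(1, 1, (10, 12)))
        a = np.abs(rng.normal(1, 1, (10, 12)))
        beta = np.abs(rng.normal(0.5, 0.2, (10, 12)))
        sign = rng.choice([0, 1], (10, 12))
        beta[sign == 0] = 0.0
        out = gas_matrix(nm(r), nm(a, "gas"), self._vw(beta, sign))
        assert (out.values >= r - 1e-12).all()


class TestSteadyStateVelocity:
    def test_positive_offset_gives_positive_mean_velocity(self):
        rng = np.random.default_rng(5)
        s = rng.poisson(10.0, (1, 200)).astype(float)
        u = 0.5 * s + 2.0
        vel = steady_state_velocity(nm(s), nm(u))
        assert vel.values[0].mean() > 0

    def test_steady_state_gene_near_zero(self):
        rng = np.random.default_rng(6)
        s = rng.poisson(10.0, (1, 200)).astype(float) + 1
        u = 0.5 * s
        vel = steady_state_velocity(nm(s), nm(u))
        assert abs(vel.values[0].mean()) < 0.2


@settings(max_examples=25, deadline=None)
@given(st.integers(min_value=0, max_value=2 ** 31 - 1))
def test_qc_filter_idempotent_property(seed):
    rng = np.random.default_rng(seed)
    vals = (rng.random((15, 20)) < 0.3) * rng.integers(1, 9, (15, 20))
    try:
        once = qc_filter(nm(vals.astype(float)),
                         QCParams(min_nonzero_fraction=0.15))
    except EmptyResultError:
        return
    twice = qc_filter(once, QCParams(min_nonzero_fraction=0.15))
    assert once.row_names == twice.row_names
    assert once.col_names == twice.col_names
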