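import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from umscape.io import CountMatrix
from umscape.qc import (
    MedianNormalizer,
    complexity_filter,
    gene_filter,
    knee_filter_cells,
    median_normalize,
    mito_filter,
    pca_libsize_regressed,
    run_qc,
    select_n_pcs,
    variable_genes,
)
from umscape.simulate import SimulationParams, simulate_atlas


class TestKneeFilter:
    def test_planted_mixture_recovered(self):
        params = SimulationParams(
            n_tumor_cells=600, n_other_cells=0, n_empty_droplets=6000,
            apoptotic_fraction=0.0, seed=2,
        )
        cm, truth = simulate_atlas(params)
        res = knee_filter_cells(cm)
        cells = (truth.cell_type != "empty").to_numpy()
        assert abs(int(res.mask.sum()) - 600) <= 0.05 * 600
        assert (res.mask & cells).sum() >= 0.95 * 600

    def test_all_equal_totals_retained_with_warning(self):
        with pytest.warns(UserWarning, match="distinct"):
            res = knee_filter_cells(np.full(50, 100.0))
        assert res.mask.all()

    def test_mask_is_definitional(self):
        rng = np.random.default_rng(1)
        totals = np.concatenate([rng.poisson(40, 500), rng.poisson(2000, 200)]).astype(float)
        res = knee_filter_cells(totals)
        np.testing.assert_array_equal(res.mask, totals > res.cutoff)

    def test_unimodal_retains_all(self):
        rng = np.random.default_rng(0)
        totals = rng.lognormal(7.6, 0.3, 800)
        with pytest.warns(UserWarning, match="unimodal"):
            res = knee_filter_cells(totals)
        assert res.mask.all()


class TestComplexityFilter:
    def test_single_gene_library_flagged(self, rng):
        counts = rng.poisson(5, size=(200, 300))
        counts[0] = 0
        counts[0, 0] = 5000  # all mass in one gene
        mask = complexity_filter(counts)
        assert not mask[0]

    def test_homogeneous_cells_mostly_retained(self, rng):
        counts = rng.poisson(5, size=(300, 200))
        assert complexity_filter(counts).mean() >= 0.99

    def test_too_few_cells_skips(self):
        with pytest.warns(UserWarning, match="skipped"):
            mask = complexity_filter(np.ones((3, 5)))
        assert mask.all()


class TestMitoFilter:
    @pytest.mark.parametrize("mito_count,kept", [(26, False), (25, True)])
    def test_boundary_is_strict(self, mito_count, kept):
        cm = CountMatrix(
            np.array([[100 - mito_count, mito_count], [99, 1]]),
            ["c1", "c2"], ["A", "MT-1"],
        )
        mask = mito_filter(cm)
        assert mask[0] == kept and mask[1]

    def test_apoptotic_subpopulation_all_flagged(self, small_atlas):
        cm, truth = small_atlas
        mask = mito_filter(cm)
        assert (~mask[truth.apoptotic.to_numpy()]).all()

    def test_no_mito_genes_warns(self):
        cm = CountMatrix(np.array([[5, 5]]), ["c1"], ["A", "B"])
        with pytest.warns(UserWarning, match="mito"):
            assert mito_filter(cm).all()


class TestGeneFilter:
    def test_low_detection_gene_removed(self, rng):
        counts = rng.poisson(5, size=(100, 20))
        counts[:, 3] = 0
        counts[:9, 3] = 1  # detected in 9 < 10 cells
        res = gene_filter(counts)
        assert not res.mask[3]
        assert res.detection_counts[3] == 9

    def test_planted_bimodal_cutoff(self, rng):
        # per-gene totals drawn from two log-normal modes; the 5-SD rule
        # should place the cutoff near mu2 - 5*sd2 = 4 (log10 scale)
        lo = 10 ** rng.normal(2.0, 0.1, 400)
        hi = 10 ** rng.normal(5.0, 0.2, 400)
        totals = np.concatenate([lo, hi])
        n_genes = totals.size
        # spread each gene's total across 200 cells so detection passes
        counts = np.maximum((totals / 200).astype(int), 1)[None, :].repeat(200, 0)
        res = gene_filter(counts)
        expect_lin = np.log10(counts.sum(axis=0))  # realized totals
        assert abs(res.low_expression_cutoff - 4.0) < 0.4
        # genes well below cutoff removed, well above kept
        assert not res.mask[expect_lin < res.low_expression_cutoff - 0.2].any()
        assert res.mask[expect_lin > res.low_expression_cutoff + 0.2].all()

    def test_degenerate_distribution_detection_rule_only(self):
        counts = np.ones((50, 30), int)
        with pytest.warns(UserWarning, match="bimodal"):
            res = gene_filter(counts)
        assert res.mask.all()


class TestMedianNormalize:
    def test_scaling_arithmetic(self):
        counts = np.diag([100, 200, 300])
        nm = median_normalize(counts)
        assert nm.median_libsize == 200
        np.testing.assert_allclose(nm.values[0, 0], 200.0)

    def test_row_sums_equal_median(self, rng):
        counts = rng.poisson(5, size=(40, 30)) + 1
        nm = median_normalize(counts)
        np.testing.assert_allclose(nm.values.sum(axis=1), nm.median_libsize, rtol=1e-12)

    def test_idempotent(self, rng):
        counts = rng.poisson(5, size=(40, 30)) + 1
        once = median_normalize(counts).values
        twice = MedianNormalizer().fit_transform(once)
        np.testing.assert_allclose(once, twice, rtol=1e-12)

    def test_zero_total_cell_rejected(self):
        with pytest.raises(ValueError, match="zero-total"):
            median_normalize(np.array([[0, 0], [1, 2]]))

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(
        hnp.arrays(
            np.int64, st.tuples(st.integers(3, 12), st.integers(2, 8)),
            elements=st.integers(0, 50),
        )
    )
    def test_row_sum_property(self, counts):
        if (counts.sum(axis=1) == 0).any():
            return
        nm = median_normalize(counts)
        np.testing.assert_allclose(nm.values.sum(axis=1), nm.median_libsize, rtol=1e-9)


class TestPCA:
    def test_library_size_regressed_out(self, rng):
        # planted: one component proportional to libsize, plus orthogonal signal
        n = 300
        lib = rng.lognormal(7.5, 0.4, n)
        signal = rng.normal(size=(n, 5))
        basis = rng.normal(size=(6, 40))
        X = np.column_stack([signal, lib]) @ basis + rng.normal(0, 0.01, (n, 40))
        pcs = pca_libsize_regressed(X, library_size=lib, n_pcs=6, seed=0)
        for j in range(pcs.scores.shape[1]):
            r = np.corrcoef(pcs.scores[:, j], lib)[0, 1]
            assert abs(r) < 1e-8

    def test_seeded_determinism(self, rng):
        X = rng.normal(size=(100, 30))
        a = pca_libsize_regressed(X, n_pcs=10, seed=4).scores
        b = pca_libsize_regressed(X, n_pcs=10, seed=4).scores
        np.testing.assert_allclose(a, b, atol=1e-10)

    def test_constant_libsize_reduces_to_centering(self, rng):
        from sklearn.decomposition import PCA

        X = rng.normal(size=(80, 20))
        lib = np.full(80, 5.0)
        pcs = pca_libsize_regressed(X, library_size=lib, n_pcs=5, seed=0)
        # regression on a constant is mean-centering; PCA scores are already
        # centered, so scores equal the plain PCA scores
        raw = PCA(n_components=5, svd_solver="randomized", random_state=0).fit_transform(X)
        np.testing.assert_allclose(pcs.scores, raw, atol=1e-8)

    def test_n_pcs_truncated_with_warning(self, rng):
        X = rng.normal(size=(10, 4))
        with pytest.warns(UserWarning, match="exceeds"):
            pcs = pca_libsize_regressed(X, n_pcs=8, seed=0)
        assert pcs.n_pcs == 4

    def test_explained_variance_non_increasing(self, rng):
        X = rng.normal(size=(100, 30)) * np.linspace(5, 0.1, 30)
        pcs = pca_libsize_regressed(X, n_pcs=10, seed=0)
        assert (np.diff(pcs.explained_variance_ratio) <= 1e-12).all()


class TestSelectNPcs:
    def test_geometric_decay(self):
        evr = 0.5 * 0.5 ** np.arange(10)
        sel = select_n_pcs(evr, target_fraction=0.90)
        assert sel.n_target == 4  # 0.5+0.25+0.125+0.0625 = 0.9375
        assert sel.n_knee <= 4

    def test_uniform_falls_back_to_target(self):
        with pytest.warns(UserWarning, match="uniform"):
            sel = select_n_pcs(np.full(10, 0.1), target_fraction=0.90)
        assert sel.n_knee == sel.n_target == 9

    def test_single_dominant_component(self):
        sel = select_n_pcs(np.array([0.99, 0.005, 0.003, 0.002]))
        assert sel.n_knee == 1

    def test_few_components_returns_all(self):
        assert select_n_pcs(np.array([0.6, 0.4])).n_knee == 2


class TestVariableGenes:
    def test_planted_sd_mixture(self, rng):
        n = 600
        low = rng.normal(0.1, 0.01, 400)
        high = rng.normal(1.0, 0.1, 200)
        sds = np.concatenate([low, high])
        X = rng.normal(0, 1, size=(n, sds.size)) * sds
        mask = variable_genes(X)
        # the mu2 - 1.5*sd2 rule itself admits ~93% of the high mode
        assert mask[400:].mean() > 0.85
        assert mask[:400].mean() < 0.05

    def test_constant_gene_never_selected(self, rng):
        X = rng.normal(size=(50, 10))
        X[:, 0] = 3.0
        assert not variable_genes(X)[0]

    def test_degenerate_falls_back_to_quartile(self):
        X = np.tile(np.array([[0.0], [1.0]]), (1, 20))
        with pytest.warns(UserWarning, match="quartile|bimodal"):
            variable_genes(X)


class TestRunQC:
    def test_masks_conjunction_and_reconcile(self, small_atlas):
        cm, truth = small_atlas
        filtered, report = run_qc(cm)
        conj = np.ones(cm.n_cells, bool)
        for m in report.cell_masks.values():
            conj &= m
        assert filtered.n_cells == conj.sum()
        audit = report.reconcile()
        assert audit["retained"] + audit["excluded"] == audit["total"]
        only = sum(v for k, v in audit.items() if k.startswith("only_"))
        assert only + audit["multi_filter_overlap"] == audit["excluded"]

    def test_clean_atlas_passes_entirely(self):
        params = SimulationParams(
            n_tumor_cells=300, n_other_cells=0, n_empty_droplets=0,
            mito_fraction_mean=0.0, apoptotic_fraction=0.0, seed=9,
        )
        cm, _ = simulate_atlas(params)
        _, report = run_qc(cm, apply_complexity=False)
        assert report.cell_mask.all()
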