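import numpy as np
import pytest
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import pdist
from scipy.stats import spearmanr

from umscape.geometry import (
    PCHA,
    DiffusionMap,
    archetype_markers,
    archetype_neighborhoods,
    diffusion_map,
    emd_score,
    furthest_sum,
    multiscale_distance,
    multiscale_distances_to,
    pcha_fit,
    select_n_archetypes,
)
from umscape.imputation import ImputedMatrix
from umscape.simulate import simulate_simplex


def sorted_matching_emd(a, b):
    """Equal-size 1-D EMD oracle: mean absolute difference of order stats."""
    return np.abs(np.sort(a) - np.sort(b)).mean()


# ---------------------------------------------------------------------------
# diffusion maps


class TestDiffusionMap:
    def test_planted_two_block_bisection(self, rng):
        X = np.vstack([rng.normal(0, 0.4, (30, 3)), rng.normal(2.2, 0.4, (30, 3))])
        dm = diffusion_map(X, k=30, ka=5, n_components=3)
        e1 = dm.components[:, 0]
        s = np.sign(e1)
        assert (s[:30] == s[0]).all() and (s[30:] == -s[0]).all()

    def test_retained_eigenvalues_below_one(self, rng):
        dm = diffusion_map(rng.normal(size=(50, 4)), k=10, ka=4, n_components=5)
        assert (np.abs(dm.eigenvalues) < 1).all()

    def test_eigenvalues_invariant_to_cell_order(self, rng):
        X = rng.normal(size=(40, 3))
        a = diffusion_map(X, k=8, ka=3, n_components=4).eigenvalues
        b = diffusion_map(X[rng.permutation(40)], k=8, ka=3, n_components=4).eigenvalues
        np.testing.assert_allclose(a, b, atol=1e-8)

    def test_disconnected_graph_reports_components(self, rng):
        X = np.vstack([rng.normal(0, 0.1, (20, 2)), rng.normal(500, 0.1, (20, 2))])
        with pytest.raises(ValueError, match="component sizes"):
            diffusion_map(X, k=5, ka=2)

    def test_chain_orders_cells_along_first_component(self):
        X = np.linspace(0, 10, 50)[:, None]
        dm = diffusion_map(X, k=5, ka=2, n_components=2)
        rho = spearmanr(dm.components[:, 0], X[:, 0]).statistic
        assert abs(rho) > 0.99


class TestMultiscaleDistance:
    def test_zero_on_diagonal(self, rng):
        dm = diffusion_map(rng.normal(size=(30, 3)), k=8, ka=3, n_components=3)
        assert multiscale_distance(dm, 4, 4) == 0.0

    def test_hand_formula_multiscale(self):
        dm = DiffusionMap(np.array([0.5]), np.array([[1.0], [0.0]]), k=1, ka=1)
        np.testing.assert_allclose(multiscale_distance(dm, 0, 1), 1.0)

    def test_single_t_matches_brute_force_sum(self, rng):
        L = 4
        lam = rng.uniform(0.1, 0.9, L)
        comps = rng.normal(size=(10, L))
        dm = DiffusionMap(lam, comps, k=1, ka=1)
        for t in (1, 2, 3):
            d = multiscale_distance(dm, 2, 7, mode="single-t", t=t)
            oracle = np.sqrt(sum(lam[l] ** (2 * t) * (comps[2, l] - comps[7, l]) ** 2
                                 for l in range(L)))
            np.testing.assert_allclose(d, oracle, atol=1e-12)

    def test_metric_axioms_exhaustive_20_cells(self, rng):
        dm = diffusion_map(rng.normal(size=(20, 3)), k=8, ka=4, n_components=4)
        D = multiscale_distances_to(dm, np.arange(20))
        np.testing.assert_allclose(D, D.T, atol=1e-10)
        assert (np.diag(D) == 0).all()
        for i in range(20):
            for j in range(20):
                for k in range(20):
                    assert D[i, j] <= D[i, k] + D[k, j] + 1e-10

    def test_unit_eigenvalue_rejected(self):
        dm = DiffusionMap(np.array([1.0]), np.array([[1.0], [0.0]]), k=1, ka=1)
        with pytest.raises(ValueError, match="eigenvalue"):
            multiscale_distance(dm, 0, 1)


# ---------------------------------------------------------------------------
# PCHA


class TestPCHA:
    def test_exact_hull_k_distinct_points(self, rng):
        X = rng.normal(size=(4, 3)) * 5
        m = pcha_fit(X, 4, seed=0)
        assert m.explained_variance >= 0.999
        D = np.linalg.norm(m.archetypes[:, None] - X[None], axis=2)
        r, c = linear_sum_assignment(D)
        assert D[r, c].max() < 1e-3 * pdist(X).max()

    def test_single_archetype_is_centroid(self, rng):
        X = rng.normal(size=(100, 4))
        m = pcha_fit(X, 1, seed=0)
        np.testing.assert_allclose(m.archetypes[0], X.mean(axis=0), atol=1e-3)

    def test_objective_monotone_non_increasing(self, rng):
        pts, _ = simulate_simplex(3, 300, 0.1, dim=4, seed=1)
        m = pcha_fit(pts, 3, seed=0)
        assert (np.diff(m.sse_history) <= 1e-12).all()

    def test_noise_free_vertex_recovery(self):
        pts, vts = simulate_simplex(4, 1000, 0.0, dim=5, seed=7, dirichlet_alpha=0.05)
        m = pcha_fit(pts, 4, seed=0, max_iter=2000, tol=1e-12)
        D = np.linalg.norm(m.archetypes[:, None] - vts[None], axis=2)
        r, c = linear_sum_assignment(D)
        assert (D[r, c] / pdist(vts).max()).max() < 1e-3

    def test_stochastic_factor_constraints(self, rng):
        pts, _ = simulate_simplex(3, 200, 0.05, dim=3, seed=2)
        m = pcha_fit(pts, 3, seed=0)
        assert (m.C >= 0).all() and (m.S >= 0).all()
        np.testing.assert_allclose(m.C.sum(axis=0), 1.0, atol=1e-8)
        np.testing.assert_allclose(m.S.sum(axis=0), 1.0, atol=1e-8)

    def test_transform_weights_on_simplex(self, rng):
        pts, _ = simulate_simplex(3, 200, 0.02, dim=3, seed=3)
        est = PCHA(n_archetypes=3, random_state=0).fit(pts)
        W = est.transform(pts[:20])
        assert (W >= 0).all()
        np.testing.assert_allclose(W.sum(axis=1), 1.0, atol=1e-8)

    def test_furthest_sum_spreads_seeds(self, rng):
        X = np.array([[0.0, 0], [10, 0], [0, 10], [0.1, 0.1], [0.2, 0.1]])
        idx = furthest_sum(X, 3, np.random.default_rng(0))
        assert {0, 1, 2} <= set(idx) | {3, 4}  # extremes dominate selection
        assert len(set(idx)) == 3


class TestSelectNArchetypes:
    def test_planted_vertex_count_recovered(self):
        pts, _ = simulate_simplex(4, 800, 0.05, dim=5, seed=0)
        chosen, ev, _ = select_n_archetypes(pts, range(2, 8), seed=0)
        assert chosen == 4
        assert (np.diff(ev) >= -1e-6).all()  # nested models

    def test_grid_of_one(self, rng):
        pts, _ = simulate_simplex(3, 100, 0.05, dim=3, seed=1)
        chosen, ev, models = select_n_archetypes(pts, [3], seed=0)
        assert chosen == 3 and len(ev) == 1 and 3 in models


# ---------------------------------------------------------------------------
# neighborhoods and markers


@pytest.fixture(scope="module")
def planted_neighborhoods():
    rng = np.random.default_rng(6)
    pts, vts = simulate_simplex(3, 400, 0.05, dim=3, seed=6, dirichlet_alpha=0.2)
    dm = diffusion_map(pts, k=25, ka=8, n_components=3)
    model = pcha_fit(pts, 3, seed=0)
    nbhd = archetype_neighborhoods(dm, model, pts)
    return pts, model, nbhd


class TestNeighborhoods:
    def test_disjoint_for_separated_archetypes(self, planted_neighborhoods):
        _, _, nbhd = planted_neighborhoods
        for a in range(3):
            for b in range(a + 1, 3):
                assert not set(nbhd.members[a]) & set(nbhd.members[b])

    def test_anchor_is_own_member(self, planted_neighborhoods):
        _, _, nbhd = planted_neighborhoods
        for a, anchor in enumerate(nbhd.anchor_indices):
            assert anchor in nbhd.members[a]

    def test_nearest_assignment_partitions_cells(self, planted_neighborhoods):
        pts, _, nbhd = planted_neighborhoods
        assert nbhd.nearest_archetype.shape == (pts.shape[0],)
        assert set(np.unique(nbhd.nearest_archetype)) <= {0, 1, 2}

    def test_radii_positive(self, planted_neighborhoods):
        _, _, nbhd = planted_neighborhoods
        assert (nbhd.radii > 0).all()


class TestEMD:
    def test_identity_and_point_mass(self):
        assert emd_score([1, 2, 3], [1, 2, 3]) == 0.0
        assert emd_score([2.0], [5.0]) == 3.0
        assert emd_score([0, 1], [1, 2]) == 1.0

    def test_matches_sorted_matching_oracle(self, rng):
        for _ in range(200):
            n = rng.integers(2, 40)
            a, b = rng.normal(size=n), rng.normal(2, 1.5, size=n)
            np.testing.assert_allclose(emd_score(a, b), sorted_matching_emd(a, b), atol=1e-8)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            emd_score([], [1.0])


class TestMarkers:
    def test_planted_exclusive_gene_scores_one(self, planted_neighborhoods):
        pts, _, nbhd = planted_neighborhoods
        n = pts.shape[0]
        values = np.zeros((n, 3))
        values[nbhd.members[0], 0] = 1.0  # exclusive to archetype 0
        values[:, 1] = 5.0  # constant
        values[:, 2] = np.random.default_rng(1).normal(size=n)
        imp = ImputedMatrix(values=values, gene_ids=["excl", "const", "noise"])
        table = archetype_markers(imp, nbhd, n_resamples=20, seed=0)
        np.testing.assert_allclose(table.loc["archetype_0", "excl"], 1.0, atol=1e-12)
        np.testing.assert_array_equal(table["const"], 0.0)
        assert table.loc["archetype_0", "excl"] > table.loc["archetype_0", "noise"]

    def test_seed_determinism(self, planted_neighborhoods):
        pts, _, nbhd = planted_neighborhoods
        values = np.random.default_rng(2).normal(size=(pts.shape[0], 4))
        imp = ImputedMatrix(values=values, gene_ids=list("abcd"))
        t1 = archetype_markers(imp, nbhd, n_resamples=10, seed=3)
        t2 = archetype_markers(imp, nbhd, n_resamples=10, seed=3)
        assert t1.equals(t2)

    def test_separation_property(self, planted_neighborhoods):
        """A planted archetype-exclusive gene outscores null genes in every
        resample average."""
        pts, _, nbhd = planted_neighborhoods
        rng = np.random.default_rng(5)
        n = pts.shape[0]
        null = rng.normal(0, 0.05, size=(n, 10))
        excl = np.zeros((n, 1))
        excl[nbhd.members[1]] = 1.0
        imp = ImputedMatrix(values=np.hstack([excl, null]),
                            gene_ids=[f"g{i}" for i in range(11)])
        tables = [
            archetype_markers(imp, nbhd, n_resamples=5, seed=s).loc["archetype_1"]
            for s in range(20)
        ]
        for t in tables:
            assert t["g0"] > t[[f"g{i}" for i in range(1, 11)]].max()
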