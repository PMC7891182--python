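"""Graph-metric unit and property tests against hand values and brute force."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import _oracles as oracle
from wmnet import (
    ConnectivityMatrix,
    RandomReferenceParams,
    SparsityGrid,
    auc,
    global_metrics,
    identify_hubs,
    metric_curves,
    nodal_metrics,
    random_reference,
    threshold_by_sparsity,
)
from wmnet.metrics import _double_edge_swap


# ---------------------------------------------------------------------------
# sparsity thresholding


class TestThresholdBySparsity:
    def test_k5_at_30_percent_keeps_3_edges(self):
        m = ConnectivityMatrix(np.ones((5, 5)) - np.eye(5))
        assert threshold_by_sparsity(m, 0.3).n_edges == 3

    def test_s_equal_1_is_identity(self, k4):
        out = threshold_by_sparsity(k4, 1.0)
        np.testing.assert_array_equal(out.weights, k4.weights)

    def test_nonpositive_sparsity_rejected(self, k4):
        with pytest.raises(ValueError):
            threshold_by_sparsity(k4, 0.0)
        with pytest.raises(ValueError):
            threshold_by_sparsity(k4, -0.1)

    def test_tie_break_is_lexicographic(self):
        # 4 nodes, all six edges weight 0.5 -> K = round(0.5*6) = 3 edges;
        # ties resolved by ascending (i, j): keep (0,1), (0,2), (0,3)
        W = np.full((4, 4), 0.5) - 0.5 * np.eye(4)
        m = ConnectivityMatrix(W)
        out = threshold_by_sparsity(m, 0.5)
        kept = {(i, j) for i, j, _ in out.edge_list()}
        assert kept == {(0, 1), (0, 2), (0, 3)}

    def test_keeps_strongest_edges_weighted(self):
        W = np.zeros((4, 4))
        W[0, 1] = W[1, 0] = 0.9
        W[2, 3] = W[3, 2] = 0.8
        W[0, 2] = W[2, 0] = 0.1
        m = ConnectivityMatrix(W)
        out = threshold_by_sparsity(m, 2 / 6)
        kept = {(i, j): w for i, j, w in out.edge_list()}
        assert kept == {(0, 1): 0.9, (2, 3): 0.8}

    def test_fewer_edges_than_k_keeps_all(self):
        W = np.zeros((6, 6))
        W[0, 1] = W[1, 0] = 0.4
        m = ConnectivityMatrix(W)
        assert threshold_by_sparsity(m, 0.9).n_edges == 1


# ---------------------------------------------------------------------------
# global and nodal metrics: hand examples


class TestGlobalMetricsExamples:
    def test_complete_unit_k4(self, k4):
        g = global_metrics(k4)
        assert g.cp == g.lp == g.eglob == g.eloc == pytest.approx(1.0)

    def test_three_node_path(self):
        W = np.zeros((3, 3))
        W[0, 1] = W[1, 0] = W[1, 2] = W[2, 1] = 1.0
        g = global_metrics(ConnectivityMatrix(W))
        # distances 1, 1, 2 -> Lp = 4/3, Eglob = (1 + 1 + 1/2)/3
        assert g.lp == pytest.approx(4 / 3)
        assert g.eglob == pytest.approx(5 / 6)

    def test_uniform_triangle_has_unit_clustering(self):
        W = np.full((3, 3), 0.5) - 0.5 * np.eye(3)
        assert global_metrics(ConnectivityMatrix(W)).cp == pytest.approx(1.0)

    def test_all_zero_matrix_degenerates_gracefully(self):
        g = global_metrics(ConnectivityMatrix(np.zeros((4, 4))))
        assert g.cp == 0 and g.eglob == 0 and g.eloc == 0
        assert np.isnan(g.lp)

    def test_single_node_rejected(self):
        with pytest.raises(ValueError):
            global_metrics(ConnectivityMatrix(np.zeros((1, 1))))


class TestNodalMetricsExamples:
    def test_star_betweenness(self, star5):
        bc = nodal_metrics(star5).betweenness
        # all C(4,2)=6 leaf pairs route through the center
        assert bc[0] == pytest.approx(6.0)
        np.testing.assert_allclose(bc[1:], 0.0)

    def test_star_nodal_efficiency(self, star5):
        eff = nodal_metrics(star5).efficiency
        assert eff[0] == pytest.approx(1.0)
        # leaf distances 1, 2, 2, 2 -> mean of 1, 1/2, 1/2, 1/2
        np.testing.assert_allclose(eff[1:], 0.625)

    def test_isolated_node_has_zero_everything(self):
        W = np.zeros((4, 4))
        W[0, 1] = W[1, 0] = 0.5
        nm = nodal_metrics(ConnectivityMatrix(W))
        assert nm.efficiency[3] == 0.0
        assert nm.betweenness[3] == 0.0


# ---------------------------------------------------------------------------
# brute-force oracle equivalence (the backbone correctness check)


def test_metrics_match_brute_force_on_random_graphs():
    """Cp/Lp/Eglob/Eloc/nodal efficiency/BC vs an independent oracle, 1e-9."""
    rng = np.random.default_rng(2024)
    for trial in range(100):
        n = int(rng.integers(4, 13))
        W = oracle.random_weighted_graph(rng, n)
        if not W.any():
            continue
        m = ConnectivityMatrix(W)
        g = global_metrics(m)
        nm = nodal_metrics(m)
        assert g.cp == pytest.approx(oracle.clustering(W), abs=1e-9)
        assert g.eglob == pytest.approx(oracle.eglob(W), abs=1e-9)
        assert g.eloc == pytest.approx(oracle.eloc(W), abs=1e-9)
        o_lp = oracle.lp(W)
        if np.isnan(o_lp):
            assert np.isnan(g.lp)
        else:
            assert g.lp == pytest.approx(o_lp, abs=1e-9)
        np.testing.assert_allclose(
            nm.efficiency, oracle.nodal_efficiency(W), atol=1e-9
        )
        np.testing.assert_allclose(
            nm.betweenness, oracle.betweenness(W), atol=1e-9
        )


# ---------------------------------------------------------------------------
# invariance and monotonicity laws


def test_scaling_weights_scales_efficiencies_and_inverts_lp():
    rng = np.random.default_rng(5)
    W = oracle.random_weighted_graph(rng, 10)
    W = np.minimum(W, 0.5)  # leave room to scale up within [0, 1]
    m = ConnectivityMatrix(W)
    g1, n1 = global_metrics(m), nodal_metrics(m)
    c = 1.7
    m2 = ConnectivityMatrix(np.minimum(W * c, 1.0))
    g2, n2 = global_metrics(m2), nodal_metrics(m2)
    assert g2.eglob == pytest.approx(c * g1.eglob, rel=1e-12)
    assert g2.lp == pytest.approx(g1.lp / c, rel=1e-12)
    assert g2.cp == pytest.approx(g1.cp, rel=1e-12)  # max-normalized
    np.testing.assert_allclose(n2.efficiency, c * n1.efficiency, rtol=1e-12)
    # hub set is scale-invariant
    assert (
        identify_hubs(n1.betweenness).nodes == identify_hubs(n2.betweenness).nodes
    )


def test_removing_an_edge_never_increases_efficiency():
    rng = np.random.default_rng(9)
    for _ in range(20):
        W = oracle.random_weighted_graph(rng, 8)
        edges = [(i, j) for i in range(8) for j in range(i + 1, 8) if W[i, j] > 0]
        if not edges:
            continue
        i, j = edges[int(rng.integers(len(edges)))]
        W2 = W.copy()
        W2[i, j] = W2[j, i] = 0.0
        g1 = global_metrics(ConnectivityMatrix(W))
        g2 = global_metrics(ConnectivityMatrix(W2))
        assert g2.eglob <= g1.eglob + 1e-12
        e1 = nodal_metrics(ConnectivityMatrix(W)).efficiency
        e2 = nodal_metrics(ConnectivityMatrix(W2)).efficiency
        assert (e2 <= e1 + 1e-12).all()


@settings(deadline=None, max_examples=25, derandomize=True)
@given(st.integers(min_value=0, max_value=10_000), st.floats(0.05, 0.95))
def test_threshold_output_is_valid_and_nested(seed, s):
    """Thresholded matrices stay symmetric/zero-diagonal; edges nest in s."""
    rng = np.random.default_rng(seed)
    W = oracle.random_weighted_graph(rng, 12, density=0.6)
    m = ConnectivityMatrix(W)
    out = threshold_by_sparsity(m, s)
    assert np.array_equal(out.weights, out.weights.T)
    assert not np.diagonal(out.weights).any()
    smaller = threshold_by_sparsity(m, s / 2)
    kept_small = {(i, j) for i, j, _ in smaller.edge_list()}
    kept_big = {(i, j) for i, j, _ in out.edge_list()}
    assert kept_small <= kept_big


# ---------------------------------------------------------------------------
# random reference / small-worldness


class TestRandomReference:
    def test_complete_graph_is_its_own_null(self, k4):
        norm = random_reference(k4, RandomReferenceParams(n_random=10, seed=0))
        assert norm.gamma == pytest.approx(1.0)
        assert norm.lam == pytest.approx(1.0)
        assert norm.sigma == pytest.approx(1.0)

    def test_rewiring_preserves_degrees_exactly(self):
        rng = np.random.default_rng(3)
        W = oracle.random_weighted_graph(rng, 20, density=0.3)
        iu, ju = np.triu_indices(20, k=1)
        nz = W[iu, ju] > 0
        eu, ev = iu[nz], ju[nz]
        deg0 = np.bincount(np.concatenate([eu, ev]), minlength=20)
        ru, rv, n_succ = _double_edge_swap(eu, ev, 20, 10 * nz.sum(), rng)
        assert n_succ > 0
        deg1 = np.bincount(np.concatenate([ru, rv]), minlength=20)
        np.testing.assert_array_equal(deg0, deg1)
        # still a simple graph
        assert len({(a, b) for a, b in zip(ru, rv)}) == len(ru)
        assert (ru < rv).all()

    def test_er_graph_gamma_near_one(self):
        """ER graphs are close to their own degree-matched null."""
        gammas = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            W = (rng.random((60, 60)) < 0.15).astype(float)
            W = np.triu(W, 1)
            W = W + W.T
            m = ConnectivityMatrix(W)
            norm = random_reference(
                m, RandomReferenceParams(n_random=10, seed=seed)
            )
            gammas.append(norm.gamma)
        assert abs(np.mean(gammas) - 1.0) < 0.15

    def test_deterministic_given_seed(self, small_cohort):
        m = threshold_by_sparsity(small_cohort.matrices[0], 0.3)
        p = RandomReferenceParams(n_random=5, seed=42)
        a = random_reference(m, p)
        b = random_reference(m, p)
        assert a == b


# ---------------------------------------------------------------------------
# curves, AUC, hubs


class TestCurvesAndAUC:
    def test_single_point_curve_matches_whole_matrix(self, k4):
        grid = SparsityGrid(s_min=0.99, s_max=0.99, step=0.01)
        curve = metric_curves(k4, grid)
        g = global_metrics(k4)
        row = curve.table.iloc[0]
        assert row["eglob"] == pytest.approx(g.eglob)
        assert row["cp"] == pytest.approx(g.cp)

    def test_default_grid_has_six_points(self):
        np.testing.assert_allclose(
            SparsityGrid().values(), [0.10, 0.11, 0.12, 0.13, 0.14, 0.15]
        )

    def test_eglob_nondecreasing_in_sparsity(self, small_cohort):
        grid = SparsityGrid(s_min=0.05, s_max=0.30, step=0.05)
        curve = metric_curves(small_cohort.matrices[0], grid, metrics=("eglob",))
        eg = curve.table["eglob"].to_numpy()
        assert (np.diff(eg) >= -1e-12).all()

    def test_auc_of_constant_curve(self):
        grid = SparsityGrid()
        assert auc(np.full(6, 2.0), grid) == pytest.approx(0.1)

    def test_auc_trapezoid_example(self):
        grid = SparsityGrid()
        assert auc(np.arange(6.0), grid) == pytest.approx(0.125)

    def test_auc_linearity(self):
        grid = SparsityGrid()
        v = np.array([0.3, 1.2, 0.7, 2.0, 1.1, 0.5])
        assert auc(3.0 * v, grid) == pytest.approx(3.0 * auc(v, grid))

    def test_auc_with_missing_value_is_nan(self):
        grid = SparsityGrid()
        v = np.array([1.0, np.nan, 1.0, 1.0, 1.0, 1.0])
        assert np.isnan(auc(v, grid))


class TestIdentifyHubs:
    def test_mean_plus_sd_rule(self):
        hubs = identify_hubs(np.array([10.0, 2.0, 2.0, 2.0]))
        assert hubs.nodes == (0,)
        assert hubs.threshold == pytest.approx(8.0)

    def test_all_equal_bc_flags_everyone(self):
        hubs = identify_hubs(np.array([3.0, 3.0, 3.0]))
        assert hubs.nodes == (0, 1, 2)

    def test_all_zero_bc_flags_everyone_at_zero(self):
        hubs = identify_hubs(np.zeros(4))
        assert hubs.nodes == (0, 1, 2, 3)
        assert hubs.threshold == 0.0

    def test_single_node_rejected(self):
        with pytest.raises(ValueError):
            identify_hubs(np.array([1.0]))
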