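"""Global and nodal topology measures against hand and brute-force oracles."""

import itertools

import numpy as np
import pytest

from scnet import (
    DensityGrid,
    auc_over_densities,
    betweenness,
    characteristic_path_length,
    clustering_coefficient,
    global_efficiency,
    local_efficiency,
)
from scnet.network import BinaryGraph

from oracles import (
    betweenness_oracle,
    clustering_oracle,
    global_efficiency_oracle,
    local_efficiency_oracle,
    path_length_oracle,
    random_graph,
)


def _graph(adj):
    adj = np.asarray(adj, dtype=np.int8)
    return BinaryGraph(
        adjacency=adj,
        density_achieved=adj.sum() / (adj.shape[0] * (adj.shape[0] - 1)),
        region_labels=tuple(f"R{i}" for i in range(adj.shape[0])),
    )


def complete(n):
    return 1 - np.eye(n, dtype=np.int8)


def star(n_leaves):
    a = np.zeros((n_leaves + 1, n_leaves + 1), dtype=np.int8)
    a[0, 1:] = a[1:, 0] = 1
    return a


def path(n):
    a = np.zeros((n, n), dtype=np.int8)
    for i in range(n - 1):
        a[i, i + 1] = a[i + 1, i] = 1
    return a


K4_MINUS_EDGE = np.array(
    [[0, 1, 1, 1], [1, 0, 1, 1], [1, 1, 0, 0], [1, 1, 0, 0]], dtype=np.int8
)


class TestClustering:
    @pytest.mark.parametrize(
        "adj,expected_mean",
        [
            (complete(3), 1.0),
            (star(3), 0.0),
            (K4_MINUS_EDGE, 5 / 6),  # two nodes at 2/3, two at 1
        ],
    )
    def test_hand_enumerated_means(self, adj, expected_mean):
        _, mean = clustering_coefficient(_graph(adj))
        assert mean == pytest.approx(expected_mean, abs=1e-12)

    def test_low_degree_nodes_score_zero(self):
        per_node, _ = clustering_coefficient(_graph(path(4)))
        assert per_node[0] == 0.0 and per_node[3] == 0.0


class TestPathLength:
    @pytest.mark.parametrize(
        "adj,expected",
        [
            (complete(4), 1.0),
            (path(4), 10 / 6),
            # two disjoint edges: only the 2 connected pairs count
            (np.kron(np.eye(2, dtype=np.int8), np.array([[0, 1], [1, 0]], np.int8)), 1.0),
        ],
    )
    def test_examples(self, adj, expected):
        assert characteristic_path_length(_graph(adj)) == pytest.approx(expected)

    def test_edgeless_graph_undefined(self):
        with pytest.raises(ValueError, match="no connected"):
            characteristic_path_length(_graph(np.zeros((4, 4), dtype=np.int8)))

    def test_strict_mode_rejects_disconnection(self):
        a = np.zeros((3, 3), dtype=np.int8)
        a[0, 1] = a[1, 0] = 1
        with pytest.raises(ValueError, match="disconnected"):
            characteristic_path_length(_graph(a), strict=True)


class TestEfficiency:
    @pytest.mark.parametrize(
        "adj,expected",
        [
            (complete(5), 1.0),
            (path(3), 5 / 6),
            (np.zeros((4, 4), dtype=np.int8), 0.0),
        ],
    )
    def test_global_examples(self, adj, expected):
        assert global_efficiency(_graph(adj)) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "adj,expected",
        [
            (complete(4), 1.0),
            (star(4), 0.0),
        ],
    )
    def test_local_examples(self, adj, expected):
        _, mean = local_efficiency(_graph(adj))
        assert mean == pytest.approx(expected)

    def test_local_efficiency_matches_subgraph_oracle(self):
        per_node, mean = local_efficiency(_graph(K4_MINUS_EDGE))
        oracle_nodes, oracle_mean = local_efficiency_oracle(K4_MINUS_EDGE)
        np.testing.assert_allclose(per_node, oracle_nodes, atol=1e-12)
        assert mean == pytest.approx(oracle_mean)

    def test_global_efficiency_nondecreasing_in_density(self, rng):
        # nested edge sets can only shorten paths
        n = 20
        iu = np.array(list(itertools.combinations(range(n), 2)))
        order = rng.permutation(len(iu))
        prev = -1.0
        adj = np.zeros((n, n), dtype=np.int8)
        for m in (20, 60, 120, 190):
            sel = iu[order[:m]]
            adj[:] = 0
            adj[sel[:, 0], sel[:, 1]] = 1
            adj |= adj.T
            eff = global_efficiency(_graph(adj))
            assert eff >= prev
            prev = eff


class TestBetweenness:
    def test_star_center_carries_all_paths(self):
        res = betweenness(_graph(star(4)))
        assert res.betweenness_raw[0] == pytest.approx(6.0)  # C(4,2) leaf pairs
        np.testing.assert_allclose(res.betweenness_raw[1:], 0.0)
        assert res.betweenness_norm[0] == pytest.approx(5.0)  # mean raw = 1.2

    def test_complete_graph_flagged_degenerate(self):
        with pytest.warns(UserWarning, match="zero"):
            res = betweenness(_graph(complete(5)))
        assert res.degenerate
        np.testing.assert_array_equal(res.betweenness_norm, 0.0)

    def test_path_midpoint(self):
        res = betweenness(_graph(path(3)))
        np.testing.assert_allclose(res.betweenness_raw, [0.0, 1.0, 0.0])

    def test_normalized_mean_is_one(self, rng):
        a = random_graph(15, 0.3, rng)
        res = betweenness(_graph(a))
        if not res.degenerate:
            assert res.betweenness_norm.mean() == pytest.approx(1.0)


class TestBruteForceEquivalence:
    """Spot equivalence on random graphs; the exhaustive sweep lives in the
    acceptance suite."""

    @pytest.mark.parametrize("n,p,seed", [(6, 0.4, 0), (10, 0.3, 1), (20, 0.2, 2)])
    def test_all_metrics_match_oracles(self, n, p, seed):
        rng = np.random.default_rng(seed)
        a = random_graph(n, p, rng)
        g = _graph(a)
        np.testing.assert_allclose(
            clustering_coefficient(g)[0], clustering_oracle(a)[0], atol=1e-10
        )
        assert global_efficiency(g) == pytest.approx(
            global_efficiency_oracle(a), abs=1e-10
        )
        np.testing.assert_allclose(
            local_efficiency(g)[0], local_efficiency_oracle(a)[0], atol=1e-10
        )
        try:
            lp = characteristic_path_length(g)
            assert lp == pytest.approx(path_length_oracle(a), abs=1e-10)
        except ValueError:
            with pytest.raises(ValueError):
                path_length_oracle(a)
        np.testing.assert_allclose(
            betweenness(g).betweenness_raw, betweenness_oracle(a), atol=1e-10
        )


class TestAuc:
    def test_constant_curve_over_default_grid(self):
        grid = DensityGrid()
        assert auc_over_densities(np.ones(len(grid)), grid) == pytest.approx(0.45)

    def test_linear_curve_is_exact(self):
        grid = DensityGrid((0.1, 0.2, 0.4))
        # integral of 2d over [0.1, 0.4] = 0.4^2 - 0.1^2
        assert auc_over_densities(2 * grid.as_array(), grid) == pytest.approx(0.15)

    def test_matches_summation_oracle(self, rng):
        grid = DensityGrid(tuple(np.round(np.arange(5, 51) / 100, 2)))
        v = rng.normal(size=len(grid))
        d = grid.as_array()
        manual = sum(
            (v[i] + v[i + 1]) / 2 * (d[i + 1] - d[i]) for i in range(len(d) - 1)
        )
        assert auc_over_densities(v, grid) == pytest.approx(manual, abs=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="match"):
            auc_over_densities(np.ones(3), DensityGrid((0.1, 0.2)))
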