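"""Thresholding, node ranking, component traces, and percolation points."""

import networkx as nx
import numpy as np
import pytest

from netpercolate import (
    AttackConfig,
    ConfigurationError,
    Connectome,
    DensityTooLowError,
    component_trace,
    percolation_point,
    proportional_threshold,
    rank_nodes,
    removal_frequency_map,
    run_attacks,
)
from netpercolate._fast import batch_attack
from netpercolate.attack import _graph_csr


class TestProportionalThreshold:
    def test_full_density_keeps_complete_graph(self):
        rng = np.random.default_rng(0)
        w = rng.random((8, 8)) + 0.01
        w = np.triu(w, 1)
        w = w + w.T
        g = proportional_threshold(w, 1.0)
        assert g.number_of_edges() == 8 * 7 // 2

    def test_keeps_exactly_the_heaviest_pairs(self):
        w = np.zeros((4, 4))
        weights = {(0, 1): 0.9, (0, 2): 0.8, (1, 2): 0.7, (0, 3): 0.4, (2, 3): 0.2}
        for (i, j), v in weights.items():
            w[i, j] = w[j, i] = v
        g = proportional_threshold(w, 3 / 6)  # m = 3
        assert set(map(frozenset, g.edges)) == {
            frozenset(p) for p in [(0, 1), (0, 2), (1, 2)]
        }

    @pytest.mark.parametrize("density", [0.05, 0.17, 0.5, 0.99])
    def test_edge_count_matches_rounding_oracle(self, density, random_connectome):
        g = proportional_threshold(random_connectome, density)
        assert g.number_of_edges() == int(np.floor(density * 190 + 0.5))

    def test_zero_edge_density_rejected(self):
        w = np.zeros((4, 4))
        with pytest.raises(DensityTooLowError):
            proportional_threshold(w, 0.01)

    def test_all_nodes_kept_as_isolates(self, random_connectome):
        g = proportional_threshold(random_connectome, 0.05)
        assert g.number_of_nodes() == 20


class TestRankNodes:
    def test_star_betweenness_starts_with_hub(self):
        g = nx.star_graph(4)  # hub is node 0
        order = rank_nodes(g, "betweenness", np.random.default_rng(0))
        assert order[0] == 0

    def test_path_tie_randomization_is_fair(self):
        g = nx.path_graph(4)  # b=1 and c=2 tie on betweenness
        rng = np.random.default_rng(1)
        first_b = sum(rank_nodes(g, "betweenness", rng)[0] == 1 for _ in range(1000))
        assert 450 <= first_b <= 550

    def test_cycle_all_tied_uniform_first_position(self):
        g = nx.cycle_graph(5)
        rng = np.random.default_rng(2)
        counts = np.zeros(5)
        for _ in range(2000):
            counts[rank_nodes(g, "eigenvector", rng)[0]] += 1
        assert counts.min() > 2000 / 5 * 0.75

    def test_random_strategy_is_permutation(self):
        g = nx.path_graph(6)
        order = rank_nodes(g, "random", np.random.default_rng(3))
        assert sorted(order) == list(range(6))

    def test_eigenvector_prefers_dominant_component_hub(self):
        g = nx.star_graph(5)
        g.add_edge(6, 7)  # small detached component
        order = rank_nodes(g, "eigenvector", np.random.default_rng(0))
        assert order[0] == 0
        assert set(order[-2:]) == {6, 7}  # near-zero scores fall to the end


class TestComponentTrace:
    def test_path_hand_enumeration(self):
        g = nx.path_graph(4)
        tr = component_trace(g, [1, 2, 0, 3])
        np.testing.assert_array_equal(tr.s1, [2, 1, 1, 0])
        np.testing.assert_array_equal(tr.s2, [1, 1, 0, 0])

    def test_complete_graph_never_fragments(self):
        g = nx.complete_graph(5)
        tr = component_trace(g, list(range(5)))
        assert np.all(tr.s2 == 0)

    def test_invalid_order_rejected(self):
        with pytest.raises(ConfigurationError):
            component_trace(nx.path_graph(3), [0, 1])

    def test_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            n = int(rng.integers(2, 9))
            g = nx.gnp_random_graph(n, rng.random(), seed=int(rng.integers(1 << 30)))
            order = list(rng.permutation(n))
            tr = component_trace(g, order)
            for k in range(1, n + 1):
                h = g.subgraph(order[k:])
                sizes = sorted((len(c) for c in nx.connected_components(h)), reverse=True)
                assert tr.s1[k - 1] == (sizes[0] if sizes else 0)
                assert tr.s2[k - 1] == (sizes[1] if len(sizes) > 1 else 0)

    def test_batch_kernel_agrees_with_reference(self):
        rng = np.random.default_rng(8)
        for _ in range(30):
            n = int(rng.integers(3, 12))
            g = nx.gnp_random_graph(n, rng.random(), seed=int(rng.integers(1 << 30)))
            orders = np.stack([rng.permutation(n) for _ in range(5)]).astype(np.int64)
            indptr, indices, _ = _graph_csr(g)
            perc, _ = batch_attack(indptr, indices, orders)
            for r in range(5):
                tr = component_trace(g, list(orders[r]))
                assert perc[r] == pytest.approx(percolation_point(tr))


class TestPercolationPoint:
    def test_path_first_peak(self):
        tr = component_trace(nx.path_graph(4), [1, 2, 0, 3])
        assert percolation_point(tr) == pytest.approx(0.25)

    def test_all_zero_trace_degenerate_convention(self):
        tr = component_trace(nx.complete_graph(5), list(range(5)))
        assert percolation_point(tr) == pytest.approx(0.2)

    def test_two_triangles_with_bridge(self):
        g = nx.Graph(
            [(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5), (2, 3)]
        )
        # removing bridge endpoint 2 first: components {0,1} and {3,4,5},
        # S2 = 2 = its maximum, reached at k = 1
        order = [2, 0, 1, 3, 4, 5]
        assert percolation_point(component_trace(g, order)) == pytest.approx(1 / 6)

    def test_isomorphism_invariance(self):
        g = nx.gnp_random_graph(7, 0.4, seed=3)
        perm = {v: (v * 3) % 7 for v in g.nodes}
        h = nx.relabel_nodes(g, perm)
        order = list(range(7))
        h_order = [perm[v] for v in order]
        assert percolation_point(component_trace(g, order)) == pytest.approx(
            percolation_point(component_trace(h, h_order))
        )


class TestRunAttacks:
    def test_deterministic_given_seed(self, random_connectome):
        cfg = AttackConfig(
            strategy="betweenness", densities=np.arange(1, 11) / 20, n_iter=10, seed=5
        )
        r1 = run_attacks(random_connectome, cfg)
        r2 = run_attacks(random_connectome, cfg)
        np.testing.assert_array_equal(r1.mean_percolation, r2.mean_percolation)
        np.testing.assert_array_equal(r1.prefail_majority, r2.prefail_majority)

    def test_unique_centralities_make_iterations_identical(self):
        # weighted path: distinct betweenness at every position
        w = np.zeros((6, 6))
        for i in range(5):
            w[i, i + 1] = w[i + 1, i] = 1.0 - 0.1 * i
        conn = Connectome(W=w, subject_id="path")
        cfg1 = AttackConfig(strategy="betweenness", densities=np.array([5 / 15]), n_iter=1, seed=0)
        cfg100 = AttackConfig(strategy="betweenness", densities=np.array([5 / 15]), n_iter=100, seed=9)
        p1 = run_attacks(conn, cfg1).mean_percolation[0]
        p100 = run_attacks(conn, cfg100).mean_percolation[0]
        assert p1 == pytest.approx(p100)

    def test_random_attack_mean_is_stable_across_seeds(self):
        g = nx.gnp_random_graph(30, 0.3, seed=0)
        w = nx.to_numpy_array(g)
        conn = Connectome(W=w)
        means = []
        for seed in range(10):
            cfg = AttackConfig(strategy="random", densities=np.array([1.0]), n_iter=100, seed=seed)
            means.append(run_attacks(conn, cfg).mean_percolation[0])
        assert np.std(means) < 0.05

    def test_too_low_density_recorded_as_missing(self):
        w = np.zeros((30, 30))
        w[0, 1] = w[1, 0] = 1.0
        cfg = AttackConfig(
            strategy="random", densities=np.array([0.001, 0.5]), n_iter=5, seed=1
        )
        r = run_attacks(Connectome(W=w), cfg)
        assert np.isnan(r.mean_percolation[0])
        assert np.isfinite(r.mean_percolation[1])

    def test_ec_attacks_no_later_than_random_on_star(self):
        # hub-and-spoke fixture: targeted EC removal hits the hub first
        w = np.zeros((10, 10))
        w[0, 1:] = w[1:, 0] = 1.0
        conn = Connectome(W=w)
        d = np.array([9 / 45])
        ec = run_attacks(conn, AttackConfig(strategy="eigenvector", densities=d, n_iter=20, seed=0))
        rnd = run_attacks(conn, AttackConfig(strategy="random", densities=d, n_iter=200, seed=0))
        assert ec.mean_percolation[0] <= rnd.mean_percolation[0]

    def test_invalid_config_rejected(self):
        with pytest.raises(ConfigurationError):
            AttackConfig(strategy="degree").validate()
        with pytest.raises(ConfigurationError):
            AttackConfig(densities=np.array([0.5, 0.4])).validate()
        with pytest.raises(ConfigurationError):
            AttackConfig(n_iter=0).validate()


class TestTraceInvariants:
    from hypothesis import given, seed, settings
    from hypothesis import strategies as st

    @given(
        n=st.integers(min_value=2, max_value=10),
        p=st.floats(min_value=0.0, max_value=1.0),
        graph_seed=st.integers(min_value=0, max_value=2**20),
    )
    @seed(1234)
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_component_sizes_and_percolation_bounds(self, n, p, graph_seed):
        g = nx.gnp_random_graph(n, p, seed=graph_seed)
        order = list(np.random.default_rng(graph_seed).permutation(n))
        tr = component_trace(g, order)
        for k in range(1, n + 1):
            assert tr.s1[k - 1] >= tr.s2[k - 1] >= 0
            assert tr.s1[k - 1] + tr.s2[k - 1] <= n - k
        pp = percolation_point(tr)
        assert 1 / n <= pp <= 1.0
        assert round(pp * n) == pytest.approx(pp * n)  # pp is a multiple of 1/N


class TestRemovalFrequencyMap:
    def _result(self, subject_id, mask):
        from netpercolate.attack import AttackResult

        return AttackResult(
            subject_id=subject_id,
            strategy="betweenness",
            densities=np.array([0.05]),
            mean_percolation=np.array([0.2]),
            prefail_majority=np.asarray(mask, dtype=bool)[None, :],
            n_iter=10,
        )

    def test_single_subject_binary_fractions(self):
        r = self._result("a", [1, 0, 1, 0])
        m = removal_frequency_map([r], 0.05)
        np.testing.assert_array_equal(m.frequencies, [1, 0, 1, 0])

    def test_disjoint_prefail_sets_give_halves(self):
        r1 = self._result("a", [1, 1, 0, 0])
        r2 = self._result("b", [0, 0, 1, 1])
        m = removal_frequency_map([r1, r2], 0.05)
        np.testing.assert_array_equal(m.frequencies, [0.5, 0.5, 0.5, 0.5])

    def test_empty_subset_rejected(self):
        with pytest.raises(ConfigurationError):
            removal_frequency_map([self._result("a", [1, 0])], 0.05, subject_ids=[])

    def test_unknown_density_rejected(self):
        with pytest.raises(ConfigurationError):
            removal_frequency_map([self._result("a", [1, 0])], 0.10)
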