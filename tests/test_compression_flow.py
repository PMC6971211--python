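import numpy as np
import pytest

import connlearn as cl
from connlearn.compression_flow import (
    betweenness,
    compression_flow,
    connected_component_count,
    peripheral_set,
    walks_to_center,
)
from connlearn.synthetic import toy_graph


class TestBetweenness:
    def test_star_leaves_zero(self):
        bc, ebc = betweenness(toy_graph("star", 6))
        assert np.allclose(bc[1:], 0.0)
        assert bc[0] == max(bc)
        assert len(ebc) == 5

    def test_path_matches_hand_count(self):
        # P5 pair counts: node 1 lies between (0,2),(0,3),(0,4); node 2
        # between (0,3),(0,4),(1,3),(1,4); normalised by (n-1)(n-2)/2 = 6
        bc, _ = betweenness(toy_graph("path", 5))
        assert np.allclose(bc, [0.0, 3 / 6, 4 / 6, 3 / 6, 0.0])

    def test_complete_graph_symmetric(self):
        bc, _ = betweenness(toy_graph("complete", 5))
        assert np.allclose(bc, bc[0])

    def test_empty_graph_rejected(self):
        with pytest.raises(ValueError):
            betweenness(np.zeros((0, 0)))


class TestPeripheralSet:
    @pytest.mark.parametrize("pct", [5, 10, 20])
    def test_star_periphery_is_leaves(self, pct):
        bc, _ = betweenness(toy_graph("star", 6))
        assert peripheral_set(bc, pct) == [1, 2, 3, 4, 5]

    def test_total_tie_includes_all(self):
        assert peripheral_set(np.zeros(7), 10) == list(range(7))

    def test_path_endpoints(self):
        bc, _ = betweenness(toy_graph("path", 5))
        assert peripheral_set(bc, 20) == [0, 4]


class TestWalks:
    def test_star_walk_traverses_spoke(self):
        edges = walks_to_center(toy_graph("star", 6), [3], center=0,
                               rng=np.random.default_rng(0))
        assert edges == {frozenset((3, 0))}

    @pytest.mark.parametrize("bias", ["bc", "weight", "uniform"])
    def test_path_walk_edge_set_is_route_prefix(self, bias):
        # on a path any walk from node 0 absorbed at node 2 can only
        # have used edges {0-1, 1-2}, whatever the backtracking
        edges = walks_to_center(toy_graph("path", 5), [0], center=2,
                               rng=np.random.default_rng(1), walk_bias=bias)
        assert edges == {frozenset((0, 1)), frozenset((1, 2))}

    def test_disconnected_source_truncates(self):
        W = np.zeros((5, 5))
        W[0, 1] = W[1, 0] = 1.0
        W[2, 3] = W[3, 2] = 1.0
        edges = walks_to_center(W, [2], center=0, rng=np.random.default_rng(2))
        assert edges == {frozenset((2, 3))}

    def test_no_sources_rejected(self):
        with pytest.raises(ValueError):
            walks_to_center(toy_graph("star", 4), [], center=0)


class TestComponentCount:
    def test_hand_counts(self):
        assert connected_component_count(set(), 5) == 5
        tree = {frozenset((i, i + 1)) for i in range(4)}
        assert connected_component_count(tree, 5) == 1
        two = {frozenset((0, 1)), frozenset((2, 3))}
        assert connected_component_count(two, 6) == 4


class TestCompressionFlow:
    def test_star_closed_form(self):
        # w spokes touch w+1 nodes, so n - |c| = w and every ratio is 1
        for seed in (0, 1, 2):
            res = compression_flow(toy_graph("star", 8), seed=seed)
            assert res.cf == pytest.approx(1.0)
            assert np.allclose(res.ratios, 1.0)
            assert res.center_node == 0

    def test_p5_closed_form(self):
        # every absorbed walk traces half the path: rho_1 = rho_2 = 1/2
        for seed in (0, 5, 9):
            res = compression_flow(toy_graph("path", 5), seed=seed)
            assert res.cf == pytest.approx(0.5)
            assert res.peripheral_set == [0, 4]

    def test_requires_edges(self):
        with pytest.raises(ValueError):
            compression_flow(np.zeros((4, 4)))

    def test_seed_reproducibility(self, small_connectomes):
        conn = small_connectomes[0]
        a = compression_flow(conn, seed=42)
        b = compression_flow(conn, seed=42)
        assert a.cf == b.cf and a.ratios == b.ratios

    def test_cf_result_invariants(self, small_connectomes):
        res = compression_flow(small_connectomes[1], seed=7)
        assert len(res.peripheral_set) >= 1
        assert all(r > 0 for r in res.ratios)
        assert res.cf == pytest.approx(np.mean(res.ratios))

    def test_seed_variability_is_small_on_modular_connectomes(self):
        """CF across 10 walk realisations has coefficient of variation < 10%."""
        import connlearn as cl

        spec = cl.CohortSpec(n_subjects=1, seed=4)
        conn = cl.build_connectome(cl.generate_cohort(spec)[0])
        values = [compression_flow(conn, seed=s).cf for s in range(10)]
        assert np.std(values) / np.mean(values) < 0.10


def test_integration_raises_cf(small_cohort, small_connectomes):
    """Run-2 style connectomes (denser between-module coupling) compress
    better than run-1 style ones on cohort average (walk-averaged CF)."""
    cf = {1: [], 2: []}
    for conn in small_connectomes:
        values = [compression_flow(conn, seed=s).cf for s in range(8)]
        cf[conn.meta["run"]].append(np.mean(values))
    assert np.mean(cf[2]) > np.mean(cf[1])
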