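"""The order-stepping pruning loop: relevance network, common neighbors,
per-order CMI pruning, worker partitioning and determinism."""

import numpy as np
import pytest

from cminet import (
    ExpressionMatrix,
    InferenceConfig,
    InvalidInputError,
    NetworkState,
    chain_fixture,
    common_neighbors,
    infer_network,
    initial_network,
    partition_pairs,
    prune_step,
    random_dag,
    simulate_expression,
    SynthConfig,
)


class TestPartitionPairs:
    @pytest.mark.parametrize(
        "n_pairs, n_workers, sizes",
        [
            (10, 2, [5, 5]),
            (10, 3, [4, 3, 3]),
            (2, 5, [1, 1, 0, 0, 0]),
            (0, 2, [0, 0]),
        ],
    )
    def test_sizes(self, n_pairs, n_workers, sizes):
        ranges = partition_pairs(n_pairs, n_workers)
        assert [hi - lo for lo, hi in ranges] == sizes

    def test_ranges_tile_the_index_space(self):
        for n_pairs in (0, 1, 7, 100):
            for n_workers in (1, 3, 8):
                ranges = partition_pairs(n_pairs, n_workers)
                covered = [i for lo, hi in ranges for i in range(lo, hi)]
                assert covered == list(range(n_pairs))

    def test_invalid_worker_count(self):
        with pytest.raises(InvalidInputError):
            partition_pairs(10, 0)


class TestInitialNetwork:
    def test_vacuous_cutoff_gives_empty_graph(self, toy_expression):
        state = initial_network(toy_expression, cutoff=1e6)
        assert state.edge_count() == 0
        assert state.order_completed == 0

    def test_negative_cutoff_gives_complete_graph(self, toy_expression):
        state = initial_network(toy_expression, cutoff=-1.0)
        assert state.edge_count() == 3  # all pairs: MI >= 0 > -1

    def test_correlated_pair_is_the_only_edge(self, toy_expression):
        # B = A + small noise, C independent; MI(A,B) >> 0.1 >> MI(.,C)
        state = initial_network(toy_expression, cutoff=0.1)
        assert state.edge_labels() == {("A", "B")}

    def test_duplicate_gene_labels_rejected(self):
        with pytest.raises(InvalidInputError):
            ExpressionMatrix(("A", "A"), ("S1", "S2", "S3"), np.zeros((2, 3)))

    def test_minimum_size_enforced(self, rng):
        one_gene = ExpressionMatrix(("A",), ("S1", "S2", "S3"), rng.normal(size=(1, 3)))
        with pytest.raises(InvalidInputError):
            initial_network(one_gene, 0.0)


def _state_from_adjacency(adj: np.ndarray) -> NetworkState:
    adj = np.asarray(adj, bool)
    return NetworkState(
        gene_labels=tuple(f"G{i+1}" for i in range(adj.shape[0])),
        weights=adj.astype(float),
        adjacency=adj,
        order_completed=0,
    )


class TestCommonNeighbors:
    def test_triangle(self):
        adj = np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]])
        assert common_neighbors(_state_from_adjacency(adj), 0, 1) == (2,)

    def test_edgeless_graph(self):
        assert common_neighbors(_state_from_adjacency(np.zeros((4, 4))), 0, 3) == ()

    def test_star_center_is_shared(self):
        adj = np.zeros((5, 5), bool)
        adj[0, 1:] = adj[1:, 0] = True  # S = gene 0, leaves 1..4
        assert common_neighbors(_state_from_adjacency(adj), 1, 2) == (0,)


class TestPruneStep:
    def test_no_eligible_edges_leaves_state_unchanged(self, toy_expression):
        state = initial_network(toy_expression, cutoff=0.1)  # single edge, no neighbors
        pruned = prune_step(state, 1, 0.1, toy_expression)
        assert pruned.edge_labels() == state.edge_labels()
        np.testing.assert_array_equal(pruned.weights, state.weights)
        assert pruned.order_completed == 1

    def test_chain_indirect_edge_removed(self):
        network, expr = chain_fixture(n_samples=1000, seed=42)
        state = initial_network(expr, cutoff=0.05)
        assert ("G1", "G2") in state.edge_labels()  # indirect pair present at order 0
        pruned = prune_step(state, 1, 0.05, expr)
        assert pruned.edge_labels() == {("G1", "G3"), ("G2", "G3")}

    def test_worker_partition_does_not_change_the_result(self):
        config = SynthConfig(n_genes=15, n_samples=300, avg_degree=3.0, seed=5)
        expr = simulate_expression(random_dag(config), config)
        state = initial_network(expr, cutoff=0.02)
        serial = prune_step(state, 1, 0.02, expr, workers=1)
        parallel = prune_step(state, 1, 0.02, expr, workers=4)
        np.testing.assert_array_equal(serial.weights, parallel.weights)
        np.testing.assert_array_equal(serial.adjacency, parallel.adjacency)

    def test_order_sequence_is_enforced(self, toy_expression):
        state = initial_network(toy_expression, cutoff=0.1)
        with pytest.raises(InvalidInputError):
            prune_step(state, 2, 0.1, toy_expression)


class TestInferNetwork:
    def test_order_zero_fixed_cutoff_is_the_relevance_network(self, toy_expression):
        direct = initial_network(toy_expression, cutoff=0.1)
        via_loop = infer_network(toy_expression, InferenceConfig(max_order=0, threshold_mode=0.1))
        np.testing.assert_array_equal(direct.weights, via_loop.weights)
        np.testing.assert_array_equal(direct.adjacency, via_loop.adjacency)

    def test_pruning_is_monotone_across_orders(self):
        config = SynthConfig(n_genes=10, n_samples=500, avg_degree=2.0, seed=9)
        expr = simulate_expression(random_dag(config), config)
        counts = []
        for order in (0, 1, 2):
            state = infer_network(expr, InferenceConfig(max_order=order, threshold_mode=0.03))
            counts.append(state.edge_count())
        assert counts[0] >= counts[1] >= counts[2]

    def test_edge_subsets_are_nested(self):
        config = SynthConfig(n_genes=12, n_samples=400, avg_degree=2.5, seed=21)
        expr = simulate_expression(random_dag(config), config)
        e0 = infer_network(expr, InferenceConfig(max_order=0, threshold_mode=0.03)).edge_labels()
        e1 = infer_network(expr, InferenceConfig(max_order=1, threshold_mode=0.03)).edge_labels()
        assert e1 <= e0

    def test_auto_threshold_runs_are_deterministic(self):
        config = SynthConfig(n_genes=15, n_samples=300, avg_degree=2.0, seed=3)
        expr = simulate_expression(random_dag(config), config)
        a = infer_network(expr, InferenceConfig(max_order=1, threshold_mode="auto"))
        b = infer_network(expr, InferenceConfig(max_order=1, threshold_mode="auto"))
        np.testing.assert_array_equal(a.weights, b.weights)
        np.testing.assert_array_equal(a.adjacency, b.adjacency)
        assert a.cutoffs_used == b.cutoffs_used

    def test_retained_weights_exceed_their_last_cutoff(self):
        config = SynthConfig(n_genes=12, n_samples=400, avg_degree=2.0, seed=13)
        expr = simulate_expression(random_dag(config), config)
        state = infer_network(expr, InferenceConfig(max_order=1, threshold_mode="auto"))
        # every retained edge was last judged at some order's cutoff; its
        # recorded weight must be strictly above the smallest cutoff applied
        assert all(
            state.weights[i, j] > min(state.cutoffs_used) for i, j in state.edges()
        )

    def test_early_stop_when_no_common_neighbors(self, toy_expression):
        # the single A-B edge has no common neighbor, so orders > 1 are skipped
        state = infer_network(toy_expression, InferenceConfig(max_order=3, threshold_mode=0.1))
        assert state.order_completed <= 1
        assert state.edge_labels() == {("A", "B")}

    def test_per_order_threshold_list(self, toy_expression):
        state = infer_network(toy_expression, InferenceConfig(max_order=1, threshold_mode=[0.1, 0.2]))
        assert state.cutoffs_used[0] == 0.1

    def test_invalid_config_rejected(self):
        with pytest.raises(InvalidInputError):
            InferenceConfig(max_order=-1)
        with pytest.raises(InvalidInputError):
            InferenceConfig(workers=0)
        with pytest.raises(InvalidInputError):
            InferenceConfig(threshold_mode="bogus")


def test_chain_pruning_succeeds_across_seeds():
    """Order-1 inference deletes the indirect chain edge in >= 18/20 seeds."""
    removed = 0
    for seed in range(20):
        _, expr = chain_fixture(n_samples=1000, seed=seed)
        state = infer_network(expr, InferenceConfig(max_order=1, threshold_mode=0.05))
        if ("G1", "G2") not in state.edge_labels():
            removed += 1
    assert removed >= 18
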