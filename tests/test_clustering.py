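"""Replicator dynamics, dominant sets, sequential partitioning, timelines."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dynfc import (
    DominantSetClustering,
    ZeroCohesionError,
    cohesive_index,
    dominant_set,
    dominant_timeline,
    partition,
    replicator_step,
    top_k_edges,
)
from oracles import exact_dominant_support, planted_clique_graph


def random_symmetric(rng, n):
    W = np.triu(rng.uniform(0, 1, (n, n)), 1)
    return W + W.T


class TestReplicator:
    def test_uniform_point_is_fixed_on_complete_unit_graph(self):
        W = np.ones((5, 5)) - np.eye(5)
        y = np.full(5, 0.2)
        np.testing.assert_allclose(replicator_step(y, W), y, atol=1e-15)

    def test_objective_never_decreases(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            W = random_symmetric(rng, int(rng.integers(3, 9)))
            y = rng.uniform(0.05, 1.0, W.shape[0])
            y /= y.sum()
            f_prev = y @ W @ y
            for _ in range(50):
                y = replicator_step(y, W)
                f = y @ W @ y
                assert f >= f_prev - 1e-12
                f_prev = f

    def test_simplex_preserved_over_long_runs(self):
        rng = np.random.default_rng(1)
        W = random_symmetric(rng, 6)
        y = np.full(6, 1 / 6)
        for _ in range(1000):
            y = replicator_step(y, W)
        assert y.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(y >= 0)

    def test_edgeless_graph_signals_no_cohesion(self):
        with pytest.raises(ZeroCohesionError):
            replicator_step(np.full(3, 1 / 3), np.zeros((3, 3)))


class TestDominantSet:
    def test_strong_clique_beats_weak_background(self):
        W = np.full((5, 5), 0.1)
        np.fill_diagonal(W, 0.0)
        for i, j in [(0, 1), (0, 2), (1, 2)]:
            W[i, j] = W[j, i] = 1.0
        support, y, converged = dominant_set(W)
        assert converged
        assert set(support) == {0, 1, 2}
        assert set(support) == set(exact_dominant_support(W))

    def test_heavier_of_two_disjoint_cliques_wins(self):
        W = np.zeros((6, 6))
        for i, j in [(0, 1), (0, 2), (1, 2)]:
            W[i, j] = W[j, i] = 1.0
        for i, j in [(3, 4), (3, 5), (4, 5)]:
            W[i, j] = W[j, i] = 0.5
        support, _, _ = dominant_set(W)
        assert set(support) == {0, 1, 2}
        assert set(support) == set(exact_dominant_support(W))

    def test_single_edge_supports_both_endpoints(self):
        W = np.zeros((2, 2))
        W[0, 1] = W[1, 0] = 0.8
        support, y, _ = dominant_set(W)
        assert set(support) == {0, 1}
        np.testing.assert_allclose(y, 0.5, atol=1e-9)

    def test_matches_exact_brute_force_on_planted_graphs(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            W = planted_clique_graph(rng, int(rng.integers(4, 7)))
            support, _, _ = dominant_set(W)
            assert frozenset(int(i) for i in support) == exact_dominant_support(W)

    def test_seeded_random_init_reproducible(self):
        rng_w = np.random.default_rng(3)
        W = planted_clique_graph(rng_w, 6)
        s1, y1, _ = dominant_set(W, rng=np.random.default_rng(42))
        s2, y2, _ = dominant_set(W, rng=np.random.default_rng(42))
        np.testing.assert_array_equal(s1, s2)
        np.testing.assert_allclose(y1, y2)


class TestPartition:
    def test_block_diagonal_extraction_order(self):
        W = np.zeros((6, 6))
        for i, j in [(0, 1), (0, 2), (1, 2)]:
            W[i, j] = W[j, i] = 1.0
        for i, j in [(3, 4), (3, 5), (4, 5)]:
            W[i, j] = W[j, i] = 0.5
        part = partition(W)
        np.testing.assert_array_equal(part.labels, [1, 1, 1, 2, 2, 2])
        assert part.ci[0] == pytest.approx(2.0)
        assert part.ci[1] == pytest.approx(1.0)

    def test_empty_graph_gives_all_singletons(self):
        part = partition(np.zeros((4, 4)))
        np.testing.assert_array_equal(sorted(part.labels), [1, 2, 3, 4])
        assert np.all(part.ci == 0.0)

    def test_labels_are_disjoint_and_exhaustive(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            n = int(rng.integers(3, 10))
            part = partition(random_symmetric(rng, n))
            assert part.labels.min() >= 1
            assert set(part.labels) == set(range(1, part.n_clusters + 1))

    def test_partition_equivariant_under_node_permutation(self):
        rng = np.random.default_rng(5)
        W = planted_clique_graph(rng, 6)
        perm = rng.permutation(6)
        p1 = partition(W)
        p2 = partition(W[np.ix_(perm, perm)])
        sets1 = {frozenset(np.flatnonzero(p1.labels == c)) for c in set(p1.labels)}
        sets2 = {
            frozenset(int(perm[i]) for i in np.flatnonzero(p2.labels == c))
            for c in set(p2.labels)
        }
        assert {frozenset(int(i) for i in s) for s in sets1} == sets2

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_partition_property_random_graphs(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 9))
        W = random_symmetric(rng, n)
        W[rng.uniform(size=W.shape) > 0.6] = 0
        W = np.triu(W, 1)
        W = W + W.T
        part = partition(W)
        assert part.labels.shape == (n,)
        assert np.all(part.labels >= 1)
        assert part.ci.shape == (part.n_clusters,)


class TestCohesiveIndex:
    def test_pair_ci_equals_edge_weight(self):
        W = np.zeros((4, 4))
        W[0, 1] = W[1, 0] = 0.6
        assert cohesive_index(W, np.array([0, 1])) == pytest.approx(0.6)

    def test_unit_triangle_ci_is_two(self):
        W = np.ones((3, 3)) - np.eye(3)
        assert cohesive_index(W, np.arange(3)) == pytest.approx(2.0)

    def test_matches_double_loop_sum(self):
        rng = np.random.default_rng(6)
        W = random_symmetric(rng, 7)
        cluster = np.array([0, 2, 3, 6])
        manual = sum(
            W[i, j] for i in cluster for j in cluster if i != j
        ) / cluster.size
        assert cohesive_index(W, cluster) == pytest.approx(manual, abs=1e-12)

    def test_empty_cluster_rejected(self):
        with pytest.raises(ValueError):
            cohesive_index(np.zeros((3, 3)), np.array([], dtype=int))


class TestDominantTimeline:
    def test_constant_block_series_gives_constant_strong_block(self, coupled_fcgs):
        W = np.zeros((6, 6))
        for i, j in [(0, 1), (0, 2), (1, 2)]:
            W[i, j] = W[j, i] = 1.0
        W[4, 5] = W[5, 4] = 0.5
        from dynfc.connectivity import FCGSeries

        n_lat = 4
        series = FCGSeries(
            adjacency=np.repeat(W[None], n_lat, axis=0),
            significance=np.repeat((W > 0)[None], n_lat, axis=0),
            raw=np.repeat(W[None], n_lat, axis=0),
            pvalues=np.zeros((n_lat, 6, 6)),
            latencies_ms=np.arange(n_lat, dtype=float),
            centers=np.arange(n_lat),
        )
        tl = dominant_timeline(series)
        expected = np.zeros((6, n_lat), dtype=bool)
        expected[[0, 1, 2]] = True
        np.testing.assert_array_equal(tl.membership, expected)

    def test_switch_latency_recovered_within_window_width(self, coupled_fcgs, coupled_dataset):
        _, truth = coupled_dataset
        ev = truth.events[0]
        tl = dominant_timeline(coupled_fcgs)
        active = np.flatnonzero(tl.membership.any(axis=0))
        assert active.size > 0
        w_ms = coupled_fcgs.window.w_l / 500.0 * 1e3
        first = tl.latencies_ms[active[0]]
        last = tl.latencies_ms[active[-1]]
        assert abs(first - ev.onset_ms) <= w_ms
        assert abs(last - ev.offset_ms) <= w_ms
        # inside the event, the dominant cluster is exactly the planted pair
        from conftest import in_window_mask

        for t in np.flatnonzero(in_window_mask(coupled_fcgs)):
            members = np.flatnonzero(tl.membership[:, t])
            assert set(members) == set(ev.pair)

    def test_column_count_matches_latency_count(self, coupled_fcgs):
        tl = dominant_timeline(coupled_fcgs)
        assert tl.membership.shape == (coupled_fcgs.n_roi, coupled_fcgs.n_latencies)

    def test_dominant_cluster_has_maximal_ci(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            W = planted_clique_graph(rng, 6)
            part = partition(W)
            lab = part.dominant_label()
            assert part.ci[lab - 1] == pytest.approx(part.ci.max())


class TestTopKEdges:
    def test_five_percent_of_fully_significant_200_nodes(self):
        rng = np.random.default_rng(8)
        W = random_symmetric(rng, 200)
        edges = top_k_edges(W, np.ones_like(W, dtype=bool), 5.0)
        assert len(edges) == 995  # floor(0.05 * 19900)

    def test_k_100_keeps_every_edge(self):
        rng = np.random.default_rng(9)
        W = random_symmetric(rng, 10)
        assert len(top_k_edges(W, np.ones_like(W, dtype=bool), 100.0)) == 45

    def test_nothing_significant_gives_empty_list(self):
        W = random_symmetric(np.random.default_rng(10), 8)
        assert top_k_edges(W, np.zeros_like(W, dtype=bool), 5.0) == []

    def test_edges_sorted_descending_with_pair_index_tiebreak(self):
        W = np.zeros((4, 4))
        W[0, 1] = W[1, 0] = 0.5
        W[0, 2] = W[2, 0] = 0.5
        W[1, 3] = W[3, 1] = 0.9
        edges = top_k_edges(W, np.ones_like(W, dtype=bool), 100.0)
        nonzero = [e for e in edges if e[2] > 0]
        assert nonzero == [(1, 3, 0.9), (0, 1, 0.5), (0, 2, 0.5)]


class TestSklearnEstimator:
    def test_fit_labels_match_partition(self):
        rng = np.random.default_rng(11)
        W = planted_clique_graph(rng, 6)
        est = DominantSetClustering().fit(W)
        np.testing.assert_array_equal(est.labels_, partition(W).labels - 1)
        assert est.n_clusters_ == est.cohesion_.size

    def test_get_params_roundtrip(self):
        est = DominantSetClustering(tol=1e-8)
        params = est.get_params()
        assert params["tol"] == 1e-8
        est2 = DominantSetClustering(**params)
        assert est2.get_params() == params
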