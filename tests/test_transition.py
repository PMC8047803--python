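"""Transition matrix, −log-probability graph, property maps, work profiles."""

import itertools

import networkx as nx
import numpy as np
import pytest

from pathsom.paths import PathTrace
from pathsom.transition import (
    build_graph,
    map_property,
    shortest_path_distance,
    transition_matrix,
    work_profile,
)


def _trace(bmus, force=None, extension=None):
    bmus = np.asarray(bmus, int)
    return PathTrace(
        replica_id="t",
        bmus=bmus,
        distances=np.zeros(len(bmus)),
        force=force,
        extension=extension,
    )


class TestTransitionMatrix:
    def test_hand_enumerated_counts(self):
        tg = transition_matrix([_trace([0, 0, 1, 1, 2])], n_neurons=3)
        expected = np.array([[1, 1, 0], [0, 1, 1], [0, 0, 0]], float)
        np.testing.assert_array_equal(tg.counts, expected)
        np.testing.assert_allclose(tg.stochastic[0], [0.5, 0.5, 0.0])
        np.testing.assert_allclose(tg.stochastic[1], [0.0, 0.5, 0.5])
        assert 2 in tg.isolated

    def test_constant_trace_is_pure_self_transition(self):
        tg = transition_matrix([_trace([3] * 10)], n_neurons=5)
        assert tg.stochastic[3, 3] == 1.0
        assert tg.counts.sum() == 9

    def test_row_sums_and_total_counts(self, trained_model, noiseless_dataset, noiseless_model):
        from pathsom.paths import trace_path

        traces = [trace_path(noiseless_model, r.features) for r in noiseless_dataset.replicas]
        tg = transition_matrix(traces, noiseless_model.n_neurons)
        occupied = tg.counts.sum(axis=1) > 0
        np.testing.assert_allclose(tg.stochastic[occupied].sum(axis=1), 1.0, atol=1e-12)
        assert tg.counts.sum() == sum(t.n_frames - 1 for t in traces)

    def test_exclude_self_mode(self):
        tg = transition_matrix([_trace([0, 0, 1, 1, 2])], n_neurons=3, include_self=False)
        assert np.all(np.diag(tg.counts) == 0)
        np.testing.assert_allclose(tg.stochastic[0], [0.0, 1.0, 0.0])

    def test_invariant_to_trace_splitting(self):
        whole = _trace([0, 1, 1, 2, 3, 3, 0])
        parts = [_trace([0, 1, 1, 2]), _trace([2, 3, 3, 0])]
        tg_whole = transition_matrix([whole], 4)
        tg_parts = transition_matrix(parts, 4)
        # splitting duplicates the boundary frame, so counts agree exactly
        np.testing.assert_array_equal(tg_whole.counts, tg_parts.counts)

    def test_rejects_empty_and_out_of_range(self):
        with pytest.raises(ValueError):
            transition_matrix([], 4)
        with pytest.raises(ValueError):
            transition_matrix([_trace([0, 9])], 4)


class TestGraph:
    def test_edge_weights_are_neg_log_probability(self):
        tg = transition_matrix([_trace([0, 1, 0, 2])], n_neurons=3)
        g = build_graph(tg)
        assert g[1][0]["weight"] == pytest.approx(0.0)  # p = 1
        assert g[0][1]["weight"] == pytest.approx(np.log(2))  # p = 0.5
        assert not g.has_edge(2, 0)  # p = 0

    def test_trivial_and_closed_form_paths(self):
        g = nx.DiGraph()
        for a, b, p in [(0, 2, 0.5), (2, 1, 0.5), (0, 1, 0.2)]:
            g.add_edge(a, b, weight=-np.log(p), probability=p)
        path, dist = shortest_path_distance(g, 0, 0)
        assert path == [] and dist == 0.0
        path, dist = shortest_path_distance(g, 0, 1)
        assert path == [0, 2, 1]
        assert dist == pytest.approx(2 * np.log(2))  # beats -ln 0.2 = ln 5

    def test_unreachable_gives_infinite_distance(self):
        g = nx.DiGraph()
        g.add_edge(0, 1, weight=0.1, probability=0.9)
        g.add_node(2)
        path, dist = shortest_path_distance(g, 1, 2)
        assert path == [] and np.isinf(dist)
        with pytest.raises(KeyError):
            shortest_path_distance(g, 0, 99)

    def test_matches_exhaustive_enumeration_on_small_graphs(self):
        rng = np.random.default_rng(1)
        for _ in range(30):
            n = int(rng.integers(3, 8))
            probs = rng.uniform(0.05, 1.0, (n, n)) * (rng.random((n, n)) < 0.5)
            np.fill_diagonal(probs, 0)
            row = probs.sum(axis=1, keepdims=True)
            with np.errstate(invalid="ignore"):
                probs = np.where(row > 0, probs / row, 0.0)
            g = nx.DiGraph()
            g.add_nodes_from(range(n))
            for a in range(n):
                for b in range(n):
                    if probs[a, b] > 0:
                        g.add_edge(a, b, weight=-np.log(probs[a, b]), probability=probs[a, b])
            a, b = rng.integers(0, n, 2)
            while b == a:
                b = int(rng.integers(0, n))
            _, dist = shortest_path_distance(g, int(a), int(b))
            # brute force over all simple paths
            best = np.inf
            for r in range(1, n):
                for mids in itertools.permutations([x for x in range(n) if x not in (a, b)], r - 1):
                    nodes = [a, *mids, b]
                    if all(g.has_edge(u, v) for u, v in zip(nodes[:-1], nodes[1:])):
                        w = sum(g[u][v]["weight"] for u, v in zip(nodes[:-1], nodes[1:]))
                        best = min(best, w)
            if np.isinf(best):
                assert np.isinf(dist)
            else:
                assert dist == pytest.approx(best, abs=1e-9)


class TestPropertyMap:
    def test_constant_force_everywhere(self):
        tr = _trace([0, 1, 1, 2], force=np.full(4, 7.0))
        pm = map_property([tr], 4)
        np.testing.assert_allclose(pm.mean[:3], 7.0)
        assert np.isnan(pm.mean[3])  # unvisited neuron is missing, not zero

    def test_mean_of_frames_in_a_neuron(self):
        tr = _trace([2, 2, 2], force=np.array([1.0, 2.0, 3.0]))
        pm = map_property([tr], 4)
        assert pm.mean[2] == pytest.approx(2.0)
        assert pm.count[2] == 3
        assert pm.sd[2] == pytest.approx(np.sqrt(2.0 / 3.0))

    def test_counts_cover_all_scalar_frames(self):
        traces = [
            _trace([0, 1, 2], force=np.ones(3)),
            _trace([1, 1], force=np.ones(2)),
        ]
        pm = map_property(traces, 4)
        assert pm.count.sum() == 5

    def test_invariant_to_trace_order(self):
        t1 = _trace([0, 1], force=np.array([1.0, 5.0]))
        t2 = _trace([1, 0], force=np.array([3.0, 2.0]))
        a = map_property([t1, t2], 3)
        b = map_property([t2, t1], 3)
        np.testing.assert_allclose(a.mean[:2], b.mean[:2])

    def test_missing_scalar_everywhere_raises(self):
        with pytest.raises(ValueError):
            map_property([_trace([0, 1])], 3)


class TestWorkProfile:
    def test_constant_force(self):
        x = np.linspace(0.0, 2.0, 21)
        w = work_profile(np.full_like(x, 10.0), x)
        assert w[0] == 0.0
        assert w[-1] == pytest.approx(20.0)  # F * Δx

    def test_zero_force(self):
        x = np.linspace(0.0, 5.0, 11)
        np.testing.assert_allclose(work_profile(np.zeros_like(x), x), 0.0)

    def test_triangle_area(self):
        x = np.linspace(0.0, 1.0, 101)
        w = work_profile(10.0 * x, x)
        assert w[-1] == pytest.approx(5.0, rel=1e-4)

    def test_monotone_for_nonnegative_force(self):
        rng = np.random.default_rng(0)
        x = np.sort(rng.uniform(0, 24, 50))
        f = rng.uniform(0, 500, 50)
        assert np.all(np.diff(work_profile(f, x)) >= 0)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            work_profile(np.ones(3), np.ones(4))
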