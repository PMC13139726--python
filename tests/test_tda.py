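"""Persistence computation: hand examples, oracles, and invariances."""

import itertools

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tdagene.tda import (
    Filtration,
    TDAConfig,
    TDAFeatures,
    compute_tda_features,
    edge_filtration,
    persistent_homology,
    summarize,
)


def dim0_oracle(n_nodes, edges, weights):
    """Incremental component tracking: a component-count drop at edge k
    emits death w_k.  Independent of the Union-Find implementation."""
    g = nx.Graph()
    g.add_nodes_from(range(n_nodes))
    deaths = []
    order = np.argsort(weights, kind="stable")
    prev = nx.number_connected_components(g)
    for k in order:
        g.add_edge(*edges[k])
        cur = nx.number_connected_components(g)
        if cur < prev:
            deaths.append(weights[k])
        prev = cur
    return sorted(deaths)


class TestFiltration:
    def test_identical_vectors_weight_zero(self):
        x = np.array([[1.0, 2.0], [1.0, 2.0]])
        f = edge_filtration(x, [(0, 1)])
        assert f.weights[0] == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("scale,expected", [(1.0, 1.0), (0.5, 0.5)])
    def test_orthogonal_vectors_scale(self, scale, expected):
        x = np.array([[1.0, 0.0], [0.0, 1.0]])
        f = edge_filtration(x, [(0, 1)], TDAConfig(scale=scale))
        assert f.weights[0] == pytest.approx(expected)

    def test_antiparallel_vectors(self):
        x = np.array([[1.0, 0.0], [-1.0, 0.0]])
        f = edge_filtration(x, [(0, 1)])
        assert f.weights[0] == pytest.approx(2.0)

    def test_zero_norm_policy(self):
        # all-zero profile carries no similarity evidence: cosine treated as 0
        x = np.array([[0.0, 0.0], [1.0, 1.0]])
        f = edge_filtration(x, [(0, 1)], TDAConfig(scale=1.5))
        assert f.weights[0] == pytest.approx(1.5)

    def test_symmetrized_duplicates_collapse(self):
        x = np.random.default_rng(0).random((3, 4))
        f = edge_filtration(x, [(0, 1), (1, 0), (2, 1), (1, 1)])
        assert len(f.weights) == 2
        assert (f.edges[:, 0] < f.edges[:, 1]).all()


class TestPersistence:
    def test_edgeless_graph(self):
        f = Filtration(np.empty((0, 2), dtype=int), np.empty(0), 5)
        p = persistent_homology(f)
        assert len(p.dim0_deaths) == 0 and len(p.dim1_births) == 0

    def test_triangle_hand_example(self):
        f = Filtration(np.array([[0, 1], [1, 2], [0, 2]]),
                       np.array([0.1, 0.2, 0.3]), 3)
        p = persistent_homology(f)
        assert list(p.dim0_deaths) == [0.1, 0.2]
        assert list(p.dim1_births) == [0.3]
        t = summarize(p)
        assert t.avg_pers0 == pytest.approx(0.15)
        assert t.max_pers0 == pytest.approx(0.2)
        assert t.norm_pers0 == pytest.approx(0.75, abs=1e-6)
        assert t.num_cycles == 1

    def test_tree_has_no_cycles(self, rng):
        # any tree: every edge merges
        n = 12
        edges = np.array([[i, rng.integers(0, i)] for i in range(1, n)])
        edges = np.sort(edges, axis=1)
        w = rng.random(n - 1)
        f = Filtration(edges[np.argsort(w, kind="stable")], np.sort(w), n)
        p = persistent_homology(f)
        assert len(p.dim0_deaths) == n - 1
        assert len(p.dim1_births) == 0

    def test_dim0_matches_component_oracle_exhaustive_k5(self):
        """All 2^10 edge subsets of K5, random weights: dim-0 diagram equals
        the incremental component-tracking oracle as a multiset."""
        rng = np.random.default_rng(42)
        all_edges = list(itertools.combinations(range(5), 2))
        for mask in range(1 << len(all_edges)):
            edges = [e for i, e in enumerate(all_edges) if mask >> i & 1]
            if not edges:
                continue
            w = rng.random(len(edges))
            order = np.argsort(w, kind="stable")
            f = Filtration(np.array(edges)[order], w[order], 5)
            p = persistent_homology(f)
            assert sorted(p.dim0_deaths) == pytest.approx(
                dim0_oracle(5, edges, w))

    @pytest.mark.parametrize("n_nodes", [6, 7, 8])
    def test_dim0_matches_component_oracle_random(self, n_nodes):
        rng = np.random.default_rng(n_nodes)
        all_edges = list(itertools.combinations(range(n_nodes), 2))
        for _ in range(60):
            k = rng.integers(1, len(all_edges) + 1)
            idx = rng.choice(len(all_edges), size=k, replace=False)
            edges = [all_edges[i] for i in idx]
            w = rng.random(k)
            order = np.argsort(w, kind="stable")
            f = Filtration(np.array(edges)[order], w[order], n_nodes)
            p = persistent_homology(f)
            assert sorted(p.dim0_deaths) == pytest.approx(
                dim0_oracle(n_nodes, edges, w))

    def test_euler_relation_on_random_graphs(self):
        """num_cycles == |E| - (|V| - C) on 120 Erdos-Renyi graphs,
        components counted by an independent library."""
        rng = np.random.default_rng(1)
        for trial in range(120):
            n = int(rng.integers(2, 25))
            p_edge = rng.uniform(0.05, 0.5)
            g = nx.gnp_random_graph(n, p_edge, seed=int(rng.integers(2**31)))
            edges = list(g.edges)
            if not edges:
                continue
            w = rng.random(len(edges))
            order = np.argsort(w, kind="stable")
            f = Filtration(np.array(edges)[order], w[order], n)
            pp = persistent_homology(f)
            c_final = nx.number_connected_components(g)
            assert len(pp.dim1_births) == len(edges) - (n - c_final)
            assert len(pp.dim0_deaths) == n - c_final


class TestSummary:
    def test_degenerate_default_vector(self):
        t = compute_tda_features(np.random.default_rng(0).random((5, 3)), [])
        assert (t.avg_pers0, t.num_cycles, t.max_pers0, t.norm_pers0) == \
            (0.0, 0, 0.0, 0.0)

    def test_single_edge(self):
        p = persistent_homology(
            Filtration(np.array([[0, 1]]), np.array([0.4]), 2))
        t = summarize(p)
        assert t.avg_pers0 == pytest.approx(0.4)
        assert t.max_pers0 == pytest.approx(0.4)
        assert t.norm_pers0 == pytest.approx(1.0, abs=1e-6)
        assert t.num_cycles == 0

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_summary_bounds(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 15))
        x = rng.standard_normal((n, 6))
        k = int(rng.integers(1, n * (n - 1) // 2 + 1))
        pairs = list(itertools.combinations(range(n), 2))
        idx = rng.choice(len(pairs), size=k, replace=False)
        t = compute_tda_features(x, [pairs[i] for i in idx])
        assert 0.0 <= t.norm_pers0 <= 1.0
        assert t.avg_pers0 <= t.max_pers0 + 1e-12
        assert t.num_cycles >= 0


class TestPipelineProperties:
    def _random_instance(self, seed, n=20):
        rng = np.random.default_rng(seed)
        x = rng.standard_normal((n, 8))
        pairs = list(itertools.combinations(range(n), 2))
        idx = rng.choice(len(pairs), size=30, replace=False)
        return x, [pairs[i] for i in idx]

    def test_deterministic(self):
        x, edges = self._random_instance(5)
        assert compute_tda_features(x, edges) == compute_tda_features(x, edges)

    @pytest.mark.parametrize("seed", range(5))
    def test_node_relabeling_invariance(self, seed):
        x, edges = self._random_instance(seed)
        perm = np.random.default_rng(seed + 100).permutation(len(x))
        x2 = x[np.argsort(perm)]
        edges2 = [(perm[u], perm[v]) for u, v in edges]
        t1, t2 = compute_tda_features(x, edges), compute_tda_features(x2, edges2)
        assert t1.num_cycles == t2.num_cycles
        assert t1.avg_pers0 == pytest.approx(t2.avg_pers0)
        assert t1.max_pers0 == pytest.approx(t2.max_pers0)

    def test_weight_scaling_identity(self):
        """scale multiplies avg/max linearly; cycles and norm are invariant
        (up to the sigma stabilizer)."""
        x, edges = self._random_instance(9)
        t1 = compute_tda_features(x, edges, TDAConfig(scale=1.0))
        t2 = compute_tda_features(x, edges, TDAConfig(scale=2.0))
        assert t2.avg_pers0 == pytest.approx(2 * t1.avg_pers0)
        assert t2.max_pers0 == pytest.approx(2 * t1.max_pers0)
        assert t2.num_cycles == t1.num_cycles
        assert t2.norm_pers0 == pytest.approx(t1.norm_pers0, abs=1e-6)

    def test_scale_zero_collapses_weights(self):
        x, edges = self._random_instance(11)
        t = compute_tda_features(x, edges, TDAConfig(scale=0.0))
        assert t.avg_pers0 == 0.0 and t.max_pers0 == 0.0
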