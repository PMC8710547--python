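"""Graph metrics against closed forms and brute-force oracles."""

import numpy as np
import networkx as nx
import pytest

import funconn as fc
from funconn.metrics import NullModelConfig, all_metrics, null_cp_lp

from oracles import (
    cp_oracle,
    eg_oracle,
    eloc_oracle,
    floyd_warshall,
    lp_oracle,
    ncp_oracle,
    ne_oracle,
    nle_oracle,
    random_graph,
)


def complete(n):
    a = np.ones((n, n), dtype=bool)
    np.fill_diagonal(a, False)
    return a


def star(n):
    a = np.zeros((n, n), dtype=bool)
    a[0, 1:] = True
    a[1:, 0] = True
    return a


def path3():
    a = np.zeros((3, 3), dtype=bool)
    a[0, 1] = a[1, 0] = a[1, 2] = a[2, 1] = True
    return a


class TestClosedForms:
    def test_complete_graph_all_ones(self):
        gm = fc.global_metrics(complete(5))
        assert gm.cp == 1.0 and gm.lp == 1.0 and gm.eg == 1.0 and gm.eloc == 1.0
        nm = fc.nodal_metrics(complete(5))
        assert np.all(nm.ne == 1.0) and np.all(nm.nle == 1.0) and np.all(nm.ncp == 1.0)

    def test_star_graph_clustering_zero(self):
        a = star(6)
        assert fc.nodal_clustering(a, 0) == 0.0
        assert fc.global_metrics(a).cp == 0.0

    def test_path3_efficiency(self):
        gm = fc.global_metrics(path3())
        assert gm.eg == pytest.approx(5.0 / 6.0, abs=1e-15)
        d = fc.shortest_paths(path3())
        assert d[0, 2] == 2.0

    def test_empty_graph(self):
        a = np.zeros((5, 5), dtype=bool)
        gm = fc.global_metrics(a)
        assert gm.cp == 0.0 and gm.eg == 0.0 and gm.eloc == 0.0
        assert np.isnan(gm.lp)

    def test_isolated_node_zero_metrics(self):
        a = complete(4)
        a = np.pad(a, (0, 1))  # node 4 isolated
        nm = fc.nodal_metrics(a.astype(bool))
        assert nm.ne[4] == 0.0 and nm.nle[4] == 0.0 and nm.ncp[4] == 0.0

    def test_disconnected_pair_infinite_distance(self):
        a = np.zeros((4, 4), dtype=bool)
        a[0, 1] = a[1, 0] = True
        d = fc.shortest_paths(a)
        assert np.isinf(d[0, 2]) and np.isinf(d[2, 3])


class TestOracleEquivalence:
    def test_all_metrics_match_bruteforce(self, rng):
        for _ in range(50):
            n = int(rng.integers(4, 16))
            adj = random_graph(rng, n, float(rng.uniform(0.2, 0.8)))
            gm, nm = all_metrics(adj)
            assert np.array_equal(fc.shortest_paths(adj), floyd_warshall(adj))
            assert gm.cp == pytest.approx(cp_oracle(adj), abs=1e-12)
            lp_ref = lp_oracle(adj)
            assert (np.isnan(gm.lp) and np.isnan(lp_ref)) or gm.lp == pytest.approx(
                lp_ref, abs=1e-12
            )
            assert gm.eg == pytest.approx(eg_oracle(adj), abs=1e-12)
            assert gm.eloc == pytest.approx(eloc_oracle(adj), abs=1e-12)
            for i in range(n):
                assert nm.ncp[i] == pytest.approx(ncp_oracle(adj, i), abs=1e-12)
                assert nm.ne[i] == pytest.approx(ne_oracle(adj, i), abs=1e-12)
                assert nm.nle[i] == pytest.approx(nle_oracle(adj, i), abs=1e-12)

    def test_nodal_means_equal_global(self, rng):
        for _ in range(20):
            adj = random_graph(rng, 12, 0.4)
            gm, nm = all_metrics(adj)
            assert gm.cp == pytest.approx(nm.ncp.mean(), abs=1e-12)
            assert gm.eg == pytest.approx(nm.ne.mean(), abs=1e-12)
            assert gm.eloc == pytest.approx(nm.nle.mean(), abs=1e-12)

    def test_relabeling_invariance(self, rng):
        adj = random_graph(rng, 14, 0.35)
        perm = rng.permutation(14)
        permuted = adj[np.ix_(perm, perm)]
        g1, g2 = fc.global_metrics(adj), fc.global_metrics(permuted)
        assert g1.cp == g2.cp and g1.lp == g2.lp
        assert g1.eg == g2.eg and g1.eloc == g2.eloc

    def test_adding_edge_never_decreases_eg(self, rng):
        for _ in range(100):
            adj = random_graph(rng, 10, 0.3)
            empty = np.argwhere(~adj & ~np.eye(10, dtype=bool))
            i, j = empty[rng.integers(len(empty))]
            before = fc.global_metrics(adj).eg
            adj2 = adj.copy()
            adj2[i, j] = adj2[j, i] = True
            assert fc.global_metrics(adj2).eg >= before - 1e-15


class TestRewiring:
    def test_degree_sequence_preserved(self, rng):
        for _ in range(30):
            adj = random_graph(rng, 15, 0.4)
            if adj.sum() < 4:
                continue
            null = fc.rewire_null(adj, NullModelConfig(seed=int(rng.integers(1 << 30))))
            assert np.array_equal(
                np.sort(adj.sum(axis=1)), np.sort(null.adjacency.sum(axis=1))
            )
            assert null.adjacency.sum() == adj.sum()
            assert not np.diag(null.adjacency).any()

    def test_complete_graph_is_rigid(self):
        a = complete(5)
        null = fc.rewire_null(a, NullModelConfig(seed=3))
        assert np.array_equal(null.adjacency, a)

    def test_two_disjoint_edges_swap(self):
        a = np.zeros((4, 4), dtype=bool)
        a[0, 1] = a[1, 0] = a[2, 3] = a[3, 2] = True
        legal = [
            {(0, 1), (2, 3)},  # unchanged (proposal rejected)
            {(0, 3), (1, 2)},
            {(0, 2), (1, 3)},
        ]
        for seed in range(10):
            null = fc.rewire_null(a, NullModelConfig(seed=seed))
            edges = {tuple(e) for e in null.edge_list()}
            assert edges in legal

    def test_deterministic_given_seed(self, rng):
        adj = random_graph(rng, 20, 0.3)
        n1 = fc.rewire_null(adj, NullModelConfig(seed=7))
        n2 = fc.rewire_null(adj, NullModelConfig(seed=7))
        assert np.array_equal(n1.adjacency, n2.adjacency)

    def test_too_few_edges_warns_and_returns_input(self):
        a = np.zeros((3, 3), dtype=bool)
        a[0, 1] = a[1, 0] = True
        with pytest.warns(UserWarning, match="rewire"):
            null = fc.rewire_null(a)
        assert np.array_equal(null.adjacency, a)


class TestNormalized:
    def test_sigma_is_gamma_over_lambda(self, rng):
        adj = random_graph(rng, 30, 0.3)
        gamma, lam, sigma = fc.normalized_metrics(adj, NullModelConfig(n_nulls=20, seed=1))
        assert sigma == pytest.approx(gamma / lam, abs=1e-12)

    def test_ring_lattice_small_world(self):
        g = nx.watts_strogatz_graph(100, 6, 0.1, seed=4)
        adj = nx.to_numpy_array(g).astype(bool)
        gamma, lam, _ = fc.normalized_metrics(adj, NullModelConfig(n_nulls=50, seed=2))
        assert gamma > 1.5
        assert 0.9 < lam < 1.6  # near-random path length, far-from-random clustering
        assert gamma > lam

    def test_null_cp_lp_seeded(self, rng):
        adj = random_graph(rng, 20, 0.3)
        cfg = NullModelConfig(n_nulls=10, seed=5)
        c1, l1 = null_cp_lp(adj, cfg)
        c2, l2 = null_cp_lp(adj, cfg)
        assert np.array_equal(c1, c2) and np.array_equal(l1, l2)


class TestAuc:
    def test_constant_curve(self):
        thr = fc.SparsitySweep().thresholds
        assert fc.auc_over_sweep(thr, np.full(31, 2.0)) == pytest.approx(0.6, abs=1e-12)

    def test_linear_ramp(self):
        thr = fc.SparsitySweep().thresholds
        ramp = np.linspace(0.0, 1.0, 31)
        assert fc.auc_over_sweep(thr, ramp) == pytest.approx(0.15, abs=1e-12)

    def test_missing_value_propagates(self, caplog):
        thr = np.array([0.1, 0.2, 0.3])
        vals = np.array([1.0, np.nan, 1.0])
        assert np.isnan(fc.auc_over_sweep(thr, vals))

    def test_single_threshold_errors(self):
        with pytest.raises(ValueError):
            fc.auc_over_sweep(np.array([0.1]), np.array([1.0]))
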