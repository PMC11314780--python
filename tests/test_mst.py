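"""Minimum spanning tree construction and topology metrics.

Every metric is checked against a hand-written path-enumeration oracle, and
tree construction against exhaustive spanning-tree search.
"""

import math

import networkx as nx
import numpy as np
import pytest

from eegfc.mst import (
    SpanningTree,
    betweenness,
    build_mst,
    degree_correlation,
    diameter,
    eccentricity,
    kappa,
    leaf_fraction,
    mst_features,
    tree_hierarchy,
)

from conftest import (
    oracle_best_spanning_tree_weight,
    oracle_tree_metrics,
    random_tree_edges,
)


def _tree_from_edges(edges, n):
    g = nx.Graph()
    g.add_nodes_from(range(n))
    g.add_edges_from(edges)
    return SpanningTree(g)


def _star(n):
    return _tree_from_edges([(0, i) for i in range(1, n)], n)


def _line(n):
    return _tree_from_edges([(i, i + 1) for i in range(n - 1)], n)


def _random_pli(n, rng):
    v = rng.uniform(0, 1, size=(n, n))
    v = (v + v.T) / 2
    np.fill_diagonal(v, 0.0)
    return v


class TestBuildMST:
    def test_three_node_example_keeps_strongest_pair(self):
        v = np.zeros((3, 3))
        v[0, 1] = v[1, 0] = 0.9
        v[0, 2] = v[2, 0] = 0.1
        v[1, 2] = v[2, 1] = 0.5
        tree = build_mst(v)
        assert sorted(tuple(sorted(e[:2])) for e in tree.edge_list()) == [(0, 1), (1, 2)]

    def test_always_a_spanning_tree(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            n = int(rng.integers(2, 12))
            tree = build_mst(_random_pli(n, rng))
            assert tree.n_edges == n - 1
            assert nx.is_connected(tree.graph)
            assert nx.is_tree(tree.graph)

    def test_matches_exhaustive_search(self):
        # total retained PLI equals the maximum over all spanning trees
        rng = np.random.default_rng(42)
        for i in range(100):
            n = int(rng.integers(4, 8))
            v = _random_pli(n, rng)
            tree = build_mst(v)
            total = sum(w for _, _, w in tree.edge_list())
            assert total == pytest.approx(oracle_best_spanning_tree_weight(v), abs=1e-9)

    def test_deterministic_under_ties(self):
        v = np.full((6, 6), 0.5)
        np.fill_diagonal(v, 0.0)
        a = build_mst(v).edge_list()
        b = build_mst(v).edge_list()
        assert a == b
        # lexicographic tie-break keeps the smallest-index edges: a star at node 0
        assert [e[:2] for e in a] == [(0, j) for j in range(1, 6)]

    def test_asymmetric_and_tiny_inputs_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            build_mst(np.array([[0.0, 0.2], [0.3, 0.0]]))
        with pytest.raises(ValueError, match="at least 2"):
            build_mst(np.zeros((1, 1)))


class TestClosedForms:
    def test_star_52(self):
        tree = _star(52)
        assert leaf_fraction(tree) == pytest.approx(51 / 52)
        assert diameter(tree) == 2
        bc, _, bmax = betweenness(tree)
        assert bc[0] == 1.0
        assert all(bc[i] == 0.0 for i in range(1, 52))
        assert bmax == 1.0
        assert tree_hierarchy(tree) == pytest.approx(0.5)

    def test_line_52_leaf_fraction_floor(self):
        assert leaf_fraction(_line(52)) == pytest.approx(2 / 52)

    def test_line_4(self):
        tree = _line(4)
        assert leaf_fraction(tree) == 0.5
        assert diameter(tree) == 3
        ecc, ecc_mean = eccentricity(tree)
        assert [ecc[i] for i in range(4)] == [3, 2, 2, 3]
        assert ecc_mean == 2.5
        bc, _, _ = betweenness(tree)
        assert bc[1] == pytest.approx(2 / 3)
        assert bc[2] == pytest.approx(2 / 3)
        assert tree_hierarchy(tree) == pytest.approx(0.5)
        assert degree_correlation(tree) == pytest.approx(-0.5)
        assert kappa(tree) == pytest.approx(5 / 3)

    def test_star_4(self):
        tree = _star(4)
        assert kappa(tree) == pytest.approx(2.0)
        assert degree_correlation(tree) == pytest.approx(-1.0)

    def test_star_diameter_2_any_n(self):
        for n in (3, 10, 52):
            assert diameter(_star(n)) == 2

    def test_line_100_tree_hierarchy_closed_form(self):
        # middle node of a 100-path mediates 49*50 pairs
        tree = _line(100)
        bmax = (49 * 50) / ((99 * 98) / 2)
        assert tree_hierarchy(tree) == pytest.approx(2 / (2 * 99 * bmax))
        assert tree_hierarchy(tree) == pytest.approx(0.0200, abs=5e-4)

    def test_two_node_degree_correlation_undefined(self):
        assert math.isnan(degree_correlation(_tree_from_edges([(0, 1)], 2)))


class TestOracleEquivalence:
    def test_all_metrics_match_path_enumeration_oracle(self):
        rng = np.random.default_rng(7)
        for i in range(100):
            n = int(rng.integers(3, 21))
            edges = random_tree_edges(n, rng)
            tree = _tree_from_edges(edges, n)
            oracle = oracle_tree_metrics(edges, n)
            assert leaf_fraction(tree) == pytest.approx(oracle["leaf_fraction"])
            assert diameter(tree) == oracle["diameter"]
            ecc, ecc_mean = eccentricity(tree)
            assert ecc_mean == pytest.approx(oracle["eccentricity_mean"])
            bc, bc_mean, bmax = betweenness(tree)
            np.testing.assert_allclose(
                [bc[v] for v in range(n)], oracle["betweenness"], atol=1e-12
            )
            assert bmax == pytest.approx(oracle["betweenness_max"])
            assert tree_hierarchy(tree) == pytest.approx(oracle["tree_hierarchy"])
            dc = degree_correlation(tree)
            if math.isnan(oracle["degree_correlation"]):
                assert math.isnan(dc)
            else:
                assert dc == pytest.approx(oracle["degree_correlation"])
            assert kappa(tree) == pytest.approx(oracle["kappa"])

    def test_betweenness_path_length_identity(self):
        # sum over nodes of raw path counts = sum over pairs of (path length - 1)
        rng = np.random.default_rng(11)
        for _ in range(20):
            n = int(rng.integers(3, 15))
            edges = random_tree_edges(n, rng)
            oracle = oracle_tree_metrics(edges, n)
            lhs = oracle["raw_betweenness"].sum()
            rhs = sum(len(p) - 2 for p in oracle["paths"].values())
            assert lhs == rhs

    def test_mean_degree_handshake_identity(self):
        rng = np.random.default_rng(13)
        for _ in range(20):
            n = int(rng.integers(2, 30))
            tree = _tree_from_edges(random_tree_edges(n, rng), n)
            assert tree.degrees.mean() == pytest.approx(2 * (n - 1) / n)

    def test_diameter_is_max_eccentricity(self):
        rng = np.random.default_rng(17)
        for _ in range(20):
            n = int(rng.integers(3, 25))
            tree = _tree_from_edges(random_tree_edges(n, rng), n)
            ecc, _ = eccentricity(tree)
            assert diameter(tree) == max(ecc.values())


class TestFeatureBundle:
    def test_bundle_matches_individual_metrics(self):
        rng = np.random.default_rng(19)
        tree = build_mst(_random_pli(12, rng))
        f = mst_features(tree)
        assert f.leaf_fraction == leaf_fraction(tree)
        assert f.diameter == diameter(tree)
        assert f.eccentricity_mean == eccentricity(tree)[1]
        _, bc_mean, bmax = betweenness(tree)
        assert f.betweenness_mean == bc_mean
        assert f.betweenness_max == bmax
        assert f.tree_hierarchy == tree_hierarchy(tree)
        assert f.kappa == kappa(tree)

    def test_star_and_line_bundles(self):
        star = mst_features(_star(52))
        assert star.leaf_fraction == pytest.approx(51 / 52)
        assert star.diameter == 2
        assert star.tree_hierarchy == pytest.approx(0.5)
        assert star.betweenness_max == 1.0
        line = mst_features(_line(4))
        assert line.leaf_fraction == 0.5
        assert line.diameter == 3
        assert line.eccentricity_mean == 2.5
        assert line.degree_correlation == pytest.approx(-0.5)
        assert line.kappa == pytest.approx(5 / 3)

    def test_topology_monotone_from_line_to_star(self):
        # interpolate a line-favoring PLI matrix toward a star-favoring one:
        # leaf fraction and kappa rise, diameter and mean eccentricity fall
        n = 20
        line_pli = np.zeros((n, n))
        for i in range(n - 1):
            line_pli[i, i + 1] = line_pli[i + 1, i] = 0.9
        star_pli = np.zeros((n, n))
        for i in range(1, n):
            star_pli[0, i] = star_pli[i, 0] = 0.9
        base = np.full((n, n), 0.05)
        np.fill_diagonal(base, 0.0)
        lf, ks, diams, eccs = [], [], [], []
        for alpha in np.linspace(0, 1, 5):
            v = base + (1 - alpha) * line_pli + alpha * star_pli
            f = mst_features(build_mst(v))
            lf.append(f.leaf_fraction)
            ks.append(f.kappa)
            diams.append(f.diameter)
            eccs.append(f.eccentricity_mean)
        assert lf[-1] > lf[0] and ks[-1] > ks[0]
        assert diams[-1] < diams[0] and eccs[-1] < eccs[0]
        assert all(np.diff(lf) >= 0) and all(np.diff(diams) <= 0)
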