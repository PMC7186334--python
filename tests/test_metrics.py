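"""Graph-measure correctness against brute-force oracles and closed forms."""

import numpy as np
import networkx as nx
import pytest

from wmhnet import (DisconnectedGraphError, WeightedGraph, global_cp,
                    global_eg, global_eloc, global_lp, global_metrics,
                    network_density, network_strength, nodal_metrics,
                    shortest_path_matrix)
from wmhnet.metrics import network_summary

from _oracles import (brute_density, brute_global_cp, brute_global_eg,
                      brute_global_eloc, brute_nodal, brute_strength,
                      floyd_warshall, random_weighted_graph)


def _graph(edges, n):
    W = np.zeros((n, n))
    for i, j, w in edges:
        W[i, j] = W[j, i] = w
    return W


TRIANGLE = _graph([(0, 1, 1), (1, 2, 1), (0, 2, 1)], 3)
TRIANGLE_HALF = _graph([(0, 1, 0.5), (1, 2, 0.5), (0, 2, 0.5)], 3)
PATH4 = _graph([(0, 1, 1), (1, 2, 1), (2, 3, 1)], 4)
STAR5 = _graph([(0, i, 1) for i in range(1, 5)], 5)
K4 = _graph([(i, j, 1) for i in range(4) for j in range(i + 1, 4)], 4)
K5 = _graph([(i, j, 1) for i in range(5) for j in range(i + 1, 5)], 5)
EMPTY4 = np.zeros((4, 4))


class TestShortestPaths:
    def test_single_edge_reciprocal_weight(self):
        D = shortest_path_matrix(_graph([(0, 1, 2.0)], 2))
        assert D[0, 1] == pytest.approx(0.5)

    def test_two_hop_sum_of_reciprocals(self):
        D = shortest_path_matrix(_graph([(0, 1, 1), (1, 2, 1)], 3))
        assert D[0, 2] == pytest.approx(2.0)

    def test_unreachable_is_inf_and_diagonal_zero(self):
        D = shortest_path_matrix(_graph([(0, 1, 1)], 3))
        assert np.isinf(D[0, 2])
        assert np.all(np.diag(D) == 0)

    def test_matches_floyd_warshall_oracle(self, rng):
        for _ in range(20):
            W = random_weighted_graph(rng, 8, 0.4)
            np.testing.assert_allclose(shortest_path_matrix(W),
                                       floyd_warshall(W), atol=1e-12)


@pytest.mark.parametrize("W, expected", [
    (PATH4, 0.5), (K5, 1.0), (EMPTY4, 0.0)])
def test_density_closed_forms(W, expected):
    assert network_density(W) == pytest.approx(expected)


@pytest.mark.parametrize("W, expected", [(TRIANGLE, 2.0), (TRIANGLE_HALF, 1.0)])
def test_strength_closed_forms(W, expected):
    assert network_strength(W) == pytest.approx(expected)


@pytest.mark.parametrize("W, expected", [(TRIANGLE, 1.0), (STAR5, 0.0)])
def test_clustering_closed_forms(W, expected):
    assert global_cp(W) == pytest.approx(expected)


def test_complete_unit_graph_efficiency_and_path_length():
    assert global_eg(K4) == pytest.approx(1.0)
    assert global_lp(K4) == pytest.approx(1.0)
    assert global_eloc(K4) == pytest.approx(1.0)  # every neighbor subgraph K3


def test_star_has_zero_local_efficiency():
    assert global_eloc(STAR5) == pytest.approx(0.0)


def test_empty_graph_efficiency_zero_and_lp_undefined():
    assert global_eg(EMPTY4) == 0.0
    with pytest.raises(DisconnectedGraphError):
        global_lp(EMPTY4)


def test_lp_eg_inverse_identity(rng):
    for _ in range(20):
        W = random_weighted_graph(rng, 9, 0.5)
        if global_eg(W) == 0:
            continue
        assert global_lp(W) * global_eg(W) == pytest.approx(1.0, abs=1e-14)


class TestNodalClosedForms:
    def test_star_center(self):
        nm = nodal_metrics(STAR5)
        assert nm.cp[0] == 0.0
        assert nm.eg[0] == pytest.approx(1.0)

    def test_path_leaf_nlp(self):
        nm = nodal_metrics(_graph([(0, 1, 1), (1, 2, 1)], 3))
        assert nm.nlp[0] == pytest.approx(1.5)  # distances 1 and 2

    def test_isolated_node(self):
        W = _graph([(0, 1, 1)], 3)
        nm = nodal_metrics(W)
        assert np.isinf(nm.nlp[2])
        assert nm.eg[2] == 0.0
        assert nm.cp[2] == 0.0


def test_all_metrics_match_brute_force_oracles(rng):
    for _ in range(40):
        n = int(rng.integers(4, 12))
        W = random_weighted_graph(rng, n, float(rng.uniform(0.25, 0.9)))
        assert network_density(W) == pytest.approx(brute_density(W), abs=1e-12)
        assert network_strength(W) == pytest.approx(brute_strength(W),
                                                    abs=1e-10)
        assert global_cp(W) == pytest.approx(brute_global_cp(W), abs=1e-10)
        assert global_eg(W) == pytest.approx(brute_global_eg(W), abs=1e-10)
        assert global_eloc(W) == pytest.approx(brute_global_eloc(W),
                                               abs=1e-10)
        cp, nlp, neg, eloc = brute_nodal(W)
        nm = nodal_metrics(W)
        np.testing.assert_allclose(nm.cp, cp, atol=1e-10)
        np.testing.assert_allclose(nm.nlp, nlp, atol=1e-10)
        np.testing.assert_allclose(nm.eg, neg, atol=1e-10)
        np.testing.assert_allclose(nm.eloc, eloc, atol=1e-10)


def test_clustering_agrees_with_networkx_onnela(rng):
    for _ in range(10):
        W = random_weighted_graph(rng, 9, 0.5)
        expected = nx.average_clustering(nx.from_numpy_array(W),
                                         weight="weight")
        assert global_cp(W) == pytest.approx(expected, abs=1e-12)


def test_permutation_invariance(rng):
    W = random_weighted_graph(rng, 10, 0.5)
    perm = rng.permutation(10)
    Wp = W[np.ix_(perm, perm)]
    g, gp = global_metrics(W), global_metrics(Wp)
    for attr in ("density", "strength", "cp", "lp", "eg", "eloc"):
        assert getattr(g, attr) == pytest.approx(getattr(gp, attr), rel=1e-10)
    nm, nmp = nodal_metrics(W), nodal_metrics(Wp)
    np.testing.assert_allclose(nm.eg[perm], nmp.eg, atol=1e-12)
    np.testing.assert_allclose(nm.cp[perm], nmp.cp, atol=1e-12)


def test_weight_scaling_behavior(rng):
    """Scaling all weights by k scales Eg by k, Lp by 1/k; leaves density,
    binary nodal clustering, and normalized clustering unchanged."""
    W = random_weighted_graph(rng, 9, 0.6)
    k = 3.7
    g, gk = global_metrics(W), global_metrics(k * W)
    assert gk.eg == pytest.approx(k * g.eg, rel=1e-10)
    assert gk.lp == pytest.approx(g.lp / k, rel=1e-10)
    assert gk.density == pytest.approx(g.density)
    assert gk.cp == pytest.approx(g.cp, rel=1e-10)
    np.testing.assert_allclose(nodal_metrics(k * W).cp, nodal_metrics(W).cp)


def test_edge_removal_monotonicity(rng):
    """Removing an edge never increases Eg and never decreases finite NLp."""
    for _ in range(10):
        W = random_weighted_graph(rng, 8, 0.6)
        edges = np.argwhere(np.triu(W, 1) > 0)
        if not len(edges):
            continue
        i, j = edges[rng.integers(len(edges))]
        W2 = W.copy()
        W2[i, j] = W2[j, i] = 0.0
        assert global_eg(W2) <= global_eg(W) + 1e-12
        nlp1, nlp2 = nodal_metrics(W).nlp, nodal_metrics(W2).nlp
        both = np.isfinite(nlp1) & np.isfinite(nlp2)
        assert np.all(nlp2[both] >= nlp1[both] - 1e-12)


def test_network_summary_consistent_with_individual_measures(rng):
    W = random_weighted_graph(rng, 10, 0.5)
    g, nm = network_summary(W)
    assert g.eg == pytest.approx(global_eg(W), abs=1e-12)
    assert g.eloc == pytest.approx(global_eloc(W), abs=1e-12)
    np.testing.assert_allclose(nm.eg, nodal_metrics(W).eg, atol=1e-12)


class TestWeightedGraphValidation:
    def test_rejects_asymmetric(self):
        M = np.zeros((3, 3))
        M[0, 1] = 1.0
        with pytest.raises(ValueError, match="symmetric"):
            WeightedGraph(M)

    def test_rejects_negative_and_nonzero_diagonal(self):
        with pytest.raises(ValueError):
            WeightedGraph(-TRIANGLE)
        M = TRIANGLE.copy()
        M[0, 0] = 1.0
        with pytest.raises(ValueError, match="diagonal"):
            WeightedGraph(M)
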