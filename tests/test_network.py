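import json

import numpy as np
import pytest

from conet.network import (
    AssociationNetwork,
    NetworkStack,
    align_networks,
    overlap_counts,
    threshold_network,
)
from .conftest import random_network


def net_from_edges(method, nodes, edges, pvalues=None):
    """Build a network from {(a, b): weight} (+ optional {(a, b): p})."""
    idx = {n: i for i, n in enumerate(nodes)}
    q = len(nodes)
    w = np.zeros((q, q))
    for (a, b), val in edges.items():
        w[idx[a], idx[b]] = w[idx[b], idx[a]] = val
    p = None
    if pvalues is not None:
        p = np.ones((q, q))
        for (a, b), val in pvalues.items():
            p[idx[a], idx[b]] = p[idx[b], idx[a]] = val
    return AssociationNetwork(method, nodes, w, p)


class TestAssociationNetwork:
    def test_asymmetric_weights_rejected(self):
        w = np.array([[0, 1.0], [0.5, 0]])
        with pytest.raises(ValueError, match="symmetric"):
            AssociationNetwork("m", ["a", "b"], w)

    def test_diagonal_forced_to_zero(self):
        w = np.array([[0.3, 1.0], [1.0, -0.2]])
        net = AssociationNetwork("m", ["a", "b"], w)
        assert net.weights[0, 0] == 0 and net.weights[1, 1] == 0

    def test_pvalues_range_checked(self):
        w = np.zeros((2, 2))
        with pytest.raises(ValueError, match="\\[0, 1\\]"):
            AssociationNetwork("m", ["a", "b"], w, [[1, 2.0], [2.0, 1]])

    def test_duplicate_nodes_rejected(self):
        with pytest.raises(ValueError, match="unique"):
            AssociationNetwork("m", ["a", "a"], np.zeros((2, 2)))


class TestAlign:
    def test_union_nodes_and_zero_padding(self):
        n1 = net_from_edges("m1", ["A", "B"], {("A", "B"): 0.5},
                            pvalues={("A", "B"): 0.01})
        n2 = net_from_edges("m2", ["B", "C"], {("B", "C"): -0.4})
        stack = align_networks([n1, n2])
        assert stack.nodes == ["A", "B", "C"]
        i, k = stack.nodes.index("A"), stack.nodes.index("C")
        assert stack.networks[0].weights[i, k] == 0
        assert stack.networks[1].weights[i, k] == 0
        # padded entries of the p-carrying network are maximally non-significant
        assert stack.networks[0].pvalues[i, k] == 1.0

    def test_single_network_flattens_to_q_squared(self):
        net = random_network(np.random.default_rng(0), ["a", "b", "c"])
        stack = align_networks([net])
        assert stack.flattened.shape == (9, 1)

    def test_unflatten_roundtrip_bit_exact(self):
        rng = np.random.default_rng(1)
        nets = [random_network(rng, list("abcd"), method=f"m{i}") for i in range(3)]
        stack = align_networks(nets)
        for i in range(3):
            assert np.array_equal(stack.unflatten(i), stack.networks[i].weights)

    def test_edge_content_insensitive_to_input_node_order(self):
        n1 = net_from_edges("m", ["B", "A", "C"], {("A", "B"): 0.5, ("B", "C"): -0.2})
        n2 = net_from_edges("m", ["C", "B", "A"], {("A", "B"): 0.5, ("B", "C"): -0.2})
        s1 = align_networks([n1])
        s2 = align_networks([n2])
        assert s1.networks[0].edge_set() == s2.networks[0].edge_set()

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            align_networks([])


class TestThreshold:
    def test_weak_edge_removed_at_printed_cutoff(self):
        net = net_from_edges("m", ["a", "b"], {("a", "b"): 0.05})
        assert threshold_network(net, 0.1, 1.0).edge_set() == set()

    def test_non_significant_edge_removed(self):
        net = net_from_edges("m", ["a", "b"], {("a", "b"): -0.5},
                             pvalues={("a", "b"): 0.2})
        assert threshold_network(net, 0.1, 0.05).edge_set() == set()

    def test_degenerate_thresholds_are_identity(self):
        rng = np.random.default_rng(2)
        net = random_network(rng, list("abcde"), with_pvalues=True)
        out = threshold_network(net, 0.0, 1.0)
        assert np.array_equal(out.weights, net.weights)

    def test_monotone_in_both_thresholds(self):
        rng = np.random.default_rng(3)
        net = random_network(rng, list("abcdef"), with_pvalues=True)
        prev = None
        for wmin, pmax in [(0.0, 1.0), (0.1, 0.5), (0.3, 0.2), (0.6, 0.05)]:
            edges = threshold_network(net, wmin, pmax).edge_set()
            if prev is not None:
                assert edges <= prev
            prev = edges


class TestOverlap:
    def test_identical_networks_fully_overlap(self):
        net = net_from_edges("m1", ["a", "b", "c"], {("a", "b"): 1, ("b", "c"): -1})
        stack = align_networks([net, net.copy()])
        counts = overlap_counts(stack)
        assert counts["edge_intersection"] == counts["edge_union"] == 2

    def test_partial_edge_overlap(self):
        n1 = net_from_edges("m1", list("ABCD"), {("A", "B"): 1, ("B", "C"): 1})
        n2 = net_from_edges("m2", list("ABCD"), {("A", "B"): 1, ("C", "D"): 1})
        counts = overlap_counts(align_networks([n1, n2]))
        assert counts["edge_intersection"] == 1
        assert counts["edge_union"] == 3
        assert counts["per_subset_counts"][("m1", "m2")] == 1
        assert counts["per_subset_counts"][("m1",)] == 1

    def test_disjoint_edge_sets(self):
        nets = [
            net_from_edges(f"m{i}", list("ABCDEF"), {(a, b): 1})
            for i, (a, b) in enumerate([("A", "B"), ("C", "D"), ("E", "F")])
        ]
        counts = overlap_counts(align_networks(nets))
        assert counts["edge_intersection"] == 0
        assert counts["edge_union"] == 3

    def test_isolated_nodes_do_not_participate(self):
        n1 = net_from_edges("m1", list("ABC"), {("A", "B"): 1})
        counts = overlap_counts(align_networks([n1]))
        assert counts["node_union"] == 2


class TestSerialization:
    def test_json_roundtrip_full_precision(self, tmp_path):
        rng = np.random.default_rng(5)
        net = random_network(rng, list("abcd"), method="sparcc", with_pvalues=True)
        path = tmp_path / "net.json"
        net.to_json(path)
        back = AssociationNetwork.from_json(path)
        assert back.method == "sparcc"
        assert back.nodes == net.nodes
        assert np.array_equal(back.weights, net.weights)
        # p-values survive only where edges exist; padding elsewhere is 1
        nz = net.weights != 0
        assert np.array_equal(back.pvalues[nz], net.pvalues[nz])

    def test_links_serialized_once_source_before_target(self):
        net = net_from_edges("m", ["b", "a"], {("a", "b"): 0.7})
        d = net.to_dict()
        assert len(d["links"]) == 1
        assert d["links"][0]["source"] == "a" and d["links"][0]["target"] == "b"

    def test_gml_and_edgelist_export(self, tmp_path):
        import networkx as nx

        net = net_from_edges("m", ["a", "b", "c"], {("a", "b"): 0.7, ("b", "c"): -0.3})
        gml = tmp_path / "net.gml"
        net.to_gml(gml)
        g = nx.read_gml(gml)
        assert set(g.edges()) == {("a", "b"), ("b", "c")}
        tsv = tmp_path / "net.tsv"
        net.to_edgelist_tsv(tsv)
        lines = tsv.read_text().strip().splitlines()
        assert lines[0] == "source\ttarget\tweight"
        assert len(lines) == 3
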