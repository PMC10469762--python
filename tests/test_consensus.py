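import itertools

import numpy as np
import pytest

from conet.consensus import scaled_sum, simple_voting
from conet.network import AssociationNetwork, align_networks

from .conftest import random_network
from .oracles import ss_oracle_include, sv_oracle_include


def stack_from_edge_weights(edge_weights):
    """Build an aligned stack from a list of per-network
    {(a, b): weight} dicts over a shared alphabet."""
    nodes = sorted({n for net in edge_weights for pair in net for n in pair})
    idx = {n: i for i, n in enumerate(nodes)}
    nets = []
    for i, net in enumerate(edge_weights):
        w = np.zeros((len(nodes), len(nodes)))
        for (a, b), val in net.items():
            w[idx[a], idx[b]] = w[idx[b], idx[a]] = val
        nets.append(AssociationNetwork(f"m{i}", nodes, w))
    return align_networks(nets)


class TestSimpleVoting:
    def test_mixed_signs_majority_included_at_half(self):
        # weights (0.5, -0.2, 0.4): M = max(1, 2) = 2 >= floor(0.5*3) = 1
        stack = stack_from_edge_weights(
            [{("a", "b"): 0.5}, {("a", "b"): -0.2}, {("a", "b"): 0.4}]
        )
        cons = simple_voting(stack, 0.5)
        assert cons.edge_set() == {frozenset(("a", "b"))}
        assert cons.edges[0].score == 2

    def test_unanimity_required_at_theta_one(self):
        agree = [{("a", "b"): 0.5}, {("a", "b"): 0.1}, {("a", "b"): 0.9}]
        flipped = [{("a", "b"): 0.5}, {("a", "b"): -0.1}, {("a", "b"): 0.9}]
        assert simple_voting(stack_from_edge_weights(agree), 1.0).edge_set() == {
            frozenset(("a", "b"))
        }
        assert simple_voting(stack_from_edge_weights(flipped), 1.0).edge_set() == set()

    def test_union_at_theta_one_over_w(self):
        nets = [{("a", "b"): 0.5}, {("b", "c"): -0.3}, {("c", "d"): 0.2}]
        cons = simple_voting(stack_from_edge_weights(nets), 1 / 3)
        assert cons.edge_set() == {
            frozenset(("a", "b")),
            frozenset(("b", "c")),
            frozenset(("c", "d")),
        }

    def test_absent_edges_never_included_at_theta_zero(self):
        stack = stack_from_edge_weights([{("a", "b"): 0.5}, {("a", "b"): 0.2}])
        cons = simple_voting(stack, 0.0)
        assert frozenset(("a", "c")) not in cons.edge_set()

    def test_majority_sign_with_strongest_tiebreak(self):
        stack = stack_from_edge_weights(
            [{("a", "b"): 0.9}, {("a", "b"): -0.2}]
        )
        cons = simple_voting(stack, 0.0)
        assert cons.edges[0].sign == 1


class TestScaledSum:
    def test_two_method_example_included(self):
        # scaled weights 1.0 and 0.5: |s| = 1.5 > (2-1)*0.333
        stack = stack_from_edge_weights(
            [{("a", "b"): 0.8, ("b", "c"): 0.4}, {("a", "b"): 0.3, ("b", "c"): 0.6}]
        )
        cons = scaled_sum(stack, 0.333)
        edge = {e.pair: e for e in cons.edges}[frozenset(("a", "b"))]
        assert edge.score == pytest.approx(1.0 + 0.5)

    def test_cancellation_excluded_at_any_theta(self):
        stack = stack_from_edge_weights(
            [{("a", "b"): 0.9, ("c", "d"): 0.9}, {("a", "b"): -0.9, ("c", "d"): 0.9}]
        )
        for theta in (0.0, 0.5, 1.0):
            assert frozenset(("a", "b")) not in scaled_sum(stack, theta).edge_set()

    def test_single_network_keeps_every_edge(self):
        stack = stack_from_edge_weights([{("a", "b"): 0.01, ("b", "c"): -0.9}])
        for theta in (0.0, 0.5, 1.0):
            assert len(scaled_sum(stack, theta).edges) == 2

    def test_invariant_to_rescaling_one_network(self):
        rng = np.random.default_rng(8)
        nets = [random_network(rng, list("abcdef"), method=f"m{i}") for i in range(3)]
        stack1 = align_networks(nets)
        scaled = nets[1].copy()
        scaled.weights *= 7.3
        stack2 = align_networks([nets[0], scaled, nets[2]])
        for theta in (0.2, 0.5):
            assert scaled_sum(stack1, theta).edge_set() == scaled_sum(stack2, theta).edge_set()

    def test_empty_network_warns_and_contributes_zero(self):
        q_nodes = ["a", "b"]
        full = AssociationNetwork("m0", q_nodes, [[0, 0.5], [0.5, 0]])
        empty = AssociationNetwork("m1", q_nodes, np.zeros((2, 2)))
        stack = align_networks([full, empty])
        with pytest.warns(UserWarning, match="no edges"):
            cons = scaled_sum(stack, 0.4)
        assert cons.edges[0].score == pytest.approx(1.0)


class TestConsensusProperties:
    @pytest.mark.parametrize("algorithm", [simple_voting, scaled_sum])
    def test_nested_edge_sets_along_theta(self, algorithm):
        thetas = [0.0, 0.333, 0.5, 0.667, 1.0]
        for seed in range(10):
            rng = np.random.default_rng(seed)
            nets = [
                random_network(rng, list("abcdefgh"), method=f"m{i}", density=0.5)
                for i in range(4)
            ]
            stack = align_networks(nets)
            prev = None
            for theta in thetas:
                edges = algorithm(stack, theta).edge_set()
                if prev is not None:
                    assert edges <= prev
                prev = edges

    @pytest.mark.parametrize("algorithm", [simple_voting, scaled_sum])
    def test_consensus_edges_subset_of_union(self, algorithm):
        rng = np.random.default_rng(42)
        nets = [random_network(rng, list("abcdef"), method=f"m{i}") for i in range(3)]
        stack = align_networks(nets)
        union = set().union(*(n.edge_set() for n in nets))
        assert algorithm(stack, 0.0).edge_set() <= union

    def test_oracle_agreement_on_enumerated_sign_patterns(self):
        """Brute-force re-evaluation of the voting and scaled-sum rules on
        every sign pattern of one edge across 3 networks."""
        mags = {0: 0.0, 1: 0.6, -1: 0.8}
        for pattern in itertools.product((-1, 0, 1), repeat=3):
            weights = [{("a", "b"): mags[s] * s, ("c", "d"): 0.5} for s in pattern]
            stack = stack_from_edge_weights(weights)
            maxima = [np.abs(stack.networks[i].weights).max() for i in range(3)]
            edge_w = [mags[s] * s for s in pattern]
            for theta in (0.0, 0.25, 1 / 3, 0.5, 0.75, 1.0):
                sv = frozenset(("a", "b")) in simple_voting(stack, theta).edge_set()
                ss = frozenset(("a", "b")) in scaled_sum(stack, theta).edge_set()
                assert sv == sv_oracle_include(edge_w, theta), (pattern, theta)
                assert ss == ss_oracle_include(edge_w, maxima, theta), (pattern, theta)

    def test_per_method_weights_recorded_on_multigraph_edges(self):
        stack = stack_from_edge_weights(
            [{("a", "b"): 0.5}, {("a", "b"): -0.2}, {("b", "c"): 0.4}]
        )
        cons = simple_voting(stack, 0.0)
        edge = {e.pair: e for e in cons.edges}[frozenset(("a", "b"))]
        assert edge.per_method_weights == {"m0": 0.5, "m1": -0.2}

    def test_empty_stack_rejected(self):
        with pytest.raises(ValueError):
            align_networks([])


try:
    from hypothesis import given, settings, strategies as st

    @given(
        st.lists(
            st.lists(st.sampled_from([-0.9, -0.4, 0.0, 0.3, 0.8]), min_size=4,
                     max_size=4),
            min_size=1,
            max_size=5,
        ),
        st.floats(min_value=0, max_value=1),
    )
    @settings(max_examples=150, derandomize=True, deadline=None)
    def test_voting_matches_oracle_on_arbitrary_weight_lists(edge_rows, theta):
        """Property form of the voting rule: for arbitrary per-network
        weights on 4 edges, implementation and brute-force oracle agree."""
        nodes = list("abcde")
        pairs = [("a", "b"), ("b", "c"), ("c", "d"), ("d", "e")]
        weights = [
            {pair: row[k] for k, pair in enumerate(pairs)} for row in edge_rows
        ]
        stack = stack_from_edge_weights(weights)
        cons_edges = simple_voting(stack, theta).edge_set()
        for k, pair in enumerate(pairs):
            edge_w = [row[k] for row in edge_rows]
            assert (frozenset(pair) in cons_edges) == sv_oracle_include(edge_w, theta)

except ImportError:  # pragma: no cover - hypothesis is a test extra
    pass
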