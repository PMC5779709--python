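"""Network data model, rich-Newick I/O, and structural queries."""

import itertools

import networkx as nx
import numpy as np
import pytest

from netmark.fixtures import MODEL_1RETIC, load_fixture
from netmark.network import (NetworkError, articulation_nodes, backbone_tree,
                             find_lowest_articulation_nodes, networks_isomorphic,
                             parse_rich_newick, random_network,
                             reticulation_diameter, rf_distance, to_plain_newick,
                             validate_network, write_rich_newick)


class TestParsing:
    def test_model_network_fields(self):
        net = parse_rich_newick(MODEL_1RETIC)
        assert sorted(net.leaf_names()) == ["A", "C", "L", "Q", "R"]
        assert net.num_reticulations == 1
        assert net.root_theta == 0.006
        r = net.reticulations()[0]
        gammas = sorted(net.edges[(p, r)].gamma for p in net.parents[r])
        assert gammas == [0.3, 0.7]

    def test_two_leaf_tree(self):
        net = parse_rich_newick("(A:1.0:0.005,B:1.0:0.005);")
        assert net.num_reticulations == 0
        assert net.leaf_names() == {"A", "B"}
        assert net.edges[(net.root(), net.leaves()[0])].length == 1.0

    @pytest.mark.parametrize("bad", [
        "(A:1:0.005,A:1:0.005);",                      # duplicate leaves
        "(A:1:0.005,B:1:0.005",                        # unterminated
        "((A:1:0.005)H#H1:1:0.005:0.6,(H#H1:1:0.005:0.3,B:1:0.005):1:0.005);",
    ])
    def test_malformed_strings_rejected(self, bad):
        with pytest.raises(NetworkError):
            parse_rich_newick(bad)

    def test_roundtrip_random_networks(self, rng):
        for _ in range(60):
            n_leaves = int(rng.integers(2, 9))
            k = int(rng.integers(0, 4))
            net = random_network(rng, n_leaves=n_leaves, n_reticulations=k)
            back = parse_rich_newick(write_rich_newick(net))
            assert networks_isomorphic(net, back)
            for r in back.reticulations():
                g = sum(back.edges[(p, r)].gamma for p in back.parents[r])
                assert abs(g - 1.0) < 1e-9


class TestValidation:
    def test_model_network_passes(self, net_1retic):
        assert validate_network(net_1retic).ok

    def test_cycle_detected_without_raising(self, net_1retic):
        net = net_1retic.copy()
        leaf = net.leaves()[0]
        net.add_edge(leaf, net.root(), 0.01, 0.005)
        diag = validate_network(net)
        assert not diag.ok
        assert any("cycle" in v for v in diag.violations)

    def test_time_inconsistency_detected(self, net_1retic):
        net = net_1retic.copy()
        child = net.children[net.root()][0]
        net.heights[child] = net.heights[net.root()] + 1.0
        diag = validate_network(net)
        assert not diag.ok
        assert any(v.startswith("time") for v in diag.violations)


def brute_force_lowest_articulations(net):
    """Oracle: delete each node from the undirected graph (with the
    above-root stub) and test connectivity, then apply the child rule."""
    g = nx.Graph()
    g.add_nodes_from(net.children)
    g.add_edges_from(net.edges)
    g.add_edge("s", net.root())
    arts = set()
    for v in net.children:
        h = g.copy()
        h.remove_node(v)
        if h.number_of_nodes() and not nx.is_connected(h):
            arts.add(v)
    return {v for v in arts
            if any(c not in arts and net.children[c] for c in net.children[v])}


class TestArticulation:
    def test_tree_has_no_lowest_articulation(self, rng):
        tree = random_network(rng, n_leaves=6, n_reticulations=0)
        assert find_lowest_articulation_nodes(tree) == set()
        assert articulation_nodes(tree) == {
            v for v in tree.children if tree.children[v]}

    def test_root_only_when_cycle_hangs_below_root(self):
        # reticulation child is a leaf and the cycle nodes have no other
        # subtrees: the root is the only lowest articulation node
        net = parse_rich_newick(
            "((B:1:0.005,(A:1:0.005)h#H1:1:0.005:0.6)x:1:0.005,"
            "(h#H1:1:0.005:0.4)y:2:0.005);")
        assert find_lowest_articulation_nodes(net) == {net.root()}

    def test_agrees_with_bruteforce_on_random_networks(self, rng):
        for _ in range(40):
            net = random_network(rng, n_leaves=int(rng.integers(3, 7)),
                                 n_reticulations=int(rng.integers(0, 3)))
            assert (find_lowest_articulation_nodes(net)
                    == brute_force_lowest_articulations(net))


class TestReticulationDiameter:
    def test_model_network_cycle_sum(self, net_1retic):
        # cycle through the reticulation: hybrid edges 0.002 and 0.003 plus
        # the path 0.016 + 0.02 + 0.035 between its parents
        r = net_1retic.reticulations()[0]
        assert reticulation_diameter(net_1retic, r) == pytest.approx(0.076)

    def test_diamond_cycle_sum(self):
        # parents of the reticulation meet at the root: cycle is the two
        # hybrid edges plus the two edges up to the root
        net = parse_rich_newick(
            "(((A:1:0.005)h#H1:0.25:0.005:0.6)p:1:0.005,"
            "(h#H1:0.75:0.005:0.4)q:1:0.005);")
        r = net.reticulations()[0]
        assert reticulation_diameter(net, r) == pytest.approx(0.25 + 0.75 + 2)

    def test_scales_linearly_with_branch_lengths(self, net_1retic):
        net = net_1retic.copy()
        for e in net.edges.values():
            e.length *= 3.0
        r = net.reticulations()[0]
        assert reticulation_diameter(net, r) == pytest.approx(3 * 0.076)

    def test_requires_reticulation(self, net_1retic):
        with pytest.raises(NetworkError):
            reticulation_diameter(net_1retic, net_1retic.root())


class TestBackbone:
    def test_model_1retic_backbone(self, net_1retic):
        bt = backbone_tree(net_1retic)
        want = parse_rich_newick(
            "(C:1:0.005,((L:1:0.005,(A:1:0.005,Q:1:0.005):1:0.005):1:0.005,"
            "R:1:0.005):1:0.005);")
        assert bt.num_reticulations == 0
        assert validate_network(bt).ok
        assert rf_distance(bt, want) == 0

    def test_model_2retic_backbone(self, net_2retic):
        bt = backbone_tree(net_2retic)
        want = parse_rich_newick(
            "(C:1:0.005,(R:1:0.005,(L:1:0.005,(A:1:0.005,Q:1:0.005)"
            ":1:0.005):1:0.005):1:0.005);")
        assert rf_distance(bt, want) == 0

    def test_tree_passes_through(self, rng):
        tree = random_network(rng, n_leaves=5, n_reticulations=0)
        assert rf_distance(backbone_tree(tree), tree) == 0

    def test_gamma_tie_errors_unless_configured(self, net_1retic):
        net = net_1retic.copy()
        r = net.reticulations()[0]
        for p in net.parents[r]:
            net.edges[(p, r)].gamma = 0.5
        with pytest.raises(NetworkError):
            backbone_tree(net)
        bt = backbone_tree(net, tie_break="postorder")
        assert bt.num_reticulations == 0

    def test_random_backbones_are_valid_trees(self, rng):
        for _ in range(20):
            net = random_network(rng, n_leaves=5,
                                 n_reticulations=int(rng.integers(1, 3)))
            bt = backbone_tree(net, tie_break="postorder")
            assert bt.num_reticulations == 0
            assert validate_network(bt).ok
            assert bt.leaf_names() == net.leaf_names()


class TestTreeMetrics:
    def test_rf_identity_and_symmetry(self, rng):
        t1 = random_network(rng, n_leaves=6, n_reticulations=0)
        t2 = random_network(rng, n_leaves=6, n_reticulations=0)
        assert rf_distance(t1, t1) == 0
        assert rf_distance(t1, t2) == rf_distance(t2, t1)

    def test_four_taxon_swap_distance_two(self):
        t1 = parse_rich_newick("((A:1:.005,B:1:.005):1:.005,"
                               "(C:1:.005,D:1:.005):1:.005);")
        t2 = parse_rich_newick("((A:1:.005,C:1:.005):1:.005,"
                               "(B:1:.005,D:1:.005):1:.005);")
        assert rf_distance(t1, t2) == 2

    def test_leaf_set_mismatch_errors(self):
        t1 = parse_rich_newick("(A:1:.005,B:1:.005);")
        t2 = parse_rich_newick("(A:1:.005,C:1:.005);")
        with pytest.raises(NetworkError):
            rf_distance(t1, t2)


class TestIsomorphism:
    def test_child_order_irrelevant(self, net_1retic):
        s = write_rich_newick(net_1retic)
        assert networks_isomorphic(net_1retic, parse_rich_newick(s))

    def test_different_reticulation_counts_differ(self, net_1retic,
                                                  net_2retic):
        assert not networks_isomorphic(net_1retic, net_2retic)

    def test_tree_vs_network_differ(self, net_1retic):
        bt = backbone_tree(net_1retic)
        assert not networks_isomorphic(bt, net_1retic)

    def test_plain_newick_export_requires_tree(self, net_1retic):
        with pytest.raises(NetworkError):
            to_plain_newick(net_1retic)
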