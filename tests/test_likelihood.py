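"""The labeled-partial-likelihood engine: rate matrix, leaf init, branch
propagation, decompose-and-split, merging, and whole-site likelihoods."""

import itertools
import math

import numpy as np
import pytest
from scipy.linalg import null_space

from netmark import MutationModel, SpeciesSite
from netmark._tree_reference import tree_site_likelihood
from netmark.fixtures import load_fixture
from netmark.likelihood import (LPL, build_rate_matrix, dataset_loglik,
                                enumerate_site_patterns, leaf_partials,
                                leaf_partials_dominant, merge_at_articulation,
                                merge_at_tree_node, pair_index, propagate_top,
                                root_stationary, site_likelihood,
                                split_at_reticulation)
from netmark.markers import MarkerMatrix
from netmark.network import parse_rich_newick, random_network
from netmark.simulate import SimConfig, simulate_markers


class TestRateMatrix:
    def test_single_lineage_block_symmetric_rates(self, model):
        Q = build_rate_matrix(1.0, model, 1)
        idx = pair_index(1)
        block = Q[np.ix_([idx[(1, 0)], idx[(1, 1)]],
                         [idx[(1, 0)], idx[(1, 1)]])]
        assert np.allclose(block, [[-1, 1], [1, -1]])

    def test_coalescence_entries_two_lineages(self):
        theta = 0.01
        Q = build_rate_matrix(theta, MutationModel(0.7, 1.3), 2)
        idx = pair_index(2)
        # two reds coalesce at (r-1) n / theta; (2,1) has no coalescence exit
        assert Q[idx[(2, 2)], idx[(1, 1)]] == pytest.approx(2 / theta)
        assert Q[idx[(2, 1)], idx[(1, 1)]] == 0.0
        assert Q[idx[(2, 1)], idx[(1, 0)]] == 0.0
        assert Q[idx[(2, 1)], idx[(2, 1)]] == pytest.approx(
            -2 / theta - 0.7 - 1.3)

    def test_placeholder_row_is_zero(self, model):
        Q = build_rate_matrix(0.005, model, 3)
        assert not Q[0].any()

    @pytest.mark.parametrize("bad", [dict(theta=0.0), dict(M=0)])
    def test_invalid_arguments(self, model, bad):
        kw = dict(theta=0.005, M=2)
        kw.update(bad)
        with pytest.raises(ValueError):
            build_rate_matrix(kw["theta"], model, kw["M"])


class TestLeafPartials:
    def test_haploid_point_mass(self):
        lpl = leaf_partials(2, 1, k=3)
        assert dict(lpl.F) == {(2, 1): 1.0}
        assert lpl.s == (0, 0, 0)

    def test_red_count_bounds(self):
        with pytest.raises(ValueError):
            leaf_partials(2, 3, k=0)
        with pytest.raises(ValueError):
            leaf_partials_dominant(2, 3, k=0)

    @pytest.mark.parametrize("n_x,r_x,expected", [
        (1, 1, {(2, 1): 1.0, (2, 2): 1.0}),
        (2, 1, {(4, 1): 1.0, (4, 2): 1 / 3}),
        (3, 0, {(6, 0): 1.0}),
    ])
    def test_dominant_known_values(self, n_x, r_x, expected):
        lpl = leaf_partials_dominant(n_x, r_x, k=0)
        got = dict(lpl.F)
        assert set(got) == set(expected)
        for key, val in expected.items():
            assert got[key] == pytest.approx(val)

    def test_dominant_matches_enumeration_oracle(self):
        """For every placement of r red alleles on 2 n_x lineages with a
        fixed pairing into individuals, the band pattern is determined;
        F(2 n_x, r) must equal the fraction of placements reproducing the
        observed number of banded individuals."""
        for n_x in range(1, 4):
            lineages = list(range(2 * n_x))
            pairs = [(2 * i, 2 * i + 1) for i in range(n_x)]
            for r_x in range(n_x + 1):
                lpl = leaf_partials_dominant(n_x, r_x, k=0)
                got = dict(lpl.F)
                for r in range(2 * n_x + 1):
                    count = 0
                    total = 0
                    for reds in itertools.combinations(lineages, r):
                        total += 1
                        bands = sum(1 for a, b in pairs
                                    if a in reds or b in reds)
                        if bands == r_x:
                            count += 1
                    expect = count / total if total else 0.0
                    assert got.get((2 * n_x, r), 0.0) == pytest.approx(expect)


class TestPropagation:
    def test_zero_length_is_identity(self, model):
        from netmark.likelihood import branch_propagator

        P = branch_propagator(0.005, model, 2, 0.0)
        lpl = leaf_partials(2, 1, k=1)
        (out,) = propagate_top([lpl], P, 2)
        assert dict(out.F) == pytest.approx({(2, 1): 1.0})
        assert out.s == lpl.s

    def test_single_lineage_closed_form(self, model):
        from netmark.likelihood import branch_propagator

        t = 0.37
        P = branch_propagator(1.0, model, 1, t)
        (out,) = propagate_top([leaf_partials(1, 1, k=0)], P, 1)
        f = dict(out.F)
        assert f[(1, 1)] == pytest.approx((1 + math.exp(-2 * t)) / 2)
        assert f[(1, 0)] == pytest.approx((1 - math.exp(-2 * t)) / 2)

    def test_negative_length_rejected(self, model):
        from netmark.likelihood import branch_propagator

        with pytest.raises(ValueError):
            branch_propagator(0.005, model, 1, -0.1)


class TestSplit:
    def test_two_lineage_split_weights_and_count(self):
        lpl = leaf_partials(2, 1, k=1)
        py, pz = split_at_reticulation([lpl], gamma=0.3, retic_id=0)
        # (2,1) splits the four possible ways
        assert len(py) == len(pz) == 4
        by_support = {next(iter(dict(l.F))): dict(l.F) for l in py}
        assert by_support[(1, 1)][(1, 1)] == pytest.approx(2 * 0.3 * 0.7)
        # the matching z side of the (1,1) split holds the other lineage
        i = [next(iter(dict(l.F))) for l in py].index((1, 1))
        assert dict(pz[i].F) == {(1, 0): 1.0}
        assert py[i].s == pz[i].s != (0,)

    def test_single_lineage_split_is_gamma_mixture(self):
        lpl = leaf_partials(1, 1, k=1)
        py, pz = split_at_reticulation([lpl], gamma=0.3, retic_id=0)
        weights = {next(iter(dict(l.F))): next(iter(dict(l.F).values()))
                   for l in py}
        assert weights[(1, 1)] == pytest.approx(0.3)
        assert weights[(0, 0)] == pytest.approx(0.7)

    def test_labels_fresh_and_paired(self):
        lpl = leaf_partials(2, 1, k=2)
        py, pz = split_at_reticulation([lpl], gamma=0.5, retic_id=1)
        labels_y = [l.s[1] for l in py]
        assert len(set(labels_y)) == len(labels_y)  # unique per split
        for ly, lz in zip(py, pz):
            assert ly.s == lz.s
            assert ly.s[0] == 0  # other coordinates copied

    def test_retic_index_out_of_range(self):
        with pytest.raises(ValueError):
            split_at_reticulation([leaf_partials(1, 0, k=1)], 0.5, retic_id=1)


class TestMerge:
    def test_hand_convolution(self):
        a, b = 0.6, 0.8
        ly = LPL.make({(1, 0): a}, (0,))
        lz = LPL.make({(1, 1): b}, (0,))
        (out,) = merge_at_tree_node([ly], [lz])
        assert dict(out.F) == pytest.approx({(2, 1): a * b / 2})

    def test_label_merge_rules(self):
        ly = LPL.make({(1, 0): 1.0}, (3, 0))
        lz = LPL.make({(1, 1): 1.0}, (3, 5))
        (out,) = merge_at_tree_node([ly], [lz])
        assert out.s == (3, 5)

    def test_incompatible_pair_skipped(self):
        ly = LPL.make({(1, 0): 1.0}, (1, 0))
        lz = LPL.make({(1, 1): 1.0}, (2, 0))
        assert merge_at_tree_node([ly], [lz]) == []

    def test_articulation_merge_sums_and_clears_labels(self):
        l1 = LPL.make({(1, 0): 0.25}, (1, 2))
        l2 = LPL.make({(1, 0): 0.5, (1, 1): 0.125}, (3, 0))
        (out,) = merge_at_articulation([l1, l2])
        assert out.s == (0, 0)
        assert dict(out.F) == pytest.approx({(1, 0): 0.75, (1, 1): 0.125})
        with pytest.raises(ValueError):
            merge_at_articulation([])


class TestRootStationary:
    def test_symmetric_single_lineage(self, model):
        x = root_stationary(0.006, model, 1)
        assert x[(1, 0)] == pytest.approx(0.5)
        assert x[(1, 1)] == pytest.approx(0.5)

    def test_general_rates_single_lineage(self):
        m = MutationModel(2.0, 0.5)
        x = root_stationary(0.006, m, 2)
        assert x[(1, 1)] == pytest.approx(0.5 / 2.5)

    def test_levels_sum_to_one_and_match_null_space(self, model):
        x = root_stationary(0.01, model, 3)
        for n in range(1, 4):
            assert sum(x[(n, r)] for r in range(n + 1)) == pytest.approx(1.0)
        # cross-check against a full null-space solve of Q restricted to n>=1
        Q = build_rate_matrix(0.01, model, 3)
        ns = null_space(Q[1:, 1:].T @ Q[1:, 1:])  # right null vector of Q
        v = null_space(Q[1:, 1:])
        assert v.shape[1] == 1
        v = v[:, 0]
        idx = pair_index(3)
        scale = v[idx[(1, 0)] - 1] + v[idx[(1, 1)] - 1]
        for (n, r), i in idx.items():
            if n == 0:
                continue
            assert v[i - 1] / scale == pytest.approx(x[(n, r)], abs=1e-10)


class TestSiteLikelihood:
    def test_single_taxon_red_is_stationary(self, model):
        net = parse_rich_newick("(A:0.037:0.006);")
        lik = site_likelihood(net, {"A": SpeciesSite(1, 1)}, model)
        assert lik == pytest.approx(0.5, abs=1e-12)
        m = MutationModel(3.0, 1.0)
        lik = site_likelihood(net, {"A": SpeciesSite(1, 1)}, m)
        assert lik == pytest.approx(0.25, abs=1e-12)

    def test_patterns_sum_to_one_on_random_networks(self, rng, model):
        for _ in range(8):
            net = random_network(rng, n_leaves=int(rng.integers(2, 5)),
                                 n_reticulations=int(rng.integers(0, 3)))
            lineages = {sp: int(rng.integers(1, 3))
                        for sp in net.leaf_names()}
            for opt in (True, False):
                tot = sum(site_likelihood(net, pat, model,
                                          use_articulation_opt=opt)
                          for pat in enumerate_site_patterns(lineages))
                assert tot == pytest.approx(1.0, abs=1e-8)

    def test_tree_case_matches_independent_implementation(self, rng, model):
        for _ in range(25):
            tree = random_network(rng, n_leaves=int(rng.integers(2, 6)),
                                  n_reticulations=0)
            lineages = {sp: int(rng.integers(1, 3))
                        for sp in tree.leaf_names()}
            pats = enumerate_site_patterns(lineages)
            pat = pats[int(rng.integers(len(pats)))]
            a = site_likelihood(tree, pat, model)
            b = tree_site_likelihood(tree, pat, model)
            assert a == pytest.approx(b, abs=1e-12)

    def test_gamma_one_equals_edge_deleted_network(self, model, net_1retic):
        """Sending one reticulation's inheritance to 1 must reproduce the
        network with the gamma = 0 edge removed (degree-2 chain kept)."""
        net = net_1retic.copy()
        r = net.reticulations()[0]
        p1, p2 = net.parents[r]
        net.edges[(p1, r)].gamma = 1.0
        net.edges[(p2, r)].gamma = 0.0
        reduced = net.copy()
        reduced.remove_edge(p2, r)
        reduced.edges[(p1, r)].gamma = None
        pat = {sp: SpeciesSite(1, int(i % 2)) for i, sp in enumerate("ACLQR")}
        assert site_likelihood(net, pat, model) == pytest.approx(
            site_likelihood(reduced, pat, model), abs=1e-10)

    def test_single_lineage_reticulation_gamma_mixture(self, model,
                                                       net_1retic):
        """With one lineage below the reticulation the likelihood is the
        gamma mixture of the two forced-routing networks."""
        def forced(g):
            net = net_1retic.copy()
            r = net.reticulations()[0]
            p1, p2 = net.parents[r]
            hi, lo = (p1, p2) if net.edges[(p1, r)].gamma == 0.7 else (p2, p1)
            net.edges[(hi, r)].gamma = g
            net.edges[(lo, r)].gamma = 1.0 - g
            return net

        pat = {sp: SpeciesSite(1, r) for sp, r in
               zip("ACLQR", (1, 0, 1, 1, 0))}
        mix = (0.7 * site_likelihood(forced(1.0), pat, model)
               + 0.3 * site_likelihood(forced(0.0), pat, model))
        assert site_likelihood(net_1retic, pat, model) == pytest.approx(
            mix, abs=1e-10)

    def test_articulation_optimization_is_exact(self, rng, model):
        for _ in range(10):
            net = random_network(rng, n_leaves=4, n_reticulations=1)
            lineages = {sp: 1 for sp in net.leaf_names()}
            pats = enumerate_site_patterns(lineages)
            pat = pats[int(rng.integers(len(pats)))]
            a = site_likelihood(net, pat, model, use_articulation_opt=True)
            b = site_likelihood(net, pat, model, use_articulation_opt=False)
            assert a == pytest.approx(b, abs=1e-12)


class TestDatasetLoglik:
    def _matrix(self, rng, model, net, n_sites=60):
        tm = {sp: [f"{sp}_0"] for sp in net.leaf_names()}
        return simulate_markers(net, tm, model,
                                SimConfig(n_sites=n_sites), rng)

    def test_duplicate_columns_equal_weighted_dedup(self, rng, model):
        import pandas as pd

        net = parse_rich_newick("(A:0.01:0.006,B:0.01:0.006);")
        mm = self._matrix(rng, model, net, 20)
        dup = MarkerMatrix(
            pd.concat([mm.data, mm.data.add_suffix("_d")], axis=1),
            mm.taxon_map)
        ll = dataset_loglik(net, mm, model)
        ll_dup = dataset_loglik(net, dup, model)
        assert ll_dup == pytest.approx(2 * ll, rel=1e-12)

    def test_thread_count_is_irrelevant(self, rng, model, net_1retic):
        mm = self._matrix(rng, model, net_1retic, 40)
        a = dataset_loglik(net_1retic, mm, model, threads=1)
        b = dataset_loglik(net_1retic, mm, model, threads=8)
        assert a == b

    def test_copies_of_one_pattern(self, model):
        import pandas as pd

        net = parse_rich_newick("(A:0.01:0.006,B:0.01:0.006);")
        m = 7
        df = pd.DataFrame(np.tile([[1], [0]], (1, m)),
                          index=["A_0", "B_0"],
                          columns=[f"s{j}" for j in range(m)])
        mm = MarkerMatrix(df, {"A": ["A_0"], "B": ["B_0"]})
        lik1 = site_likelihood(net, mm.site_observation(0), model)
        assert dataset_loglik(net, mm, model) == pytest.approx(
            m * math.log(lik1))

    def test_polymorphic_conditioning_renormalizes(self, model, net_1retic):
        from netmark.likelihood import LikelihoodEngine

        eng = LikelihoodEngine(net_1retic, model, {sp: 1 for sp in "ACLQR"})
        p_mono = eng.monomorphic_probability()
        pats = enumerate_site_patterns({sp: 1 for sp in "ACLQR"})
        poly = [p for p in pats
                if 0 < sum(o.r for o in p.values()) < 5]
        tot = sum(eng.site_likelihood(p) for p in poly) / (1 - p_mono)
        assert tot == pytest.approx(1.0, abs=1e-8)

    def test_empty_matrix_rejected(self, model, net_1retic):
        import pandas as pd

        df = pd.DataFrame(index=[f"{sp}_0" for sp in "ACLQR"])
        mm = MarkerMatrix(df, {sp: [f"{sp}_0"] for sp in "ACLQR"})
        with pytest.raises(ValueError):
            dataset_loglik(net_1retic, mm, model)
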