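"""Mk likelihoods, Q posteriors, stochastic maps and transition counts."""

import itertools

import numpy as np
import pytest
from scipy.linalg import expm

from symphy import mk, synth
from symphy.phylo import parse_newick


def brute_force_loglik(tree, tips, Q, prior):
    """Enumeration oracle: sum over all internal-node state assignments."""
    k = Q.shape[0]
    states = np.zeros(tree.n_nodes, dtype=int)
    for lab, s in tips.items():
        states[tree.tip_labels.index(lab)] = s
    P = {i: expm(Q * tree.length[i]) for i in range(tree.n_nodes)
         if tree.parent[i] >= 0}
    internal = list(range(tree.n_tips, tree.n_nodes))
    total = 0.0
    for assign in itertools.product(range(k), repeat=len(internal)):
        for i, a in zip(internal, assign):
            states[i] = a
        pr = prior[states[tree.root]]
        for i in range(tree.n_nodes):
            p = tree.parent[i]
            if p >= 0:
                pr *= P[i][states[p], states[i]]
        total += pr
    return np.log(total)


class TestMkLoglik:
    def test_zero_rate_two_tips_same_state(self):
        tree = parse_newick("(A:1,B:1);")
        Q = mk.RateMatrix.from_rates(["0", "1"], [0.0], "equal_rates")
        ll = mk.mk_loglik(tree, {"A": 0, "B": 0}, Q)
        assert ll == pytest.approx(np.log(0.5), abs=1e-12)

    def test_matches_enumeration_on_four_tips(self, balanced_four_tree):
        Q = mk.RateMatrix.from_rates(["0", "1"], [0.3], "equal_rates")
        tips = {"A": 0, "B": 1, "C": 0, "D": 1}
        ll = mk.mk_loglik(balanced_four_tree, tips, Q)
        oracle = brute_force_loglik(balanced_four_tree, tips, Q.Q,
                                    np.array([0.5, 0.5]))
        assert ll == pytest.approx(oracle, rel=1e-10)

    def test_state_relabelling_invariance_under_er(self, balanced_four_tree):
        Q = mk.RateMatrix.from_rates(["0", "1"], [0.4], "equal_rates")
        tips = {"A": 0, "B": 1, "C": 0, "D": 0}
        flipped = {k: 1 - v for k, v in tips.items()}
        assert mk.mk_loglik(balanced_four_tree, tips, Q) == pytest.approx(
            mk.mk_loglik(balanced_four_tree, flipped, Q), rel=1e-12)

    def test_enumeration_agreement_on_random_trees(self):
        """Property: pruning equals enumeration on small random instances."""
        rng = np.random.Generator(np.random.PCG64(7))
        for case in range(25):
            n = int(rng.integers(3, 6))
            tree = synth.sim_tree(n, root_age=1.0, seed=2000 + case)
            k = int(rng.integers(2, 4))
            rates = rng.exponential(1.0, size=k * (k - 1))
            Q = mk.RateMatrix.from_rates([str(i) for i in range(k)], rates)
            tips = {lab: int(rng.integers(k)) for lab in tree.tip_labels}
            ll = mk.mk_loglik(tree, tips, Q)
            oracle = brute_force_loglik(tree, tips, Q.Q, np.full(k, 1 / k))
            assert ll == pytest.approx(oracle, rel=1e-9)

    def test_ambiguous_tip_sums_over_states(self):
        tree = parse_newick("(A:1,B:1);")
        Q = mk.RateMatrix.from_rates(["0", "1"], [0.2], "equal_rates")
        l0 = np.exp(mk.mk_loglik(tree, {"A": 0, "B": 0}, Q))
        l1 = np.exp(mk.mk_loglik(tree, {"A": 0, "B": 1}, Q))
        lam = np.exp(mk.mk_loglik(tree, {"A": 0, "B": None}, Q))
        assert lam == pytest.approx(l0 + l1, rel=1e-10)


class TestQPosterior:
    def test_er_rate_recovered_from_simulation(self):
        tree = synth.sim_tree(200, root_age=1.0, seed=3)
        Q = mk.RateMatrix.from_rates(["0", "1"], [0.5], "equal_rates")
        hits = 0
        for rep in range(5):
            sim = synth.sim_mk_trait(tree, Q, seed=rep)
            post = mk.sample_q_posterior(
                tree, sim["tip_states"], ["0", "1"], "equal_rates",
                n_iter=1500, burnin=500, thin=5, seed=rep)
            med = float(np.median(post.draws))
            hits += abs(med - 0.5) / 0.5 < 0.5
        assert hits >= 4

    def test_single_observed_state_rejected(self, balanced_four_tree):
        with pytest.raises(ValueError):
            mk.sample_q_posterior(balanced_four_tree,
                                  {t: 0 for t in "ABCD"}, ["0", "1"])

    def test_equal_rates_has_one_free_parameter(self, medium_tree):
        Q = mk.RateMatrix.from_rates(["0", "1"], [0.004], "equal_rates")
        sim = synth.sim_mk_trait(medium_tree, Q, seed=5)
        post = mk.sample_q_posterior(medium_tree, sim["tip_states"],
                                     ["0", "1"], "equal_rates",
                                     n_iter=300, burnin=100, seed=1)
        assert post.draws.shape[1] == 1


class TestStochasticMaps:
    def setup_maps(self, n_maps=300):
        tree = parse_newick("((A:1,B:1):1,(C:1,D:1):1);")
        Q = mk.RateMatrix.from_rates(["0", "1"], [0.4], "equal_rates")
        tips = {"A": 0, "B": 1, "C": 1, "D": 1}
        return tree, Q, tips, mk.stochastic_maps(tree, tips, Q, n_maps, seed=9)

    def test_maps_respect_observed_tips(self):
        tree, Q, tips, maps = self.setup_maps()
        for m in maps:
            for lab, s in tips.items():
                assert m.node_states[tree.tip_labels.index(lab)] == s

    def test_segments_tile_branches_and_match_endpoints(self):
        tree, Q, tips, maps = self.setup_maps(100)
        for m in maps:
            for i in range(tree.n_nodes):
                if tree.parent[i] < 0:
                    continue
                segs = m.segments[i]
                assert sum(t for _, t in segs) == pytest.approx(
                    tree.length[i], abs=1e-9)
                assert segs[0][0] == m.node_states[tree.parent[i]]
                assert segs[-1][0] == m.node_states[i]

    def test_differing_tips_force_a_change(self):
        tree = parse_newick("(A:1,B:1);")
        Q = mk.RateMatrix.from_rates(["0", "1"], [0.01], "equal_rates")
        maps = mk.stochastic_maps(tree, {"A": 0, "B": 1}, Q, 200, seed=4)
        assert all(m.total_changes() >= 1 for m in maps)

    def test_map_frequencies_match_analytic_marginals(self):
        tree, Q, tips, maps = self.setup_maps(2000)
        freq, _ = mk.summarize_node_states(maps, 2)
        M = mk.node_marginals(tree, tips, Q)
        se = np.sqrt(M * (1 - M) / 2000)
        assert np.max(np.abs(freq - M) - 3 * se - 1e-9) < 0.0

    def test_uniformization_matches_unconditional_change_rate(self):
        # one long branch, symmetric 2-state chain: E[changes] = q * t
        tree = parse_newick("(A:4,B:0.0001);")
        q, t = 0.5, 4.0
        Q = mk.RateMatrix.from_rates(["0", "1"], [q], "equal_rates")
        maps = mk.stochastic_maps(tree, {"A": None, "B": None}, Q, 4000,
                                  seed=11)
        i = tree.tip_labels.index("A")
        mean_changes = np.mean([len(m.segments[i]) - 1 for m in maps])
        assert mean_changes == pytest.approx(q * t, rel=0.08)


class TestNodeSummaries:
    def test_majority_rule_strictly_above_half(self):
        maps = mk.stochastic_maps(
            parse_newick("(A:1,B:1);"),
            {"A": 0, "B": 0},
            mk.RateMatrix.from_rates(["0", "1"], [0.05], "equal_rates"),
            100, seed=2)
        freq, assigned = mk.summarize_node_states(maps, 2)
        root = 2
        assert freq[root, 0] > 0.5 and assigned[root] == 0

    def test_tie_is_uncertain_under_majority_but_not_modal(self):
        class FakeMap:
            def __init__(self, s):
                self.node_states = np.array(s)
        maps = [FakeMap([0]), FakeMap([1])]
        _, assigned = mk.summarize_node_states(maps, 2, rule="majority")
        assert assigned[0] == -1
        _, modal = mk.summarize_node_states(maps, 2, rule="modal")
        assert modal[0] in (0, 1)


class TestTransitionCounts:
    def test_single_origin(self, three_tip_tree):
        # nodes: A B C N0(root) N1; subtree (A,B) gained state 1
        assignment = np.array([1, 1, 0, 0, 1])
        res = mk.count_state_transitions(three_tip_tree, assignment, {1})
        assert res["n_origins"] == 1 and res["n_losses"] == 0

    def test_origin_then_loss_along_path(self, caterpillar_four_tree):
        tree = caterpillar_four_tree
        assignment = np.zeros(tree.n_nodes, dtype=int)
        n1 = tree.index_of("N1")
        assignment[n1] = 1  # gained below root, lost towards its children
        res = mk.count_state_transitions(tree, assignment, {1})
        assert res["n_origins"] == 1
        assert res["n_losses"] == len(tree.children_lists()[n1])

    def test_counts_match_edge_scan_on_random_labelling(self, medium_tree):
        rng = np.random.Generator(np.random.PCG64(6))
        assignment = rng.integers(0, 2, medium_tree.n_nodes)
        res = mk.count_state_transitions(medium_tree, assignment, {1})
        origins = losses = 0
        for i in range(medium_tree.n_nodes):
            p = medium_tree.parent[i]
            if p < 0:
                continue
            if assignment[p] == 0 and assignment[i] == 1:
                origins += 1
            if assignment[p] == 1 and assignment[i] == 0:
                losses += 1
        assert (res["n_origins"], res["n_losses"]) == (origins, losses)

    def test_uncertain_nodes_are_skipped_and_reported(self, three_tip_tree):
        assignment = np.array([1, 1, 0, 0, -1])
        res = mk.count_state_transitions(three_tip_tree, assignment, {1})
        assert res["skipped_edges"] == 3  # edges touching N1
        assert res["n_origins"] == 0
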