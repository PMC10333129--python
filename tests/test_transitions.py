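"""Node transition categories, posterior resampling and pooling."""

import numpy as np
import pandas as pd
import pytest

from symphy import synth, transitions
from symphy.phylo import parse_newick


@pytest.fixture
def classified_tree():
    # ((A,B)N1,C)N0 with tips A=1, B=1, C=0
    tree = parse_newick("((A:1,B:1):1,C:2);")
    return tree


class TestClassifyNodes:
    def run(self, tree, states):
        out = transitions.classify_nodes(tree, np.array(states))
        return dict(zip(out["node"], out["category"]))

    def test_obligate_node_with_obligate_children(self, classified_tree):
        # N0=0, N1=1, tips A=1 B=1 C=0
        cats = self.run(classified_tree, [1, 1, 0, 0, 1])
        assert cats["N1"] == "ObToOb"
        assert cats["N0"] == "NonToOb"

    def test_non_node_with_non_children(self, classified_tree):
        cats = self.run(classified_tree, [0, 0, 0, 0, 0])
        assert cats == {"N0": "NonToNon", "N1": "NonToNon"}

    def test_ob_node_with_any_non_child_is_loss(self, classified_tree):
        # N1 obligate with children A=1, B=0 -> precedes a loss; likewise
        # N0 obligate with the non-obligate tip C as a descendant
        cats = self.run(classified_tree, [1, 0, 0, 1, 1])
        assert cats["N1"] == "ObToNon"
        assert cats["N0"] == "ObToNon"
        cats = self.run(classified_tree, [1, 1, 1, 1, 1])
        assert cats["N0"] == "ObToOb" and cats["N1"] == "ObToOb"

    def test_unassigned_nodes_excluded(self, classified_tree):
        out = transitions.classify_nodes(classified_tree,
                                         np.array([1, 1, 0, -1, 1]))
        assert set(out["node"]) == {"N1"}

    def test_category_counts_sum_to_classified_nodes(self, medium_tree):
        rng = np.random.default_rng(1)
        states = rng.integers(0, 2, medium_tree.n_nodes)
        out = transitions.classify_nodes(medium_tree, states)
        assert len(out) == medium_tree.n_nodes - medium_tree.n_tips
        assert set(out["category"]) <= set(transitions.CATEGORIES)


class TestResampling:
    def test_zero_uncertainty_gives_identical_resamples(self, medium_tree):
        n_int = medium_tree.n_nodes - medium_tree.n_tips
        labels = medium_tree.labels[medium_tree.n_tips:]
        probs = np.tile(np.where(np.arange(n_int) % 2 == 0, 1.0, 0.0), (5, 1))
        tips = np.zeros(medium_tree.n_tips, dtype=int)
        out = transitions.resample_classifications(
            medium_tree, probs, labels, tips, n_resamples=6, seed=3)
        first = out[0]
        for other in out[1:]:
            pd.testing.assert_frame_equal(first, other)

    def test_uncertain_nodes_flip_at_draw_frequency(self, medium_tree):
        # half the posterior draws put every node above 0.5, half below:
        # thresholded resamples should reproduce that draw-level frequency
        n_int = medium_tree.n_nodes - medium_tree.n_tips
        labels = medium_tree.labels[medium_tree.n_tips:]
        probs = np.where(np.arange(10)[:, None] % 2 == 0, 0.8, 0.2)
        probs = np.broadcast_to(probs, (10, n_int))
        tips = np.zeros(medium_tree.n_tips, dtype=int)
        out = transitions.resample_classifications(
            medium_tree, probs, labels, tips, n_resamples=60, seed=4)
        root_label = medium_tree.labels[medium_tree.root]
        root_cats = [o.set_index("node").loc[root_label, "category"]
                     for o in out]
        frac_ob = np.mean([c.startswith("Ob") for c in root_cats])
        assert 0.3 < frac_ob < 0.7

    def test_bernoulli_mode_flips_at_half_probability(self, medium_tree):
        n_int = medium_tree.n_nodes - medium_tree.n_tips
        labels = medium_tree.labels[medium_tree.n_tips:]
        probs = np.full((5, n_int), 0.5)
        tips = np.zeros(medium_tree.n_tips, dtype=int)
        out = transitions.resample_classifications(
            medium_tree, probs, labels, tips, n_resamples=60, seed=4,
            mode="bernoulli")
        root_label = medium_tree.labels[medium_tree.root]
        root_cats = [o.set_index("node").loc[root_label, "category"]
                     for o in out]
        frac_ob = np.mean([c.startswith("Ob") for c in root_cats])
        assert 0.3 < frac_ob < 0.7

    def test_default_resample_count(self, medium_tree):
        n_int = medium_tree.n_nodes - medium_tree.n_tips
        labels = medium_tree.labels[medium_tree.n_tips:]
        probs = np.zeros((2, n_int))
        tips = np.zeros(medium_tree.n_tips, dtype=int)
        out = transitions.resample_classifications(
            medium_tree, probs, labels, tips, seed=1)
        assert len(out) == 100


class TestAncestralNutrientModel:
    def test_identical_nutrients_give_null_contrasts(self):
        tree = synth.sim_tree(40, seed=50)
        rng = np.random.default_rng(51)
        states = np.concatenate([
            rng.integers(0, 2, tree.n_tips),
            rng.integers(0, 2, tree.n_nodes - tree.n_tips)])
        cls = [transitions.classify_nodes(tree, states)] * 3
        labels = tree.labels[tree.n_tips:]
        node_values = pd.DataFrame({
            "node": labels,
            "B5": rng.normal(0, 0.03, len(labels)),
            "B9": rng.normal(0, 0.03, len(labels)),
        })
        res = transitions.ancestral_nutrient_model(tree, cls, node_values,
                                                   seed=52)
        assert (res.contrasts["pmcmc"] > 0.05).all()
        assert (res.contrasts["mean"].abs() < 0.15).all()

    def test_pooled_draw_count(self):
        tree = synth.sim_tree(30, seed=60)
        rng = np.random.default_rng(61)
        states = rng.integers(0, 2, tree.n_nodes)
        cls = [transitions.classify_nodes(tree, states)] * 4
        labels = tree.labels[tree.n_tips:]
        node_values = pd.DataFrame({
            "node": labels,
            "B5": rng.normal(size=len(labels)),
            "B9": rng.normal(size=len(labels)),
        })
        res = transitions.ancestral_nutrient_model(tree, cls, node_values,
                                                   seed=62)
        expected = res.n_resamples * res.draws_per_resample
        for draws in res.pooled_draws.values():
            assert len(draws) == expected

    def test_category_counts_cover_all_internal_nodes(self):
        tree = synth.sim_tree(30, seed=63)
        rng = np.random.default_rng(64)
        states = rng.integers(0, 2, tree.n_nodes)
        cls = [transitions.classify_nodes(tree, states)]
        labels = tree.labels[tree.n_tips:]
        node_values = pd.DataFrame({
            "node": labels,
            "B5": rng.normal(size=len(labels)),
            "B9": rng.normal(size=len(labels)),
        })
        res = transitions.ancestral_nutrient_model(tree, cls, node_values,
                                                   seed=65)
        counts = res.category_counts[list(transitions.CATEGORIES)].sum(axis=1)
        assert (counts == tree.n_nodes - tree.n_tips).all()
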