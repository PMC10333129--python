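"""Paired-trait models, stepping-stone estimates and Bayes factors."""

import numpy as np
import pytest
from scipy.special import betaln

from symphy import mk, pagel, synth
from symphy.phylo import parse_newick


class TestPairedLikelihood:
    def test_dependent_with_tied_rates_collapses_to_independent(
            self, balanced_four_tree):
        tx = {"A": 0, "B": 1, "C": 0, "D": 1}
        ty = {"A": 1, "B": 0, "C": 1, "D": 0}
        r4 = np.array([0.3, 0.5, 0.2, 0.7])
        r8 = np.repeat(r4, 2)[[0, 1, 2, 3, 4, 5, 6, 7]]
        r8 = np.array([0.3, 0.3, 0.5, 0.5, 0.2, 0.2, 0.7, 0.7])
        lli = pagel.paired_loglik(balanced_four_tree, tx, ty, r4, "independent")
        lld = pagel.paired_loglik(balanced_four_tree, tx, ty, r8, "dependent")
        assert lli == pytest.approx(lld, rel=1e-12)

    def test_independent_model_factorizes_over_traits(self, balanced_four_tree):
        # with y constant-compatible rates the 4-state likelihood equals the
        # product of two single-trait pruning likelihoods
        tx = {"A": 0, "B": 1, "C": 1, "D": 0}
        ty = {"A": 1, "B": 1, "C": 0, "D": 0}
        r4 = np.array([0.4, 0.6, 0.25, 0.15])
        lli = pagel.paired_loglik(balanced_four_tree, tx, ty, r4, "independent")
        Qx = mk.RateMatrix.from_rates(["0", "1"], r4[:2])
        Qy = mk.RateMatrix.from_rates(["0", "1"], r4[2:])
        sep = (mk.mk_loglik(balanced_four_tree, tx, Qx)
               + mk.mk_loglik(balanced_four_tree, ty, Qy))
        assert lli == pytest.approx(sep, rel=1e-9)

    def test_all_zero_rates_monomorphic_tips(self, balanced_four_tree):
        zeros = {t: 0 for t in "ABCD"}
        ll = pagel.paired_loglik(balanced_four_tree, zeros, zeros,
                                 np.zeros(8), "dependent")
        assert ll == pytest.approx(np.log(0.25), abs=1e-12)

    def test_dual_transitions_forbidden(self):
        rm = pagel.paired_rate_matrix(np.arange(1.0, 9.0), "dependent")
        # 00 <-> 11 and 01 <-> 10 entries are exactly zero
        assert rm.Q[0, 3] == 0 and rm.Q[3, 0] == 0
        assert rm.Q[1, 2] == 0 and rm.Q[2, 1] == 0


class TestSteppingStone:
    def toy(self, k, n):
        def ll(th):
            x = th[0]
            if not 0 < x < 1:
                return -np.inf
            return k * np.log(x) + (n - k) * np.log(1 - x)

        def lp(th):
            return 0.0 if 0 < th[0] < 1 else -np.inf

        def prop(th, rng, step):
            return th + rng.normal(0, 0.15, size=1)

        return ll, lp, prop

    @pytest.mark.parametrize("k,n", [(7, 10), (2, 12)])
    def test_beta_bernoulli_matches_closed_form(self, k, n):
        ll, lp, prop = self.toy(k, n)
        res = pagel.stepping_stone(ll, lp, prop, np.array([0.5]),
                                   n_stones=100, iters_per_stone=1000, seed=5)
        exact = betaln(k + 1, n - k + 1)
        assert res["lnml"] == pytest.approx(exact, abs=0.1)

    def test_occam_penalty_for_uninformative_parameter(self):
        # adding a parameter the likelihood ignores costs marginal likelihood
        k, n = 7, 10
        ll1, lp1, prop1 = self.toy(k, n)
        res1 = pagel.stepping_stone(ll1, lp1, prop1, np.array([0.5]),
                                    n_stones=50, iters_per_stone=600, seed=6)

        def ll2(th):
            return ll1(th[:1])

        def lp2(th):
            # second parameter has a N(0, 10) prior but no likelihood role;
            # an improper/wide prior dilutes the marginal likelihood
            if not 0 < th[0] < 1:
                return -np.inf
            return -0.5 * th[1] ** 2 / 100.0 - 0.5 * np.log(2 * np.pi * 100.0)

        def prop2(th, rng, step):
            return th + rng.normal(0, [0.15, 2.0], size=2)

        res2 = pagel.stepping_stone(ll2, lp2, prop2, np.array([0.5, 0.0]),
                                    n_stones=50, iters_per_stone=600, seed=6)
        assert res1["lnml"] >= res2["lnml"] - 0.15

    def test_stone_count_convergence_on_toy(self):
        ll, lp, prop = self.toy(5, 9)
        a = pagel.stepping_stone(ll, lp, prop, np.array([0.5]),
                                 n_stones=100, iters_per_stone=500, seed=1)
        b = pagel.stepping_stone(ll, lp, prop, np.array([0.5]),
                                 n_stones=200, iters_per_stone=500, seed=2)
        assert abs(a["lnml"] - b["lnml"]) < 0.2


class TestEvidence:
    @pytest.mark.parametrize(
        "lc,ls,bf,cat",
        [(-10.0, -12.0, 4.0, "positive"),
         (-8.0, -8.0, 0.0, "none"),
         (-5.0, -11.0, 12.0, "very strong"),
         (-5.0, -8.0, 6.0, "strong")],
    )
    def test_bayes_factor_and_category(self, lc, ls, bf, cat):
        rep = pagel.bayes_factor(lc, ls)
        assert rep.bayes_factor == pytest.approx(bf)
        assert rep.category == cat

    def test_nonfinite_lnml_rejected(self):
        with pytest.raises(ValueError):
            pagel.bayes_factor(float("nan"), -1.0)


class TestRateContrast:
    def make_chain(self, a, b):
        draws = np.column_stack([a, b] + [np.ones_like(a)] * 6)
        return pagel.PairedChain("dependent", list(pagel.DEPENDENT_RATES),
                                 draws, np.ones_like(a), np.zeros_like(a),
                                 0.3, 0)

    def test_identical_rates_give_zero_difference(self):
        a = np.full(200, 0.7)
        c = self.make_chain(a, a)
        s = pagel.rate_contrast(c, "x+|y0", "x+|y1")
        assert s.mean == pytest.approx(0.0)
        assert s.pmcmc == pytest.approx(1.0)

    def test_shifted_rates_exclude_zero(self, rng):
        a = rng.normal(2.0, 0.05, 300)
        c = self.make_chain(a + 1.0, a)
        s = pagel.rate_contrast(c, "x+|y0", "x+|y1")
        assert s.ci_low > 0


class TestMcmcSanity:
    def test_prior_only_run_matches_hyperprior_moments(self, medium_tree):
        rng = np.random.default_rng(0)
        tx = {l: int(rng.random() < 0.5) for l in medium_tree.tip_labels}
        ty = {l: int(rng.random() < 0.5) for l in medium_tree.tip_labels}
        chains = pagel.fit_paired_mcmc(
            medium_tree, tx, ty, "independent", n_iter=20000, burnin=4000,
            thin=10, n_chains=1, seed=3, likelihood_on=False)
        # marginal prior mean of each rate = E[m] = 5 under m ~ U(0, 10)
        means = chains[0].draws.mean(axis=0)
        assert np.all(means > 2.0) and np.all(means < 8.0)

    def test_constant_trait_rejected(self, medium_tree):
        tips1 = {l: 1 for l in medium_tree.tip_labels}
        tips0 = {l: i % 2 for i, l in enumerate(medium_tree.tip_labels)}
        with pytest.raises(ValueError, match="constant"):
            pagel.fit_paired_mcmc(medium_tree, tips1, tips0)

    def test_three_chains_by_default_and_rates_positive(self):
        tree = synth.sim_tree(40, seed=8)
        rng = np.random.default_rng(1)
        tx = {l: int(rng.random() < 0.5) for l in tree.tip_labels}
        ty = {l: int(rng.random() < 0.5) for l in tree.tip_labels}
        chains = pagel.fit_paired_mcmc(tree, tx, ty, "dependent",
                                       n_iter=800, burnin=300, thin=10, seed=4)
        assert len(chains) == 3
        for c in chains:
            assert np.all(c.draws > 0)
            assert c.draws.shape[1] == 8
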