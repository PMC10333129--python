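"""Mixed-model engine: conjugate exactness, link handling, summaries,
variance partitioning, node prediction and convergence diagnostics."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import invgamma, kstest

from symphy import pglmm, synth
from symphy.pglmm import (ChainSettings, LOGIT_LINK_VAR, MixedModel,
                          RandomTerm, Response)
from symphy.stats import hpd_interval, pmcmc, summarize_draws


class TestGaussianConjugate:
    def test_residual_variance_matches_closed_form_posterior(self):
        rng = np.random.default_rng(1)
        y = rng.normal(0.0, 1.5, 40)
        y -= y.mean()
        m = MixedModel(pd.DataFrame({"y": y}), [Response("y")],
                       intercept=False)
        chain = m.fit(ChainSettings(n_iter=6000, burnin=1000, thin=1,
                                    seed=2))[0]
        nu0, s0 = 0.002, 0.002
        a = (nu0 + len(y)) / 2
        b = (s0 + float(y @ y)) / 2
        ks = kstest(chain.ve[:, 0, 0], invgamma(a, scale=b).cdf)
        assert ks.statistic < 0.05


class TestBinomial:
    def test_intercept_only_half_successes_centres_at_zero(self):
        df = pd.DataFrame({"k": [5] * 30, "n": [10] * 30})
        m = MixedModel(df, [Response("k", "binomial", "n")])
        chain = m.fit(ChainSettings(n_iter=4000, burnin=1000, thin=3,
                                    seed=3))[0]
        b = chain.beta_draws("k:(Intercept)")
        assert abs(b.mean()) < 0.3

    def test_binomial_residual_fixed_at_one(self):
        df = pd.DataFrame({"k": [2, 5, 7, 3] * 5, "n": [10] * 20})
        m = MixedModel(df, [Response("k", "binomial", "n")])
        chain = m.fit(ChainSettings(n_iter=500, burnin=100, thin=2, seed=4))[0]
        assert np.all(chain.ve[:, 0, 0] == 1.0)

    def test_trials_below_one_rejected(self):
        df = pd.DataFrame({"k": [0], "n": [0]})
        with pytest.raises(ValueError):
            MixedModel(df, [Response("k", "binomial", "n")])


class TestPoisson:
    def test_intercept_recovers_log_mean(self):
        rng = np.random.default_rng(5)
        y = rng.poisson(20.0, 80)
        m = MixedModel(pd.DataFrame({"y": y}), [Response("y", "poisson")])
        chain = m.fit(ChainSettings(n_iter=4000, burnin=1500, thin=3,
                                    seed=6))[0]
        b = chain.beta_draws("y:(Intercept)")
        assert abs(np.median(b) - np.log(20.0)) < 0.3


class TestMissingData:
    def test_gaussian_imputation_leaves_fixed_effects_stable(self):
        tree = synth.sim_tree(80, seed=9)
        cfg = synth.TraitSimConfig(nutrients=("B5",), h2=(0.8, 0.8),
                                   missingness=0.0)
        data, _ = synth.sim_correlated_traits(tree, cfg, seed=10)
        cov = tree.covariance()

        def fit(df, seed):
            m = MixedModel(df, [Response("B5")],
                           random_terms=[RandomTerm("phylo", "family", cov,
                                                    "idh")])
            return m.fit(ChainSettings(n_iter=2000, burnin=600, thin=3,
                                       seed=seed))[0]

        full = fit(data, 11)
        masked = data.copy()
        rng = np.random.default_rng(12)
        drop = rng.choice(len(masked), size=len(masked) // 5, replace=False)
        masked.loc[drop, "B5"] = np.nan
        part = fit(masked, 13)
        b_full = full.beta_draws("B5:(Intercept)")
        b_part = part.beta_draws("B5:(Intercept)")
        assert abs(b_full.mean() - b_part.mean()) < 0.5 * b_full.std() + 0.15


class TestSummaries:
    def test_pmcmc_formula(self):
        draws = np.ones(1000)
        assert pmcmc(draws) == pytest.approx(2 / 1001)
        sym = np.concatenate([np.ones(500), -np.ones(500)])
        assert pmcmc(sym) == pytest.approx(1.0)

    def test_hpd_contains_bulk(self):
        lo, hi = hpd_interval(np.array([1.0, 2.0, 3.0]), 0.95)
        assert lo == 1.0 and hi == 3.0

    def test_summary_mode_inside_interval(self, rng):
        draws = rng.normal(2.0, 0.5, 2000)
        s = summarize_draws(draws, "x")
        assert s.ci_low <= s.mode <= s.ci_high


class TestVariancePartition:
    def make_chain(self, v_phylo, v_e, family="gaussian"):
        tree = synth.sim_tree(10, seed=1)
        df = pd.DataFrame({"y": np.zeros(10), "n": np.ones(10) * 4,
                           "family": tree.tip_labels})
        resp = (Response("y", "binomial", "n") if family == "binomial"
                else Response("y"))
        m = MixedModel(df, [resp],
                       random_terms=[RandomTerm("phylo", "family",
                                                tree.covariance(), "idh")])
        chain = pglmm.PosteriorChain(m, ChainSettings(n_iter=110, burnin=10,
                                                      thin=1), 0)
        n = chain.beta.shape[0]
        chain.vcomp["phylo"][:] = v_phylo
        chain.ve[:] = 0.0
        chain.ve[:, 0, 0] = v_e
        return chain

    def test_logit_icc_includes_link_variance(self):
        chain = self.make_chain(1.0, 1.0, "binomial")
        draws, s = pglmm.variance_partition(chain, "phylo", "y")
        expected = 1.0 / (2.0 + LOGIT_LINK_VAR)
        assert s.mean == pytest.approx(expected, abs=1e-9)
        assert expected == pytest.approx(0.1889, abs=5e-4)

    def test_zero_variance_gives_zero_icc(self):
        chain = self.make_chain(0.0, 1.0)
        draws, _ = pglmm.variance_partition(chain, "phylo", "y")
        assert np.all(draws == 0.0)

    def test_gaussian_icc(self):
        chain = self.make_chain(3.0, 1.0)
        draws, _ = pglmm.variance_partition(chain, "phylo", "y")
        assert np.allclose(draws, 0.75)

    def test_icc_bounds_hold_for_every_draw(self):
        tree = synth.sim_tree(50, seed=2)
        cfg = synth.TraitSimConfig(nutrients=("B5",), h2=(0.5, 0.5),
                                   missingness=0.0)
        data, _ = synth.sim_correlated_traits(tree, cfg, seed=3)
        m = MixedModel(data, [Response("B5")],
                       random_terms=[RandomTerm("phylo", "family",
                                                tree.covariance(), "idh")])
        chain = m.fit(ChainSettings(n_iter=800, burnin=200, thin=2, seed=4))[0]
        draws, _ = pglmm.variance_partition(chain, "phylo", "B5")
        assert np.all((draws >= 0) & (draws <= 1))


class TestPhyloCorrelation:
    def test_diagonal_draws_give_zero(self):
        tree = synth.sim_tree(10, seed=1)
        df = pd.DataFrame({"a": np.zeros(10), "b": np.zeros(10),
                           "family": tree.tip_labels})
        m = MixedModel(df, [Response("a"), Response("b")],
                       random_terms=[RandomTerm("phylo", "family",
                                                tree.covariance(),
                                                "unstructured")])
        chain = pglmm.PosteriorChain(m, ChainSettings(110, 10, 1), 0)
        chain.vcomp["phylo"][:] = np.eye(2)
        draws, _ = pglmm.phylo_correlation(chain, "phylo", "a", "b")
        assert np.all(draws == 0)
        chain.vcomp["phylo"][:] = np.array([[1.0, 0.5], [0.5, 1.0]])
        draws, _ = pglmm.phylo_correlation(chain, "phylo", "a", "b")
        assert np.allclose(draws, 0.5)

    def test_idh_term_refuses_correlation(self):
        tree = synth.sim_tree(10, seed=1)
        df = pd.DataFrame({"a": np.zeros(10), "b": np.zeros(10),
                           "family": tree.tip_labels})
        m = MixedModel(df, [Response("a"), Response("b")],
                       random_terms=[RandomTerm("phylo", "family",
                                                tree.covariance(), "idh")])
        chain = pglmm.PosteriorChain(m, ChainSettings(110, 10, 1), 0)
        with pytest.raises(ValueError, match="unstructured"):
            pglmm.phylo_correlation(chain, "phylo", "a", "b")


class TestNodePrediction:
    def test_conditional_means_match_kriging_formula(self):
        tree = synth.sim_tree(5, seed=7)
        df = pd.DataFrame({"y": [0.2, -0.1, 0.4, 0.0, -0.3],
                           "family": tree.tip_labels})
        m = MixedModel(df, [Response("y")],
                       random_terms=[RandomTerm("phylo", "family",
                                                tree.covariance(), "idh")])
        chain = m.fit(ChainSettings(n_iter=300, burnin=100, thin=2, seed=8))[0]
        out = pglmm.predict_nodes(chain, tree, "phylo", "y", mode="plugin")
        # oracle: direct kriging C_nt C_tt^-1 u averaged over draws
        full = tree.covariance(include_internal=True)
        s = full.matrix.diagonal().max()
        Cf = full.matrix / s
        pos = {l: i for i, l in enumerate(full.labels)}
        labs = chain.model.Clabels["phylo"]
        ti = np.array([pos[l] for l in labs])
        ni = np.array([pos[l] for l in out["node"]])
        K = Cf[np.ix_(ni, ti)] @ np.linalg.inv(
            Cf[np.ix_(ti, ti)] + 1e-8 * np.eye(5))
        icol = chain.beta_names.index("y:(Intercept)")
        expected = np.mean(
            [K @ chain.u["phylo"][d, :, 0] + chain.beta[d, icol]
             for d in range(chain.u["phylo"].shape[0])], axis=0)
        np.testing.assert_allclose(out["expectation"].to_numpy(), expected,
                                   atol=1e-8)

    def test_strong_signal_tips_all_one_gives_confident_root(self):
        tree = synth.sim_tree(40, seed=9)
        df = pd.DataFrame({"k": [8] * 40, "n": [8] * 40,
                           "family": tree.tip_labels})
        m = MixedModel(df, [Response("k", "binomial", "n")],
                       random_terms=[RandomTerm("phylo", "family",
                                                tree.covariance(), "idh")])
        chain = m.fit(ChainSettings(n_iter=1500, burnin=500, thin=3,
                                    seed=10))[0]
        out = pglmm.predict_nodes(chain, tree, "phylo", "k", seed=1)
        assert (out["posterior_prob"] > 0.5).all()


class TestGelmanRubin:
    def make_chains(self, shift):
        tree = synth.sim_tree(10, seed=1)
        df = pd.DataFrame({"y": np.zeros(10), "family": tree.tip_labels})
        m = MixedModel(df, [Response("y")])
        rng = np.random.default_rng(0)
        chains = []
        for c in range(2):
            ch = pglmm.PosteriorChain(m, ChainSettings(1010, 10, 1), c)
            ch.beta[:, 0] = rng.normal(shift * c, 1.0, ch.beta.shape[0])
            ch.ve[:] = 1.0
            chains.append(ch)
        return chains

    def test_identical_distributions_give_psrf_near_one(self):
        out = pglmm.gelman_rubin(self.make_chains(0.0))
        psrf = out.set_index("parameter").loc["y:(Intercept)", "psrf"]
        assert psrf < 1.05
        assert out.attrs["converged"]

    def test_shifted_chains_flagged(self):
        out = pglmm.gelman_rubin(self.make_chains(5.0))
        psrf = out.set_index("parameter").loc["y:(Intercept)", "psrf"]
        assert psrf > 1.1
        assert not out.attrs["converged"]

    def test_white_noise_ess_close_to_n(self):
        out = pglmm.gelman_rubin(self.make_chains(0.0))
        ess = out.set_index("parameter").loc["y:(Intercept)", "ess"]
        assert ess == pytest.approx(2000, rel=0.2)
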