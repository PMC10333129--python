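"""Correlated evolution of two binary traits on a phylogeny.

Implements the classic test contrasting an *independent* model, where each
trait follows its own 2-state chain (4 rates), against a *dependent* model
where each trait's transition rates may depend on the current state of the
other (8 rates).  The joint process is a 4-state CTMC over combined states
(0,0), (0,1), (1,0), (1,1) with simultaneous double transitions forbidden.

Model comparison uses log marginal likelihoods estimated by stepping-stone
sampling along a power-posterior path, summarized as a Bayes factor
2*(lnML_dependent - lnML_independent) with the conventional 2/5/10
evidence thresholds.  Rate priors are exponential with a uniform(0, 10)
hyper-prior on the prior mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from symphy.mk import PruningEngine, RateMatrix
from symphy.phylo import Phylogeny
from symphy.stats import ParamSummary, hpd_interval, pmcmc, posterior_mode

__all__ = [
    "PAIRED_STATES",
    "INDEPENDENT_RATES",
    "DEPENDENT_RATES",
    "paired_rate_matrix",
    "paired_loglik",
    "fit_paired_mcmc",
    "stepping_stone",
    "stepping_stone_lnml",
    "bayes_factor",
    "rate_contrast",
    "EvidenceReport",
    "PairedChain",
]

# combined state index = 2*x + y for traits (x, y)
PAIRED_STATES = ["00", "01", "10", "11"]

# Dependent model: each single-trait move has its own rate conditional on
# the other trait's state.  "x+|y0" = gain of x while y = 0, "y-|x1" = loss
# of y while x = 1, and so on.
DEPENDENT_RATES = [
    "x+|y0", "x+|y1", "x-|y0", "x-|y1",
    "y+|x0", "y+|x1", "y-|x0", "y-|x1",
]
# Independent model: trait x has rates (x+, x-) regardless of y, likewise y.
INDEPENDENT_RATES = ["x+", "x-", "y+", "y-"]


def paired_rate_matrix(rates: np.ndarray | dict, kind: str) -> RateMatrix:
    """Build the 4-state generator from named single-trait rates.

    ``kind`` is 'dependent' (8 rates) or 'independent' (4 rates); the
    entries for simultaneous changes of both traits are exactly zero.
    """
    names = DEPENDENT_RATES if kind == "dependent" else INDEPENDENT_RATES
    if isinstance(rates, dict):
        r = np.array([rates[n] for n in names], dtype=float)
    else:
        r = np.asarray(rates, dtype=float)
    if len(r) != len(names):
        raise ValueError(f"{kind} model needs {len(names)} rates")
    if kind == "independent":
        # expand to the 8 conditional rates with ties
        xg, xl, yg, yl = r
        r = np.array([xg, xg, xl, xl, yg, yg, yl, yl])
    xg0, xg1, xl0, xl1, yg0, yg1, yl0, yl1 = r
    Q = np.zeros((4, 4))
    # state order 00, 01, 10, 11 (index 2x + y)
    Q[0, 2] = xg0  # 00 -> 10: gain x while y=0
    Q[1, 3] = xg1  # 01 -> 11
    Q[2, 0] = xl0  # 10 -> 00: loss x while y=0
    Q[3, 1] = xl1  # 11 -> 01
    Q[0, 1] = yg0  # 00 -> 01: gain y while x=0
    Q[2, 3] = yg1  # 10 -> 11
    Q[1, 0] = yl0  # 01 -> 00
    Q[3, 2] = yl1  # 11 -> 10
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return RateMatrix(PAIRED_STATES, Q, constraint=kind)


def combine_tip_states(
    tips_x: dict[str, int], tips_y: dict[str, int]
) -> dict[str, int]:
    if set(tips_x) != set(tips_y):
        raise ValueError("the two traits must cover the same tips")
    return {lab: 2 * int(tips_x[lab]) + int(tips_y[lab]) for lab in tips_x}


def paired_loglik(
    tree: Phylogeny,
    tips_x: dict[str, int],
    tips_y: dict[str, int],
    rates: np.ndarray | dict,
    kind: str = "dependent",
    root_prior="uniform",
) -> float:
    rm = paired_rate_matrix(rates, kind)
    eng = PruningEngine(tree, combine_tip_states(tips_x, tips_y), 4)
    return eng.loglik(rm.Q, root_prior)


# ---------------------------------------------------------------------------
# MCMC over rates with the exponential/uniform hyper-prior


@dataclass
class PairedChain:
    """Thinned draws of rates (and the hyper prior mean) for one model."""

    kind: str
    rate_names: list[str]
    draws: np.ndarray          # (n, n_rates)
    hyper_mean: np.ndarray     # (n,)
    logliks: np.ndarray
    acceptance: float
    seed: int

    def rates(self, name: str) -> np.ndarray:
        return self.draws[:, self.rate_names.index(name)]


class _PairedModel:
    """Target density over theta = (log rates..., hyper mean m)."""

    def __init__(self, tree, tips_x, tips_y, kind, root_prior="uniform",
                 hyper_range: tuple[float, float] = (0.0, 10.0)):
        self.kind = kind
        self.names = DEPENDENT_RATES if kind == "dependent" else INDEPENDENT_RATES
        self.n_rates = len(self.names)
        self.eng = PruningEngine(tree, combine_tip_states(tips_x, tips_y), 4)
        self.root_prior = root_prior
        self.lo, self.hi = hyper_range

    def log_prior(self, theta: np.ndarray) -> float:
        m = theta[-1]
        if not (self.lo < m <= self.hi):
            return -np.inf
        rates = np.exp(theta[: self.n_rates])
        # exponential(mean m) on each rate, with log-transform Jacobian
        return float(
            -self.n_rates * np.log(m)
            - rates.sum() / m
            + theta[: self.n_rates].sum()
        )

    def log_lik(self, theta: np.ndarray) -> float:
        rates = np.exp(theta[: self.n_rates])
        Q = paired_rate_matrix(rates, self.kind).Q
        return self.eng.loglik(Q, self.root_prior)

    def sample_prior(self, rng: np.random.Generator) -> np.ndarray:
        m = rng.uniform(max(self.lo, 1e-3), self.hi)
        rates = rng.exponential(m, size=self.n_rates)
        return np.concatenate([np.log(np.maximum(rates, 1e-12)), [m]])

    def propose(self, theta: np.ndarray, rng: np.random.Generator,
                step: float) -> np.ndarray:
        out = theta.copy()
        out[: self.n_rates] += rng.normal(0.0, step, size=self.n_rates)
        return out

    def gibbs_update(self, theta: np.ndarray,
                     rng: np.random.Generator) -> np.ndarray:
        """Exact conditional draw of the hyper mean m given the rates.

        p(m | rates) on (lo, hi) is proportional to m^-n exp(-S/m), a
        truncated inverse-gamma(n - 1, S); sampling it directly avoids
        the funnel between m and small rates that a random walk cannot
        cross.  m has no likelihood role, so this is valid at any power-
        posterior temperature.
        """
        S = float(np.exp(theta[: self.n_rates]).sum())
        a = self.n_rates - 1
        out = theta.copy()
        # rejection sampling: m = S / Gamma(a) draw, truncated to (lo, hi]
        for _ in range(200):
            m = S / rng.gamma(a)
            if self.lo < m <= self.hi:
                out[-1] = max(m, 1e-12)
                return out
        out[-1] = float(np.clip(S / max(a - 1.0, 1.0), 1e-6, self.hi))
        return out

    def initial(self) -> np.ndarray:
        scale = self.eng.tree.total_branch_length()
        r0 = max(2.0 / scale, 1e-4)
        return np.concatenate(
            [np.full(self.n_rates, np.log(r0)), [min(max(r0 * 2, 0.5), 9.0)]]
        )


def _run_mh(model, theta0, n_iter, burnin, thin, rng, step=0.4, beta=1.0,
            adapt=True):
    """Random-walk MH on the (power-)posterior prior * lik**beta."""
    theta = theta0.copy()
    lp = model.log_prior(theta)
    ll = model.log_lik(theta) if np.isfinite(lp) else -np.inf
    draws, lls = [], []
    n_acc = n_tot = 0
    for it in range(n_iter):
        prop = model.propose(theta, rng, step)
        plp = model.log_prior(prop)
        if np.isfinite(plp):
            pll = model.log_lik(prop)
            ratio = plp + beta * pll - (lp + beta * ll)
        else:
            pll, ratio = -np.inf, -np.inf
        n_tot += 1
        if np.log(rng.random()) < ratio:
            theta, lp, ll = prop, plp, pll
            n_acc += 1
        gibbs = getattr(model, "gibbs_update", None)
        if gibbs is not None:
            theta = gibbs(theta, rng)
            lp = model.log_prior(theta)
        if adapt and it < burnin and it % 50 == 49:
            step *= np.exp(0.5 * (n_acc / n_tot - 0.3))
            step = float(np.clip(step, 0.01, 3.0))
        if it >= burnin and (it - burnin) % thin == 0:
            draws.append(theta.copy())
            lls.append(ll)
    return np.array(draws), np.array(lls), n_acc / max(n_tot, 1), theta, step


def fit_paired_mcmc(
    tree: Phylogeny,
    tips_x: dict[str, int],
    tips_y: dict[str, int],
    kind: str = "dependent",
    n_iter: int = 50_000,
    burnin: int = 10_000,
    thin: int = 40,
    n_chains: int = 3,
    seed: int = 0,
    root_prior="uniform",
    likelihood_on: bool = True,
) -> list[PairedChain]:
    """Posterior over transition rates for one model kind.

    Three chains by default; desk-scale iteration counts (50k) stand in
    for full-length runs, which are available by raising ``n_iter``.
    ``likelihood_on=False`` samples the prior only (for prior-predictive
    checks).
    """
    for tips, nm in ((tips_x, "x"), (tips_y, "y")):
        vals = set(tips.values())
        if len(vals) < 2:
            raise ValueError(f"trait {nm} is constant across tips")
    model = _PairedModel(tree, tips_x, tips_y, kind, root_prior)
    if not likelihood_on:
        model = _PriorOnly(model)
    chains = []
    for c in range(n_chains):
        rng = np.random.Generator(np.random.PCG64([seed, c]))
        draws, lls, acc, _, _ = _run_mh(
            model, model.initial(), n_iter, burnin, thin, rng
        )
        chains.append(
            PairedChain(
                kind=kind,
                rate_names=list(model.names if not isinstance(model, _PriorOnly)
                                else model.base.names),
                draws=np.exp(draws[:, :-1]),
                hyper_mean=draws[:, -1],
                logliks=lls,
                acceptance=acc,
                seed=seed,
            )
        )
    return chains


class _PriorOnly:
    def __init__(self, base: _PairedModel):
        self.base = base
        self.names = base.names

    def log_prior(self, theta):
        return self.base.log_prior(theta)

    def log_lik(self, theta):
        return 0.0

    def propose(self, theta, rng, step):
        return self.base.propose(theta, rng, step)

    def gibbs_update(self, theta, rng):
        return self.base.gibbs_update(theta, rng)

    def initial(self):
        return self.base.initial()


# ---------------------------------------------------------------------------
# stepping-stone marginal likelihood


def stepping_stone(
    log_lik,
    log_prior,
    propose,
    theta0: np.ndarray,
    n_stones: int = 100,
    iters_per_stone: int = 1000,
    seed: int = 0,
    alpha: float = 0.3,
    step: float = 0.4,
) -> dict:
    """Generic stepping-stone estimate of the log marginal likelihood.

    Powers follow quantiles of Beta(alpha, 1): beta_k = (k/K)**(1/alpha),
    so stones concentrate near the prior where the integrand changes
    fastest.  The chain is annealed from the posterior (beta = 1) down to
    the prior, warm-starting each stone at the previous stone's state.
    Returns the estimate plus per-stone diagnostics.
    """

    class _M:
        pass

    model = _M()
    # plain instance attributes: called without implicit self
    model.log_prior = log_prior
    model.log_lik = log_lik
    model.propose = propose

    rng = np.random.Generator(np.random.PCG64(seed))
    K = n_stones
    betas = (np.arange(K + 1) / K) ** (1.0 / alpha)
    theta = theta0.copy()
    # burn in at the posterior
    _, _, _, theta, step = _run_mh(
        model, theta, iters_per_stone, iters_per_stone, 1, rng, step=step,
        beta=1.0,
    )
    lnml = 0.0
    stone_terms = []
    for k in range(K - 1, -1, -1):
        b_low, b_high = betas[k], betas[k + 1]
        draws, lls, acc, theta, step = _run_mh(
            model, theta, iters_per_stone, iters_per_stone // 5, 1, rng,
            step=step, beta=b_low, adapt=False,
        )
        w = (b_high - b_low) * lls
        mx = np.max(w)
        term = mx + np.log(np.mean(np.exp(w - mx)))
        if not np.isfinite(term):
            raise ArithmeticError(f"non-finite stone mean at beta={b_low}")
        lnml += term
        stone_terms.append({"beta": float(b_low), "term": float(term),
                            "acceptance": float(acc)})
    return {"lnml": float(lnml), "stones": stone_terms, "n_stones": K,
            "iters_per_stone": iters_per_stone}


def stepping_stone_lnml(
    tree: Phylogeny,
    tips_x: dict[str, int],
    tips_y: dict[str, int],
    kind: str = "dependent",
    n_stones: int = 100,
    iters_per_stone: int = 1000,
    seed: int = 0,
    root_prior="uniform",
) -> dict:
    """Stepping-stone log marginal likelihood for one paired-trait model."""
    model = _PairedModel(tree, tips_x, tips_y, kind, root_prior)
    return stepping_stone(
        model.log_lik,
        model.log_prior,
        model.propose,
        model.initial(),
        n_stones=n_stones,
        iters_per_stone=iters_per_stone,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# evidence and contrasts


@dataclass
class EvidenceReport:
    lnml_dependent: float
    lnml_independent: float
    bayes_factor: float
    category: str

    def as_dict(self) -> dict:
        return self.__dict__.copy()


def bayes_factor(lnml_complex: float, lnml_simple: float) -> EvidenceReport:
    """BF = 2 * (lnML_complex - lnML_simple); 2/5/10 evidence thresholds."""
    if not (np.isfinite(lnml_complex) and np.isfinite(lnml_simple)):
        raise ValueError("non-finite marginal likelihood")
    bf = 2.0 * (lnml_complex - lnml_simple)
    if bf > 10:
        cat = "very strong"
    elif bf > 5:
        cat = "strong"
    elif bf > 2:
        cat = "positive"
    else:
        cat = "none"
    return EvidenceReport(lnml_complex, lnml_simple, bf, cat)


def rate_contrast(chains: list[PairedChain] | PairedChain, rate_a: str,
                  rate_b: str) -> ParamSummary:
    """Posterior summary of the difference rate_a - rate_b."""
    if isinstance(chains, PairedChain):
        chains = [chains]
    diff = np.concatenate([c.rates(rate_a) - c.rates(rate_b) for c in chains])
    lo, hi = hpd_interval(diff)
    return ParamSummary(
        name=f"{rate_a} - {rate_b}",
        mode=posterior_mode(diff),
        mean=float(diff.mean()),
        ci_low=lo,
        ci_high=hi,
        pmcmc=pmcmc(diff),
        n_draws=len(diff),
    )
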