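"""Bayesian phylogenetic (generalized, multi-response) mixed models.

The model for responses y_1..y_r observed on n units (insect families,
host-symbiont combinations, sister pairs, ...) is a latent Gaussian mixed
model: each observation has a latent value

    l_ij = x_i' beta_j + sum_t u_t[level_t(i), j] + e_ij

with random-effect matrices u_t drawn from N(0, V_t (x) C_t) for a
term-specific covariance C_t (typically a phylogenetic shared-path-length
matrix, an identity, or a Schur product of host and symbiont matrices) and
response-level covariance V_t that is either unstructured (inverse-Wishart
updates) or independent per response ("idh", inverse-gamma updates).

Link functions follow the response family: identity for Gaussian (the
latent *is* the observation, imputed when missing), logit for binomial
counts, log for Poisson counts.  Non-Gaussian latents are updated by
adaptive random-walk Metropolis; everything Gaussian is Gibbs-sampled from
its exact conditional.  The residual variance of binomial responses is not
identifiable and is fixed at 1 on the latent scale; intraclass
correlations on the logit scale therefore include the pi^2/3 link
variance.

Summaries report posterior modes with 95% highest-density intervals and
pMCMC values; multi-chain convergence is assessed with the Gelman-Rubin
potential scale reduction factor and effective sample sizes (via arviz).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from symphy.phylo import PhyloCovariance, Phylogeny
from symphy.stats import ParamSummary, summarize_draws

__all__ = [
    "Response",
    "RandomTerm",
    "ChainSettings",
    "PriorSpec",
    "MixedModel",
    "PosteriorChain",
    "variance_partition",
    "phylo_correlation",
    "heritability",
    "predict_nodes",
    "gelman_rubin",
    "LOGIT_LINK_VAR",
]

LOGIT_LINK_VAR = np.pi**2 / 3.0

_FAMILIES = ("gaussian", "binomial", "poisson")


@dataclass
class Response:
    """One response column: name, error family and (binomial) trials column."""

    name: str
    family: str = "gaussian"
    trials: str | None = None  # column with binomial sample sizes

    def __post_init__(self):
        if self.family not in _FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if self.family == "binomial" and self.trials is None:
            raise ValueError("binomial responses need a trials column")


@dataclass
class RandomTerm:
    """A covariance-structured random effect.

    ``levels`` names the data column holding the level label of each unit;
    ``covariance`` is a :class:`PhyloCovariance` whose labels cover those
    levels (``None`` gives an identity = i.i.d. effects).  ``structure``
    is ``"unstructured"`` (full response covariance, needed to estimate
    phylogenetic correlations) or ``"idh"`` (independent variance per
    response).  ``responses`` restricts the term to a response subset.
    """

    name: str
    levels: str
    covariance: PhyloCovariance | None = None
    structure: str = "unstructured"
    responses: list[str] | None = None


@dataclass
class ChainSettings:
    """Desk-scale defaults; raise ``n_iter`` for publication-length runs."""

    n_iter: int = 6000
    burnin: int = 1000
    thin: int = 5
    n_chains: int = 1
    seed: int = 0

    @property
    def n_draws(self) -> int:
        return (self.n_iter - self.burnin) // self.thin


@dataclass
class PriorSpec:
    """Inverse-Wishart/inverse-gamma variance priors, normal fixed prior.

    The variance prior follows the (V, nu) convention with conditional
    update IW(nu + q, nu*V + S): small nu gives a weak prior.  For
    binomial responses the default fixed-effect prior variance is
    1 + pi^2/3, approximately flat on the probability scale.
    """

    variance_v: float = 1.0
    variance_nu: float = 0.002
    fixed_mu: float = 0.0
    fixed_v: float = 1e10
    binomial_fixed_v: float = 1.0 + LOGIT_LINK_VAR


def _scale_cov(cov: PhyloCovariance) -> tuple[list[str], np.ndarray]:
    """Scale to unit height and jitter so the matrix is invertible."""
    C = cov.matrix.copy()
    s = float(C.diagonal().max())
    if s <= 0:
        raise ValueError("degenerate covariance (zero height)")
    C = C / s
    C = C + 1e-8 * np.eye(len(C))
    return list(cov.labels), C


class PosteriorChain:
    """Thinned draws of a fitted mixed model (one MCMC chain)."""

    def __init__(self, model: "MixedModel", settings: ChainSettings, seed: int):
        self.model = model
        self.settings = settings
        self.seed = seed
        n = settings.n_draws
        self.beta = np.empty((n, model.n_beta))
        self.vcomp = {
            t.name: np.empty((n, len(model.term_resp[t.name]),
                              len(model.term_resp[t.name])))
            for t in model.random_terms
        }
        self.ve = np.empty((n, model.r, model.r))
        self.u = {
            t.name: np.empty((n, model.q[t.name], len(model.term_resp[t.name])))
            for t in model.random_terms
        }
        self.latent_acceptance: dict[str, float] = {}
        self._i = 0

    # names ------------------------------------------------------------
    @property
    def beta_names(self) -> list[str]:
        return self.model.beta_names

    def beta_draws(self, name: str) -> np.ndarray:
        return self.beta[:, self.beta_names.index(name)]

    def summarize(self, prob: float = 0.95) -> pd.DataFrame:
        rows = [summarize_draws(self.beta[:, i], nm, prob).as_dict()
                for i, nm in enumerate(self.beta_names)]
        for t in self.model.random_terms:
            resp = self.model.term_resp[t.name]
            for a, ra in enumerate(resp):
                rows.append(summarize_draws(
                    self.vcomp[t.name][:, a, a], f"V[{t.name}:{ra}]", prob
                ).as_dict())
        for j, r in enumerate(self.model.responses):
            rows.append(summarize_draws(
                self.ve[:, j, j], f"V[residual:{r.name}]", prob).as_dict())
        return pd.DataFrame(rows)


def _stack_chains(chains: list[PosteriorChain], extract) -> np.ndarray:
    return np.concatenate([np.asarray(extract(c)) for c in chains], axis=0)


class MixedModel:
    """Model specification + Gibbs/Metropolis sampler.

    Parameters
    ----------
    data : DataFrame with one row per unit.
    responses : list of :class:`Response`.
    fixed : columns entering every response's design (numeric; build
        factor dummies upstream).  Per-response intercepts are added
        unless ``intercept=False``.
    random_terms : list of :class:`RandomTerm`.
    residual : ``"diagonal"`` or ``"unstructured"`` (all-Gaussian only).
    """

    def __init__(
        self,
        data: pd.DataFrame,
        responses: list[Response],
        fixed: list[str] | None = None,
        random_terms: list[RandomTerm] | None = None,
        residual: str = "diagonal",
        intercept: bool = True,
        priors: PriorSpec | None = None,
    ):
        self.data = data.reset_index(drop=True)
        self.responses = responses
        self.r = len(responses)
        self.n = len(self.data)
        self.random_terms = random_terms or []
        self.priors = priors or PriorSpec()
        self.families = [r.family for r in responses]
        if residual == "unstructured" and any(f != "gaussian" for f in self.families):
            raise ValueError("unstructured residual requires all-Gaussian responses")
        self.residual = residual

        # responses / trials / observed mask
        self.y = np.zeros((self.n, self.r))
        self.trials = np.ones((self.n, self.r))
        self.observed = np.zeros((self.n, self.r), dtype=bool)
        for j, resp in enumerate(responses):
            col = pd.to_numeric(self.data[resp.name], errors="coerce")
            self.observed[:, j] = col.notna().to_numpy()
            self.y[:, j] = col.fillna(0.0).to_numpy()
            if resp.family == "binomial":
                tr = pd.to_numeric(self.data[resp.trials]).to_numpy(float)
                if np.any(tr[self.observed[:, j]] < 1):
                    raise ValueError("binomial trials must be >= 1")
                self.trials[:, j] = np.where(np.isfinite(tr), tr, 1.0)

        # fixed-effect designs (block per response)
        fixed = fixed or []
        self.fixed_cols = list(fixed)
        Xbase = [np.asarray(pd.to_numeric(self.data[c]).to_numpy(float))
                 for c in fixed]
        cols = ([np.ones(self.n)] if intercept else []) + Xbase
        names = (["(Intercept)"] if intercept else []) + list(fixed)
        if not cols:
            cols, names = [np.zeros(self.n)], []
        self.X = np.column_stack(cols) if names else np.zeros((self.n, 0))
        self.p = self.X.shape[1]
        self.n_beta = self.p * self.r
        self.beta_names = [
            f"{resp.name}:{nm}" for resp in responses for nm in names
        ]

        # random terms: level maps and covariance inverses
        self.q: dict[str, int] = {}
        self.level_index: dict[str, np.ndarray] = {}
        self.Cinv: dict[str, np.ndarray] = {}
        self.C: dict[str, np.ndarray] = {}
        self.Clabels: dict[str, list[str]] = {}
        self.term_resp: dict[str, list[str]] = {}
        self.term_resp_idx: dict[str, np.ndarray] = {}
        rnames = [r.name for r in responses]
        for t in self.random_terms:
            levels = self.data[t.levels].astype(str).to_numpy()
            if t.covariance is None:
                labs = sorted(set(levels))
                C = np.eye(len(labs))
            else:
                labs, C = _scale_cov(t.covariance)
                missing = sorted(set(levels) - set(labs))
                if missing:
                    raise KeyError(
                        f"term {t.name!r}: levels missing from covariance: "
                        f"{missing[:5]}"
                    )
            pos = {lab: i for i, lab in enumerate(labs)}
            self.level_index[t.name] = np.array([pos[l] for l in levels])
            self.q[t.name] = len(labs)
            self.C[t.name] = C
            self.Cinv[t.name] = np.linalg.inv(C)
            self.Clabels[t.name] = labs
            tr = t.responses if t.responses is not None else rnames
            self.term_resp[t.name] = list(tr)
            self.term_resp_idx[t.name] = np.array([rnames.index(x) for x in tr])

    # -- sampler -------------------------------------------------------

    def fit(self, settings: ChainSettings | None = None) -> list[PosteriorChain]:
        settings = settings or ChainSettings()
        return [
            self._run_chain(settings, seed=[settings.seed, c])
            for c in range(settings.n_chains)
        ]

    def _run_chain(self, settings: ChainSettings, seed) -> PosteriorChain:
        rng = np.random.Generator(np.random.PCG64(seed))
        n, r, p = self.n, self.r, self.p
        pri = self.priors

        # state; beta starts at the least-squares fit of the initial
        # latents so the random effects do not absorb obvious fixed-effect
        # structure during a short burn-in
        beta = np.zeros((p, r))
        latent0 = self._init_latent()
        if p > 0:
            for j in range(r):
                obs = self.observed[:, j]
                if obs.sum() >= p:
                    beta[:, j] = np.linalg.lstsq(
                        self.X[obs], latent0[obs, j], rcond=None)[0]
        u = {t.name: np.zeros((self.q[t.name], len(self.term_resp[t.name])))
             for t in self.random_terms}
        V = {t.name: np.eye(len(self.term_resp[t.name]))
             for t in self.random_terms}
        Ve = np.eye(r)
        latent = latent0
        steps = np.full(r, 0.8)
        acc = np.zeros(r)
        tot = np.zeros(r)

        chain = PosteriorChain(self, settings, seed if np.isscalar(seed) else seed[-1])
        keep = 0
        for it in range(settings.n_iter):
            pred_random = self._sum_random(u)
            # 1. latent updates (non-Gaussian MH, Gaussian imputation)
            mean = self.X @ beta + pred_random
            latent = self._update_latents(latent, mean, Ve, steps, acc, tot, rng)
            if it < settings.burnin and it % 50 == 49:
                with np.errstate(invalid="ignore"):
                    rate = np.where(tot > 0, acc / np.maximum(tot, 1), 0.4)
                steps *= np.exp(0.6 * (rate - 0.4))
                np.clip(steps, 0.05, 10.0, out=steps)
                acc[:] = 0
                tot[:] = 0

            # 2+3. location effects.  The fixed effects and the first
            # random term are drawn jointly: separate Gibbs blocks mix
            # very slowly when a high-variance phylogenetic field can
            # trade off against the fixed effects (e.g. a clade-aligned
            # factor), and the joint conditional is Gaussian at the same
            # Cholesky cost.  Remaining terms update block-wise.
            if self.random_terms and self.residual == "diagonal" and self.p > 0:
                t0 = self.random_terms[0]
                others = self._sum_random(u, skip=t0.name)
                beta, u[t0.name] = self._draw_beta_u_joint(
                    t0, latent - others, V[t0.name], Ve, rng)
                for t in self.random_terms[1:]:
                    others = self._sum_random(u, skip=t.name)
                    resid = latent - self.X @ beta - others
                    u[t.name] = self._draw_u(t, resid, V[t.name], Ve, rng)
            else:
                beta = self._draw_beta(latent - pred_random, Ve, rng)
                for t in self.random_terms:
                    others = self._sum_random(u, skip=t.name)
                    resid = latent - self.X @ beta - others
                    u[t.name] = self._draw_u(t, resid, V[t.name], Ve, rng)

            # 4. variance components
            for t in self.random_terms:
                V[t.name] = self._draw_V(t, u[t.name], rng)
            resid = latent - self.X @ beta - self._sum_random(u)
            Ve = self._draw_Ve(resid, rng)

            if it >= settings.burnin and (it - settings.burnin) % settings.thin == 0:
                if keep < chain.beta.shape[0]:
                    chain.beta[keep] = beta.T.ravel()  # response-major
                    for t in self.random_terms:
                        chain.vcomp[t.name][keep] = V[t.name]
                        chain.u[t.name][keep] = u[t.name]
                    chain.ve[keep] = Ve
                    keep += 1
        chain._i = keep
        with np.errstate(invalid="ignore"):
            chain.latent_acceptance = {
                resp.name: float(a / t) if t > 0 else float("nan")
                for resp, a, t in zip(self.responses, acc, np.maximum(tot, 1))
            }
        return chain

    # -- pieces --------------------------------------------------------

    def _init_latent(self) -> np.ndarray:
        lat = np.zeros((self.n, self.r))
        for j, resp in enumerate(self.responses):
            obs = self.observed[:, j]
            if resp.family == "gaussian":
                lat[obs, j] = self.y[obs, j]
            elif resp.family == "binomial":
                k = self.y[obs, j]
                nn = self.trials[obs, j]
                prop = (k + 0.5) / (nn + 1.0)
                lat[obs, j] = np.log(prop / (1 - prop))
            else:
                lat[obs, j] = np.log(self.y[obs, j] + 0.5)
        return lat

    def _sum_random(self, u: dict, skip: str | None = None) -> np.ndarray:
        out = np.zeros((self.n, self.r))
        for t in self.random_terms:
            if t.name == skip:
                continue
            idx = self.level_index[t.name]
            cols = self.term_resp_idx[t.name]
            out[:, cols] += u[t.name][idx, :]
        return out

    def _data_loglik(self, lat_col: np.ndarray, j: int) -> np.ndarray:
        """Observation-wise data log-likelihood for one response column."""
        resp = self.responses[j]
        obs = self.observed[:, j]
        out = np.zeros(self.n)
        if resp.family == "binomial":
            k = self.y[obs, j]
            nn = self.trials[obs, j]
            x = lat_col[obs]
            out[obs] = k * x - nn * np.logaddexp(0.0, x)
        elif resp.family == "poisson":
            x = lat_col[obs]
            out[obs] = self.y[obs, j] * x - np.exp(x)
        return out

    def _update_latents(self, latent, mean, Ve, steps, acc, tot, rng):
        lat = latent.copy()
        ve = Ve.diagonal()
        for j, resp in enumerate(self.responses):
            obs = self.observed[:, j]
            if resp.family == "gaussian":
                miss = ~obs
                if miss.any():
                    lat[miss, j] = self._impute_gaussian(lat, mean, Ve, j, miss, rng)
                lat[obs, j] = self.y[obs, j]
                continue
            # observed non-Gaussian: random-walk MH on the latent scale
            cur = lat[:, j]
            prop = cur + rng.normal(0.0, steps[j], size=self.n)
            dl = self._data_loglik(prop, j) - self._data_loglik(cur, j)
            dprior = (-(prop - mean[:, j]) ** 2 + (cur - mean[:, j]) ** 2) / (2 * ve[j])
            accept = np.log(rng.random(self.n)) < dl + dprior
            accept &= obs
            lat[accept, j] = prop[accept]
            acc[j] += accept.sum()
            tot[j] += obs.sum()
            # missing non-Gaussian latents: draw from the prior predictive
            miss = ~obs
            if miss.any():
                lat[miss, j] = mean[miss, j] + rng.normal(0, np.sqrt(ve[j]), miss.sum())
        return lat

    def _impute_gaussian(self, lat, mean, Ve, j, miss, rng):
        if self.residual == "diagonal" or self.r == 1:
            return mean[miss, j] + rng.normal(0, np.sqrt(Ve[j, j]), miss.sum())
        # conditional on the other (latent-complete) responses of the unit
        out = np.empty(miss.sum())
        others = [k for k in range(self.r) if k != j]
        S12 = Ve[j, others]
        S22i = np.linalg.inv(Ve[np.ix_(others, others)])
        w = S12 @ S22i
        cvar = Ve[j, j] - w @ S12
        rows = np.flatnonzero(miss)
        dev = lat[rows][:, others] - mean[rows][:, others]
        out = mean[rows, j] + dev @ w + rng.normal(0, np.sqrt(max(cvar, 1e-12)), len(rows))
        return out

    def _draw_beta(self, target, Ve, rng):
        p, r = self.p, self.r
        if p == 0:
            return np.zeros((0, r))
        prior_prec = np.zeros((r, p))
        for j, resp in enumerate(self.responses):
            v = (self.priors.binomial_fixed_v
                 if resp.family == "binomial" else self.priors.fixed_v)
            prior_prec[j, :] = 1.0 / v
        if self.residual == "diagonal":
            beta = np.empty((p, r))
            ve = Ve.diagonal()
            XtX = self.X.T @ self.X
            for j in range(r):
                A = XtX / ve[j] + np.diag(prior_prec[j])
                b = self.X.T @ target[:, j] / ve[j]
                beta[:, j] = _mvn_from_precision(A, b, rng)
            return beta
        Vei = np.linalg.inv(Ve)
        XtX = self.X.T @ self.X
        A = _kron(Vei, XtX)
        A[np.arange(r * p), np.arange(r * p)] += prior_prec.ravel()
        b = (self.X.T @ target @ Vei).T.ravel()  # (j major, p minor)
        flat = _mvn_from_precision(A, b, rng)
        return flat.reshape(r, p).T

    def _draw_beta_u_joint(self, t: RandomTerm, target, Vt, Ve, rng):
        """Joint Gaussian draw of (beta, u_t) with diagonal residual.

        ``target`` is the latent matrix minus every other random term.
        Parameter order: beta response-major (j, p), then u level-major
        (level, term-response).
        """
        p, r = self.p, self.r
        q = self.q[t.name]
        cols = self.term_resp_idx[t.name]
        rt = len(cols)
        idx = self.level_index[t.name]
        ve = Ve.diagonal()
        nb, nu = p * r, q * rt
        A = np.zeros((nb + nu, nb + nu))
        b = np.zeros(nb + nu)

        XtX = self.X.T @ self.X
        S = np.zeros((q, p))          # M' X: level-wise sums of design rows
        np.add.at(S, idx, self.X)
        counts = np.bincount(idx, minlength=q).astype(float)

        for j, resp in enumerate(self.responses):
            pv = (self.priors.binomial_fixed_v
                  if resp.family == "binomial" else self.priors.fixed_v)
            blk = slice(j * p, (j + 1) * p)
            A[blk, blk] = XtX / ve[j] + np.eye(p) / pv
            b[j * p:(j + 1) * p] = self.X.T @ target[:, j] / ve[j]

        Vti = np.linalg.inv(Vt)
        A[nb:, nb:] = _kron(self.Cinv[t.name], Vti)
        for a, j in enumerate(cols):
            ii = nb + a + rt * np.arange(q)
            A[ii, ii] += counts / ve[j]
            blk = slice(j * p, (j + 1) * p)
            cross = S.T / ve[j]       # (p, q)
            A[blk, nb + a::rt] = cross
            A[nb + a::rt, blk] = cross.T
            bu = np.zeros(q)
            np.add.at(bu, idx, target[:, j] / ve[j])
            b[nb + a::rt] += bu

        flat = _mvn_from_precision(A, b, rng)
        beta = flat[:nb].reshape(r, p).T
        u = flat[nb:].reshape(q, rt)
        return beta, u

    def _draw_u(self, t: RandomTerm, resid, Vt, Ve, rng):
        q = self.q[t.name]
        cols = self.term_resp_idx[t.name]
        rt = len(cols)
        idx = self.level_index[t.name]
        Vti = np.linalg.inv(Vt)
        prior = _kron(self.Cinv[t.name], Vti)  # vec row-major (level, resp)
        b = np.zeros((q, rt))
        if self.residual == "diagonal":
            ve = Ve.diagonal()[cols]
            D = np.zeros((q, rt))
            for a, j in enumerate(cols):
                np.add.at(b[:, a], idx, resid[:, j] / ve[a])
                np.add.at(D[:, a], idx, 1.0 / ve[a])
            A = prior
            A[np.arange(q * rt), np.arange(q * rt)] += D.ravel()
        else:
            Vei = np.linalg.inv(Ve[np.ix_(cols, cols)])
            counts = np.bincount(idx, minlength=q).astype(float)
            A = prior + _kron(np.diag(counts), Vei)
            for a in range(rt):
                contrib = resid[:, cols] @ Vei[:, a]
                np.add.at(b[:, a], idx, contrib)
        flat = _mvn_from_precision(A, b.ravel(), rng)
        return flat.reshape(q, rt)

    def _draw_V(self, t: RandomTerm, ut, rng):
        # prior IW(nu0 * V, nu0) with nu0 = (r_t - 1) + variance_nu, the
        # weak default used for phylogenetic variance components
        q = self.q[t.name]
        rt = ut.shape[1]
        S = ut.T @ self.Cinv[t.name] @ ut
        if t.structure == "idh" or rt == 1:
            nu0 = self.priors.variance_nu
            s0 = nu0 * self.priors.variance_v
            out = np.zeros((rt, rt))
            for a in range(rt):
                out[a, a] = _invgamma_rvs((nu0 + q) / 2.0,
                                          (s0 + S[a, a]) / 2.0, rng)
            return out
        nu0 = (rt - 1) + self.priors.variance_nu
        df = nu0 + q
        scale = nu0 * self.priors.variance_v * np.eye(rt) + S
        return _invwishart_rvs(df, scale, rng)

    def _draw_Ve(self, resid, rng):
        n, r = self.n, self.r
        if self.residual == "diagonal":
            nu0 = self.priors.variance_nu
            s0 = nu0 * self.priors.variance_v
            Ve = np.zeros((r, r))
            for j, resp in enumerate(self.responses):
                if resp.family == "binomial":
                    Ve[j, j] = 1.0  # not identifiable; fixed on latent scale
                    continue
                ss = float(resid[:, j] @ resid[:, j])
                Ve[j, j] = _invgamma_rvs((nu0 + n) / 2.0, (s0 + ss) / 2.0, rng)
            return Ve
        nu0 = (r - 1) + self.priors.variance_nu
        df = nu0 + n
        scale = nu0 * self.priors.variance_v * np.eye(r) + resid.T @ resid
        return _invwishart_rvs(df, scale, rng)


def _kron(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Kronecker product via broadcasting (faster than np.kron here)."""
    qa, qb = A.shape[0], B.shape[0]
    return (A[:, None, :, None] * B[None, :, None, :]).reshape(qa * qb, qa * qb)


def _mvn_from_precision(A, b, rng) -> np.ndarray:
    """Draw from N(A^-1 b, A^-1) reusing one Cholesky of the precision."""
    from scipy.linalg import solve_triangular

    try:
        L = np.linalg.cholesky(A)
    except np.linalg.LinAlgError:
        A = A + 1e-8 * np.trace(A) / len(A) * np.eye(len(A))
        L = np.linalg.cholesky(A)
    w = solve_triangular(L, b, lower=True, check_finite=False)
    z = rng.standard_normal(len(b))
    # mean + L^-T z in a single triangular solve
    return solve_triangular(L.T, w + z, lower=False, check_finite=False)


def _invgamma_rvs(a: float, scale: float, rng) -> float:
    return scale / rng.gamma(a)


def _invwishart_rvs(df: float, S: np.ndarray, rng) -> np.ndarray:
    """Inverse-Wishart draw via Bartlett decomposition (small matrices)."""
    r = S.shape[0]
    if r == 1:
        return np.array([[_invgamma_rvs(df / 2.0, S[0, 0] / 2.0, rng)]])
    Linv = np.linalg.cholesky(np.linalg.inv(S))
    A = np.zeros((r, r))
    for i in range(r):
        A[i, i] = np.sqrt(rng.chisquare(df - i))
        for j in range(i):
            A[i, j] = rng.standard_normal()
    W = Linv @ A
    W = W @ W.T  # Wishart(df, S^-1)
    return np.linalg.inv(W)


# ---------------------------------------------------------------------------
# post-processing


def variance_partition(
    chains: list[PosteriorChain] | PosteriorChain,
    term: str,
    response: str,
) -> tuple[np.ndarray, ParamSummary]:
    """Per-draw intraclass correlation V_term / (sum V_RE + V_e + link var).

    For logit-link (binomial) responses the link variance pi^2/3 enters
    the denominator; for Gaussian and Poisson responses it is zero.
    """
    if isinstance(chains, PosteriorChain):
        chains = [chains]
    model = chains[0].model
    rnames = [r.name for r in model.responses]
    j = rnames.index(response)
    fam = model.responses[j].family
    link = LOGIT_LINK_VAR if fam == "binomial" else 0.0

    def icc_of(chain: PosteriorChain) -> np.ndarray:
        denom = chain.ve[:, j, j] + link
        num = None
        for t in model.random_terms:
            resp = model.term_resp[t.name]
            if response in resp:
                a = resp.index(response)
                v = chain.vcomp[t.name][:, a, a]
                denom = denom + v
                if t.name == term:
                    num = v
        if num is None:
            raise KeyError(f"term {term!r} does not cover response {response!r}")
        return num / denom

    draws = np.concatenate([icc_of(c) for c in chains])
    return draws, summarize_draws(draws, f"ICC[{term}:{response}]")


def heritability(chains, term: str, response: str):
    """Phylogenetic heritability = ICC of the phylogenetic term."""
    return variance_partition(chains, term, response)


def phylo_correlation(
    chains: list[PosteriorChain] | PosteriorChain,
    term: str,
    response_a: str,
    response_b: str,
) -> tuple[np.ndarray, ParamSummary]:
    """Per-draw correlation cov_ab / sqrt(v_a v_b) for one random term."""
    if isinstance(chains, PosteriorChain):
        chains = [chains]
    model = chains[0].model
    tt = next(t for t in model.random_terms if t.name == term)
    if tt.structure != "unstructured":
        raise ValueError(
            f"term {term!r} was fitted as {tt.structure!r}; correlations need "
            "an unstructured covariance"
        )
    resp = model.term_resp[term]
    a, b = resp.index(response_a), resp.index(response_b)

    def r_of(chain):
        V = chain.vcomp[term]
        return V[:, a, b] / np.sqrt(V[:, a, a] * V[:, b, b])

    draws = np.concatenate([r_of(c) for c in chains])
    return draws, summarize_draws(draws, f"r[{term}:{response_a},{response_b}]")


def residual_correlation(chains, response_a: str, response_b: str):
    if isinstance(chains, PosteriorChain):
        chains = [chains]
    model = chains[0].model
    rnames = [r.name for r in model.responses]
    a, b = rnames.index(response_a), rnames.index(response_b)
    draws = np.concatenate(
        [c.ve[:, a, b] / np.sqrt(c.ve[:, a, a] * c.ve[:, b, b]) for c in chains]
    )
    return draws, summarize_draws(draws, f"r[residual:{response_a},{response_b}]")


def predict_nodes(
    chains: list[PosteriorChain] | PosteriorChain,
    tree: Phylogeny,
    term: str,
    response: str,
    mode: str = "marginal",
    seed: int = 0,
) -> pd.DataFrame:
    """Posterior predictions for internal nodes of the phylogeny.

    For each retained draw the internal-node random effects are drawn
    from their conditional multivariate normal given the tip-level
    effects (standard kriging under the Brownian covariance), added to
    the fixed-effect intercept and inverse-linked.  ``mode='plugin'``
    skips the conditional noise and uses the conditional mean (cheap
    smoke-test variant).  Returns a frame with per-node posterior mean
    probability/expectation and a >0.5 classification for binomial
    responses.
    """
    if isinstance(chains, PosteriorChain):
        chains = [chains]
    model = chains[0].model
    tt = next(t for t in model.random_terms if t.name == term)
    labs = model.Clabels[term]
    resp_idx = model.term_resp[term].index(response)
    j = [r.name for r in model.responses].index(response)
    fam = model.responses[j].family

    full = tree.covariance(include_internal=True)
    s = float(full.matrix.diagonal().max())
    Cf = full.matrix / s
    pos = {lab: i for i, lab in enumerate(full.labels)}
    missing = [l for l in labs if l not in pos]
    if missing:
        raise KeyError(f"fitted levels not on tree: {missing[:5]}")
    tip_idx = np.array([pos[l] for l in labs])
    node_labels = [l for l in full.labels if l not in set(labs)]
    node_idx = np.array([pos[l] for l in node_labels])
    Ctt = Cf[np.ix_(tip_idx, tip_idx)] + 1e-8 * np.eye(len(tip_idx))
    Cnt = Cf[np.ix_(node_idx, tip_idx)]
    Cnn = Cf[np.ix_(node_idx, node_idx)]
    K = Cnt @ np.linalg.inv(Ctt)
    Sigma = Cnn - K @ Cnt.T
    Sigma = (Sigma + Sigma.T) / 2
    w, Vv = np.linalg.eigh(Sigma)
    w = np.clip(w, 0, None)
    Lr = Vv * np.sqrt(w)

    rng = np.random.Generator(np.random.PCG64(seed))
    icol = None
    iname = f"{response}:(Intercept)"
    if iname in model.beta_names:
        icol = model.beta_names.index(iname)

    preds = []
    for chain in chains:
        n_draws = chain.u[term].shape[0]
        for d in range(n_draws):
            ut = chain.u[term][d, :, resp_idx]
            mu = K @ ut
            if mode == "marginal":
                v = chain.vcomp[term][d, resp_idx, resp_idx]
                mu = mu + np.sqrt(v) * (Lr @ rng.standard_normal(len(node_idx)))
            eta = mu + (chain.beta[d, icol] if icol is not None else 0.0)
            preds.append(eta)
    eta = np.array(preds)  # (draws, nodes)
    if fam == "binomial":
        pp = 1.0 / (1.0 + np.exp(-eta))
        out = pd.DataFrame({
            "node": node_labels,
            "posterior_prob": pp.mean(axis=0),
            "eta_mean": eta.mean(axis=0),
        })
        out["state"] = np.where(out["posterior_prob"] > 0.5, 1, 0)
        out.attrs["draws"] = pp
    elif fam == "poisson":
        out = pd.DataFrame({"node": node_labels,
                            "expectation": np.exp(eta).mean(axis=0),
                            "eta_mean": eta.mean(axis=0)})
        out.attrs["draws"] = np.exp(eta)
    else:
        out = pd.DataFrame({"node": node_labels, "expectation": eta.mean(axis=0),
                            "eta_mean": eta.mean(axis=0)})
        out.attrs["draws"] = eta
    return out


def gelman_rubin(chains: list[PosteriorChain]) -> pd.DataFrame:
    """PSRF and ESS per fixed effect and variance component (via arviz).

    The convergence flag requires every PSRF <= 1.1; with a single chain
    PSRF is reported as NaN and only ESS is computed.
    """
    import arviz as az

    model = chains[0].model
    series: dict[str, np.ndarray] = {}
    for i, nm in enumerate(model.beta_names):
        series[nm] = np.stack([c.beta[:, i] for c in chains])
    for t in model.random_terms:
        resp = model.term_resp[t.name]
        for a, ra in enumerate(resp):
            series[f"V[{t.name}:{ra}]"] = np.stack(
                [c.vcomp[t.name][:, a, a] for c in chains]
            )
    rows = []
    multi = len(chains) >= 2
    for nm, arr in series.items():
        da = arr  # (chain, draw)
        psrf = float(az.rhat(az.convert_to_dataset(da[None] if da.ndim == 1 else da))["x"].values) if multi else float("nan")
        ess = float(az.ess(az.convert_to_dataset(da[None] if da.ndim == 1 else da))["x"].values)
        rows.append({"parameter": nm, "psrf": psrf, "ess": ess})
    out = pd.DataFrame(rows)
    out.attrs["converged"] = bool((out["psrf"].dropna() <= 1.1).all()) if multi else None
    return out
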