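"""Discrete-trait continuous-time Markov chain (Mk) engine.

Provides the machinery for ancestral-state work on a phylogeny:

- pruning-algorithm log-likelihood of tip states under a rate matrix Q,
- Metropolis-Hastings posterior sampling of Q under equal-rates (ER) or
  all-rates-different (ARD) constraints,
- analytic marginal ancestral-state posteriors,
- stochastic character mapping: joint node-state sampling plus exact
  conditional branch histories via uniformization,
- node-state summaries over a set of maps and origin/loss counting.

States are referred to by integer index internally; :class:`RateMatrix`
carries the human-readable labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from symphy.phylo import Phylogeny

__all__ = [
    "RateMatrix",
    "CharacterMap",
    "PruningEngine",
    "mk_loglik",
    "node_marginals",
    "sample_q_posterior",
    "stochastic_maps",
    "summarize_node_states",
    "count_state_transitions",
]


@dataclass
class RateMatrix:
    """CTMC generator with state labels.

    Off-diagonal entries are non-negative transition rates; each row sums
    to zero.  ``constraint`` records how the matrix was parameterized.
    """

    states: list[str]
    Q: np.ndarray
    constraint: str = "all_rates_different"

    def __post_init__(self):
        self.Q = np.asarray(self.Q, dtype=float)
        k = len(self.states)
        if self.Q.shape != (k, k):
            raise ValueError("Q shape does not match state labels")
        off = self.Q[~np.eye(k, dtype=bool)]
        if np.any(off < -1e-12):
            raise ValueError("negative off-diagonal rate")
        if np.max(np.abs(self.Q.sum(axis=1))) > 1e-9 * max(1.0, np.abs(self.Q).max()):
            raise ValueError("rows of Q must sum to zero")

    @property
    def k(self) -> int:
        return len(self.states)

    @classmethod
    def from_rates(
        cls, states: list[str], rates: np.ndarray, constraint: str = "all_rates_different"
    ) -> "RateMatrix":
        """Build Q from off-diagonal rates filled row-major (ER: one rate)."""
        k = len(states)
        Q = np.zeros((k, k))
        rates = np.atleast_1d(np.asarray(rates, dtype=float))
        if constraint == "equal_rates":
            Q[~np.eye(k, dtype=bool)] = rates[0]
        else:
            Q[~np.eye(k, dtype=bool)] = rates
        np.fill_diagonal(Q, -Q.sum(axis=1))
        return cls(states, Q, constraint)

    def stationary(self) -> np.ndarray:
        """Stationary distribution (left null vector of Q)."""
        w, v = np.linalg.eig(self.Q.T)
        i = int(np.argmin(np.abs(w)))
        pi = np.real(v[:, i])
        pi = np.abs(pi)
        return pi / pi.sum()


@dataclass
class CharacterMap:
    """One stochastic character map: sampled node states plus, per node,
    the piecewise-constant history on the branch above it.

    ``segments[i]`` lists ``(state, dwell_time)`` pairs running from the
    parent of node ``i`` towards ``i``; dwell times sum to the branch
    length and the last segment's state equals ``node_states[i]``.
    """

    node_states: np.ndarray
    segments: list[list[tuple[int, float]]]

    def n_changes(self, i: int) -> int:
        return max(len(self.segments[i]) - 1, 0)

    def total_changes(self) -> int:
        return sum(self.n_changes(i) for i in range(len(self.segments)))

    def dwell_times(self, k: int) -> np.ndarray:
        out = np.zeros(k)
        for segs in self.segments:
            for s, t in segs:
                out[s] += t
        return out


# ---------------------------------------------------------------------------
# pruning core


@njit(cache=True)
def _prune_ll(post, child_flat, child_ptr, P, tipL, n_tips, prior):
    n_nodes = child_ptr.shape[0] - 1
    k = tipL.shape[1]
    L = np.zeros((n_nodes, k))
    L[:n_tips] = tipL
    logscale = 0.0
    for idx in range(post.shape[0]):
        a = post[idx]
        v = np.ones(k)
        for ci in range(child_ptr[a], child_ptr[a + 1]):
            c = child_flat[ci]
            w = np.zeros(k)
            for i in range(k):
                acc = 0.0
                for j in range(k):
                    acc += P[c, i, j] * L[c, j]
                w[i] = acc
            v = v * w
        s = v.sum()
        if s <= 0.0:
            return -np.inf, L, logscale
        L[a] = v / s
        logscale += np.log(s)
    root = post[post.shape[0] - 1]
    tot = 0.0
    for i in range(k):
        tot += prior[i] * L[root, i]
    if tot <= 0.0:
        return -np.inf, L, logscale
    return np.log(tot) + logscale, L, logscale


class PruningEngine:
    """Preprocessed tree + tip data for repeated likelihood evaluation.

    Building the engine once and calling :meth:`loglik` with many Q
    matrices is what the MCMC samplers do; transition matrices along all
    edges are obtained from a single eigendecomposition of Q.
    """

    def __init__(self, tree: Phylogeny, tip_states: dict[str, int | None], k: int):
        self.tree = tree
        self.k = int(k)
        self.post = tree.postorder()
        internal_mask = self.post >= tree.n_tips
        self.post_internal = self.post[internal_mask].astype(np.int64)
        children = tree.children_lists()
        flat, ptr = [], [0]
        for i in range(tree.n_nodes):
            flat.extend(children[i])
            ptr.append(len(flat))
        self.child_flat = np.array(flat, dtype=np.int64)
        self.child_ptr = np.array(ptr, dtype=np.int64)
        self.lengths = tree.length.copy()
        tipL = np.zeros((tree.n_tips, k))
        for lab, st in tip_states.items():
            i = tree.tip_labels.index(lab)
            if st is None:
                tipL[i, :] = 1.0
            else:
                if not (0 <= int(st) < k):
                    raise ValueError(f"state {st} out of range for {k} states")
                tipL[i, int(st)] = 1.0
        unset = np.flatnonzero(tipL.sum(axis=1) == 0)
        if len(unset):
            missing = [tree.tip_labels[i] for i in unset]
            raise ValueError(f"tips without states: {missing[:5]}...")
        self.tipL = tipL

    # -- transition matrices ------------------------------------------

    def transition_stack(self, Q: np.ndarray) -> np.ndarray:
        """P[e] = expm(Q * length[e]) for every node's stem branch."""
        lam, U = np.linalg.eig(Q)
        try:
            Uinv = np.linalg.inv(U)
        except np.linalg.LinAlgError:
            return self._expm_stack(Q)
        E = np.exp(np.outer(self.lengths, lam))  # (n_nodes, k)
        P = np.real((U[None, :, :] * E[:, None, :]) @ Uinv)
        if not np.all(np.isfinite(P)):
            return self._expm_stack(Q)
        np.clip(P, 0.0, None, out=P)
        # renormalize rows (eigendecomposition roundoff)
        P /= P.sum(axis=2, keepdims=True)
        return np.ascontiguousarray(P)

    def _expm_stack(self, Q: np.ndarray) -> np.ndarray:
        from scipy.linalg import expm

        P = np.empty((len(self.lengths), self.k, self.k))
        for e, t in enumerate(self.lengths):
            P[e] = expm(Q * t)
        np.clip(P, 0.0, None, out=P)
        P /= P.sum(axis=2, keepdims=True)
        return P

    def root_prior(self, Q: np.ndarray, kind: str = "uniform") -> np.ndarray:
        if isinstance(kind, np.ndarray):
            return kind
        if kind == "uniform":
            return np.full(self.k, 1.0 / self.k)
        if kind == "stationary":
            return RateMatrix([str(i) for i in range(self.k)], Q).stationary()
        raise ValueError(f"unknown root prior {kind!r}")

    # -- likelihood ----------------------------------------------------

    def loglik(self, Q: np.ndarray, root_prior="uniform") -> float:
        prior = self.root_prior(Q, root_prior)
        P = self.transition_stack(Q)
        ll, _, _ = _prune_ll(
            self.post_internal, self.child_flat, self.child_ptr, P,
            self.tipL, self.tree.n_tips, prior,
        )
        return float(ll)

    def _partials(self, Q: np.ndarray, root_prior="uniform"):
        prior = self.root_prior(Q, root_prior)
        P = self.transition_stack(Q)
        ll, L, _ = _prune_ll(
            self.post_internal, self.child_flat, self.child_ptr, P,
            self.tipL, self.tree.n_tips, prior,
        )
        return float(ll), L, P, prior

    # -- marginal ancestral posteriors ---------------------------------

    def node_marginals(self, Q: np.ndarray, root_prior="uniform") -> np.ndarray:
        """Exact marginal posterior state probabilities for every node."""
        ll, L, P, prior = self._partials(Q, root_prior)
        if not np.isfinite(ll):
            raise ValueError("zero likelihood; marginals undefined")
        tree = self.tree
        children = tree.children_lists()
        D = np.zeros((tree.n_nodes, self.k))  # outside partials
        D[tree.root] = prior
        # preorder
        for a in self.post[::-1]:
            kids = children[a]
            if not kids:
                continue
            # contribution of each child's siblings seen from a
            up = [P[c] @ L[c] for c in kids]
            for ci, c in enumerate(kids):
                sib = D[a].copy()
                for cj, w in enumerate(up):
                    if cj != ci:
                        sib *= w
                D[c] = sib @ P[c]
        M = D * L
        M /= M.sum(axis=1, keepdims=True)
        return M

    # -- joint node-state sampling + branch histories -------------------

    def sample_node_states(self, Q: np.ndarray, rng: np.random.Generator,
                           root_prior="uniform") -> np.ndarray:
        ll, L, P, prior = self._partials(Q, root_prior)
        if not np.isfinite(ll):
            raise ValueError("zero likelihood; cannot sample")
        tree = self.tree
        children = tree.children_lists()
        states = np.full(tree.n_nodes, -1, dtype=np.int64)
        w = prior * L[tree.root]
        states[tree.root] = rng.choice(self.k, p=w / w.sum())
        for a in self.post[::-1]:
            for c in children[a]:
                w = P[c][states[a]] * L[c]
                states[c] = rng.choice(self.k, p=w / w.sum())
        return states

    def sample_map(self, Q: np.ndarray, rng: np.random.Generator,
                   root_prior="uniform") -> CharacterMap:
        states = self.sample_node_states(Q, rng, root_prior)
        P = self.transition_stack(Q)
        tree = self.tree
        segments: list[list[tuple[int, float]]] = [[] for _ in range(tree.n_nodes)]
        for i in range(tree.n_nodes):
            p = tree.parent[i]
            if p < 0:
                continue
            segments[i] = _bridge_uniformization(
                Q, P[i], int(states[p]), int(states[i]), float(tree.length[i]), rng
            )
        return CharacterMap(states, segments)


def _bridge_uniformization(
    Q: np.ndarray, Pt: np.ndarray, a: int, b: int, t: float,
    rng: np.random.Generator,
) -> list[tuple[int, float]]:
    """Exact CTMC bridge from state ``a`` to ``b`` over time ``t``.

    Uniformization: the chain is embedded in a Poisson process of rate
    mu = max_i(-Q_ii) with one-step matrix R = I + Q/mu; the number of
    (possibly virtual) events is drawn from its conditional distribution
    given the endpoints, event times are order statistics of uniforms and
    event states are sampled backward-forward through powers of R.
    """
    k = Q.shape[0]
    mu = float(np.max(-np.diag(Q)))
    if mu <= 0.0 or t <= 0.0:
        if a != b:
            raise ValueError("impossible endpoint pair under zero rates")
        return [(a, t)]
    R = np.eye(k) + Q / mu
    pab = Pt[a, b]
    # conditional number of events: P(n) ∝ pois(mu t; n) * (R^n)[a, b]
    log_pois = -mu * t
    Rn = np.eye(k)
    powers = [Rn]
    u = rng.random() * pab
    acc = 0.0
    n = 0
    term = np.exp(log_pois)
    max_n = int(20 + 10 * mu * t + 6 * np.sqrt(max(mu * t, 1.0)))
    while True:
        acc += term * powers[n][a, b]
        if acc >= u or n >= max_n:
            break
        n += 1
        term *= mu * t / n
        powers.append(powers[-1] @ R)
    if n == 0:
        return [(a, t)]
    # event states: s_0 = a, s_n = b
    seq = [a]
    for i in range(1, n):
        w = R[seq[-1], :] * powers[n - i][:, b]
        seq.append(int(rng.choice(k, p=w / w.sum())))
    seq.append(b)
    times = np.sort(rng.random(n)) * t
    # collapse virtual (self) jumps into dwell segments
    segs: list[tuple[int, float]] = []
    cur_state = a
    cur_start = 0.0
    for i in range(1, n + 1):
        if seq[i] != cur_state:
            segs.append((cur_state, times[i - 1] - cur_start))
            cur_start = times[i - 1]
            cur_state = seq[i]
    segs.append((cur_state, t - cur_start))
    return segs


# ---------------------------------------------------------------------------
# public functional API


def mk_loglik(
    tree: Phylogeny,
    tip_states: dict[str, int | None],
    rate_matrix: RateMatrix,
    root_prior="uniform",
) -> float:
    """Pruning-algorithm log-likelihood of discrete tip states under Q."""
    eng = PruningEngine(tree, tip_states, rate_matrix.k)
    return eng.loglik(rate_matrix.Q, root_prior)


def node_marginals(
    tree: Phylogeny,
    tip_states: dict[str, int | None],
    rate_matrix: RateMatrix,
    root_prior="uniform",
) -> np.ndarray:
    """Analytic marginal posterior state probabilities, rows = nodes."""
    eng = PruningEngine(tree, tip_states, rate_matrix.k)
    return eng.node_marginals(rate_matrix.Q, root_prior)


def parsimony_changes(tree: Phylogeny, tip_states: dict[str, int | None], k: int) -> int:
    """Fitch parsimony count of state changes (used to centre rate priors)."""
    sets = {}
    for lab in tree.tip_labels:
        st = tip_states.get(lab)
        i = tree.tip_labels.index(lab)
        sets[i] = set(range(k)) if st is None else {int(st)}
    children = tree.children_lists()
    changes = 0
    for a in tree.postorder():
        kids = children[a]
        if not kids:
            continue
        inter = set.intersection(*(sets[c] for c in kids))
        if inter:
            sets[a] = inter
        else:
            sets[a] = set.union(*(sets[c] for c in kids))
            changes += len(kids) - 1 if len(kids) > 2 else 1
    return changes


@dataclass
class QPosterior:
    """Thinned MCMC draws of off-diagonal rates for an Mk model."""

    states: list[str]
    constraint: str
    draws: np.ndarray  # (n_draws, n_free)
    logliks: np.ndarray
    acceptance: float
    seed: int

    def rate_matrices(self) -> list[RateMatrix]:
        return [
            RateMatrix.from_rates(self.states, r, self.constraint)
            for r in self.draws
        ]

    def median_matrix(self) -> RateMatrix:
        return RateMatrix.from_rates(
            self.states, np.median(self.draws, axis=0), self.constraint
        )


def sample_q_posterior(
    tree: Phylogeny,
    tip_states: dict[str, int],
    states: list[str],
    constraint: str = "all_rates_different",
    prior_mean: float | None = None,
    n_iter: int = 4000,
    burnin: int = 1000,
    thin: int = 5,
    seed: int = 0,
    root_prior="uniform",
) -> QPosterior:
    """Metropolis-Hastings posterior over Mk transition rates.

    Rates carry independent exponential priors whose mean defaults to the
    Fitch parsimony change count divided by total tree length (a natural
    scale for "about one change where the data demand one").  Proposals
    are multiplicative log-normal random walks with an adaptive step size
    targeting roughly 30% acceptance.
    """
    k = len(states)
    observed = {int(s) for s in tip_states.values() if s is not None}
    if len(observed) < 2:
        raise ValueError("need at least 2 observed states to estimate rates")
    eng = PruningEngine(tree, tip_states, k)
    if prior_mean is None:
        pc = max(parsimony_changes(tree, tip_states, k), 1)
        prior_mean = pc / eng.tree.total_branch_length()
    n_free = 1 if constraint == "equal_rates" else k * (k - 1)
    rng = np.random.Generator(np.random.PCG64(seed))
    x = np.log(np.full(n_free, prior_mean))
    step = 0.5

    def logpost(lx):
        rates = np.exp(lx)
        lp = float(np.sum(-rates / prior_mean))  # exp prior, log-scale Jacobian
        lp += float(np.sum(lx))  # Jacobian of the log transform
        ll = eng.loglik(
            RateMatrix.from_rates(states, rates, constraint).Q, root_prior
        )
        return lp + ll, ll

    cur_lp, cur_ll = logpost(x)
    draws, lls = [], []
    n_acc = n_tot = 0
    for it in range(n_iter):
        prop = x + rng.normal(0.0, step, size=n_free)
        lp, ll = logpost(prop)
        n_tot += 1
        if np.log(rng.random()) < lp - cur_lp:
            x, cur_lp, cur_ll = prop, lp, ll
            n_acc += 1
        if it < burnin and it % 100 == 99:
            rate = n_acc / n_tot
            step *= np.exp(0.5 * (rate - 0.3))
            step = float(np.clip(step, 1e-3, 5.0))
        if it >= burnin and (it - burnin) % thin == 0:
            draws.append(np.exp(x))
            lls.append(cur_ll)
    return QPosterior(
        states, constraint, np.array(draws), np.array(lls), n_acc / n_tot, seed
    )


def stochastic_maps(
    tree: Phylogeny,
    tip_states: dict[str, int],
    q_draws: QPosterior | list[RateMatrix] | RateMatrix,
    n_maps: int = 1000,
    seed: int = 0,
    root_prior="uniform",
) -> list[CharacterMap]:
    """Sample stochastic character maps conditioned on the tip data.

    Each map draws a Q (cycling through posterior draws when given), then
    samples node states from the conditional scaled likelihoods and branch
    histories by uniformization conditioned on the endpoint states.
    """
    if isinstance(q_draws, RateMatrix):
        mats = [q_draws]
    elif isinstance(q_draws, QPosterior):
        mats = q_draws.rate_matrices()
    else:
        mats = list(q_draws)
    k = mats[0].k
    eng = PruningEngine(tree, tip_states, k)
    rng = np.random.Generator(np.random.PCG64(seed))
    maps = []
    for m in range(n_maps):
        Q = mats[m % len(mats)].Q
        maps.append(eng.sample_map(Q, rng, root_prior))
    return maps


def summarize_node_states(
    maps: list[CharacterMap],
    k: int,
    rule: str = "majority",
) -> tuple[np.ndarray, np.ndarray]:
    """Empirical node-state frequencies across maps plus an assignment.

    ``rule='majority'`` assigns the modal state only when its frequency
    strictly exceeds 0.5 (else -1, "uncertain"); ``rule='modal'`` always
    assigns the most frequent state, the convention used for multi-state
    feeding niches.
    """
    if not maps:
        raise ValueError("no maps supplied")
    n_nodes = len(maps[0].node_states)
    freq = np.zeros((n_nodes, k))
    for m in maps:
        freq[np.arange(n_nodes), m.node_states] += 1.0
    freq /= len(maps)
    modal = freq.argmax(axis=1)
    if rule == "modal":
        assigned = modal
    else:
        assigned = np.where(freq.max(axis=1) > 0.5, modal, -1)
    return freq, assigned.astype(np.int64)


def count_state_transitions(
    tree: Phylogeny,
    assignment: np.ndarray,
    focal_states: set[int] | int,
) -> dict:
    """Count origins and losses of a focal state set over tree edges.

    An origin is an edge whose parent is assigned outside the focal set
    and whose child is assigned inside it; a loss is the reverse.  Edges
    touching an unassigned (-1) node are skipped and reported.
    """
    if isinstance(focal_states, int):
        focal_states = {focal_states}
    origins, losses, skipped = [], [], 0
    for i in range(tree.n_nodes):
        p = tree.parent[i]
        if p < 0:
            continue
        sp, si = int(assignment[p]), int(assignment[i])
        if sp < 0 or si < 0:
            skipped += 1
            continue
        if sp not in focal_states and si in focal_states:
            origins.append((int(p), i))
        elif sp in focal_states and si not in focal_states:
            losses.append((int(p), i))
    return {
        "n_origins": len(origins),
        "n_losses": len(losses),
        "origin_edges": origins,
        "loss_edges": losses,
        "skipped_edges": skipped,
    }
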