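"""Synthetic data generators with known ground truth.

Every generator is deterministic under a fixed seed and returns, next to
the data, a "truth" dictionary carrying the parameters that produced it,
so recovery and calibration tests never have to re-derive them.

The generators emulate the structure of family-level comparative data on
insect-microbe symbiosis: a time-calibrated ultrametric tree (default
root age 400 Myr, echoing the insect timescale), a binary obligate-
symbiosis trait, continuous dietary-nutrient traits with high
phylogenetic signal (defaults within the 0.7-0.96 heritability range
typical of such data), per-family binomial sampling of species, Poisson
species-richness counts, and host-symbiont association tables with
tunable co-phylogenetic signal.

Two distinct binary-trait generators exist on purpose: an Mk (CTMC)
simulator that exercises the discrete-state engine, and a liability-
threshold simulator that matches exactly the latent-Gaussian structure
the binomial-logit mixed models assume.
"""

from __future__ import annotations

import json
import random as _pyrandom
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from dendropy.model import birthdeath

from symphy.mk import RateMatrix
from symphy.phylo import Phylogeny
from symphy.pglmm import LOGIT_LINK_VAR

__all__ = [
    "sim_tree",
    "sim_mk_trait",
    "TraitSimConfig",
    "sim_correlated_traits",
    "sim_host_symbiont",
    "sim_richness",
    "write_truth",
]


def sim_tree(
    n_tips: int = 150,
    birth: float = 1.0,
    death: float = 0.5,
    root_age: float = 400.0,
    seed: int = 0,
    max_retries: int = 50,
) -> Phylogeny:
    """Birth-death tree conditioned on ``n_tips``, rescaled to ``root_age``.

    Complete extinction triggers a retry (with a perturbed seed); the
    retry count is recorded on the returned tree as ``sim_retries``.
    """
    if n_tips < 3:
        raise ValueError("need at least 3 tips")
    retries = 0
    for attempt in range(max_retries):
        try:
            tree = birthdeath.birth_death_tree(
                birth, death,
                num_extant_tips=n_tips,
                rng=_pyrandom.Random((seed, attempt).__hash__() & 0x7FFFFFFF),
            )
            break
        except Exception:
            retries += 1
    else:
        raise RuntimeError("birth-death simulation failed repeatedly")
    tree.seed_node.edge.length = 0.0
    for i, leaf in enumerate(sorted(tree.leaf_node_iter(),
                                    key=lambda nd: nd.taxon.label)):
        leaf.taxon.label = f"F{i:03d}"
    phy = Phylogeny.from_dendropy(tree)
    # the simulator stops exactly at the nth birth, leaving a zero-length
    # cherry; continue the (memoryless) process by the waiting time to the
    # next birth, extending every tip branch equally (stays ultrametric)
    ext_rng = np.random.Generator(np.random.PCG64([seed, 915]))
    phy.length[: phy.n_tips] += ext_rng.exponential(1.0 / (n_tips * birth))
    height = float(phy.tip_depths().max())
    phy.length *= root_age / height
    phy.sim_retries = retries
    return phy


def sim_mk_trait(
    tree: Phylogeny, rate_matrix: RateMatrix, seed: int = 0,
    root_state: int | None = None,
) -> dict:
    """Simulate a discrete CTMC root-to-tips, keeping the full history.

    Returns tip states, true node states and per-branch change counts;
    the stored truth lets recovery tests score origin/loss counts and
    posterior rate estimates directly.
    """
    rng = np.random.Generator(np.random.PCG64(seed))
    Q = rate_matrix.Q
    k = rate_matrix.k
    states = np.full(tree.n_nodes, -1, dtype=np.int64)
    changes = np.zeros(tree.n_nodes, dtype=np.int64)
    if root_state is None:
        root_state = int(rng.integers(k))
    states[tree.root] = root_state
    order = tree.postorder()[::-1]
    for nd in order:
        p = tree.parent[nd]
        if p < 0:
            continue
        s = int(states[p])
        t_left = float(tree.length[nd])
        nch = 0
        while True:
            rate = -Q[s, s]
            if rate <= 0:
                break
            wait = rng.exponential(1.0 / rate)
            if wait >= t_left:
                break
            t_left -= wait
            probs = Q[s].copy()
            probs[s] = 0.0
            probs = probs / probs.sum()
            s = int(rng.choice(k, p=probs))
            nch += 1
        states[nd] = s
        changes[nd] = nch
    tips = {tree.labels[i]: int(states[i]) for i in range(tree.n_tips)}
    return {
        "tip_states": tips,
        "node_states": states,
        "branch_changes": changes,
        "truth": {"Q": Q.tolist(), "root_state": int(root_state), "seed": seed},
    }


@dataclass
class TraitSimConfig:
    """Study conditions for the correlated liability/nutrient generator.

    ``phylo_corr`` is the latent phylogenetic correlation between the
    binary-trait liability and each nutrient (first entry) and among
    nutrients; ``h2`` gives per-trait phylogenetic heritability on the
    scale the binomial-logit model uses (link variance included for the
    liability).
    """

    nutrients: tuple[str, ...] = ("B5", "B9")
    phylo_corr: np.ndarray | None = None   # (1+m, 1+m); default r=-0.4 with B5/B9
    h2: tuple[float, ...] = (0.8, 0.8, 0.8)  # liability, then nutrients
    mean_liability: float = 0.0
    n_sampled_mean: float = 4.0              # species examined per family
    missingness: float = 0.05

    def corr(self) -> np.ndarray:
        if self.phylo_corr is not None:
            R = np.asarray(self.phylo_corr, float)
        else:
            m = len(self.nutrients)
            R = np.eye(1 + m)
            R[0, 1:] = -0.4
            R[1:, 0] = -0.4
            if m > 1:
                R[1:, 1:] += 0.5 * (np.ones((m, m)) - np.eye(m))
        w = np.linalg.eigvalsh(R)
        if w.min() < -1e-10:
            raise ValueError("phylo_corr must be positive semi-definite")
        return R


def sim_correlated_traits(
    tree: Phylogeny, config: TraitSimConfig | None = None, seed: int = 0
) -> tuple[pd.DataFrame, dict]:
    """Liability-threshold binary trait + correlated Gaussian nutrients.

    Multivariate Brownian phylogenetic effects with the configured
    cross-trait correlation are combined with independent residual noise
    so each trait hits its target heritability; the binary trait is
    produced by per-family binomial sampling with success probability
    logistic(liability), exactly the generative model the binomial-logit
    BPMM assumes.
    """
    config = config or TraitSimConfig()
    rng = np.random.Generator(np.random.PCG64(seed))
    n = tree.n_tips
    m = len(config.nutrients)
    R = config.corr()
    C = tree.covariance().matrix
    C = C / C.diagonal().max()
    Lc = np.linalg.cholesky(C + 1e-10 * np.eye(n))
    A = Lc @ rng.standard_normal((n, 1 + m)) @ np.linalg.cholesky(R).T

    h2 = np.asarray(config.h2, float)
    if len(h2) != 1 + m:
        raise ValueError("h2 must cover liability plus each nutrient")
    # liability: residual fixed at 1 on the latent scale; the phylo
    # variance implied by the target heritability includes pi^2/3
    h0 = h2[0]
    v_phylo_liab = h0 * (1.0 + LOGIT_LINK_VAR) / (1.0 - h0)
    liab = (config.mean_liability
            + np.sqrt(v_phylo_liab) * A[:, 0]
            + rng.standard_normal(n))
    n_sampled = 1 + rng.poisson(config.n_sampled_mean - 1.0, size=n)
    p = 1.0 / (1.0 + np.exp(-liab))
    n_obligate = rng.binomial(n_sampled, p)

    data = {
        "family": tree.tip_labels,
        "n_sampled": n_sampled,
        "n_obligate": n_obligate,
    }
    for jj, nut in enumerate(config.nutrients):
        hj = h2[1 + jj]
        x = np.sqrt(hj) * A[:, 1 + jj] + np.sqrt(1 - hj) * rng.standard_normal(n)
        if config.missingness > 0:
            mask = rng.random(n) < config.missingness
            x = np.where(mask, np.nan, x)
        data[nut] = x
    df = pd.DataFrame(data)
    truth = {
        "phylo_corr": R.tolist(),
        "h2": h2.tolist(),
        "v_phylo_liability": float(v_phylo_liab),
        "liability": liab.tolist(),
        "seed": seed,
    }
    return df, truth


def sim_state_linked_nutrient(
    tree: Phylogeny,
    node_states: np.ndarray,
    state_effect: float = -1.5,
    bm_sd: float = 1.0,
    noise_sd: float = 0.3,
    saturation: float | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Nutrient trait that declines only *after* a discrete state is entered.

    The trait is Brownian motion on the tree plus a state-linked shift.
    By default the shift accumulates with the time a lineage has spent in
    the derived state (approximated branch-wise from the node states),
    saturating at ``state_effect`` once the dwell time reaches
    ``saturation`` (default: a quarter of tree height).  This emulates
    lineages gradually specializing on nutrient-poor diets following the
    acquisition of the derived state, so ancestors immediately preceding
    a transition carry essentially no shift.  Tip values get additional
    independent noise.
    """
    rng = np.random.Generator(np.random.PCG64(seed))
    n = tree.n_tips
    height = float(tree.tip_depths().max())
    if saturation is None:
        saturation = 0.25 * height
    C = tree.covariance().matrix
    C = C / C.diagonal().max()
    bm = bm_sd * (np.linalg.cholesky(C + 1e-10 * np.eye(n))
                  @ rng.standard_normal(n))
    states = np.asarray(node_states)
    # dwell time in the derived state along each root-to-tip path,
    # attributing a branch to the state of its child node
    dwell = np.zeros(tree.n_nodes)
    for nd in tree.postorder()[::-1]:
        p = tree.parent[nd]
        if p < 0:
            continue
        dwell[nd] = dwell[p] + (tree.length[nd] if states[nd] == 1 else 0.0)
    shift = state_effect * np.minimum(dwell[:n] / saturation, 1.0)
    shift *= states[:n]  # lineages that reverted carry no present shift
    x = bm + shift + noise_sd * rng.standard_normal(n)
    df = pd.DataFrame({"family": tree.tip_labels, "value": x})
    truth = {"state_effect": state_effect, "bm_sd": bm_sd,
             "noise_sd": noise_sd, "saturation": saturation,
             "tip_shift": shift.tolist(), "seed": seed}
    return df, truth


def sim_host_symbiont(
    host_tree: Phylogeny, signal: float = 1.0, seed: int = 0,
    mean_with: float = 3.0, mean_without: float = 2.0,
) -> tuple[Phylogeny, pd.DataFrame, dict]:
    """Symbiont tree plus association table with tunable congruence.

    The symbiont tree mirrors the host tree's shape; each symbiont
    lineage keeps its mirrored host with probability ``signal`` and is
    re-assigned to a random host otherwise, so ``signal=1`` gives perfect
    co-divergence and ``signal=0`` random associations.
    """
    if not (0.0 <= signal <= 1.0):
        raise ValueError("signal must lie in [0, 1]")
    rng = np.random.Generator(np.random.PCG64(seed))
    sym = Phylogeny(
        host_tree.parent.copy(), host_tree.length.copy(),
        [lab.replace("F", "S") if lab.startswith("F") else f"S_{lab}"
         for lab in host_tree.labels],
        host_tree.n_tips,
    )
    hosts = host_tree.tip_labels
    rows = []
    true_links = {}
    for i, s in enumerate(sym.tip_labels):
        if rng.random() < signal:
            h = hosts[i]
        else:
            h = hosts[int(rng.integers(len(hosts)))]
        true_links[s] = h
        rows.append({
            "host_family": h,
            "symbiont_lineage": s,
            "n_with": 1 + int(rng.poisson(mean_with - 1.0)),
            "n_without": int(rng.poisson(mean_without)),
            "intracellular": bool(rng.random() < 0.7),
            "vertical": False,
        })
    table = pd.DataFrame(rows)
    truth = {"signal": float(signal), "links": true_links, "seed": seed}
    return sym, table, truth


def sim_richness(
    tree: Phylogeny,
    trait: np.ndarray | pd.Series,
    base_log_rate: float = 3.0,
    trait_effect: float = 0.0,
    age_effect: float = 0.0,
    clade_sd: float = 0.5,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Per-family species richness with age, trait and clade effects.

    log-rate = base + age_effect * scaled stem age + trait_effect * trait
    + phylogenetically structured clade effect; counts are Poisson,
    truncated at 1 (a family always contains its type species) with the
    truncation count recorded in the truth sidecar.
    """
    rng = np.random.Generator(np.random.PCG64(seed))
    n = tree.n_tips
    trait = np.asarray(trait, float)
    C = tree.covariance().matrix
    C = C / C.diagonal().max()
    clade = clade_sd * (np.linalg.cholesky(C + 1e-10 * np.eye(n))
                        @ rng.standard_normal(n))
    age = tree.length[: tree.n_tips].copy()  # stem age of each family
    z_age = (age - age.mean()) / max(age.std(), 1e-12)
    eta = base_log_rate + age_effect * z_age + trait_effect * trait + clade
    lam = np.exp(eta)
    rich = rng.poisson(lam)
    truncated = int(np.sum(rich < 1))
    rich = np.maximum(rich, 1)
    metabolism = np.where(rng.random(n) < 0.5, "holo", "hemi")
    df = pd.DataFrame({
        "family": tree.tip_labels,
        "species_richness": rich,
        "family_age": age,
        "metabolism": metabolism,
    })
    truth = {
        "base_log_rate": base_log_rate,
        "trait_effect": trait_effect,
        "age_effect": age_effect,
        "clade_sd": clade_sd,
        "n_truncated": truncated,
        "seed": seed,
    }
    return df, truth


def write_truth(truth: dict, path) -> None:
    """Write a truth sidecar as JSON."""
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=2, default=str)
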