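"""Ancestral B-vitamin levels around gains and losses of symbiosis.

The question "did low B vitamins precede obligate symbiosis, or follow
it?" is answered by classifying every internal node of the phylogeny by
its symbiosis transition context and comparing reconstructed nutrient
levels across the four categories:

- ``NonToNon``: non-obligate node, all immediate descendants non-obligate
- ``NonToOb``: non-obligate node with at least one obligate descendant
  (the step preceding an origin)
- ``ObToOb``: obligate node with obligate descendants (maintenance)
- ``ObToNon``: obligate node with at least one non-obligate descendant
  (the step preceding a loss)

Classification uncertainty is propagated by repeating the analysis over
posterior resamples of the node states; within each resample the node
categories enter a multi-response Gaussian mixed model for the
reconstructed B5/B9 levels with a phylogenetic covariance linked to the
internal-node labels, and the retained draws are pooled across resamples
before contrasts are formed:

- origin:      NonToOb - NonToNon  (before symbiosis evolves)
- maintenance: ObToOb  - NonToNon  (once symbiosis is established)
- loss:        ObToNon - ObToOb    (before symbiosis is lost)
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from symphy.phylo import PhyloCovariance, Phylogeny
from symphy.pglmm import (ChainSettings, MixedModel, RandomTerm, Response,
                          predict_nodes)
from symphy.stats import summarize_draws

log = logging.getLogger(__name__)

__all__ = [
    "CATEGORIES",
    "CONTRASTS",
    "classify_nodes",
    "resample_classifications",
    "ancestral_nutrient_model",
    "transition_pipeline",
]

CATEGORIES = ("NonToNon", "NonToOb", "ObToOb", "ObToNon")
# contrast name -> (minuend category, subtrahend category)
CONTRASTS = {
    "origin": ("NonToOb", "NonToNon"),
    "maintenance": ("ObToOb", "NonToNon"),
    "loss": ("ObToNon", "ObToOb"),
}


def classify_nodes(tree: Phylogeny, states: np.ndarray) -> pd.DataFrame:
    """Four-way transition category for each assigned internal node.

    ``states`` holds 0 (non-obligate) / 1 (obligate) / -1 (unassigned)
    for every node, tips included.  A node needs its own state and at
    least one assigned immediate descendant; others are excluded with a
    warning.
    """
    states = np.asarray(states)
    children = tree.children_lists()
    rows, skipped = [], 0
    for a in range(tree.n_tips, tree.n_nodes):
        s = int(states[a])
        kids = [int(states[c]) for c in children[a] if states[c] >= 0]
        if s < 0 or not kids:
            skipped += 1
            continue
        if s == 0:
            cat = "NonToOb" if any(k == 1 for k in kids) else "NonToNon"
        else:
            cat = "ObToNon" if any(k == 0 for k in kids) else "ObToOb"
        rows.append({"node": tree.labels[a], "category": cat})
    if skipped:
        log.warning("excluded %d unassigned internal nodes", skipped)
    return pd.DataFrame(rows)


def resample_classifications(
    tree: Phylogeny,
    node_probs: np.ndarray,
    node_labels: list[str],
    tip_states: np.ndarray,
    n_resamples: int = 100,
    seed: int = 0,
    mode: str = "threshold",
) -> list[pd.DataFrame]:
    """Propagate node-state uncertainty into the classification.

    ``node_probs`` is a (draws x internal nodes) matrix of per-draw
    posterior probabilities of the obligate state (the prediction draws
    of the binomial mixed model, which are spatially coherent within a
    draw).  Each resample picks one posterior draw (cycling through the
    chain) and, under the default ``mode='threshold'``, classifies every
    node by that draw's probability exceeding 0.5 - a joint posterior
    sample of the state field, so transition boundaries move coherently
    between resamples.  ``mode='bernoulli'`` instead samples each node
    independently from the draw's probability (a noisier variant kept
    for comparison).  With zero posterior uncertainty all resamples
    coincide; tip states stay fixed at their observed values.
    """
    node_probs = np.atleast_2d(np.asarray(node_probs, float))
    rng = np.random.Generator(np.random.PCG64(seed))
    pos = {lab: i for i, lab in enumerate(tree.labels)}
    node_idx = np.array([pos[l] for l in node_labels])
    n_draws = node_probs.shape[0]
    out = []
    for k in range(n_resamples):
        d = (k * max(n_draws // max(n_resamples, 1), 1)) % n_draws
        states = np.full(tree.n_nodes, -1, dtype=np.int64)
        states[: tree.n_tips] = np.asarray(tip_states, dtype=np.int64)
        if mode == "threshold":
            node_states = (node_probs[d] > 0.5).astype(int)
        elif mode == "bernoulli":
            node_states = (rng.random(len(node_idx)) < node_probs[d]).astype(int)
        else:
            raise ValueError(f"unknown resampling mode {mode!r}")
        states[node_idx] = node_states
        out.append(classify_nodes(tree, states))
    return out


@dataclass
class TransitionModelResult:
    contrasts: pd.DataFrame          # per nutrient x contrast summary
    pooled_draws: dict               # (nutrient, contrast) -> draws
    category_counts: pd.DataFrame    # per-resample category counts
    n_resamples: int
    draws_per_resample: int


def ancestral_nutrient_model(
    tree: Phylogeny,
    classifications: list[pd.DataFrame],
    node_values: pd.DataFrame,
    nutrients: tuple[str, ...] = ("B5", "B9"),
    settings: ChainSettings | None = None,
    seed: int = 0,
    node_value_draws: dict[str, np.ndarray] | None = None,
) -> TransitionModelResult:
    """Per-resample mixed models of node nutrients across categories.

    ``node_values`` has one row per internal node (column ``node``) with
    the reconstructed nutrient levels.  For every resampled
    classification a Gaussian multi-response model with the four-level
    category factor (no intercept, one mean per category) and an
    internal-node phylogenetic covariance is fitted at desk-scale
    settings chosen to retain ~10 draws per resample; retained draws are
    pooled across resamples, so the pooled posterior has
    n_resamples x draws_per_resample draws, and contrasts are summarized
    from the pool.

    When ``node_value_draws`` maps each nutrient to a (posterior draws x
    nodes) matrix of reconstruction draws (aligned with ``node_values``
    rows), each resample uses one reconstruction draw instead of the
    posterior mean, so ancestral-value uncertainty - which is large for
    deep nodes - propagates into the pooled contrasts alongside the
    classification uncertainty.
    """
    # desk-scale mirror of long per-resample chains: keep 10 draws each
    settings = settings or ChainSettings(n_iter=1100, burnin=100, thin=100,
                                         n_chains=1, seed=seed)
    full = tree.covariance(include_internal=True)
    internal = [l for l in full.labels if l not in set(tree.tip_labels)]
    node_cov = full.submatrix(internal)

    pooled: dict[tuple[str, str], list[np.ndarray]] = {
        (nut, con): [] for nut in nutrients for con in CONTRASTS
    }
    counts_rows = []
    draws_per = None
    for ridx, cls in enumerate(classifications):
        vals = node_values
        if node_value_draws is not None:
            n_rec = min(v.shape[0] for v in node_value_draws.values())
            d = (ridx * max(n_rec // max(len(classifications), 1), 1)) % n_rec
            vals = node_values[["node"]].copy()
            for nut in nutrients:
                vals[nut] = node_value_draws[nut][d]
        df = cls.merge(vals, on="node", how="inner").dropna(
            subset=list(nutrients))
        counts = df["category"].value_counts()
        counts_rows.append({"resample": ridx,
                            **{c: int(counts.get(c, 0)) for c in CATEGORIES}})
        present = [c for c in CATEGORIES if counts.get(c, 0) > 0]
        for c in CATEGORIES:
            df[f"cat_{c}"] = (df["category"] == c).astype(float)
        cov = node_cov.submatrix(df["node"].tolist())
        model = MixedModel(
            df,
            [Response(nut) for nut in nutrients],
            fixed=[f"cat_{c}" for c in present],
            random_terms=[RandomTerm("phylo", "node", cov, "unstructured")],
            intercept=False,
        )
        st = ChainSettings(settings.n_iter, settings.burnin, settings.thin,
                           1, [settings.seed, ridx][1] * 100003 + settings.seed)
        chain = model.fit(st)[0]
        draws_per = chain.beta.shape[0]
        for nut in nutrients:
            for con, (hi, lo) in CONTRASTS.items():
                if hi in present and lo in present:
                    d = (chain.beta_draws(f"{nut}:cat_{hi}")
                         - chain.beta_draws(f"{nut}:cat_{lo}"))
                    pooled[(nut, con)].append(d)
                else:
                    log.info("resample %d: contrast %s skipped (empty cell)",
                             ridx, con)
    rows = []
    pooled_out = {}
    for (nut, con), parts in pooled.items():
        if not parts:
            continue
        draws = np.concatenate(parts)
        pooled_out[(nut, con)] = draws
        s = summarize_draws(draws, f"{nut}:{con}")
        rows.append({"nutrient": nut, "contrast": con, "mode": s.mode,
                     "mean": s.mean, "ci_low": s.ci_low, "ci_high": s.ci_high,
                     "pmcmc": s.pmcmc, "n_draws": s.n_draws})
    return TransitionModelResult(
        contrasts=pd.DataFrame(rows),
        pooled_draws=pooled_out,
        category_counts=pd.DataFrame(counts_rows),
        n_resamples=len(classifications),
        draws_per_resample=draws_per or 0,
    )


def transition_pipeline(
    tree: Phylogeny,
    table: pd.DataFrame,
    nutrients: tuple[str, ...] = ("B5", "B9"),
    n_resamples: int = 100,
    seed: int = 0,
    binomial_settings: ChainSettings | None = None,
    nutrient_settings: ChainSettings | None = None,
    resample_settings: ChainSettings | None = None,
    resample_mode: str = "threshold",
    reconstruction_mode: str = "plugin",
) -> TransitionModelResult:
    """End-to-end before/after analysis on a family table.

    Steps: (1) binomial mixed model of the obligate proportion with a
    phylogenetic random effect; (2) posterior node-state predictions;
    (3) Gaussian reconstruction of ancestral nutrient levels (posterior
    mean node expectations from a multi-response phylogenetic model of
    the tip nutrients); (4) resampled classification and per-resample
    category models, pooled into contrasts.
    """
    cov = tree.covariance()
    bs = binomial_settings or ChainSettings(n_iter=4000, burnin=1500, thin=5,
                                            seed=seed)
    m_bin = MixedModel(
        table,
        [Response("n_obligate", "binomial", "n_sampled")],
        random_terms=[RandomTerm("phylo", "family", cov, "unstructured")],
    )
    ch_bin = m_bin.fit(bs)[0]
    pred = predict_nodes(ch_bin, tree, "phylo", "n_obligate", seed=seed)
    node_probs = pred.attrs["draws"]

    ns = nutrient_settings or ChainSettings(n_iter=3000, burnin=1000, thin=4,
                                            seed=seed + 1)
    m_nut = MixedModel(
        table,
        [Response(nut) for nut in nutrients],
        random_terms=[RandomTerm("phylo", "family", cov, "unstructured")],
    )
    ch_nut = m_nut.fit(ns)[0]
    frames = []
    node_value_draws = {}
    for nut in nutrients:
        pn = predict_nodes(ch_nut, tree, "phylo", nut,
                           mode=reconstruction_mode, seed=seed + 2)
        ser = pn.set_index("node")["expectation"].rename(nut)
        ser.attrs = {}
        frames.append(ser)
        node_value_draws[nut] = pn.attrs["draws"]
    node_values = pd.concat(frames, axis=1).reset_index()

    prop = table["n_obligate"].to_numpy() / table["n_sampled"].to_numpy()
    tip_states = (prop > 0.5).astype(int)
    order = {f: i for i, f in enumerate(tree.tip_labels)}
    tip_states = tip_states[np.argsort([order[f] for f in table["family"]])]

    classifications = resample_classifications(
        tree, node_probs, pred["node"].tolist(), tip_states,
        n_resamples=n_resamples, seed=seed + 3, mode=resample_mode,
    )
    return ancestral_nutrient_model(
        tree, classifications, node_values, nutrients,
        settings=resample_settings, seed=seed + 4,
        node_value_draws=node_value_draws,
    )
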