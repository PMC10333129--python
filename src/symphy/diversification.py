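"""Species-richness analyses: family-level models and sister contrasts.

Diversification is examined through raw species richness (never derived
"diversification rates"): a multi-response model relating richness and
the obligate-symbiosis proportion across all families, focal-vs-
background contrasts for niche x symbiosis combinations, Poisson models
over sister pairs, and a log2 richness-ratio model restricted to sister
pairs that differ in their percentage of obligately symbiotic species.

All models are fitted through :mod:`symphy.pglmm`; families grafted onto
the tree (whose ages are uncertain) are excluded from richness models by
default.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from symphy.phylo import Phylogeny
from symphy.pglmm import (ChainSettings, MixedModel, PosteriorChain,
                          RandomTerm, Response, phylo_correlation)
from symphy.stats import ParamSummary, summarize_draws

log = logging.getLogger(__name__)

__all__ = [
    "assemble_sister_pairs",
    "empirical_logit",
    "richness_model",
    "niche_contrasts",
    "sister_richness_model",
    "sister_log2_analysis",
]


def empirical_logit(prop: np.ndarray, n: np.ndarray) -> np.ndarray:
    """logit of a proportion clipped by eps = 0.5/n (finite at 0% / 100%)."""
    prop = np.asarray(prop, float)
    n = np.asarray(n, float)
    eps = 0.5 / np.maximum(n, 1.0)
    p = np.clip(prop, eps, 1.0 - eps)
    return np.log(p / (1.0 - p))


def _drop_grafted(table: pd.DataFrame, tree: Phylogeny,
                  exclude_grafted: bool) -> tuple[pd.DataFrame, Phylogeny]:
    if not exclude_grafted or not tree.grafted:
        return table, tree
    keep = [t for t in tree.tip_labels if t not in tree.grafted]
    log.info("excluding %d grafted families from richness analyses",
             len(tree.grafted))
    return table[table["family"].isin(keep)].reset_index(drop=True), \
        tree.prune_to(keep)


def assemble_sister_pairs(tree: Phylogeny, table: pd.DataFrame) -> pd.DataFrame:
    """All cherries of the tree joined with the family table.

    One row per pair: families, richness, percentage obligate, feeding
    niches, pair age (cherry divergence time) and the cherry's node
    label, which links the pair to the phylogeny in the mixed models.
    """
    tab = table.set_index("family")
    rows = []
    for a, b, age, node in tree.sister_pairs():
        if a not in tab.index or b not in tab.index:
            continue
        ra, rb = tab.loc[a], tab.loc[b]
        rows.append({
            "family_a": a, "family_b": b,
            "richness_a": ra["species_richness"],
            "richness_b": rb["species_richness"],
            "pct_obligate_a": 100.0 * ra["n_obligate"] / max(ra["n_sampled"], 1),
            "pct_obligate_b": 100.0 * rb["n_obligate"] / max(rb["n_sampled"], 1),
            "n_sampled_a": ra["n_sampled"], "n_sampled_b": rb["n_sampled"],
            "niche_a": ra.get("feeding_niche", ""),
            "niche_b": rb.get("feeding_niche", ""),
            "pair_age": age, "node": node,
        })
    return pd.DataFrame(rows)


def richness_model(
    table: pd.DataFrame,
    tree: Phylogeny,
    settings: ChainSettings | None = None,
    exclude_grafted: bool = True,
) -> dict:
    """Joint model of obligate symbiosis and species richness.

    Responses: binomial obligate proportion and Poisson richness; fixed
    effects: standardized family age and metabolism (holo vs hemi);
    random: unstructured phylogenetic covariance across both responses,
    whose off-diagonal yields the phylogenetic correlation between
    symbiosis and richness.
    """
    table, tree = _drop_grafted(table, tree, exclude_grafted)
    df = table.copy()
    df["z_age"] = (df["family_age"] - df["family_age"].mean()) / df["family_age"].std()
    df["holo"] = (df["metabolism"] == "holo").astype(float)
    cov = tree.covariance()
    model = MixedModel(
        df,
        [Response("n_obligate", "binomial", "n_sampled"),
         Response("species_richness", "poisson")],
        fixed=["z_age", "holo"],
        random_terms=[RandomTerm("phylo", "family", cov, "unstructured")],
    )
    st = settings or ChainSettings(n_iter=5000, burnin=1500, thin=5)
    chains = model.fit(st)
    draws, rsum = phylo_correlation(chains, "phylo", "n_obligate",
                                    "species_richness")
    return {
        "chains": chains,
        "summary": chains[0].summarize(),
        "phylo_correlation": rsum,
        "phylo_correlation_draws": draws,
    }


def niche_contrasts(
    table: pd.DataFrame,
    tree: Phylogeny,
    focal_cells: list[tuple[str, int]] | None = None,
    settings: ChainSettings | None = None,
    min_families: int = 2,
    exclude_grafted: bool = True,
) -> pd.DataFrame:
    """Focal niche x symbiosis cell versus all other families.

    For each focal (feeding niche, obligate flag) combination a Poisson
    richness model is refitted with a two-level focal-vs-background
    factor (plus age and metabolism); the returned contrast is the focal
    coefficient on the log scale.
    """
    table, tree = _drop_grafted(table, tree, exclude_grafted)
    df = table.copy()
    df["obligate"] = ((df["n_obligate"] / df["n_sampled"]) > 0.5).astype(int)
    df["z_age"] = (df["family_age"] - df["family_age"].mean()) / df["family_age"].std()
    df["holo"] = (df["metabolism"] == "holo").astype(float)
    cov = tree.covariance()
    if focal_cells is None:
        focal_cells = [
            (niche, ob)
            for (niche, ob), grp in df.groupby(["feeding_niche", "obligate"])
            if len(grp) >= min_families
        ]
    st = settings or ChainSettings(n_iter=4000, burnin=1500, thin=5)
    rows = []
    for niche, ob in focal_cells:
        focal = (df["feeding_niche"] == niche) & (df["obligate"] == ob)
        if focal.sum() < min_families:
            log.info("skipping focal cell (%s, %d): %d families",
                     niche, ob, int(focal.sum()))
            continue
        dff = df.assign(focal=focal.astype(float))
        model = MixedModel(
            dff,
            [Response("species_richness", "poisson")],
            fixed=["focal", "z_age", "holo"],
            random_terms=[RandomTerm("phylo", "family", cov, "unstructured")],
        )
        chain = model.fit(st)[0]
        s = summarize_draws(
            chain.beta_draws("species_richness:focal"), f"{niche}|ob={ob}")
        rows.append({"feeding_niche": niche, "obligate": ob,
                     "n_focal": int(focal.sum()), "mode": s.mode,
                     "mean": s.mean, "ci_low": s.ci_low, "ci_high": s.ci_high,
                     "pmcmc": s.pmcmc})
    return pd.DataFrame(rows)


def sister_richness_model(
    pairs: pd.DataFrame,
    tree: Phylogeny,
    settings: ChainSettings | None = None,
    include_niche: bool = False,
) -> dict:
    """Poisson richness across sister-pair members.

    Two rows per pair; fixed effects: empirical-logit percentage of
    obligately symbiotic species, pair age (standardized); random
    effects: pair identity (exchangeable) and the pair's node linked to
    the internal-node phylogenetic covariance.
    """
    if len(pairs) < 10:
        raise ValueError("need at least 10 sister pairs")
    long = []
    for _, p in pairs.iterrows():
        for side in ("a", "b"):
            long.append({
                "family": p[f"family_{side}"],
                "richness": p[f"richness_{side}"],
                "logit_pct": empirical_logit(
                    np.array([p[f"pct_obligate_{side}"] / 100.0]),
                    np.array([p[f"n_sampled_{side}"]]))[0],
                "pair": f"{p['family_a']}*{p['family_b']}",
                "node": p["node"],
                "pair_age": p["pair_age"],
                "niche": p[f"niche_{side}"],
            })
    df = pd.DataFrame(long)
    df["z_age"] = (df["pair_age"] - df["pair_age"].mean()) / max(
        df["pair_age"].std(), 1e-12)
    df["z_logit_pct"] = (df["logit_pct"] - df["logit_pct"].mean()) / max(
        df["logit_pct"].std(), 1e-12)
    fixed = ["z_logit_pct", "z_age"]
    if include_niche:
        dummies = pd.get_dummies(df["niche"], prefix="niche", drop_first=True)
        df = pd.concat([df, dummies.astype(float)], axis=1)
        fixed += list(dummies.columns)
    full = tree.covariance(include_internal=True)
    node_cov = full.submatrix(sorted(set(df["node"])))
    model = MixedModel(
        df,
        [Response("richness", "poisson")],
        fixed=fixed,
        random_terms=[
            RandomTerm("pair", "pair", None, "idh"),
            RandomTerm("node", "node", node_cov, "idh"),
        ],
    )
    st = settings or ChainSettings(n_iter=4000, burnin=1500, thin=5)
    chains = model.fit(st)
    s = summarize_draws(
        np.concatenate([c.beta_draws("richness:z_logit_pct") for c in chains]),
        "pct_obligate_effect")
    return {"chains": chains, "summary": chains[0].summarize(),
            "pct_obligate_effect": s}


def sister_log2_analysis(
    pairs: pd.DataFrame,
    tree: Phylogeny,
    settings: ChainSettings | None = None,
) -> dict:
    """log2 richness ratio for sister pairs that differ in symbiosis.

    Each qualifying pair is oriented so the family with the higher
    percentage of obligate species is the numerator; the Gaussian model
    regresses the log2 ratio on the (positive) percentage difference and
    pair age, with the pair's node linked to the phylogeny as a random
    effect.
    """
    diff = pairs[pairs["pct_obligate_a"] != pairs["pct_obligate_b"]].copy()
    if diff.empty:
        raise ValueError("no sister pairs differ in percentage obligate")
    rows = []
    for _, p in diff.iterrows():
        if p["pct_obligate_a"] >= p["pct_obligate_b"]:
            hi, lo = "a", "b"
        else:
            hi, lo = "b", "a"
        rows.append({
            "log2_ratio": np.log2(p[f"richness_{hi}"] / p[f"richness_{lo}"]),
            "pct_diff": p[f"pct_obligate_{hi}"] - p[f"pct_obligate_{lo}"],
            "pair_age": p["pair_age"],
            "node": p["node"],
        })
    df = pd.DataFrame(rows)
    df["z_diff"] = (df["pct_diff"] - df["pct_diff"].mean()) / max(
        df["pct_diff"].std(), 1e-12)
    df["z_age"] = (df["pair_age"] - df["pair_age"].mean()) / max(
        df["pair_age"].std(), 1e-12)
    full = tree.covariance(include_internal=True)
    node_cov = full.submatrix(sorted(set(df["node"])))
    model = MixedModel(
        df,
        [Response("log2_ratio", "gaussian")],
        fixed=["z_diff", "z_age"],
        random_terms=[RandomTerm("node", "node", node_cov, "idh")],
    )
    st = settings or ChainSettings(n_iter=4000, burnin=1500, thin=5)
    chains = model.fit(st)
    s = summarize_draws(
        np.concatenate([c.beta_draws("log2_ratio:z_diff") for c in chains]),
        "pct_diff_effect")
    return {"chains": chains, "data": df, "summary": chains[0].summarize(),
            "pct_diff_effect": s}
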