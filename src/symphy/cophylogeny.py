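"""Host-symbiont co-evolution: association tables, interaction
covariances and the ParaFit congruence test.

The variance-partitioning analyses ask how much of the variation in
obligate symbiosis (or in dietary B vitamins) is explained by which
*combination* of host and symbiont lineages occurs.  Each row of an
association table is one host-family x symbiont-lineage combination with
binomial counts (species sampled with / without that symbiont), and four
covariance structures over rows feed the mixed models:

- ``h``: hosts as exchangeable units (identity by host),
- ``[h]``: host phylogenetic covariance expanded to rows,
- ``[s]``: symbiont phylogenetic covariance expanded to rows,
- ``[hs]``: the elementwise (Schur) product of [h] and [s] - positive
  semi-definite by the Schur product theorem - capturing co-evolutionary
  interactions where related hosts pair with related symbionts.

ParaFit tests global congruence between the two trees given the binary
association matrix: principal coordinates of the two patristic distance
matrices (Lingoes-corrected when needed) are cross-multiplied through the
association matrix and the sum of squares compared against permutations
that reassign symbionts' host links.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from symphy.phylo import PhyloCovariance, Phylogeny

log = logging.getLogger(__name__)

__all__ = [
    "build_association_table",
    "interaction_covariances",
    "parafit_global",
]


def build_association_table(
    records: pd.DataFrame,
    symbiont_tree: Phylogeny,
    exclude_vertical: bool = True,
) -> pd.DataFrame:
    """Validate and filter a host x symbiont association table.

    ``records`` columns: host_family, symbiont_lineage, n_with,
    n_without, intracellular, vertical.  Vertically transmitted symbionts
    inflate co-phylogenetic signal through shared inheritance rather than
    recruitment and are excluded by default; rows whose symbiont is
    absent from the symbiont tree raise, and rows with no sampled species
    are dropped with a logged count.
    """
    tab = records.copy()
    tips = set(symbiont_tree.tip_labels)
    missing = sorted(set(tab["symbiont_lineage"]) - tips)
    if missing:
        raise KeyError(f"symbionts absent from symbiont tree: {missing[:5]}")
    if exclude_vertical and "vertical" in tab.columns:
        n0 = len(tab)
        tab = tab[~tab["vertical"].astype(bool)]
        if len(tab) < n0:
            log.info("excluded %d vertically transmitted rows", n0 - len(tab))
    empty = (tab["n_with"] + tab["n_without"]) <= 0
    if empty.any():
        log.info("dropping %d combinations with zero sampled species",
                 int(empty.sum()))
        tab = tab[~empty]
    if (tab[["n_with", "n_without"]] < 0).to_numpy().any():
        raise ValueError("negative counts in association table")
    tab = tab.reset_index(drop=True)
    tab["n_sampled"] = tab["n_with"] + tab["n_without"]
    return tab


def combination_grid(
    host_tree: Phylogeny,
    symbiont_tree: Phylogeny,
    links: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """All pairwise host x symbiont combinations.

    The variance-partitioning models operate on the full grid, not just
    observed associations - the contrast between combinations that do and
    do not occur is what identifies the interaction structure.  When
    ``links`` (host_family, symbiont_lineage, optionally n_with /
    n_without) is given, its counts are carried onto matching grid rows;
    all other combinations get n_with = 0.
    """
    rows = []
    linked = {}
    if links is not None:
        for _, r in links.iterrows():
            linked[(str(r["host_family"]), str(r["symbiont_lineage"]))] = r
    for h in host_tree.tip_labels:
        for s in symbiont_tree.tip_labels:
            r = linked.get((h, s))
            rows.append({
                "host_family": h,
                "symbiont_lineage": s,
                "n_with": int(r["n_with"]) if r is not None and "n_with" in r
                else (1 if r is not None else 0),
                "n_without": int(r["n_without"])
                if r is not None and "n_without" in r else 1,
                "intracellular": bool(r["intracellular"])
                if r is not None and "intracellular" in r else False,
                "vertical": bool(r["vertical"])
                if r is not None and "vertical" in r else False,
            })
    return pd.DataFrame(rows)


def interaction_covariances(
    host_tree: Phylogeny,
    symbiont_tree: Phylogeny,
    table: pd.DataFrame,
) -> dict[str, PhyloCovariance]:
    """The four row-level covariance structures h, [h], [s], [hs].

    Phylogenetic matrices are scaled to unit height before expansion so
    the Schur product stays on a correlation-like scale.  All four are
    PSD: h and the expansions by construction, [hs] by the Schur product
    theorem.
    """
    hosts = table["host_family"].astype(str).to_numpy()
    syms = table["symbiont_lineage"].astype(str).to_numpy()
    row_labels = [f"{h}*{s}" for h, s in zip(hosts, syms)]
    if len(set(row_labels)) != len(row_labels):
        raise ValueError("duplicate host x symbiont combinations")

    Ch = host_tree.covariance().scaled()
    Cs = symbiont_tree.covariance().scaled()
    hpos = {l: i for i, l in enumerate(Ch.labels)}
    spos = {l: i for i, l in enumerate(Cs.labels)}
    hi = np.array([hpos[h] for h in hosts])
    si = np.array([spos[s] for s in syms])

    H = Ch.matrix[np.ix_(hi, hi)]
    S = Cs.matrix[np.ix_(si, si)]
    same_host = (hi[:, None] == hi[None, :]).astype(float)
    HS = H * S
    out = {
        "h": PhyloCovariance(row_labels, same_host),
        "[h]": PhyloCovariance(row_labels, H),
        "[s]": PhyloCovariance(row_labels, S),
        "[hs]": PhyloCovariance(row_labels, HS),
    }
    for k, cov in out.items():
        w = np.linalg.eigvalsh((cov.matrix + cov.matrix.T) / 2)
        if w.min() < -1e-8:
            raise ValueError(f"structure {k} not PSD (min eig {w.min():.2e})")
    return out


def interaction_random_terms(
    host_tree: Phylogeny,
    symbiont_tree: Phylogeny,
    table: pd.DataFrame,
) -> tuple[pd.DataFrame, list]:
    """Mixed-model random terms for the h, [h], [s], [hs] structures.

    The host-level structures are parameterized at host level (h: i.i.d.
    host effects, [h]: host phylogenetic covariance) and the symbiont
    structure at symbiont level, which keeps their covariances full rank;
    only the interaction [hs] lives on combination rows, with the Schur-
    product covariance.  Returns the table with a ``combo`` level column
    plus the four :class:`~symphy.pglmm.RandomTerm` objects.
    """
    from symphy.pglmm import RandomTerm

    covs = interaction_covariances(host_tree, symbiont_tree, table)
    tab = table.copy()
    tab["combo"] = covs["[hs]"].labels
    terms = [
        RandomTerm("h", "host_family", None, "idh"),
        RandomTerm("[h]", "host_family", host_tree.covariance().scaled(),
                   "idh"),
        RandomTerm("[s]", "symbiont_lineage",
                   symbiont_tree.covariance().scaled(), "idh"),
        RandomTerm("[hs]", "combo", covs["[hs]"], "idh"),
    ]
    return tab, terms


def _pcoa(D: np.ndarray) -> np.ndarray:
    """Principal coordinates of a distance matrix.

    Negative eigenvalues (non-Euclidean distances) are handled with the
    Lingoes correction: add a constant to all squared off-diagonal
    distances and re-decompose.
    """
    n = len(D)
    J = np.eye(n) - np.ones((n, n)) / n

    def decompose(D2):
        G = -0.5 * J @ D2 @ J
        w, V = np.linalg.eigh((G + G.T) / 2)
        return w[::-1], V[:, ::-1]

    w, V = decompose(D**2)
    tol = 1e-8 * max(abs(w[0]), 1.0)
    if w[-1] < -tol:
        c = -w[-1]
        D2 = D**2 + 2 * c * (1 - np.eye(n))
        w, V = decompose(D2)
    keep = w > tol
    return V[:, keep] * np.sqrt(w[keep])


def parafit_global(
    host_tree: Phylogeny,
    symbiont_tree: Phylogeny,
    links: pd.DataFrame,
    n_perm: int = 1000,
    seed: int = 0,
) -> dict:
    """Global ParaFit test of host-symbiont phylogenetic congruence.

    ``links`` columns: host_family, symbiont_lineage (one row per
    association).  The statistic is the sum of squared entries of
    B_s' A' B_h where B_h, B_s are principal coordinates of the two
    patristic distance matrices and A is the binary association matrix;
    the p-value compares it against ``n_perm`` permutations that
    reassign each symbiont's host uniformly at random,
    p = (1 + #{perm >= observed}) / (n_perm + 1).
    """
    hlabs, Dh = host_tree.patristic_distances()
    slabs, Ds = symbiont_tree.patristic_distances()
    hpos = {l: i for i, l in enumerate(hlabs)}
    spos = {l: i for i, l in enumerate(slabs)}
    A = np.zeros((len(hlabs), len(slabs)))
    for _, row in links.iterrows():
        A[hpos[str(row["host_family"])], spos[str(row["symbiont_lineage"])]] = 1.0
    n_links = int(A.sum())
    if n_links < 2 or A.any(axis=1).sum() < 2 or A.any(axis=0).sum() < 2:
        log.warning("degenerate association matrix; ParaFit p set to 1")
        return {"statistic": 0.0, "p_value": 1.0, "n_perm": n_perm,
                "seed": seed, "degenerate": True}

    Bh = _pcoa(Dh)
    Bs = _pcoa(Ds)

    def stat(Amat):
        C = Bs.T @ Amat.T @ Bh
        return float(np.sum(C * C))

    obs = stat(A)
    rng = np.random.Generator(np.random.PCG64(seed))
    n_h = len(hlabs)
    count = 0
    for _ in range(n_perm):
        Ap = np.zeros_like(A)
        for s in range(A.shape[1]):
            hosts_of_s = np.flatnonzero(A[:, s])
            new_hosts = rng.integers(n_h, size=len(hosts_of_s))
            for h in new_hosts:
                Ap[h, s] += 1.0
        if stat(Ap) >= obs:
            count += 1
    p = (1 + count) / (n_perm + 1)
    return {"statistic": obs, "p_value": float(p), "n_perm": n_perm,
            "seed": seed, "degenerate": False}
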