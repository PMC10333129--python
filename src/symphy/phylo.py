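"""Phylogeny container and tree utilities.

A :class:`Phylogeny` is a rooted tree with branch lengths in millions of
years (Myr).  Newick parsing and writing are delegated to :mod:`dendropy`;
internally the tree is stored as flat arrays (parent pointers, branch
lengths, labels) which makes the pruning-style algorithms used elsewhere in
the package straightforward and fast.

The utilities here cover what the comparative analyses need: phylogenetic
variance-covariance matrices (optionally including internal nodes), tip
grafting for taxa absent from a published tree, sister-pair (cherry)
extraction, pruning to a taxon subset and patristic distances.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import dendropy
import numpy as np

__all__ = [
    "Phylogeny",
    "PhyloCovariance",
    "parse_newick",
    "write_newick",
]

# Branch lengths created at graft points may be exactly zero; they are
# perturbed by this amount so covariance matrices stay positive definite.
ZERO_BRANCH_EPS = 1e-8


class NewickError(ValueError):
    """Raised for malformed or inconsistent Newick input."""


@dataclass
class PhyloCovariance:
    """Shared-path-length covariance among tips (and optionally nodes).

    ``matrix[i, j]`` is the depth (distance from the root) of the most
    recent common ancestor of elements ``i`` and ``j``; the diagonal holds
    root-to-element path lengths.
    """

    labels: list[str]
    matrix: np.ndarray

    def scaled(self) -> "PhyloCovariance":
        """Return a copy scaled so the largest diagonal entry is 1."""
        s = float(self.matrix.diagonal().max())
        return PhyloCovariance(list(self.labels), self.matrix / s)

    def submatrix(self, labels: list[str]) -> "PhyloCovariance":
        idx = [self.labels.index(l) for l in labels]
        return PhyloCovariance(list(labels), self.matrix[np.ix_(idx, idx)])


class Phylogeny:
    """Rooted labelled tree with branch lengths.

    Nodes are indexed 0..n-1 with tips first, then internal nodes; the
    root is the last internal node in preorder terms.  Unlabelled internal
    nodes receive auto-generated labels ``N<preorder-index>``.
    """

    def __init__(
        self,
        parent: np.ndarray,
        length: np.ndarray,
        labels: list[str],
        n_tips: int,
        grafted: set[str] | None = None,
    ):
        self.parent = np.asarray(parent, dtype=np.int64)
        self.length = np.asarray(length, dtype=np.float64)
        self.labels = list(labels)
        self.n_tips = int(n_tips)
        self.grafted = set(grafted or ())
        self._validate()

    # -- construction -------------------------------------------------

    def _validate(self) -> None:
        n = len(self.parent)
        if len(self.length) != n or len(self.labels) != n:
            raise ValueError("parent/length/labels size mismatch")
        roots = np.flatnonzero(self.parent < 0)
        if len(roots) != 1:
            raise NewickError(f"tree must have exactly one root, got {len(roots)}")
        tips = self.labels[: self.n_tips]
        if len(set(tips)) != len(tips):
            dup = sorted({t for t in tips if tips.count(t) > 1})
            raise NewickError(f"duplicate tip labels: {dup}")
        nonroot = self.parent >= 0
        if np.any(self.length[nonroot] < 0):
            raise NewickError("negative branch length")

    @classmethod
    def from_dendropy(cls, tree: dendropy.Tree) -> "Phylogeny":
        nodes = list(tree.preorder_node_iter())
        tips = [nd for nd in nodes if nd.is_leaf()]
        internals = [nd for nd in nodes if not nd.is_leaf()]
        order = tips + internals
        index = {id(nd): i for i, nd in enumerate(order)}
        n = len(order)
        parent = np.full(n, -1, dtype=np.int64)
        length = np.zeros(n)
        labels: list[str] = []
        preorder_pos = {id(nd): i for i, nd in enumerate(nodes)}
        for nd in order:
            i = index[id(nd)]
            if nd.parent_node is not None:
                parent[i] = index[id(nd.parent_node)]
                if nd.edge.length is None:
                    raise NewickError(f"missing branch length above node {i}")
                length[i] = float(nd.edge.length)
            if nd.is_leaf():
                labels.append(nd.taxon.label if nd.taxon else f"T{i}")
            else:
                lab = nd.label or (nd.taxon.label if nd.taxon else None)
                labels.append(lab or f"N{preorder_pos[id(nd)]}")
        return cls(parent, length, labels, n_tips=len(tips))

    @classmethod
    def from_newick(cls, text: str) -> "Phylogeny":
        try:
            tree = dendropy.Tree.get(
                data=text,
                schema="newick",
                suppress_internal_node_taxa=True,
                preserve_underscores=True,
            )
        except Exception as exc:  # dendropy raises several error types
            raise NewickError(f"could not parse Newick: {exc}") from exc
        return cls.from_dendropy(tree)

    def to_dendropy(self) -> dendropy.Tree:
        return dendropy.Tree.get(
            data=self.to_newick(),
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )

    def to_newick(self, internal_labels: bool = True) -> str:
        children = self.children_lists()
        root = int(np.flatnonzero(self.parent < 0)[0])

        def fmt(i: int) -> str:
            if i < self.n_tips:
                base = _quote(self.labels[i])
            else:
                kids = ",".join(fmt(c) for c in children[i])
                lab = _quote(self.labels[i]) if internal_labels else ""
                base = f"({kids}){lab}"
            if self.parent[i] >= 0:
                base += f":{self.length[i]:.10g}"
            return base

        import sys

        old = sys.getrecursionlimit()
        sys.setrecursionlimit(max(old, 10 * len(self.labels) + 100))
        try:
            return fmt(root) + ";"
        finally:
            sys.setrecursionlimit(old)

    # -- basic structure ----------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def root(self) -> int:
        return int(np.flatnonzero(self.parent < 0)[0])

    @property
    def tip_labels(self) -> list[str]:
        return self.labels[: self.n_tips]

    def children_lists(self) -> list[list[int]]:
        out: list[list[int]] = [[] for _ in range(self.n_nodes)]
        for i, p in enumerate(self.parent):
            if p >= 0:
                out[int(p)].append(i)
        return out

    def postorder(self) -> np.ndarray:
        """Node indices ordered children-before-parents."""
        children = self.children_lists()
        order: list[int] = []
        stack = [self.root]
        while stack:
            nd = stack.pop()
            order.append(nd)
            stack.extend(children[nd])
        return np.array(order[::-1], dtype=np.int64)

    def depths(self) -> np.ndarray:
        """Distance of every node from the root."""
        d = np.zeros(self.n_nodes)
        for i in self.postorder()[::-1]:  # preorder
            p = self.parent[i]
            if p >= 0:
                d[i] = d[p] + self.length[i]
        return d

    def tip_depths(self) -> np.ndarray:
        return self.depths()[: self.n_tips]

    def total_branch_length(self) -> float:
        return float(self.length[self.parent >= 0].sum())

    def is_ultrametric(self, rel_tol: float = 1e-6) -> bool:
        d = self.tip_depths()
        span = d.max() - d.min()
        return bool(span <= rel_tol * max(d.max(), 1e-300))

    def index_of(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"no node labelled {label!r}") from None

    def clade_tips(self, node: int) -> list[int]:
        """Tip indices descending from ``node`` (inclusive if a tip)."""
        children = self.children_lists()
        out: list[int] = []
        stack = [node]
        while stack:
            nd = stack.pop()
            if nd < self.n_tips:
                out.append(nd)
            stack.extend(children[nd])
        return sorted(out)

    # -- covariance ----------------------------------------------------

    def covariance(self, include_internal: bool = False) -> PhyloCovariance:
        """Shared-path-length (Brownian) covariance matrix.

        With ``include_internal`` the matrix covers tips and internal
        nodes jointly, which is what ancestral-node random effects in the
        mixed models require.
        """
        depth = self.depths()
        n = self.n_nodes if include_internal else self.n_tips
        C = np.zeros((n, n))
        children = self.children_lists()

        # For each internal node a, C[i, j] = depth[a] for all (i, j) whose
        # MRCA is a, i.e. pairs drawn from distinct child subtrees of a.
        def members(nd: int) -> list[int]:
            if include_internal:
                out = []
                stack = [nd]
                while stack:
                    x = stack.pop()
                    out.append(x)
                    stack.extend(children[x])
                return out
            return self.clade_tips(nd)

        for a in range(self.n_nodes):
            if a < self.n_tips:
                continue
            kids = children[a]
            groups = [members(k) for k in kids]
            for gi in range(len(groups)):
                for gj in range(gi + 1, len(groups)):
                    ii = np.array(groups[gi])
                    jj = np.array(groups[gj])
                    C[np.ix_(ii, jj)] = depth[a]
                    C[np.ix_(jj, ii)] = depth[a]
            if include_internal:
                # a is the MRCA of itself with every descendant
                desc = [m for g in groups for m in g]
                C[a, desc] = depth[a]
                C[desc, a] = depth[a]
        np.fill_diagonal(C[: self.n_tips, : self.n_tips], depth[: self.n_tips])
        if include_internal:
            np.fill_diagonal(C, depth)
            # root depth 0 would make C singular; keep true path lengths,
            # callers add jitter where needed.
        labels = self.labels if include_internal else self.tip_labels
        return PhyloCovariance(list(labels), C[:n, :n] if include_internal else C)

    def patristic_distances(self) -> tuple[list[str], np.ndarray]:
        """Pairwise tip-to-tip path lengths."""
        C = self.covariance().matrix
        d = C.diagonal()
        D = d[:, None] + d[None, :] - 2.0 * C
        np.fill_diagonal(D, 0.0)
        return self.tip_labels, D

    # -- editing -------------------------------------------------------

    def graft_tip(
        self, new_tip: str, sister: str, where: str = "half"
    ) -> "Phylogeny":
        """Attach ``new_tip`` next to the clade labelled ``sister``.

        The attachment point sits on the sister clade's stem branch: at
        half its length (``where='half'``, the default) or at its top
        (``where='top'``).  The new tip's branch length is chosen so an
        ultrametric tree stays ultrametric.  Grafted tips are flagged in
        ``self.grafted`` so age-sensitive analyses can drop them.
        """
        if where not in ("half", "top"):
            raise ValueError("where must be 'half' or 'top'")
        if new_tip in self.labels:
            raise ValueError(f"tip {new_tip!r} already present")
        s = self.index_of(sister)
        if self.parent[s] < 0:
            raise ValueError("cannot graft onto the root stem")
        depth = self.depths()
        stem = self.length[s]
        frac = 0.5 if where == "half" else 1.0
        attach_depth = depth[self.parent[s]] + (1.0 - frac) * stem
        tip_height = float(self.tip_depths().max())
        new_len = max(tip_height - attach_depth, ZERO_BRANCH_EPS)

        # rebuild arrays: new tip index n_tips, new internal node appended
        n = self.n_nodes
        old_to_new = {}
        for i in range(n):
            old_to_new[i] = i if i < self.n_tips else i + 1
        nt = self.n_tips
        new_tip_idx = nt
        new_int_idx = n + 1
        parent = np.empty(n + 2, dtype=np.int64)
        length = np.empty(n + 2)
        labels = [""] * (n + 2)
        for i in range(n):
            j = old_to_new[i]
            p = self.parent[i]
            parent[j] = old_to_new[int(p)] if p >= 0 else -1
            length[j] = self.length[i]
            labels[j] = self.labels[i]
        # splice the new internal node into the sister stem
        s_new = old_to_new[s]
        parent[new_int_idx] = parent[s_new]
        length[new_int_idx] = max((1.0 - frac) * stem, ZERO_BRANCH_EPS)
        labels[new_int_idx] = f"N{new_int_idx}"
        parent[s_new] = new_int_idx
        length[s_new] = max(frac * stem, ZERO_BRANCH_EPS)
        parent[new_tip_idx] = new_int_idx
        length[new_tip_idx] = new_len
        labels[new_tip_idx] = new_tip
        out = Phylogeny(
            parent,
            length,
            labels,
            n_tips=nt + 1,
            grafted=self.grafted | {new_tip},
        )
        return out

    def prune_to(self, keep: list[str]) -> "Phylogeny":
        """Restrict the tree to a subset of tips (suppressing unifurcations)."""
        missing = [t for t in keep if t not in self.tip_labels]
        if missing:
            raise KeyError(f"tips not in tree: {missing}")
        tree = self.to_dendropy()
        taxa = [t for t in tree.taxon_namespace if t.label in set(keep)]
        tree.retain_taxa(taxa)
        out = Phylogeny.from_dendropy(tree)
        out.grafted = self.grafted & set(keep)
        return out

    # -- sisters --------------------------------------------------------

    def sister_pairs(self) -> list[tuple[str, str, float, str]]:
        """All cherries as ``(tip_a, tip_b, pair_age, node_label)``.

        ``pair_age`` is the depth-from-tips of the pair's MRCA, i.e. the
        divergence time on an ultrametric tree.
        """
        children = self.children_lists()
        depth = self.depths()
        height = float(self.tip_depths().max())
        out = []
        for a in range(self.n_tips, self.n_nodes):
            kids = children[a]
            if len(kids) == 2 and all(k < self.n_tips for k in kids):
                i, j = sorted(kids)
                out.append(
                    (self.labels[i], self.labels[j], height - depth[a], self.labels[a])
                )
        return out

    def __repr__(self) -> str:
        return f"Phylogeny(n_tips={self.n_tips}, n_nodes={self.n_nodes})"


def _quote(label: str) -> str:
    if any(c in label for c in " ()[]{}:;,'\t\n"):
        return "'" + label.replace("'", "''") + "'"
    return label


def parse_newick(text: str) -> Phylogeny:
    return Phylogeny.from_newick(text)


def write_newick(tree: Phylogeny) -> str:
    return tree.to_newick()
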