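"""Dated-tree data model: Newick I/O, validation, pruning, lineage-through-time.

The tree container is array-based (parent pointers, branch lengths, postorder
cache) because the diversification likelihoods downstream traverse branches in
tight numerical loops. All branch lengths are in Myr; node *age* means time
before present, with contemporaneous tips at age 0 for ultrametric trees.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "Phylogeny",
    "NewickParseError",
    "TreeValidationError",
    "parse_newick",
    "write_newick",
    "validate_dated",
    "prune_to_taxa",
    "ltt_series",
]


class NewickParseError(ValueError):
    """Raised when a Newick string cannot be parsed into a valid tree."""


class TreeValidationError(ValueError):
    """Raised when a tree violates a structural or dating invariant."""


class Phylogeny:
    """Rooted tree with branch lengths, tips labelled by unique identifiers.

    Parameters
    ----------
    parent : sequence of int
        Parent index per node, ``-1`` for the root (exactly one).
    length : sequence of float
        Branch length (Myr) above each node; the root's entry is ignored and
        stored as 0 (the stem edge is not part of the tree).
    labels : sequence of str or None
        Tip label per node; ``None`` for internal nodes.
    """

    def __init__(self, parent: Sequence[int], length: Sequence[float],
                 labels: Sequence[str | None]):
        self.parent = np.asarray(parent, dtype=np.int64)
        self.length = np.asarray(length, dtype=float).copy()
        self.labels = tuple(labels)
        n = self.parent.size
        if not (self.length.size == n and len(self.labels) == n):
            raise TreeValidationError("parent/length/labels size mismatch")
        roots = np.flatnonzero(self.parent < 0)
        if roots.size != 1:
            raise TreeValidationError(f"tree must have exactly one root, found {roots.size}")
        self.root = int(roots[0])
        self.length[self.root] = 0.0
        if np.any(self.length < 0):
            bad = int(np.flatnonzero(self.length < 0)[0])
            raise TreeValidationError(f"negative branch length at node {bad}")
        self.children: list[list[int]] = [[] for _ in range(n)]
        for i in range(n):
            if i != self.root:
                self.children[self.parent[i]].append(i)
        self.is_tip = np.array([len(c) == 0 for c in self.children])
        for i in range(n):
            if self.is_tip[i] and self.labels[i] is None:
                raise TreeValidationError(f"tip node {i} has no label")
        tips = [self.labels[i] for i in range(n) if self.is_tip[i]]
        dup = {t for t in tips if tips.count(t) > 1}
        if dup:
            raise TreeValidationError(f"duplicate tip labels: {sorted(dup)}")
        self._postorder: np.ndarray | None = None

    # -- basic structure ---------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return self.parent.size

    @property
    def n_tips(self) -> int:
        return int(self.is_tip.sum())

    @property
    def tip_labels(self) -> list[str]:
        return [self.labels[i] for i in range(self.n_nodes) if self.is_tip[i]]

    def tip_index(self) -> dict[str, int]:
        return {self.labels[i]: i for i in range(self.n_nodes) if self.is_tip[i]}

    def postorder(self) -> np.ndarray:
        """Node indices in postorder (children before parents), cached."""
        if self._postorder is None:
            order: list[int] = []
            stack = [self.root]
            while stack:  # iterative: trees can be thousands of tips deep
                node = stack.pop()
                order.append(node)
                stack.extend(self.children[node])
            self._postorder = np.array(order[::-1], dtype=np.int64)
        return self._postorder

    def depths(self) -> np.ndarray:
        """Root-to-node path lengths (Myr)."""
        d = np.zeros(self.n_nodes)
        for node in self.postorder()[::-1]:
            if node != self.root:
                d[node] = d[self.parent[node]] + self.length[node]
        return d

    @property
    def height(self) -> float:
        """Maximum root-to-tip distance (Myr) — the tree's age if dated."""
        return float(self.depths()[self.is_tip].max())

    def ages(self) -> np.ndarray:
        """Node ages before present: height minus depth."""
        return self.height - self.depths()

    def branching_times(self) -> np.ndarray:
        """Internal-node ages, descending; requires an ultrametric tree."""
        ult, _ = validate_dated(self)
        if not ult:
            raise TreeValidationError("branching times undefined: tree is not ultrametric")
        ages = self.ages()[~self.is_tip]
        return np.sort(ages)[::-1]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Phylogeny):
            return NotImplemented
        return write_newick(self) == write_newick(other)

    def __repr__(self) -> str:
        return f"<Phylogeny: {self.n_tips} tips, height {self.height:.4g} Myr>"


# -- I/O -------------------------------------------------------------------

def parse_newick(text: str) -> Phylogeny:
    """Parse a strict Newick string (branch lengths required) into a Phylogeny.

    Raises
    ------
    NewickParseError
        On malformed input, missing branch lengths, or duplicate tip labels,
        naming the offending token where possible.
    """
    try:
        dtree = dendropy.Tree.get(
            data=text, schema="newick",
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error classes
        raise NewickParseError(f"malformed Newick: {exc}") from exc
    dnodes = list(dtree.preorder_node_iter())
    if len(dnodes) < 2:
        raise NewickParseError("tree must contain at least two nodes")
    index = {id(nd): i for i, nd in enumerate(dnodes)}
    parent, length, labels = [], [], []
    for nd in dnodes:
        if nd.parent_node is None:
            parent.append(-1)
            length.append(0.0)
        else:
            parent.append(index[id(nd.parent_node)])
            if nd.edge.length is None:
                tok = nd.taxon.label if nd.taxon else "<internal>"
                raise NewickParseError(f"missing branch length at '{tok}'")
            length.append(float(nd.edge.length))
        labels.append(nd.taxon.label if (nd.taxon and nd.is_leaf()) else None)
    try:
        return Phylogeny(parent, length, labels)
    except TreeValidationError as exc:
        raise NewickParseError(str(exc)) from exc


def write_newick(tree: Phylogeny) -> str:
    """Serialize to Newick; branch lengths round-trip exactly (repr floats)."""
    parts: dict[int, str] = {}
    for node in tree.postorder():
        if tree.is_tip[node]:
            parts[node] = f"{tree.labels[node]}:{float(tree.length[node])!r}"
        else:
            inner = ",".join(parts[c] for c in tree.children[node])
            if node == tree.root:
                parts[node] = f"({inner});"
            else:
                parts[node] = f"({inner}):{float(tree.length[node])!r}"
    return parts[tree.root]


# -- validation ------------------------------------------------------------

def validate_dated(tree: Phylogeny, tol: float | None = None) -> tuple[bool, float]:
    """Check ultrametricity and report tree height.

    ``tol`` defaults to ``1e-6 x height`` (published supertrees carry rounding
    noise). Returns ``(ultrametric, height)``.
    """
    depths = tree.depths()[tree.is_tip]
    height = float(depths.max())
    if tol is None:
        tol = 1e-6 * max(height, 1.0)
    return bool(depths.max() - depths.min() <= tol), height


# -- pruning ---------------------------------------------------------------

def prune_to_taxa(tree: Phylogeny, keep: Iterable[str]) -> Phylogeny:
    """Restrict the tree to a subset of tips.

    Unifurcations left behind are collapsed by summing branch lengths, and the
    result is re-rooted at the MRCA of the kept tips (the stem edge above it is
    discarded), so a pruned dated tree is ultrametric from its own root and tip
    ages are unchanged.
    """
    keep = set(keep)
    if not keep:
        raise ValueError("keep must be a non-empty set of tip labels")
    have = set(tree.tip_labels)
    missing = sorted(keep - have)
    if missing:
        raise ValueError(f"tip labels not in tree: {missing}")

    retained = np.zeros(tree.n_nodes, dtype=bool)
    for node in tree.postorder():
        if tree.is_tip[node]:
            retained[node] = tree.labels[node] in keep
        else:
            retained[node] = any(retained[c] for c in tree.children[node])

    # new root = deepest retained node with >=2 retained children (MRCA)
    def retained_children(node: int) -> list[int]:
        return [c for c in tree.children[node] if retained[c]]

    new_root = tree.root
    while not tree.is_tip[new_root] and len(retained_children(new_root)) == 1:
        new_root = retained_children(new_root)[0]

    parent_out: list[int] = []
    length_out: list[float] = []
    labels_out: list[str | None] = []

    def build(node: int, parent_idx: int, extra_len: float) -> None:
        kids = retained_children(node)
        if not tree.is_tip[node] and len(kids) == 1:
            # collapse the unifurcation: its branch accrues onto the child
            build(kids[0], parent_idx, extra_len + tree.length[node])
            return
        idx = len(parent_out)
        parent_out.append(parent_idx)
        length_out.append(0.0 if parent_idx < 0 else tree.length[node] + extra_len)
        labels_out.append(tree.labels[node] if tree.is_tip[node] else None)
        for c in kids:
            build(c, idx, 0.0)

    import sys
    old_limit = sys.getrecursionlimit()
    sys.setrecursionlimit(max(old_limit, 10 * tree.n_nodes + 100))
    try:
        build(new_root, -1, 0.0)
    finally:
        sys.setrecursionlimit(old_limit)
    return Phylogeny(parent_out, length_out, labels_out)


# -- lineage-through-time --------------------------------------------------

def ltt_series(tree: Phylogeny, tol: float | None = None) -> pd.DataFrame:
    """Lineage-through-time series of an ultrametric tree.

    One row per distinct internal-node age (descending), with the cumulative
    reconstructed-lineage count after the event(s) at that age. Coincident node
    ages (within ``tol``, default ``1e-9 x height``) are merged into a single
    row whose count jump equals the number of coincident bifurcations. For a
    rooted binary tree the first count is 2 and the last equals the tip count.

    Returns a DataFrame with columns ``age_mya`` and ``n_lineages``.
    """
    ult, height = validate_dated(tree)
    if not ult:
        raise TreeValidationError("LTT undefined for non-ultrametric trees")
    if tol is None:
        tol = 1e-9 * max(height, 1.0)
    ages = tree.ages()
    events = sorted(
        ((ages[i], len(tree.children[i]) - 1) for i in range(tree.n_nodes)
         if not tree.is_tip[i]),
        key=lambda e: -e[0],
    )
    rows: list[tuple[float, int]] = []
    count = 1
    for age, jump in events:
        count += jump
        if rows and rows[-1][0] - age <= tol:
            rows[-1] = (rows[-1][0], count)
        else:
            rows.append((age, count))
    return pd.DataFrame(rows, columns=["age_mya", "n_lineages"])
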