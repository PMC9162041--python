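"""Phylogenetic trees, extended OTU tables and abundance representations.

The community test operates on an "extended" OTU table: the observed
leaf-level counts augmented with one column per internal node of the rooted
phylogeny (root excluded), where an internal node's count is the sum of the
counts of its descendant leaves.  Relative abundances are taken against the
per-sample *leaf* total, and four transforms of the relative-abundance
matrix feed the per-taxon score tests:

``u``   presence/absence, ``I(A > 0)``
``w``   raw relative abundance ``A``
``.5``  square-root transform ``sqrt(A)`` (generalized-UniFrac-like)
``a``   raw relative abundance restricted to leaf columns only

Each transform carries a UniFrac-like weight vector ``omega``: the sample
standard deviation of the column times the length of the branch leading to
the node (branch length omitted for the leaf-only transform, where the tree
plays no role).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import dendropy

__all__ = [
    "PhyloTree",
    "ExtendedCountTable",
    "RelativeAbundanceTable",
    "AbundanceRepresentation",
    "MEASURES",
    "read_newick",
    "parse_newick",
    "build_extended_table",
    "relative_abundance",
    "make_representation",
    "compute_weights",
]

MEASURES = ("u", "w", ".5", "a")


@dataclass
class PhyloTree:
    """Array-backed rooted phylogeny.

    Nodes are indexed ``0..n_nodes-1`` in preorder with the root at index 0.
    ``parent[root] == -1``; ``branch_length[v]`` is the length of the edge
    leading *to* ``v`` (NaN for the root, whose edge is never used).
    """

    parent: np.ndarray
    branch_length: np.ndarray
    labels: list
    children: list = field(repr=False)
    root: int = 0

    def __post_init__(self):
        self.parent = np.asarray(self.parent, dtype=np.intp)
        self.branch_length = np.asarray(self.branch_length, dtype=float)
        n = self.parent.size
        if np.count_nonzero(self.parent < 0) != 1:
            raise ValueError("tree must have exactly one root")
        bl = self.branch_length[np.arange(n) != self.root]
        if not np.all(np.isfinite(bl)) or np.any(bl < 0):
            raise ValueError("branch lengths must be finite and >= 0")
        self._leaves = np.array(
            [v for v in range(n) if not self.children[v]], dtype=np.intp
        )
        leaf_labels = [self.labels[v] for v in self._leaves]
        if any(lab is None for lab in leaf_labels):
            raise ValueError("every leaf must be labelled")
        if len(set(leaf_labels)) != len(leaf_labels):
            raise ValueError("duplicate leaf labels in tree")

    @property
    def n_nodes(self) -> int:
        return self.parent.size

    @property
    def leaves(self) -> np.ndarray:
        """Node indices of the leaves, in tree (preorder) order."""
        return self._leaves

    @property
    def n_leaves(self) -> int:
        return self._leaves.size

    @property
    def leaf_labels(self) -> list:
        return [self.labels[v] for v in self._leaves]

    def internal_nonroot(self) -> np.ndarray:
        """Indices of internal nodes other than the root, in postorder."""
        return np.array(
            [v for v in self.postorder() if self.children[v] and v != self.root],
            dtype=np.intp,
        )

    def postorder(self) -> list:
        order, stack = [], [(self.root, False)]
        while stack:
            v, done = stack.pop()
            if done:
                order.append(v)
            else:
                stack.append((v, True))
                for c in reversed(self.children[v]):
                    stack.append((c, False))
        return order

    def node_depths(self) -> np.ndarray:
        """Root-to-node path lengths (root depth 0)."""
        depth = np.zeros(self.n_nodes)
        for v in reversed(self.postorder()):  # preorder-ish: parents first
            if v != self.root:
                depth[v] = depth[self.parent[v]] + self.branch_length[v]
        return depth

    def leaf_sets(self) -> list:
        """Per-node sorted arrays of descendant-leaf *positions* (0..q-1)."""
        pos = {int(v): i for i, v in enumerate(self._leaves)}
        sets = [None] * self.n_nodes
        for v in self.postorder():
            if not self.children[v]:
                sets[v] = np.array([pos[int(v)]], dtype=np.intp)
            else:
                sets[v] = np.concatenate([sets[c] for c in self.children[v]])
        return sets

    def cophenetic_distances(self) -> np.ndarray:
        """Leaf-by-leaf patristic distance matrix, leaves in tree order."""
        q = self.n_leaves
        depth = self.node_depths()
        sets = self.leaf_sets()
        D = np.zeros((q, q))
        leaf_depth = depth[self._leaves]
        for v in self.postorder():
            kids = self.children[v]
            if not kids:
                continue
            for i in range(len(kids)):
                for j in range(i + 1, len(kids)):
                    a, b = sets[kids[i]], sets[kids[j]]
                    d = leaf_depth[a][:, None] + leaf_depth[b][None, :] - 2.0 * depth[v]
                    D[np.ix_(a, b)] = d
                    D[np.ix_(b, a)] = d.T
        return D

    def to_newick(self, label_suffix: Optional[dict] = None) -> str:
        """Serialize to Newick; ``label_suffix`` maps node label -> suffix tag."""
        suf = label_suffix or {}

        def fmt(v: int) -> str:
            lab = self.labels[v] or ""
            lab = lab + suf.get(lab, "")
            if self.children[v]:
                inner = ",".join(fmt(c) for c in self.children[v])
                s = f"({inner}){lab}"
            else:
                s = lab
            if v != self.root:
                s += f":{self.branch_length[v]:g}"
            return s

        return fmt(self.root) + ";"


def _from_dendropy(t: dendropy.Tree, allow_missing_lengths: bool) -> PhyloTree:
    if t.is_rooted is False:
        raise ValueError("tree is explicitly unrooted; a rooted phylogeny is required")
    nodes = list(t.preorder_node_iter())
    index = {id(nd): i for i, nd in enumerate(nodes)}
    parent = np.full(len(nodes), -1, dtype=np.intp)
    bl = np.full(len(nodes), np.nan)
    labels: list = [None] * len(nodes)
    children: list = [[] for _ in nodes]
    for i, nd in enumerate(nodes):
        if nd.parent_node is not None:
            p = index[id(nd.parent_node)]
            parent[i] = p
            children[p].append(i)
            if nd.edge.length is None:
                if not allow_missing_lengths:
                    raise ValueError(
                        "missing branch length in Newick input; pass "
                        "allow_missing_lengths=True to substitute 0"
                    )
                bl[i] = 0.0
            else:
                bl[i] = float(nd.edge.length)
        if nd.taxon is not None:
            labels[i] = nd.taxon.label
        elif nd.label is not None:
            labels[i] = nd.label
    return PhyloTree(parent=parent, branch_length=bl, labels=labels, children=children)


def parse_newick(newick: str, allow_missing_lengths: bool = False) -> PhyloTree:
    """Parse a rooted Newick string (multifurcations allowed)."""
    try:
        t = dendropy.Tree.get(
            data=newick,
            schema="newick",
            rooting="default-rooted",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as e:  # dendropy raises several error types
        raise ValueError(f"failed to parse Newick: {e}") from None
    return _from_dendropy(t, allow_missing_lengths)


def read_newick(path, allow_missing_lengths: bool = False) -> PhyloTree:
    """Read a rooted phylogeny with branch lengths from a Newick file."""
    with open(path) as fh:
        return parse_newick(fh.read(), allow_missing_lengths)


@dataclass
class ExtendedCountTable:
    """Counts for leaves plus internal (non-root) nodes.

    Columns: the ``q`` leaf OTUs first, in the order of the input count
    table, then the internal nodes in tree postorder.  ``node_index[k]`` is
    the tree-node index behind column ``k``.
    """

    counts: np.ndarray
    col_labels: list
    node_index: np.ndarray
    q: int
    tree: PhyloTree
    sample_ids: list

    @property
    def n(self) -> int:
        return self.counts.shape[0]

    @property
    def m(self) -> int:
        return self.counts.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.sample_ids, columns=self.col_labels)


@dataclass
class RelativeAbundanceTable:
    """Per-sample relative abundances of the extended OTUs.

    The denominator is the per-sample *leaf* total, so internal-node values
    can exceed any single leaf's but never exceed 1.
    """

    values: np.ndarray
    col_labels: list
    node_index: np.ndarray
    q: int
    tree: PhyloTree
    sample_ids: list


@dataclass
class AbundanceRepresentation:
    """One abundance transform ``M`` plus its weight vector ``omega``."""

    kind: str
    M: np.ndarray
    omega: np.ndarray
    col_labels: list
    node_index: np.ndarray


def _internal_label(tree: PhyloTree, v: int, used: set) -> str:
    lab = tree.labels[v]
    if lab is None or lab in used:
        lab = f"node{v}"
    return lab


def build_extended_table(leaf_counts, tree: PhyloTree) -> ExtendedCountTable:
    """Augment a sample-by-leaf count table with internal-node columns.

    ``leaf_counts`` is a DataFrame (rows = samples, columns = leaf OTU IDs
    matching the tree's leaf labels; order may differ — matched by name).
    Each internal column is the sum over its descendant leaves; the root is
    excluded.
    """
    if not isinstance(leaf_counts, pd.DataFrame):
        leaf_counts = pd.DataFrame(np.asarray(leaf_counts), columns=tree.leaf_labels)
    table_labels = [str(c) for c in leaf_counts.columns]
    tree_labels = tree.leaf_labels
    missing = sorted(set(table_labels) ^ set(tree_labels))
    if len(set(table_labels)) != len(table_labels):
        raise ValueError("duplicate OTU column labels in count table")
    if missing:
        raise ValueError(
            f"count-table columns and tree leaves disagree on: {missing[:10]}"
        )
    X_leaf = leaf_counts.to_numpy()
    if not np.issubdtype(X_leaf.dtype, np.number):
        raise ValueError("counts must be numeric")
    if np.any(X_leaf < 0) or np.any(X_leaf != np.floor(X_leaf)):
        raise ValueError("counts must be non-negative integers")
    X_leaf = X_leaf.astype(np.int64)
    n, q = X_leaf.shape

    # leaf columns keep the count-table order (canonical across samples)
    col_of_label = {lab: j for j, lab in enumerate(table_labels)}
    leaf_node_for_col = np.empty(q, dtype=np.intp)
    for v, lab in zip(tree.leaves, tree_labels):
        leaf_node_for_col[col_of_label[lab]] = v

    internal = tree.internal_nonroot()
    m = q + internal.size
    X = np.zeros((n, m), dtype=np.int64)
    X[:, :q] = X_leaf

    # accumulate internal counts bottom-up over descendant-leaf positions
    sets = tree.leaf_sets()
    leafpos_to_col = np.empty(tree.n_leaves, dtype=np.intp)
    for j in range(q):
        v = leaf_node_for_col[j]
        leafpos_to_col[np.flatnonzero(tree.leaves == v)[0]] = j
    labels = list(table_labels)
    used = set(labels)
    node_index = np.concatenate([leaf_node_for_col, internal])
    for t, v in enumerate(internal):
        cols = leafpos_to_col[sets[v]]
        X[:, q + t] = X_leaf[:, cols].sum(axis=1)
        lab = _internal_label(tree, int(v), used)
        labels.append(lab)
        used.add(lab)
    return ExtendedCountTable(
        counts=X,
        col_labels=labels,
        node_index=node_index,
        q=q,
        tree=tree,
        sample_ids=list(leaf_counts.index),
    )


def relative_abundance(ext: ExtendedCountTable) -> RelativeAbundanceTable:
    """Divide every extended count by the sample's leaf-count total."""
    leaf_tot = ext.counts[:, : ext.q].sum(axis=1)
    if np.any(leaf_tot == 0):
        bad = [ext.sample_ids[i] for i in np.flatnonzero(leaf_tot == 0)]
        raise ValueError(f"samples with zero leaf total: {bad[:10]}")
    A = ext.counts / leaf_tot[:, None]
    return RelativeAbundanceTable(
        values=A,
        col_labels=ext.col_labels,
        node_index=ext.node_index,
        q=ext.q,
        tree=ext.tree,
        sample_ids=ext.sample_ids,
    )


def compute_weights(M: np.ndarray, tree: Optional[PhyloTree], kind: str,
                    node_index: Optional[np.ndarray] = None) -> np.ndarray:
    """UniFrac-like taxon weights.

    For the tree-aware transforms (``u``/``w``/``.5``) the weight of column
    ``k`` is ``SD(M[:, k]) * b_k`` with ``b_k`` the length of the branch
    leading to the node; for the leaf-only transform (``a``) it is the SD
    alone.  SD is the sample standard deviation (n-1 denominator).
    """
    sd = np.std(np.asarray(M, dtype=float), axis=0, ddof=1)
    if kind == "a":
        return sd
    if kind not in MEASURES:
        raise ValueError(f"unknown representation kind: {kind!r}")
    if tree is None or node_index is None:
        raise ValueError("tree and node_index required for tree-aware weights")
    return sd * tree.branch_length[node_index]


def make_representation(A: RelativeAbundanceTable, kind: str) -> AbundanceRepresentation:
    """Build one of the four abundance transforms with its weights."""
    if kind == "u":
        M = (A.values > 0).astype(float)
        cols = slice(None)
    elif kind == "w":
        M = A.values.copy()
        cols = slice(None)
    elif kind == ".5":
        M = np.sqrt(A.values)
        cols = slice(None)
    elif kind == "a":
        M = A.values[:, : A.q].copy()
        cols = slice(0, A.q)
    else:
        raise ValueError(f"unknown representation kind: {kind!r}")
    labels = A.col_labels[cols] if isinstance(cols, slice) else A.col_labels
    node_index = A.node_index[cols]
    omega = compute_weights(M, A.tree, kind, node_index)
    return AbundanceRepresentation(
        kind=kind, M=M, omega=omega, col_labels=list(labels), node_index=node_index
    )
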