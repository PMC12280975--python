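"""Phylogeny I/O and the Brownian-motion variance-covariance matrix.

A rooted, branch-length-annotated tree induces the covariance structure of a
trait evolving by Brownian motion: ``V[i, j]`` is the branch length shared by
the root-to-tip paths of tips *i* and *j* (the depth of their most recent
common ancestor), and ``V[i, i]`` is the root-to-tip depth of tip *i*.  This
module reads/writes newick, prunes trees to the analyzed taxa, builds ``V``
and rescales it onto prior-friendly scales.

Parsing and pruning are delegated to :mod:`dendropy`; the covariance
construction is local because it is the quantity everything downstream
consumes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import dendropy
import numpy as np

from .errors import (
    DegenerateTreeError,
    NewickFormatError,
    TaxonLookupError,
    TreeValidationError,
)

__all__ = [
    "PhyloTree",
    "PhyloCovariance",
    "read_newick",
    "write_newick",
    "prune_to_taxa",
    "phylo_vcv",
    "normalize_vcv",
    "normalize_label",
]


def normalize_label(label: str) -> str:
    """Canonical taxon label: spaces to underscores, case-folded.

    Species names arrive with spaces or underscores inconsistently across
    sources; data tables and trees are joined on this normalized form.
    """
    return label.strip().replace(" ", "_").casefold()


@dataclass(frozen=True)
class PhyloTree:
    """A rooted phylogeny with unique tip labels and nonnegative branch lengths.

    Thin immutable wrapper around a :class:`dendropy.Tree`; all mutating
    operations return a new instance.
    """

    _tree: dendropy.Tree = field(repr=False)

    def __post_init__(self):
        tips = [leaf.taxon.label if leaf.taxon else None
                for leaf in self._tree.leaf_node_iter()]
        if any(t is None for t in tips):
            raise TreeValidationError("tree contains unlabeled tips")
        if len(tips) < 2:
            raise TreeValidationError(f"tree must have >= 2 tips, got {len(tips)}")
        if len(set(tips)) != len(tips):
            dupes = sorted({t for t in tips if tips.count(t) > 1})
            raise TreeValidationError(f"duplicate tip labels: {', '.join(dupes)}")
        for edge in self._tree.preorder_edge_iter():
            if edge.tail_node is None:
                continue  # root edge; length may be absent
            ln = edge.length
            if ln is None:
                raise TreeValidationError(
                    f"edge above {_node_name(edge.head_node)} has no branch length")
            if not math.isfinite(ln) or ln < 0:
                raise TreeValidationError(
                    f"edge above {_node_name(edge.head_node)} has invalid length {ln!r}")

    # ------------------------------------------------------------------
    @property
    def tips(self) -> list[str]:
        """Tip labels in the tree's leaf-iteration order."""
        return [leaf.taxon.label for leaf in self._tree.leaf_node_iter()]

    @property
    def n_tips(self) -> int:
        return len(self._tree.leaf_nodes())

    def tip_depths(self) -> dict[str, float]:
        """Root-to-tip path length for every tip."""
        depths: dict[str, float] = {}
        for node in self._tree.preorder_node_iter():
            # the root's own edge, if present, is a stem (e.g. left by
            # pruning) and counts toward every root-to-tip path
            parent_depth = getattr(node.parent_node, "_pd_depth", 0.0) \
                if node.parent_node is not None else 0.0
            node._pd_depth = parent_depth + (node.edge.length or 0.0)
            if node.is_leaf():
                depths[node.taxon.label] = node._pd_depth
        return depths

    def depth(self) -> float:
        """Maximum root-to-tip depth."""
        return max(self.tip_depths().values())

    def to_newick(self) -> str:
        return self._tree.as_string(schema="newick",
                                    suppress_rooting=True).strip()

    def copy(self) -> "PhyloTree":
        return PhyloTree(self._tree.clone(depth=1))

    # dendropy access for simulation utilities
    @property
    def dendropy_tree(self) -> dendropy.Tree:
        return self._tree


def _node_name(node) -> str:
    if node.taxon is not None:
        return node.taxon.label
    return node.label or "<internal>"


def read_newick(text: str) -> PhyloTree:
    """Parse a single newick (or single-tree NEXUS) string into a tree.

    Accepts quoted labels, bracket comments and scientific-notation branch
    lengths; underscores in unquoted labels are preserved verbatim.
    """
    schema = "nexus" if text.lstrip()[:6].upper() == "#NEXUS" else "newick"
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema=schema,
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises assorted error types
        if "Duplicate taxon labels" in str(exc):
            raise TreeValidationError(f"duplicate tip labels: {exc}") from exc
        raise NewickFormatError(f"could not parse {schema}: {exc}") from exc
    return PhyloTree(tree)


def write_newick(tree: PhyloTree) -> str:
    """Serialize a tree to a newick string (one tree, trailing semicolon)."""
    return tree.to_newick()


def prune_to_taxa(tree: PhyloTree, keep) -> PhyloTree:
    """Restrict a tree to the tips in ``keep``.

    Root-to-tip depths of retained tips are unchanged; internal nodes left
    with a single child are collapsed with their branch lengths summed.
    """
    keep = set(keep)
    missing = keep - set(tree.tips)
    if missing:
        raise TaxonLookupError(missing)
    if len(keep) < 2:
        raise TreeValidationError("pruning must retain >= 2 tips")
    pruned = tree.dendropy_tree.extract_tree_with_taxa_labels(
        labels=keep, suppress_unifurcations=False)
    # collapse degree-2 internal nodes by summing edge lengths; the root is
    # kept even if unifurcating so root-to-tip depths are preserved exactly
    for node in list(pruned.preorder_node_iter()):
        parent = node.parent_node
        if parent is None or node.is_leaf():
            continue
        children = node.child_nodes()
        if len(children) == 1:
            child = children[0]
            child.edge.length = ((child.edge.length or 0.0)
                                 + (node.edge.length or 0.0))
            parent.remove_child(node)
            parent.add_child(child)
    return PhyloTree(pruned)


@dataclass(frozen=True)
class PhyloCovariance:
    """Ordered taxon labels with the Brownian-motion covariance matrix ``V``.

    Invariants: ``V`` symmetric positive semidefinite, ``V[i, i]`` equals the
    root-to-tip depth of tip *i*, off-diagonals never exceed either diagonal.
    """

    labels: tuple[str, ...]
    matrix: np.ndarray

    def __post_init__(self):
        V = np.asarray(self.matrix, dtype=float)
        object.__setattr__(self, "matrix", V)
        n = len(self.labels)
        if V.shape != (n, n):
            raise ValueError(f"matrix shape {V.shape} does not match {n} labels")
        if not np.allclose(V, V.T, rtol=0.0, atol=1e-12):
            raise ValueError("covariance matrix is not symmetric")

    @property
    def n(self) -> int:
        return len(self.labels)

    def index_of(self, labels) -> np.ndarray:
        pos = {lab: i for i, lab in enumerate(self.labels)}
        missing = [lab for lab in labels if lab not in pos]
        if missing:
            raise TaxonLookupError(missing)
        return np.array([pos[lab] for lab in labels], dtype=int)

    def subset(self, labels) -> "PhyloCovariance":
        """Row/column subset in the given label order."""
        idx = self.index_of(labels)
        return PhyloCovariance(tuple(labels), self.matrix[np.ix_(idx, idx)])


def phylo_vcv(tree: PhyloTree) -> PhyloCovariance:
    """Brownian-motion covariance: shared root-to-tip branch length per pair.

    Computed in one postorder sweep: every edge of length *l* adds *l* to
    ``V[i, j]`` for all pairs of tips below it.
    """
    dtree = tree.dendropy_tree
    leaves = list(dtree.leaf_node_iter())
    labels = tuple(leaf.taxon.label for leaf in leaves)
    index = {id(leaf): i for i, leaf in enumerate(leaves)}
    n = len(leaves)
    V = np.zeros((n, n))
    for node in dtree.postorder_node_iter():
        if node.is_leaf():
            node._pd_below = np.array([index[id(node)]], dtype=int)
        else:
            node._pd_below = np.concatenate([c._pd_below for c in node.child_nodes()])
        ln = node.edge.length or 0.0
        if ln < 0:
            raise TreeValidationError(f"negative branch length {ln}")
        # a root stem (edge above the seed node) is shared by every tip
        idx = node._pd_below
        V[np.ix_(idx, idx)] += ln
    V = 0.5 * (V + V.T)  # exact symmetry regardless of accumulation order
    return PhyloCovariance(labels, V)


def normalize_vcv(cov: PhyloCovariance, mode: str = "correlation") -> PhyloCovariance:
    """Rescale a phylogenetic covariance onto a unit scale.

    ``unit_depth`` divides the whole matrix by ``max(diag(V))`` (preserves
    relative tip depths on non-ultrametric trees); ``correlation`` divides
    ``V[i, j]`` by ``sqrt(V[i, i] * V[j, j])`` so the diagonal is exactly 1.
    Both preserve symmetry and positive semidefiniteness.
    """
    V = cov.matrix
    d = np.diag(V)
    if np.any(d <= 0):
        bad = [cov.labels[i] for i in np.where(d <= 0)[0]]
        raise DegenerateTreeError(
            f"zero root-to-tip depth for: {', '.join(bad)}")
    if mode == "unit_depth":
        out = V / d.max()
    elif mode == "correlation":
        s = np.sqrt(d)
        out = V / np.outer(s, s)
        np.fill_diagonal(out, 1.0)
    else:
        raise ValueError(f"unknown normalization mode {mode!r}")
    return PhyloCovariance(cov.labels, 0.5 * (out + out.T))
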