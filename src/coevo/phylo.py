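"""Rooted time trees and the phylogenetic covariance structure.

Under Brownian-Motion trait evolution on a rooted tree with branch lengths in
time units, the covariance of trait values between two tips equals the
trait's rate times the shared path length from the root to their most recent
common ancestor.  This module reads Newick trees, validates them, and builds
that species covariance matrix C, which every model fit downstream consumes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "Phylogeny",
    "SpeciesCovariance",
    "read_newick",
    "vcv",
    "prune",
    "TreeFormatError",
]

#: relative tolerance for declaring a tree ultrametric
ULTRAMETRIC_RTOL = 1e-6


class TreeFormatError(ValueError):
    """Raised when a Newick file cannot be interpreted as a valid time tree."""


@dataclass
class Phylogeny:
    """A rooted tree with nonnegative branch lengths in time units.

    Parameters
    ----------
    tree : dendropy.Tree
        The underlying tree. Branch lengths are required on every edge
        except, optionally, the root edge (ignored).

    Attributes
    ----------
    tip_labels : list of str
        Tip labels in preorder traversal order (the canonical ordering used
        everywhere in this package).
    root_height : float
        Maximum root-to-tip path length.
    is_ultrametric : bool
        True iff all root-to-tip path lengths agree within relative
        tolerance ``ULTRAMETRIC_RTOL``.
    """

    tree: dendropy.Tree
    tip_labels: list = field(init=False)
    root_height: float = field(init=False)
    is_ultrametric: bool = field(init=False)

    def __post_init__(self):
        self._validate()

    def _validate(self):
        leaves = [nd for nd in self.tree.preorder_node_iter() if nd.is_leaf()]
        if len(leaves) < 2:
            raise TreeFormatError("tree must have at least 2 tips")
        labels = []
        for lf in leaves:
            if lf.taxon is None or not (lf.taxon.label or "").strip():
                raise TreeFormatError("every tip must carry a nonempty label")
            labels.append(lf.taxon.label)
        if len(set(labels)) != len(labels):
            raise TreeFormatError("tip labels must be unique")
        root = self.tree.seed_node
        for nd in self.tree.preorder_node_iter():
            if nd is root:
                continue
            if nd.edge.length is None:
                raise TreeFormatError(
                    "missing branch length on edge above %r" % _node_name(nd)
                )
            if nd.edge.length < 0:
                raise TreeFormatError("negative branch length above %r" % _node_name(nd))
        depths = self._tip_depths()
        self.tip_labels = labels
        self.root_height = float(max(depths.values()))
        dmin, dmax = min(depths.values()), max(depths.values())
        self.is_ultrametric = (dmax - dmin) <= ULTRAMETRIC_RTOL * max(dmax, 1e-300)

    def _tip_depths(self):
        depths = {}
        self.tree.seed_node._coevo_depth = 0.0
        for nd in self.tree.preorder_node_iter():
            if nd is not self.tree.seed_node:
                nd._coevo_depth = nd.parent_node._coevo_depth + nd.edge.length
            if nd.is_leaf():
                depths[nd.taxon.label] = nd._coevo_depth
        return depths

    @property
    def n_tips(self) -> int:
        return len(self.tip_labels)

    def newick(self) -> str:
        return self.tree.as_string(schema="newick", suppress_rooting=True).strip()

    def write_newick(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.newick() + "\n")


def _node_name(nd):
    return nd.taxon.label if nd.taxon is not None else "<internal>"


@dataclass
class SpeciesCovariance:
    """Phylogenetic covariance matrix: C[i, j] = depth of MRCA(i, j).

    Symmetric positive semidefinite; the diagonal holds root-to-tip depths.
    ``species`` fixes the row/column order (preorder tip order of the source
    tree).
    """

    matrix: np.ndarray
    species: list

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.species)
        if self.matrix.shape != (n, n):
            raise ValueError("covariance matrix shape does not match species list")
        if not np.allclose(self.matrix, self.matrix.T):
            raise ValueError("covariance matrix must be symmetric")

    @property
    def n(self) -> int:
        return len(self.species)

    def subset(self, keep) -> "SpeciesCovariance":
        """Submatrix restricted to ``keep``, preserving the current order."""
        keep = set(keep)
        idx = [i for i, s in enumerate(self.species) if s in keep]
        missing = keep - set(self.species)
        if missing:
            raise KeyError("unknown species: %s" % sorted(missing))
        return SpeciesCovariance(
            self.matrix[np.ix_(idx, idx)], [self.species[i] for i in idx]
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.species, columns=self.species)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t")


def read_newick(path) -> Phylogeny:
    """Read a rooted tree from a Newick file.

    Dialect: trailing semicolon required, branch lengths required on all
    edges except optionally the root edge; internal node labels are ignored.
    Non-ultrametric trees are accepted with a warning.
    """
    with open(path) as fh:
        text = fh.read()
    if not text.strip():
        raise TreeFormatError("empty Newick file: %s" % path)
    if not text.strip().endswith(";"):
        raise TreeFormatError("Newick string must end with ';'")
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise TreeFormatError("could not parse Newick file %s: %s" % (path, exc))
    phylo = Phylogeny(tree)
    if not phylo.is_ultrametric:
        warnings.warn(
            "tree is not ultrametric (root-to-tip depths differ); "
            "Brownian-Motion fits remain valid but depths enter C as given",
            UserWarning,
            stacklevel=2,
        )
    return phylo


def vcv(phylo: Phylogeny) -> SpeciesCovariance:
    """Species covariance matrix under unit-rate Brownian Motion.

    C[i, i] is the root-to-tip depth of tip i and C[i, j] the depth of the
    most recent common ancestor of tips i and j. Species order is the
    preorder tip order of the tree.
    """
    labels = phylo.tip_labels
    idx = {lab: i for i, lab in enumerate(labels)}
    n = len(labels)
    C = np.zeros((n, n))
    phylo._tip_depths()  # refresh _coevo_depth annotations
    for nd in phylo.tree.postorder_node_iter():
        if nd.is_leaf():
            i = idx[nd.taxon.label]
            nd._coevo_tips = [i]
            C[i, i] = nd._coevo_depth
        else:
            groups = [ch._coevo_tips for ch in nd.child_nodes()]
            d = nd._coevo_depth
            for gi in range(len(groups)):
                for gj in range(gi + 1, len(groups)):
                    for a in groups[gi]:
                        for b in groups[gj]:
                            C[a, b] = C[b, a] = d
            nd._coevo_tips = [t for g in groups for t in g]
    return SpeciesCovariance(C, list(labels))


def prune(phylo: Phylogeny, keep) -> Phylogeny:
    """Induced subtree on the tips in ``keep``.

    Degree-2 internal nodes created by the pruning are collapsed with their
    branch lengths summed, so path lengths among retained tips are preserved.
    """
    keep = list(dict.fromkeys(keep))
    unknown = set(keep) - set(phylo.tip_labels)
    if unknown:
        raise KeyError("unknown tip labels: %s" % sorted(unknown))
    if len(keep) < 2:
        raise ValueError("need at least 2 tips to prune to")
    keep_set = set(keep)
    sub = dendropy.Tree(phylo.tree)  # deep clone sharing the taxon namespace
    # drop unkept leaves, repeating until no further leaves appear
    changed = True
    while changed:
        changed = False
        for nd in list(sub.leaf_node_iter()):
            lab = nd.taxon.label if nd.taxon is not None else None
            if lab not in keep_set:
                nd.parent_node.remove_child(nd)
                changed = True
    # collapse non-root degree-2 nodes, summing branch lengths; a root left
    # with a single child keeps that edge so root-to-MRCA depth is preserved
    for nd in list(sub.postorder_node_iter()):
        if nd is sub.seed_node or nd.is_leaf():
            continue
        children = nd.child_nodes()
        if len(children) == 1:
            child = children[0]
            child.edge.length = (child.edge.length or 0.0) + (nd.edge.length or 0.0)
            parent = nd.parent_node
            pos = parent.child_nodes().index(nd)
            parent.remove_child(nd)
            parent.insert_child(pos, child)  # preserve preorder tip order
    return Phylogeny(sub)
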