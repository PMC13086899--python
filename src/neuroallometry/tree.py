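"""Rooted phylogenies and the Brownian-motion covariance they induce.

A rooted tree with branch lengths defines, for every pair of tip species,
the amount of evolutionary history they share: the path length from the
root to their most recent common ancestor.  Under a Brownian-motion model
of trait evolution this shared history is exactly the covariance between
the two species' trait values, so the tree maps to an n x n
variance-covariance matrix C with C[i, i] the root-to-tip depth of
species i and C[i, j] the root-to-MRCA depth of the pair.  Every
downstream statistic in this package (generalized least squares,
Blomberg's K) is a function of C.

Trees are stored as thin wrappers around :class:`dendropy.Tree`; Newick
is the only interchange format.  The stem edge of the root, if present,
is ignored when computing depths and covariances, following the usual
comparative-methods convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np

__all__ = [
    "PhyloTree",
    "PhyloCovariance",
    "NewickParseError",
    "TreeValidationError",
    "normalize_label",
]


class NewickParseError(ValueError):
    """Raised when a Newick string cannot be parsed."""


class TreeValidationError(ValueError):
    """Raised when a parsed tree violates a structural requirement."""


def normalize_label(label: str) -> str:
    """Canonical species label: stripped, with spaces mapped to underscores.

    Used everywhere tip labels are matched against table rows, so
    ``"Noctua pronuba"`` and ``" Noctua_pronuba "`` refer to the same
    species.
    """
    return "_".join(str(label).strip().split())


@dataclass
class PhyloCovariance:
    """Brownian-motion variance-covariance structure of a tree.

    Attributes
    ----------
    species : list of str
        Tip labels, fixing the row/column order of ``matrix``.
    matrix : ndarray, shape (n, n)
        ``matrix[i, j]`` is the root-to-MRCA path length of tips i and j;
        the diagonal holds root-to-tip depths.  Symmetric and positive
        semi-definite by construction.
    """

    species: list[str]
    matrix: np.ndarray

    @property
    def depths(self) -> np.ndarray:
        return np.diag(self.matrix).copy()

    def submatrix(self, keep: list[str]) -> "PhyloCovariance":
        idx = [self.species.index(s) for s in keep]
        return PhyloCovariance(list(keep), self.matrix[np.ix_(idx, idx)])


class PhyloTree:
    """A rooted phylogeny with branch lengths on every edge."""

    def __init__(self, dtree: dendropy.Tree):
        self._tree = dtree
        self._validate()

    # ------------------------------------------------------------------ I/O

    @classmethod
    def from_newick(cls, text: str, default_branch_length: float | None = None) -> "PhyloTree":
        """Parse a Newick string.

        Parameters
        ----------
        text : str
            A single Newick tree with branch lengths on all edges.
        default_branch_length : float, optional
            If given, edges lacking a length are assigned this value
            instead of being rejected.
        """
        try:
            dtree = dendropy.Tree.get(
                data=text,
                schema="newick",
                preserve_underscores=True,
                suppress_internal_node_taxa=True,
            )
        except Exception as exc:  # dendropy raises several error classes
            if "duplicate" in str(exc).lower():
                raise TreeValidationError(f"duplicate tip label: {exc}") from exc
            offset = getattr(exc, "col_num", None)
            where = f" near character {offset}" if offset is not None else ""
            raise NewickParseError(f"malformed Newick string{where}: {exc}") from exc
        dtree.is_rooted = True
        for edge in dtree.preorder_edge_iter():
            if edge.head_node is dtree.seed_node:
                continue  # stem edge may be absent
            if edge.length is None:
                if default_branch_length is None:
                    raise TreeValidationError(
                        "edge without branch length (set default_branch_length to allow)"
                    )
                edge.length = default_branch_length
        return cls(dtree)

    def to_newick(self) -> str:
        s = self._tree.as_string(schema="newick", suppress_rooting=True,
                                 unquoted_underscores=True)
        return s.strip()

    # ----------------------------------------------------------- validation

    def _validate(self) -> None:
        labels = self.tip_labels
        if len(labels) < 2:
            raise TreeValidationError("tree must have at least 2 tips")
        if any(not lbl for lbl in labels):
            raise TreeValidationError("empty tip label")
        if len(set(labels)) != len(labels):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise TreeValidationError(f"duplicate tip labels: {dupes}")
        zero_terminal = []
        for node in self._tree.preorder_node_iter():
            if node is self._tree.seed_node:
                continue
            bl = node.edge.length
            if bl is None or not np.isfinite(bl) or bl < 0:
                raise TreeValidationError(
                    f"branch length {bl!r} on edge above "
                    f"{node.taxon.label if node.taxon else 'internal node'}"
                )
            if bl == 0 and node.is_leaf():
                zero_terminal.append(node.taxon.label)
        if zero_terminal:
            warnings.warn(
                f"zero-length terminal branches ({zero_terminal}); the "
                "covariance matrix may be singular if such tips also share "
                "all internal history",
                stacklevel=3,
            )

    # ----------------------------------------------------------- properties

    @property
    def tip_labels(self) -> list[str]:
        return [leaf.taxon.label for leaf in self._tree.leaf_node_iter()]

    @property
    def n_tips(self) -> int:
        return len(self._tree.leaf_nodes())

    def tip_depths(self) -> dict[str, float]:
        """Root-to-tip path length per tip (stem edge excluded)."""
        depths = {}
        for leaf, d in self._node_depths().items():
            if leaf.is_leaf():
                depths[leaf.taxon.label] = d
        return depths

    def is_ultrametric(self, tol: float = 1e-8) -> bool:
        d = np.array(list(self.tip_depths().values()))
        return bool(np.ptp(d) <= tol * max(d.max(), 1.0))

    def _node_depths(self) -> dict:
        depths = {self._tree.seed_node: 0.0}
        for node in self._tree.preorder_node_iter():
            if node is self._tree.seed_node:
                continue
            depths[node] = depths[node.parent_node] + node.edge.length
        return depths

    # ----------------------------------------------------------- operations

    def substitute_tips(self, mapping: dict[str, str]) -> "PhyloTree":
        """Rename tips, leaving topology and branch lengths untouched.

        The study practice this supports: when a species is absent from a
        published phylogeny, it is placed by relabelling its closest
        relative's tip.
        """
        labels = set(self.tip_labels)
        missing = sorted(set(mapping) - labels)
        if missing:
            raise TreeValidationError(f"tips not in tree: {missing}")
        remaining = labels - set(mapping)
        collisions = sorted(set(mapping.values()) & remaining)
        if collisions:
            raise TreeValidationError(f"new labels collide with existing tips: {collisions}")
        if len(set(mapping.values())) != len(mapping):
            raise TreeValidationError("mapping assigns the same new label twice")
        new = self._tree.clone(depth=1)
        new.taxon_namespace = dendropy.TaxonNamespace()
        for leaf in new.leaf_node_iter():
            old = leaf.taxon.label
            leaf.taxon = new.taxon_namespace.new_taxon(mapping.get(old, old))
        return PhyloTree(new)

    def prune_to(self, keep) -> "PhyloTree":
        """Restrict the tree to a subset of tips.

        Pairwise path lengths between retained tips are preserved;
        internal nodes left with a single child are collapsed and their
        branch lengths summed.
        """
        keep = set(keep)
        labels = set(self.tip_labels)
        unknown = sorted(keep - labels)
        if unknown:
            raise TreeValidationError(f"tips not in tree: {unknown}")
        if len(keep) < 2:
            raise TreeValidationError("must keep at least 2 tips")
        new = self._tree.clone(depth=1)
        new.retain_taxa_with_labels(sorted(keep))
        new.seed_node.edge.length = None  # drop accumulated stem length
        return PhyloTree(new)

    def vcv(self) -> PhyloCovariance:
        """Brownian-motion variance-covariance matrix of the tips.

        Computed in one postorder sweep: every internal node sets the
        covariance of all tip pairs whose MRCA it is to its own depth.
        Polytomies need no special handling.
        """
        depths = self._node_depths()
        leaves = list(self._tree.leaf_node_iter())
        labels = [lf.taxon.label for lf in leaves]
        index = {lf: i for i, lf in enumerate(leaves)}
        n = len(leaves)
        C = np.zeros((n, n))
        tipsets: dict = {}
        for node in self._tree.postorder_node_iter():
            if node.is_leaf():
                i = index[node]
                C[i, i] = depths[node]
                tipsets[node] = [i]
            else:
                children = [tipsets.pop(ch) for ch in node.child_nodes()]
                d = depths[node]
                for a in range(len(children)):
                    for b in range(a + 1, len(children)):
                        for i in children[a]:
                            for j in children[b]:
                                C[i, j] = C[j, i] = d
                merged = [i for grp in children for i in grp]
                tipsets[node] = merged
        return PhyloCovariance(labels, C)

    def __repr__(self) -> str:  # pragma: no cover
        return f"PhyloTree(n_tips={self.n_tips})"
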