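"""Phylogenetic tree container, Newick I/O, bipartitions and Robinson–Foulds distance.

Trees are stored internally as :class:`dendropy.Tree` objects but are always
interpreted as *unrooted* topologies for comparison purposes: metrics operate
on the set of nontrivial bipartitions (splits), which is invariant to the
rooting used for storage.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field

import dendropy
import numpy as np

__all__ = [
    "PhyloTree",
    "DistanceMatrix",
    "NewickError",
    "parse_newick",
    "write_newick",
    "bipartitions",
    "rf_distance",
    "patristic_distances",
]

_LABEL_RE = re.compile(r"^[A-Za-z0-9_.\-]+$")


class NewickError(ValueError):
    """Raised for malformed Newick input (unbalanced parentheses, duplicate labels...)."""


class PhyloTree:
    """A phylogenetic tree with labelled leaves and optional branch lengths.

    The tree may be stored with a bifurcating or trifurcating root; all
    topology comparisons unroot it first.  Leaf labels must be unique,
    nonempty, and drawn from the dialect ``[A-Za-z0-9_.-]``.
    """

    def __init__(self, dtree: dendropy.Tree):
        self._tree = dtree
        self._validate()

    # -- construction -------------------------------------------------------

    @classmethod
    def from_newick(cls, text: str) -> "PhyloTree":
        try:
            dtree = dendropy.Tree.get(
                data=text,
                schema="newick",
                preserve_underscores=True,
                suppress_internal_node_taxa=True,
            )
        except Exception as exc:  # dendropy raises several parse error types
            raise NewickError(f"malformed Newick: {exc}") from exc
        return cls(dtree)

    def _validate(self) -> None:
        labels = [leaf.taxon.label if leaf.taxon else None
                  for leaf in self._tree.leaf_node_iter()]
        if any(lab is None or lab == "" for lab in labels):
            raise NewickError("every leaf must carry a nonempty label")
        dupes = {lab for lab in labels if labels.count(lab) > 1}
        if dupes:
            raise NewickError(f"duplicate leaf labels: {sorted(dupes)}")
        bad = [lab for lab in labels if not _LABEL_RE.match(lab)]
        if bad:
            raise NewickError(f"labels outside [A-Za-z0-9_.-]: {bad}")
        for edge in self._tree.preorder_edge_iter():
            if edge.length is not None and edge.length < 0:
                raise NewickError(f"negative branch length on edge above "
                                  f"{_node_name(edge.head_node)}")

    def copy(self) -> "PhyloTree":
        return PhyloTree(self._tree.clone(depth=1))

    # -- basic queries -------------------------------------------------------

    @property
    def dendropy_tree(self) -> dendropy.Tree:
        return self._tree

    @property
    def leaf_labels(self) -> list[str]:
        return [leaf.taxon.label for leaf in self._tree.leaf_node_iter()]

    @property
    def n_leaves(self) -> int:
        return sum(1 for _ in self._tree.leaf_node_iter())

    def has_branch_lengths(self) -> bool:
        return all(e.length is not None
                   for e in self._tree.preorder_edge_iter()
                   if e.head_node.parent_node is not None)

    # -- I/O -----------------------------------------------------------------

    def to_newick(self) -> str:
        s = self._tree.as_string(
            schema="newick",
            suppress_rooting=True,
            unquoted_underscores=True,
            suppress_internal_node_labels=True,
        ).strip()
        return s

    # -- topology ------------------------------------------------------------

    def bipartitions(self) -> frozenset[frozenset[str]]:
        """Nontrivial splits as a set of leaf-label sets (canonical side).

        Each split is stored as the smaller side; ties broken lexicographically.
        A binary unrooted tree on N leaves yields exactly N-3 splits; trees with
        fewer than 4 leaves yield the empty set.
        """
        universe = frozenset(self.leaf_labels)
        splits: set[frozenset[str]] = set()
        for node in self._tree.postorder_node_iter():
            if node.is_leaf() or node.parent_node is None:
                continue
            below = frozenset(lf.taxon.label for lf in node.leaf_iter())
            if len(below) < 2 or len(universe - below) < 2:
                continue
            splits.add(_canonical_side(below, universe))
        return frozenset(splits)

    def __repr__(self) -> str:  # pragma: no cover
        return f"PhyloTree(n_leaves={self.n_leaves})"


def _node_name(node) -> str:
    return node.taxon.label if node.taxon else "<internal>"


def _canonical_side(side: frozenset[str], universe: frozenset[str]) -> frozenset[str]:
    other = universe - side
    if len(side) < len(other):
        return side
    if len(other) < len(side):
        return other
    return side if sorted(side) < sorted(other) else other


# -- module-level operations ------------------------------------------------


def parse_newick(text: str) -> PhyloTree:
    """Parse a Newick string into a :class:`PhyloTree`."""
    return PhyloTree.from_newick(text)


def write_newick(tree: PhyloTree) -> str:
    """Serialize a tree to Newick (branch lengths included when present)."""
    return tree.to_newick()


def bipartitions(tree: PhyloTree) -> frozenset[frozenset[str]]:
    return tree.bipartitions()


def rf_distance(t1: PhyloTree, t2: PhyloTree) -> tuple[int, float]:
    """Robinson–Foulds distance between two trees on the same leaf set.

    Returns ``(raw, normalized)`` where raw counts splits unique to either
    tree and normalized divides by ``2(N-3)``, the maximum attainable for two
    binary trees, giving a value in [0, 1] (0 for trees with N <= 3 leaves).
    """
    l1, l2 = set(t1.leaf_labels), set(t2.leaf_labels)
    if l1 != l2:
        raise ValueError(
            f"leaf sets differ: only in first={sorted(l1 - l2)}, "
            f"only in second={sorted(l2 - l1)}")
    b1, b2 = t1.bipartitions(), t2.bipartitions()
    raw = len(b1 ^ b2)
    n = len(l1)
    denom = 2 * (n - 3)
    norm = raw / denom if denom > 0 else 0.0
    return raw, norm


@dataclass
class DistanceMatrix:
    """Symmetric leaf-to-leaf distance matrix in substitutions/site."""

    labels: list[str]
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError(f"matrix shape {self.values.shape} != ({n},{n})")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite distances")
        if np.any(self.values < 0):
            raise ValueError("negative distances")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("matrix not symmetric")
        if not np.allclose(np.diag(self.values), 0.0):
            raise ValueError("nonzero diagonal")

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i = self.labels.index(pair[0])
        j = self.labels.index(pair[1])
        return float(self.values[i, j])

    def to_tsv(self) -> str:
        out = io.StringIO()
        out.write("\t".join(self.labels) + "\n")
        for row in self.values:
            out.write("\t".join(f"{x:.10g}" for x in row) + "\n")
        return out.getvalue()

    @classmethod
    def from_tsv(cls, text: str) -> "DistanceMatrix":
        lines = [ln for ln in text.strip().splitlines() if ln.strip()]
        labels = lines[0].split("\t")
        values = np.array([[float(x) for x in ln.split("\t")] for ln in lines[1:]])
        return cls(labels, values)


def patristic_distances(tree: PhyloTree) -> DistanceMatrix:
    """Sum of branch lengths along leaf-to-leaf paths (additive by construction)."""
    dtree = tree.dendropy_tree
    for edge in dtree.preorder_edge_iter():
        head = edge.head_node
        if head.parent_node is not None and edge.length is None:
            raise ValueError(f"missing branch length above {_node_name(head)}")
    pdm = dtree.phylogenetic_distance_matrix()
    labels = sorted(tree.leaf_labels)
    taxa = {t.label: t for t in dtree.taxon_namespace}
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = pdm.patristic_distance(taxa[labels[i]], taxa[labels[j]])
    return DistanceMatrix(labels, d)
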