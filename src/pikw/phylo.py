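"""Time-calibrated phylogenies: parsing, validation, pruning, binarization.

Trees are rooted, with branch lengths in time units (the unit is whatever the
input tree uses, e.g. Myr). The central derived structure is the shared-path
matrix: entry (i, j) is the root-to-MRCA path length of tips i and j, which
under Brownian motion is (up to the rate) the covariance of the tip values.

A :class:`TimeTree` may carry a root stem length. Pruning keeps the original
root position (the stem of the pruned tree absorbs any suppressed basal path),
so root-to-tip depths — and hence the Brownian covariance of the retained
tips — are unchanged by pruning.
"""

from __future__ import annotations

import io
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, Sequence

import dendropy
import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "TimeTree",
    "Node",
    "SharedPathMatrix",
    "NewickParseError",
    "TreeValidationError",
    "parse_newick",
    "write_newick",
    "prune_to",
    "resolve_polytomies",
    "shared_paths",
    "is_ultrametric",
]


class NewickParseError(ValueError):
    """Raised when Newick text cannot be parsed; carries a character offset."""

    def __init__(self, message: str, offset: Optional[int] = None):
        self.offset = offset
        if offset is not None:
            message = f"{message} (near character {offset})"
        super().__init__(message)


class TreeValidationError(ValueError):
    """Raised when a tree violates a TimeTree invariant."""


@dataclass
class Node:
    """One node of a rooted tree; ``length`` is the subtending edge length."""

    length: float = 0.0
    label: Optional[str] = None  # tip label; None for internal nodes
    children: list["Node"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def preorder(self) -> Iterator["Node"]:
        stack = [self]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def leaves(self) -> Iterator["Node"]:
        for node in self.preorder():
            if node.is_leaf:
                yield node


class TimeTree:
    """Rooted, time-calibrated phylogeny with unique, non-empty tip labels."""

    def __init__(self, root: Node):
        self.root = root
        self.validate()

    # -- basic accessors ---------------------------------------------------
    @property
    def tip_labels(self) -> list[str]:
        """Tip labels in tree (preorder leaf) order."""
        return [leaf.label for leaf in self.root.leaves()]

    @property
    def n_tips(self) -> int:
        return sum(1 for _ in self.root.leaves())

    def tip_depths(self) -> dict[str, float]:
        """Root-to-tip path length per tip, including any root stem length."""
        depths: dict[str, float] = {}

        def walk(node: Node, acc: float) -> None:
            acc += node.length
            if node.is_leaf:
                depths[node.label] = acc
            else:
                for child in node.children:
                    walk(child, acc)

        walk(self.root, 0.0)
        return depths

    def total_branch_length(self) -> float:
        return sum(n.length for n in self.root.preorder())

    def is_binary(self) -> bool:
        return all(
            len(n.children) == 2 for n in self.root.preorder() if not n.is_leaf
        )

    def copy(self) -> "TimeTree":
        def clone(node: Node) -> Node:
            return Node(node.length, node.label, [clone(c) for c in node.children])

        return TimeTree(clone(self.root))

    # -- validation --------------------------------------------------------
    def validate(self) -> None:
        labels = []
        for node in self.root.preorder():
            if not (math.isfinite(node.length) and node.length >= 0):
                raise TreeValidationError(
                    f"branch length {node.length!r} is not finite and >= 0"
                )
            if node.is_leaf:
                if not node.label:
                    raise TreeValidationError("tip with empty label")
                labels.append(node.label)
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        if dupes:
            raise TreeValidationError(f"duplicate tip labels: {dupes}")
        if len(labels) < 1:
            raise TreeValidationError("tree has no tips")

    def __repr__(self) -> str:  # pragma: no cover
        return f"TimeTree(n_tips={self.n_tips})"


@dataclass
class SharedPathMatrix:
    """Tip-by-tip matrix of root-to-MRCA path lengths (time units).

    Symmetric; the diagonal holds root-to-tip depths; every off-diagonal
    entry is bounded by the smaller of the two corresponding diagonals.
    """

    labels: list[str]
    values: np.ndarray

    def restrict(self, keep: Sequence[str]) -> "SharedPathMatrix":
        idx = [self.labels.index(l) for l in keep]
        return SharedPathMatrix(list(keep), self.values[np.ix_(idx, idx)])


# ---------------------------------------------------------------------------
# Newick I/O (dendropy does the actual grammar work)
# ---------------------------------------------------------------------------

def _from_dendropy(dtree: dendropy.Tree) -> TimeTree:
    def convert(dnode) -> Node:
        length = dnode.edge.length
        if length is None:
            length = 0.0
            if dnode.parent_node is not None:
                logger.warning(
                    "edge without a branch length; defaulting to 0"
                )
        if dnode.is_leaf():
            label = dnode.taxon.label if dnode.taxon is not None else dnode.label
            return Node(float(length), label, [])
        return Node(
            float(length), None, [convert(c) for c in dnode.child_nodes()]
        )

    return TimeTree(convert(dtree.seed_node))


def parse_newick(text: str) -> TimeTree:
    """Parse one Newick tree into a validated :class:`TimeTree`.

    Edges without a stated length default to 0 with a logged warning.
    Polytomies are legal at parse time; ``resolve_polytomies`` removes them.
    """
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several error types
        if "Duplicate taxon labels" in str(exc):
            raise TreeValidationError(f"duplicate tip labels: {exc}") from exc
        offset = getattr(exc, "col_num", None)
        raise NewickParseError(f"malformed Newick: {exc}", offset) from exc
    return _from_dendropy(dtree)


def _format_length(x: float) -> str:
    return f"{x:.6g}"


def write_newick(tree: TimeTree) -> str:
    """Serialize with 6-significant-digit branch lengths (deterministic)."""

    def fmt(node: Node) -> str:
        if node.is_leaf:
            return f"{node.label}:{_format_length(node.length)}"
        inner = ",".join(fmt(c) for c in node.children)
        return f"({inner}):{_format_length(node.length)}"

    if tree.root.is_leaf:
        return f"{tree.root.label}:{_format_length(tree.root.length)};"
    inner = ",".join(fmt(c) for c in tree.root.children)
    if tree.root.length > 0:
        return f"({inner}):{_format_length(tree.root.length)};"
    return f"({inner});"


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def prune_to(tree: TimeTree, species: Iterable[str]) -> TimeTree:
    """Prune to exactly ``species``, preserving every root-to-tip depth.

    Degree-2 internal nodes left behind by pruning are suppressed by summing
    their incident branch lengths; basal path segments are folded into the
    stem of the pruned tree so depths (and the Brownian covariance structure
    of the retained tips) are unchanged.
    """
    keep = set(species)
    tips = set(tree.tip_labels)
    missing = sorted(keep - tips)
    if missing:
        raise TreeValidationError(f"species not in tree: {missing}")
    if len(keep) < 2:
        raise TreeValidationError("pruning requires at least 2 species")

    def rebuild(node: Node) -> Optional[Node]:
        if node.is_leaf:
            if node.label in keep:
                return Node(node.length, node.label, [])
            return None
        kept_children = [c for c in (rebuild(c) for c in node.children) if c]
        if not kept_children:
            return None
        if len(kept_children) == 1:
            child = kept_children[0]
            child.length += node.length
            return child
        return Node(node.length, None, kept_children)

    new_root = rebuild(tree.root)
    return TimeTree(new_root)


def resolve_polytomies(tree: TimeTree) -> TimeTree:
    """Replace every polytomy by a caterpillar of zero-length edges.

    Children are ordered lexicographically by the smallest tip label in their
    subtree, then joined left-to-right with zero-length internal edges. This
    is deterministic and leaves all tip depths and pairwise MRCA depths —
    hence the Brownian covariance — exactly unchanged.
    """
    out = tree.copy()

    def min_tip(node: Node) -> str:
        return min(leaf.label for leaf in node.leaves())

    polytomies = 0
    for node in list(out.root.preorder()):
        if len(node.children) > 2:
            polytomies += 1
            ordered = sorted(node.children, key=min_tip)
            current = ordered[0]
            for nxt in ordered[1:-1]:
                current = Node(0.0, None, [current, nxt])
            node.children = [current, ordered[-1]]
    if polytomies:
        logger.info(
            "resolved %d polytomy(ies) with zero-length caterpillars "
            "(deterministic stand-in for literature-dated resolutions)",
            polytomies,
        )
    return TimeTree(out.root)


def shared_paths(tree: TimeTree) -> SharedPathMatrix:
    """Root-to-MRCA path length for every tip pair; diagonal = tip depth."""
    labels = tree.tip_labels
    index = {l: i for i, l in enumerate(labels)}
    n = len(labels)
    values = np.zeros((n, n))

    def walk(node: Node, acc: float) -> list[int]:
        acc += node.length
        if node.is_leaf:
            i = index[node.label]
            values[i, i] = acc
            return [i]
        groups = [walk(c, acc) for c in node.children]
        for gi in range(len(groups)):
            for gj in range(gi + 1, len(groups)):
                for i in groups[gi]:
                    for j in groups[gj]:
                        values[i, j] = values[j, i] = acc
        return [i for g in groups for i in g]

    walk(tree.root, 0.0)
    return SharedPathMatrix(labels, values)


def is_ultrametric(tree: TimeTree, rel_tol: float = 1e-6) -> bool:
    """True iff tip-depth spread is at most ``rel_tol`` times the max depth."""
    depths = list(tree.tip_depths().values())
    dmax = max(depths)
    if dmax == 0:
        return True
    return (dmax - min(depths)) <= rel_tol * dmax
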