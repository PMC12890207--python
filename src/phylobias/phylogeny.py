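"""Rooted time-calibrated phylogenies: Newick I/O, node ages, pruning, time slices.

Trees are rooted, branch lengths are in millions of years (My), and time runs
backward: the present is age 0 and ages increase into the past, so an
ultrametric tree has all tips at age 0 and the root at the crown age.  A
clade's *stem age* (when its lineage split from its sister) can be recorded
alongside the crown tree; most Newick files do not carry one, in which case
callers fall back to the crown age.

The heavy lifting of Newick parsing/serialisation and taxon pruning is
delegated to :mod:`dendropy`; this module owns the age arithmetic, the
time-slicing convention, and the interval grid used to bin node ages.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from io import StringIO
from typing import Iterable, Mapping

import dendropy

#: Two tip ages closer than this (in My) are considered equal; used for the
#: ultrametricity check and for identifying extant (age-0) tips.
ULTRAMETRIC_TOL = 1e-9


class NewickParseError(ValueError):
    """Raised when a Newick string cannot be parsed into a valid tree."""


class TreeError(ValueError):
    """Raised for operations on trees that violate their preconditions."""


@dataclass
class Phylogeny:
    """A rooted phylogeny with branch lengths in My.

    Wraps a :class:`dendropy.Tree` and caches node ages.  ``stem_age``, if
    set, is the age at which the clade's lineage split from its sister and
    must be at least the crown (root) age.
    """

    dtree: dendropy.Tree
    stem_age: float | None = None
    _ages: dict | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self._validate()

    # -- validation -------------------------------------------------------

    def _validate(self) -> None:
        labels: set[str] = set()
        for node in self.dtree.preorder_node_iter():
            if node is not self.dtree.seed_node:
                bl = node.edge.length
                if bl is None:
                    raise NewickParseError(
                        f"missing branch length on edge above {_node_name(node)!r}"
                    )
                if not math.isfinite(bl) or bl < 0:
                    raise TreeError(
                        f"branch length {bl!r} above {_node_name(node)!r} "
                        "is not finite and non-negative"
                    )
            if node.is_leaf():
                label = _leaf_label(node)
                if not label:
                    raise NewickParseError("tip with empty label")
                if label in labels:
                    raise NewickParseError(f"duplicate tip label {label!r}")
                labels.add(label)
        if self.stem_age is not None and self.stem_age < self.crown_age - ULTRAMETRIC_TOL:
            raise TreeError(
                f"stem age {self.stem_age} is younger than crown age {self.crown_age}"
            )

    # -- basic anatomy ----------------------------------------------------

    @property
    def root(self) -> dendropy.Node:
        return self.dtree.seed_node

    @property
    def tip_labels(self) -> tuple[str, ...]:
        return tuple(_leaf_label(l) for l in self.dtree.leaf_node_iter())

    @property
    def n_tips(self) -> int:
        return sum(1 for _ in self.dtree.leaf_node_iter())

    @property
    def crown_age(self) -> float:
        """Age of the root: the maximum root-to-tip path length."""
        return self.ages()[self.root]

    def stem_or_crown_age(self) -> float:
        """Stem age if recorded, otherwise the crown age (with a warning)."""
        if self.stem_age is not None:
            return self.stem_age
        warnings.warn(
            "no stem age recorded; falling back to crown age", stacklevel=2
        )
        return self.crown_age

    @property
    def is_ultrametric(self) -> bool:
        ages = self.ages()
        return all(
            abs(ages[l]) <= ULTRAMETRIC_TOL for l in self.dtree.leaf_node_iter()
        )

    def ages(self) -> dict[dendropy.Node, float]:
        """Map every node to its age (My before present; farthest tip = 0)."""
        if self._ages is None:
            depth: dict[dendropy.Node, float] = {self.root: 0.0}
            for node in self.dtree.preorder_node_iter():
                if node is self.root:
                    continue
                depth[node] = depth[node.parent_node] + node.edge.length
            height = max(depth.values()) if depth else 0.0
            self._ages = {n: height - d for n, d in depth.items()}
        return self._ages

    def tip_ages(self) -> dict[str, float]:
        ages = self.ages()
        return {_leaf_label(l): ages[l] for l in self.dtree.leaf_node_iter()}

    def parent_ages(self) -> dict[str, float]:
        """Age of each tip's parent node (the tip's naive origin age)."""
        ages = self.ages()
        out = {}
        for leaf in self.dtree.leaf_node_iter():
            if leaf.parent_node is None:
                raise TreeError("single-tip tree has no parent split")
            out[_leaf_label(leaf)] = ages[leaf.parent_node]
        return out

    def copy(self) -> "Phylogeny":
        return Phylogeny(self.dtree.clone(depth=1), stem_age=self.stem_age)


def _leaf_label(node: dendropy.Node) -> str:
    if node.taxon is not None and node.taxon.label:
        return node.taxon.label
    return node.label or ""


def _node_name(node: dendropy.Node) -> str:
    lab = _leaf_label(node)
    return lab if lab else "<unlabelled node>"


# ---------------------------------------------------------------------------
# Newick I/O


def parse_newick(text: str, stem_age: float | None = None) -> Phylogeny:
    """Parse a single rooted Newick tree with branch lengths on all edges.

    The accepted dialect is deliberately small: unquoted alphanumeric and
    underscore labels, decimal branch lengths, no comments or annotations.
    A branch length on the root edge, if present, is folded into the stem
    age (crown age + root edge length).
    """
    if not text or not text.strip():
        raise NewickParseError("empty Newick input")
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises a zoo of error classes
        raise NewickParseError(f"malformed Newick: {exc}") from exc
    _lift_single_tip(dtree)
    root_edge = dtree.seed_node.edge.length
    tree = Phylogeny(dtree, stem_age=stem_age)
    if root_edge is not None and stem_age is None:
        tree.stem_age = tree.crown_age + root_edge
    return tree


def _lift_single_tip(dtree: dendropy.Tree) -> None:
    """Turn a lone labelled node with an edge length ('A:3;') into a proper
    root-to-tip branch so the length is a real branch, not a root edge."""
    seed = dtree.seed_node
    if seed.is_leaf() and seed.edge.length is not None:
        taxon, length = seed.taxon, seed.edge.length
        seed.taxon = None
        seed.edge.length = None
        child = seed.new_child(edge_length=length)
        child.taxon = taxon


def write_newick(tree: Phylogeny) -> str:
    """Serialise to a Newick string; round-trips through :func:`parse_newick`."""
    root = tree.dtree.seed_node
    children = root.child_nodes()
    if len(children) == 1 and children[0].is_leaf():
        only = children[0]  # single-branch tree: normalise to 'label:length;'
        return f"{_leaf_label(only)}:{only.edge.length};"
    out = tree.dtree.as_string(
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
    ).strip()
    return out


# ---------------------------------------------------------------------------
# Ages, pruning, slicing


def node_ages(tree: Phylogeny) -> dict[dendropy.Node, float]:
    """Ages of all nodes in My before present (root age = tree height)."""
    return dict(tree.ages())


def prune_to_tips(tree: Phylogeny, keep: Iterable[str]) -> Phylogeny:
    """Restrict the tree to the given tips.

    Degree-2 nodes created by pruning are suppressed with their branch
    lengths summed, so every retained node keeps its age exactly — the
    mechanism by which subsampling inflates tips' apparent origin ages.
    """
    keep = set(keep)
    if not keep:
        raise TreeError("keep set is empty")
    known = set(tree.tip_labels)
    unknown = keep - known
    if unknown:
        raise TreeError(f"unknown tip labels: {sorted(unknown)}")
    pruned = tree.dtree.extract_tree_with_taxa_labels(keep)
    _lift_single_tip(pruned)
    return Phylogeny(pruned, stem_age=tree.stem_age)


def lineage_count_at(tree: Phylogeny, T: float) -> int:
    """Number of lineages alive at age ``T``.

    Counts branches crossing the time slice at age ``T``; a node exactly at
    ``T`` counts as already split (its child branches are the units), and a
    tip exactly at ``T`` counts as one lineage.  Equals the tip count at
    ``T = 0`` on an ultrametric tree and 2 just below the crown age for a
    bifurcating root.
    """
    if T < 0:
        raise TreeError(f"negative age {T}")
    limit = tree.stem_age if tree.stem_age is not None else tree.crown_age
    if T > limit + ULTRAMETRIC_TOL:
        raise TreeError(f"age {T} exceeds stem age {limit}")
    ages = tree.ages()
    count = 0
    for node in tree.dtree.preorder_node_iter():
        a = ages[node]
        if abs(a - T) <= ULTRAMETRIC_TOL:
            count += len(node.child_nodes()) if not node.is_leaf() else 1
        elif a < T and node.parent_node is not None and ages[node.parent_node] > T + ULTRAMETRIC_TOL:
            count += 1
    if count == 0 and T > tree.crown_age - ULTRAMETRIC_TOL:
        # slice falls on the stem lineage, above the crown
        count = 1
    return count


def total_branch_length(tree: Phylogeny) -> float:
    """Sum of all branch lengths in My."""
    return sum(
        node.edge.length
        for node in tree.dtree.preorder_node_iter()
        if node is not tree.root and node.edge.length is not None
    )


# ---------------------------------------------------------------------------
# Interval grid


@dataclass(frozen=True)
class IntervalGrid:
    """Ordered half-open age intervals ``[b_k, b_{k+1})`` backward from the present.

    ``boundaries`` must be strictly increasing and start at 0; with the
    default 5 My width the intervals are [0, 5), [5, 10), ...  A node whose
    age falls exactly on an interior boundary ``b_k`` belongs to interval
    ``k`` (the interval whose young edge it sits on), consistent with the
    time-slice convention that a node at the slice has already split.
    """

    boundaries: tuple[float, ...]

    def __post_init__(self) -> None:
        b = self.boundaries
        if len(b) < 2:
            raise ValueError("grid needs at least two boundaries")
        if b[0] != 0:
            raise ValueError("first boundary must be 0")
        if any(b[i] >= b[i + 1] for i in range(len(b) - 1)):
            raise ValueError("boundaries must be strictly increasing")

    @classmethod
    def regular(cls, width: float = 5.0, max_age: float = 100.0) -> "IntervalGrid":
        """Uniform grid of the given width covering at least ``max_age``."""
        if width <= 0:
            raise ValueError("grid width must be positive")
        k = max(1, math.ceil(max_age / width - 1e-12))
        return cls(tuple(i * width for i in range(k + 1)))

    @property
    def n_intervals(self) -> int:
        return len(self.boundaries) - 1

    def bounds(self, k: int) -> tuple[float, float]:
        return self.boundaries[k], self.boundaries[k + 1]

    def index_of(self, age: float) -> int | None:
        """Interval index containing ``age``, or None if outside the grid."""
        if age < 0:
            raise ValueError(f"negative age {age}")
        b = self.boundaries
        for k in range(len(b) - 1):
            if b[k] <= age < b[k + 1]:
                return k
        return None

    def midpoints(self) -> tuple[float, ...]:
        b = self.boundaries
        return tuple((b[k] + b[k + 1]) / 2 for k in range(len(b) - 1))
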