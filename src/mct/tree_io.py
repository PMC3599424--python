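"""Newick input/output and profile assembly.

Trees are stored unrooted: an :class:`XTree` is a leaf set plus the set of
bipartitions induced by its internal edges, which is all the consensus
machinery needs.  Rooted Newick input is collapsed at the root (suppressing
a degree-2 root changes no bipartition).  Branch lengths and internal
labels are accepted on input and discarded.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Sequence, Tuple

import dendropy

from .splits import Bipartition

__all__ = [
    "XTree",
    "Profile",
    "NewickParseError",
    "LeafSetMismatchError",
    "parse_newick",
    "parse_profile",
    "read_profile",
    "write_newick",
    "write_profile",
]


class NewickParseError(ValueError):
    """Malformed Newick text or invalid leaf labelling."""


class LeafSetMismatchError(ValueError):
    """Trees of a profile do not share the same leaf set."""

    def __init__(self, index: int, missing: FrozenSet[str], extra: FrozenSet[str]):
        self.index = index
        self.missing = missing
        self.extra = extra
        super().__init__(
            f"tree #{index} has a different leaf set: "
            f"missing {sorted(missing)}, extra {sorted(extra)}"
        )


@dataclass(frozen=True)
class XTree:
    """An unrooted tree with leaves bijectively labelled by taxon set X.

    Internal nodes have degree >= 3; the tree is fully represented by its
    leaf set and the set of splits of its internal edges.
    """

    leaves: FrozenSet[str]
    splits: FrozenSet[Bipartition]

    def __post_init__(self) -> None:
        if len(self.leaves) < 3:
            raise ValueError(f"an X-tree needs >= 3 leaves, got {len(self.leaves)}")
        if any(not lbl for lbl in self.leaves):
            raise ValueError("empty leaf label")
        for s in self.splits:
            if s.leaves != self.leaves:
                raise ValueError(f"{s!r} is not a split of the tree's leaf set")
        if len(self.splits) > len(self.leaves) - 3:
            raise ValueError(
                f"{len(self.splits)} internal edges on {len(self.leaves)} leaves "
                f"(max {len(self.leaves) - 3})"
            )

    @property
    def n(self) -> int:
        return len(self.leaves)

    @property
    def internal_edge_count(self) -> int:
        return len(self.splits)

    @property
    def is_resolved(self) -> bool:
        """Fully resolved (binary): n - 3 internal edges."""
        return len(self.splits) == len(self.leaves) - 3

    @property
    def is_star(self) -> bool:
        return not self.splits

    def newick(self, supports: Optional[Mapping[Bipartition, int]] = None) -> str:
        return write_newick(self, supports)


@dataclass(frozen=True)
class Profile:
    """An ordered collection of m X-trees over an identical leaf set."""

    trees: Tuple[XTree, ...]
    X: FrozenSet[str]

    def __post_init__(self) -> None:
        if not self.trees:
            raise ValueError("a profile needs at least one tree")
        for i, t in enumerate(self.trees):
            if t.leaves != self.X:
                raise LeafSetMismatchError(
                    i, missing=self.X - t.leaves, extra=t.leaves - self.X
                )

    @classmethod
    def from_trees(cls, trees: Iterable[XTree]) -> "Profile":
        trees = tuple(trees)
        if not trees:
            raise ValueError("a profile needs at least one tree")
        return cls(trees=trees, X=trees[0].leaves)

    @property
    def m(self) -> int:
        return len(self.trees)

    @property
    def n(self) -> int:
        return len(self.X)

    def subprofile(self, indices: Iterable[int]) -> "Profile":
        """The sub-profile of the trees at the given 0-based indices."""
        return Profile(trees=tuple(self.trees[i] for i in sorted(indices)), X=self.X)

    def __len__(self) -> int:
        return len(self.trees)

    def __getitem__(self, i: int) -> XTree:
        return self.trees[i]


def _tree_from_dendropy(dtree: dendropy.Tree) -> XTree:
    labels: List[str] = []
    for leaf in dtree.leaf_node_iter():
        if leaf.taxon is None or not leaf.taxon.label:
            raise NewickParseError("unlabelled leaf in Newick tree")
        labels.append(str(leaf.taxon.label))
    if len(set(labels)) != len(labels):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        raise NewickParseError(f"duplicate leaf labels: {dupes}")
    leaves = frozenset(labels)
    n = len(leaves)
    if n < 3:
        raise NewickParseError(f"an X-tree needs >= 3 leaves, got {n}")

    # Leaf set below each node; any side of size in [2, n-2] is a split.
    # Collecting into a set suppresses the duplicate produced by a
    # degree-2 root, i.e. rooted input is unrooted for free.
    splits = set()
    below: Dict[int, FrozenSet[str]] = {}
    for node in dtree.postorder_node_iter():
        if node.is_leaf():
            below[id(node)] = frozenset([str(node.taxon.label)])
        else:
            kids = [below[id(c)] for c in node.child_nodes()]
            below[id(node)] = frozenset().union(*kids)
        side = below[id(node)]
        if 2 <= len(side) <= n - 2:
            splits.add(Bipartition(side, leaves - side))
    return XTree(leaves=leaves, splits=frozenset(splits))


def parse_newick(text: str) -> XTree:
    """Parse one Newick statement into an unrooted X-tree.

    Accepts quoted labels, branch lengths, internal labels and bracketed
    comments.  Raises :class:`NewickParseError` (with the position reported
    by the parser) on malformed input or duplicate leaf labels.
    """
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises assorted error classes
        raise NewickParseError(f"invalid Newick: {exc}") from exc
    return _tree_from_dendropy(dtree)


def parse_profile(text: str) -> Profile:
    """Parse a multi-tree Newick string (one statement per tree).

    All trees must be over the identical leaf set; otherwise a
    :class:`LeafSetMismatchError` names the first offending tree (0-based)
    and the symmetric difference of labels.
    """
    try:
        tlist = dendropy.TreeList.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:
        raise NewickParseError(f"invalid Newick: {exc}") from exc
    if len(tlist) == 0:
        raise NewickParseError("no trees found in input")
    trees = [_tree_from_dendropy(t) for t in tlist]
    X = trees[0].leaves
    for i, t in enumerate(trees):
        if t.leaves != X:
            raise LeafSetMismatchError(i, missing=X - t.leaves, extra=t.leaves - X)
    return Profile(trees=tuple(trees), X=X)


def read_profile(path) -> Profile:
    with open(path, "r", encoding="utf-8") as fh:
        return parse_profile(fh.read())


def write_newick(
    tree: XTree, supports: Optional[Mapping[Bipartition, int]] = None
) -> str:
    """Serialize an X-tree to Newick.

    The unrooted tree is written rooted at the lexicographically smallest
    leaf.  When ``supports`` is given, each internal edge's support count is
    emitted as the label of the corresponding internal node.  Children are
    ordered deterministically (clades by size then labels, leaves sorted).
    """
    root = min(tree.leaves)
    # each split becomes the clade on the side away from the root leaf
    clades = sorted(
        (s.side_b if root in s.side_a else s.side_a for s in tree.splits),
        key=lambda c: (len(c), tuple(sorted(c))),
    )
    support_of = {}
    if supports:
        for s, v in supports.items():
            support_of[s.side_b if root in s.side_a else s.side_a] = v

    def render(members: FrozenSet[str], inner: Sequence[FrozenSet[str]]) -> str:
        maximal = [c for c in inner if not any(c < d for d in inner)]
        parts = []
        for c in sorted(maximal, key=lambda c: (len(c), tuple(sorted(c)))):
            sub = [d for d in inner if d < c]
            label = str(support_of[c]) if c in support_of else ""
            parts.append(render(c, sub) + label)
        loose = members - frozenset().union(*maximal) if maximal else members
        parts.extend(_quote(l) for l in sorted(loose))
        return "(" + ",".join(parts) + ")"

    rest = tree.leaves - {root}
    body = render(rest, clades)
    return f"({_quote(root)},{body[1:-1]});"


def _quote(label: str) -> str:
    if any(ch in label for ch in " ()[]{}:;,'\t\n"):
        return "'" + label.replace("'", "''") + "'"
    return label


def write_profile(profile: Profile, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for t in profile.trees:
            fh.write(write_newick(t) + "\n")
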