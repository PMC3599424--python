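"""Bipartition algebra and consensus-tree construction.

An unrooted leaf-labelled tree is treated as the set of bipartitions
(splits) of its leaf set induced by its internal edges.  All consensus
variants implemented here (strict, majority, extended majority) operate on
weighted split sets, where the weight of a split is the number of profile
trees that contain it.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Dict, FrozenSet, Iterable, Mapping, Optional, Set

if TYPE_CHECKING:  # pragma: no cover - import cycle guard
    from .tree_io import Profile, XTree

__all__ = [
    "Bipartition",
    "WeightedSplitSet",
    "ConsensusTree",
    "extract_splits",
    "split_counts",
    "are_compatible",
    "majority_consensus",
    "strict_consensus",
    "extended_majority_consensus",
    "tree_from_splits",
]


class Bipartition:
    """A split of the taxon set X induced by one internal edge.

    The two sides are stored in a canonical orientation: ``side_a`` is the
    side containing the lexicographically smallest taxon label, so equality
    and hashing are orientation-independent.  Both sides must contain at
    least two taxa (pendant edges induce no split).
    """

    __slots__ = ("side_a", "side_b", "_hash")

    def __init__(self, side_a: Iterable[str], side_b: Iterable[str]) -> None:
        a = frozenset(side_a)
        b = frozenset(side_b)
        if len(a) < 2 or len(b) < 2:
            raise ValueError(
                f"both sides of a split need >= 2 taxa, got {len(a)} and {len(b)}"
            )
        if a & b:
            raise ValueError(f"split sides overlap: {sorted(a & b)}")
        if min(b) < min(a):
            a, b = b, a
        self.side_a: FrozenSet[str] = a
        self.side_b: FrozenSet[str] = b
        self._hash = hash((a, b))

    @property
    def leaves(self) -> FrozenSet[str]:
        """The full taxon set X = side_a ∪ side_b."""
        return self.side_a | self.side_b

    def side_of(self, label: str) -> FrozenSet[str]:
        if label in self.side_a:
            return self.side_a
        if label in self.side_b:
            return self.side_b
        raise KeyError(label)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Bipartition):
            return NotImplemented
        return self.side_a == other.side_a and self.side_b == other.side_b

    def __hash__(self) -> int:
        return self._hash

    def __repr__(self) -> str:
        fmt = lambda s: ",".join(sorted(s))
        return f"Bipartition({fmt(self.side_a)} | {fmt(self.side_b)})"

    def _sort_key(self):
        return (tuple(sorted(self.side_a)), tuple(sorted(self.side_b)))


def are_compatible(a: Bipartition, b: Bipartition) -> bool:
    """True iff the two splits can coexist on one tree.

    Standard split compatibility: two splits of the same X are compatible
    iff at least one of the four pairwise side intersections is empty.
    """
    if a.leaves != b.leaves:
        raise ValueError("splits are over different taxon sets")
    return (
        not (a.side_a & b.side_a)
        or not (a.side_a & b.side_b)
        or not (a.side_b & b.side_a)
        or not (a.side_b & b.side_b)
    )


def _all_pairwise_compatible(splits: Iterable[Bipartition]) -> Optional[tuple]:
    """Return an incompatible pair, or None if all pairs are compatible."""
    items = list(splits)
    for i, s in enumerate(items):
        for t in items[i + 1 :]:
            if not are_compatible(s, t):
                return (s, t)
    return None


def extract_splits(tree: "XTree") -> Set[Bipartition]:
    """The set of bipartitions of ``tree``, one per internal edge."""
    return set(tree.splits)


@dataclass(frozen=True)
class WeightedSplitSet:
    """Support counts m_i over the union of all splits in a profile."""

    counts: Mapping[Bipartition, int]
    m: int
    #: rank of first appearance in the profile (trees in order, splits in
    #: canonical order within a tree); used for deterministic tie-breaking
    first_seen: Mapping[Bipartition, int] = field(default_factory=dict)

    def majority_splits(self) -> Dict[Bipartition, int]:
        """Splits present in strictly more than half the trees."""
        half = self.m / 2
        return {s: c for s, c in self.counts.items() if c > half}

    def common_splits(self) -> Dict[Bipartition, int]:
        return {s: c for s, c in self.counts.items() if c == self.m}


def split_counts(profile: "Profile") -> WeightedSplitSet:
    """Count, for every split in the profile, how many trees contain it."""
    counts: Counter = Counter()
    first_seen: Dict[Bipartition, int] = {}
    rank = 0
    for tree in profile.trees:
        for split in sorted(tree.splits, key=Bipartition._sort_key):
            counts[split] += 1
            if split not in first_seen:
                first_seen[split] = rank
                rank += 1
    return WeightedSplitSet(counts=dict(counts), m=profile.m, first_seen=first_seen)


def tree_from_splits(splits: Iterable[Bipartition], X: Iterable[str]) -> "XTree":
    """The unique unrooted tree whose internal-edge split set is ``splits``.

    By the splits-equivalence theorem a pairwise-compatible split collection
    is realized by exactly one X-tree.
    """
    from .tree_io import XTree

    leaves = frozenset(X)
    splits = frozenset(splits)
    for s in splits:
        if s.leaves != leaves:
            raise ValueError(f"{s!r} is not a split of the given taxon set")
    bad = _all_pairwise_compatible(splits)
    if bad is not None:
        raise ValueError(f"incompatible splits: {bad[0]!r} vs {bad[1]!r}")
    return XTree(leaves=leaves, splits=splits)


@dataclass(frozen=True)
class ConsensusTree:
    """A consensus tree with per-edge support counts.

    ``weight`` is the majority-only weight W_π(A) = Σ m_i over the majority
    edges of the tree; this is the quantity the generalized score uses.
    ``total_weight`` additionally counts non-majority edges (it differs from
    ``weight`` only for the extended majority consensus).
    """

    tree: "XTree"
    support: Mapping[Bipartition, int]
    weight: int
    total_weight: int

    @property
    def splits(self) -> FrozenSet[Bipartition]:
        return self.tree.splits


def majority_consensus(class_profile: "Profile") -> ConsensusTree:
    """Majority-rule consensus: exactly the splits with m_i > m/2.

    Majority splits are always pairwise compatible, so the consensus tree
    exists; this is asserted via :func:`tree_from_splits`.  For a singleton
    class the consensus is the tree itself and the weight its internal-edge
    count.
    """
    wss = split_counts(class_profile)
    maj = wss.majority_splits()
    tree = tree_from_splits(maj, class_profile.X)
    w = sum(maj.values())
    return ConsensusTree(tree=tree, support=maj, weight=w, total_weight=w)


def strict_consensus(class_profile: "Profile") -> ConsensusTree:
    """Strict consensus: only the splits common to every tree (m_i = m)."""
    wss = split_counts(class_profile)
    common = wss.common_splits()
    tree = tree_from_splits(common, class_profile.X)
    w = sum(common.values())
    return ConsensusTree(tree=tree, support=common, weight=w, total_weight=w)


def extended_majority_consensus(class_profile: "Profile") -> ConsensusTree:
    """Greedy completion of the majority consensus with compatible splits.

    Non-majority splits are examined in decreasing support order and added
    when compatible with everything already accepted.  Ties at equal
    support are broken by order of first appearance in the profile (trees
    in input order, splits in canonical order within a tree) — the greedy
    result is not unique in general, so a fixed rule is needed for
    reproducibility.

    The returned ``weight`` is the majority-only weight used by the
    generalized score; ``total_weight`` includes the greedily added edges.
    """
    wss = split_counts(class_profile)
    maj = wss.majority_splits()
    accepted: Dict[Bipartition, int] = dict(maj)
    half = wss.m / 2
    candidates = [
        (s, c) for s, c in wss.counts.items() if c <= half
    ]
    candidates.sort(key=lambda sc: (-sc[1], wss.first_seen[sc[0]]))
    for s, c in candidates:
        if all(are_compatible(s, t) for t in accepted):
            accepted[s] = c
    tree = tree_from_splits(accepted, class_profile.X)
    return ConsensusTree(
        tree=tree,
        support=accepted,
        weight=sum(maj.values()),
        total_weight=sum(accepted.values()),
    )
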