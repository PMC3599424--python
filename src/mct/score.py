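"""The generalized score of a partition of a tree profile.

For a partition of the m profile trees into k classes with sizes p_i and
per-class majority consensus trees C_i of weight W_i (sum of support counts
over the majority edges of C_i), the generalized score is

    W_k = sum_i  p_i * W_i .

W_1 (single class) is the homogeneity reference; W_m, the score of the
atomic partition into singletons, equals the total internal-edge count of
the profile.  A partition with W_k > W_1 is evidence that the profile is
heterogeneous and carries several consensus trees.  All scores are exact
integers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, FrozenSet, Iterable, List, Tuple

from .splits import ConsensusTree, majority_consensus
from .tree_io import Profile, XTree

__all__ = [
    "TreePartition",
    "ScoredPartition",
    "generalized_score",
    "atomic_score",
    "two_tree_single_consensus",
    "class_majority_weight",
]


@dataclass(frozen=True)
class TreePartition:
    """A partition of the tree indices {0..m-1} into k non-empty classes."""

    classes: Tuple[FrozenSet[int], ...]

    def __post_init__(self) -> None:
        if not self.classes:
            raise ValueError("a partition needs at least one class")
        seen: set = set()
        for c in self.classes:
            if not c:
                raise ValueError("empty class in partition")
            if seen & c:
                raise ValueError(f"overlapping classes: {sorted(seen & c)}")
            seen |= c
        expected = set(range(len(seen)))
        if seen != expected:
            raise ValueError(
                f"classes must cover 0..{len(seen) - 1} exactly, got {sorted(seen)}"
            )

    @classmethod
    def from_sets(cls, classes: Iterable[Iterable[int]]) -> "TreePartition":
        # canonical class order: by smallest member
        cs = sorted((frozenset(c) for c in classes), key=min)
        return cls(classes=tuple(cs))

    @classmethod
    def atomic(cls, m: int) -> "TreePartition":
        return cls(classes=tuple(frozenset([i]) for i in range(m)))

    @classmethod
    def single(cls, m: int) -> "TreePartition":
        return cls(classes=(frozenset(range(m)),))

    @property
    def k(self) -> int:
        return len(self.classes)

    @property
    def m(self) -> int:
        return sum(len(c) for c in self.classes)

    @property
    def is_atomic(self) -> bool:
        return all(len(c) == 1 for c in self.classes)

    def __str__(self) -> str:
        return " | ".join(
            "{" + ",".join(str(i + 1) for i in sorted(c)) + "}"
            for c in sorted(self.classes, key=min)
        )


@dataclass(frozen=True)
class ScoredPartition:
    """A partition together with its per-class consensus trees and W_k."""

    partition: TreePartition
    class_consensus: Tuple[ConsensusTree, ...]
    score: int

    @property
    def k(self) -> int:
        return self.partition.k


def class_majority_weight(profile: Profile, indices: FrozenSet[int]) -> int:
    """Weight of the majority consensus of a class, without building the tree.

    Counts the splits over the class's trees and sums the counts of those
    occurring in strictly more than half of them.  This is the hot path of
    the partition search.
    """
    p = len(indices)
    counts: Dict = {}
    for i in indices:
        for s in profile.trees[i].splits:
            counts[s] = counts.get(s, 0) + 1
    half = p / 2
    return sum(c for c in counts.values() if c > half)


def generalized_score(profile: Profile, partition: TreePartition) -> ScoredPartition:
    """Score a partition: Σ class size × class majority-consensus weight."""
    if partition.m != profile.m:
        raise ValueError(
            f"partition covers {partition.m} trees but the profile has {profile.m}"
        )
    consensus: List[ConsensusTree] = []
    score = 0
    for cls in partition.classes:
        ct = majority_consensus(profile.subprofile(cls))
        consensus.append(ct)
        score += len(cls) * ct.weight
    return ScoredPartition(
        partition=partition, class_consensus=tuple(consensus), score=score
    )


def score_value(profile: Profile, partition: TreePartition) -> int:
    """The generalized score as a bare integer (no consensus trees built)."""
    return sum(
        len(cls) * class_majority_weight(profile, cls) for cls in partition.classes
    )


def atomic_score(profile: Profile) -> int:
    """W_m = Σ n_i: the total internal-edge count of the profile.

    Equals the generalized score of the atomic partition, since a singleton
    class's consensus is the tree itself with every edge supported once.
    """
    return sum(t.internal_edge_count for t in profile.trees)


def two_tree_single_consensus(t1: XTree, t2: XTree) -> bool:
    """Do two X-trees admit a single consensus?

    For a pair, the majority splits are exactly the k shared splits, each
    with support 2, so the single-class score is W_1 = 2 x 2k and the
    atomic score is W_2 = n1 + n2.  The pair admits a single consensus iff
    W_1 > W_2, i.e. iff 4k > n1 + n2 — more than half of each tree's
    edges shared, for trees of equal resolution.  A tie (e.g. two star
    trees) is reported as False: homogeneity is only declared on a
    strictly greater single-class score.
    """
    if t1.leaves != t2.leaves:
        raise ValueError("trees are over different leaf sets")
    k = len(t1.splits & t2.splits)
    return 4 * k > t1.internal_edge_count + t2.internal_edge_count
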