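"""Search for the partition of a profile maximizing the generalized score.

Two agglomerative strategies build a series of nested partitions with
m, m-1, ..., 1 classes:

* average linkage on a pairwise tree-similarity matrix (RF or quartet),
  merging at each step the two classes of maximal average cross-class
  similarity;
* greedy ascending merging, which at each step evaluates the generalized
  score of every possible two-class fusion and performs the best one.

Every level of every hierarchy is scored and the best partition over all
of them decides the verdict: a ``single`` consensus (best at k = 1),
``multiple`` consensus trees (best at 1 < k < m for a non-atomic
partition), or the ``atomic`` consensus (best at the partition into
singletons).  The hierarchical optimum is a lower bound on the true
optimum over all set partitions; an exhaustive oracle is provided for
small m.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Dict, FrozenSet, List, Optional, Sequence, Tuple

import numpy as np

from .score import (
    ScoredPartition,
    TreePartition,
    class_majority_weight,
    generalized_score,
)
from .similarity import SimilarityMatrix, similarity_matrix
from .tree_io import Profile

__all__ = [
    "Dendrogram",
    "SearchResult",
    "average_linkage_hierarchy",
    "greedy_ascending_hierarchy",
    "score_hierarchy",
    "best_partition",
    "exhaustive_best_partition",
    "iter_set_partitions",
]

#: largest profile size accepted by the exhaustive oracle (Bell(10) = 115975)
EXHAUSTIVE_MAX_M = 10

DEFAULT_METHODS = ("rf", "qs", "greedy")


@dataclass(frozen=True)
class Dendrogram:
    """An agglomeration history: m nested partitions with k = m .. 1."""

    merge_history: Tuple[Tuple[FrozenSet[int], FrozenSet[int]], ...]
    level_partitions: Tuple[TreePartition, ...]

    def __post_init__(self) -> None:
        m = self.level_partitions[0].k
        for lvl, part in enumerate(self.level_partitions):
            if part.k != m - lvl:
                raise ValueError("hierarchy levels must have k = m..1 classes")

    @property
    def m(self) -> int:
        return self.level_partitions[0].k

    def partition_at(self, k: int) -> TreePartition:
        """The nested partition with k classes."""
        return self.level_partitions[self.m - k]


def _merge_tie_key(a: FrozenSet[int], b: FrozenSet[int]):
    """Deterministic order on candidate merges with equal objective.

    Compares the pair of class representatives (smallest member index,
    smaller first), then the full sorted class contents.
    """
    ra, rb = sorted((min(a), min(b)))
    return (ra, rb, tuple(sorted(a | b)))


def _run_agglomeration(m: int, objective) -> Dendrogram:
    """Generic agglomeration: repeatedly merge the argmax pair of classes.

    ``objective(a, b)`` returns the value of merging classes a and b;
    larger is better.  Ties are broken by :func:`_merge_tie_key`.
    """
    classes: List[FrozenSet[int]] = [frozenset([i]) for i in range(m)]
    levels = [TreePartition.from_sets(classes)]
    history: List[Tuple[FrozenSet[int], FrozenSet[int]]] = []
    while len(classes) > 1:
        best = None
        best_val = None
        for a, b in combinations(classes, 2):
            val = objective(a, b)
            if (
                best is None
                or val > best_val
                or (val == best_val and _merge_tie_key(a, b) < _merge_tie_key(*best))
            ):
                best, best_val = (a, b), val
        a, b = best
        history.append((a, b))
        classes = [c for c in classes if c is not a and c is not b] + [a | b]
        levels.append(TreePartition.from_sets(classes))
    return Dendrogram(merge_history=tuple(history), level_partitions=tuple(levels))


def average_linkage_hierarchy(sim: SimilarityMatrix) -> Dendrogram:
    """Average-linkage (UPGMA) agglomeration on a similarity matrix.

    At each step the two classes with the largest unweighted average of
    cross-class pairwise similarities are merged (equivalent to UPGMA on
    the dissimilarity 1 - S).
    """
    if sim.m < 2:
        raise ValueError("need at least 2 trees")
    v = sim.values

    def objective(a: FrozenSet[int], b: FrozenSet[int]) -> float:
        return float(np.mean([v[i, j] for i in a for j in b]))

    return _run_agglomeration(sim.m, objective)


def greedy_ascending_hierarchy(profile: Profile) -> Dendrogram:
    """Agglomeration maximizing the generalized score at each step.

    Among all fusions of two running classes, the one yielding the
    (k-1)-class partition of maximal generalized score is performed.  Only
    the terms touched by a fusion change, so each candidate is evaluated
    from the weight of the merged class alone.
    """
    if profile.m < 2:
        raise ValueError("need at least 2 trees")

    cache: Dict[FrozenSet[int], int] = {}

    def weight(c: FrozenSet[int]) -> int:
        if c not in cache:
            cache[c] = class_majority_weight(profile, c)
        return cache[c]

    def objective(a: FrozenSet[int], b: FrozenSet[int]) -> int:
        # score delta vs. current partition is what matters; the shared
        # remainder Σ p_i W_i over untouched classes cancels in comparisons
        u = a | b
        return len(u) * weight(u) - len(a) * weight(a) - len(b) * weight(b)

    return _run_agglomeration(profile.m, objective)


def score_hierarchy(profile: Profile, dendro: Dendrogram) -> List[ScoredPartition]:
    """Generalized score of every level of a hierarchy, k = m down to 1."""
    return [generalized_score(profile, part) for part in dendro.level_partitions]


@dataclass(frozen=True)
class SearchResult:
    """Outcome of the multi-hierarchy search.

    ``scores_by_method`` maps a method name to its per-level scores as a
    dict k -> W_k.  ``verdict`` is ``single`` when the best partition is
    the one-class partition, ``atomic`` when it is the partition into
    singletons, and ``multiple`` otherwise.
    """

    scores_by_method: Dict[str, Dict[int, int]]
    levels_by_method: Dict[str, Tuple[ScoredPartition, ...]]
    best: ScoredPartition
    verdict: str


def _preference(sp: ScoredPartition) -> Tuple:
    # maximize score; on ties prefer the single class (homogeneity is the
    # null position), then fewer classes
    return (-sp.score, sp.k != 1, sp.k)


def best_partition(
    profile: Profile, methods: Sequence[str] = DEFAULT_METHODS
) -> SearchResult:
    """Run the requested hierarchies and return the best-scoring partition.

    ``methods`` is a subset of {"rf", "qs", "greedy"}.  The single-class
    partition and the atomic partition sit at the ends of every hierarchy,
    so both are always scored.
    """
    if profile.m < 2:
        raise ValueError("need at least 2 trees")
    methods = tuple(dict.fromkeys(m.lower() for m in methods))
    unknown = set(methods) - set(DEFAULT_METHODS)
    if unknown:
        raise ValueError(f"unknown methods: {sorted(unknown)}")
    if not methods:
        raise ValueError("no methods requested")

    levels_by_method: Dict[str, Tuple[ScoredPartition, ...]] = {}
    scores_by_method: Dict[str, Dict[int, int]] = {}
    candidates: List[ScoredPartition] = []
    for method in methods:
        if method == "greedy":
            dendro = greedy_ascending_hierarchy(profile)
        else:
            dendro = average_linkage_hierarchy(similarity_matrix(profile, method))
        scored = score_hierarchy(profile, dendro)
        levels_by_method[method] = tuple(scored)
        scores_by_method[method] = {sp.k: sp.score for sp in scored}
        candidates.extend(scored)

    best = min(candidates, key=_preference)
    if best.k == 1:
        verdict = "single"
    elif best.partition.is_atomic:
        verdict = "atomic"
    else:
        verdict = "multiple"
    return SearchResult(
        scores_by_method=scores_by_method,
        levels_by_method=levels_by_method,
        best=best,
        verdict=verdict,
    )


def iter_set_partitions(items: Sequence[int]):
    """Yield all set partitions of ``items`` (Bell-number many)."""
    items = list(items)
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in iter_set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [part[i] + [first]] + part[i + 1 :]
        yield [[first]] + part


def exhaustive_best_partition(profile: Profile) -> ScoredPartition:
    """Global optimum of the generalized score over all set partitions.

    Only feasible for small profiles (m <= 10); refuses larger ones.  Ties
    are resolved like the hierarchical search: single class first, then
    fewer classes.
    """
    if profile.m > EXHAUSTIVE_MAX_M:
        raise ValueError(
            f"exhaustive search limited to m <= {EXHAUSTIVE_MAX_M}, got {profile.m}"
        )
    best_part: Optional[TreePartition] = None
    best_key = None
    for raw in iter_set_partitions(range(profile.m)):
        part = TreePartition.from_sets(raw)
        score = sum(
            len(c) * class_majority_weight(profile, c) for c in part.classes
        )
        key = (-score, part.k != 1, part.k)
        if best_key is None or key < best_key:
            best_key, best_part = key, part
    return generalized_score(profile, best_part)
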