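"""Pairwise tree similarities: Robinson-Foulds rate and quartet-share rate.

Both similarities map a pair of X-trees to [0, 1] and drive the
average-linkage clustering of a profile.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Dict, FrozenSet, Tuple

import numpy as np

from .tree_io import Profile, XTree

__all__ = [
    "SimilarityMatrix",
    "rf_similarity",
    "quartet_similarity",
    "similarity_matrix",
]

METHODS = ("rf", "qs")


@dataclass(frozen=True)
class SimilarityMatrix:
    """Symmetric m x m matrix of pairwise tree similarities in [0, 1]."""

    values: np.ndarray
    method: str

    def __post_init__(self) -> None:
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("similarity matrix must be square")
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}")

    @property
    def m(self) -> int:
        return self.values.shape[0]

    def __getitem__(self, ij) -> float:
        return float(self.values[ij])

    def to_tsv(self, names=None) -> str:
        names = list(names) if names is not None else [str(i + 1) for i in range(self.m)]
        lines = ["\t".join([""] + names)]
        for i in range(self.m):
            lines.append("\t".join([names[i]] + [f"{self.values[i, j]:.6f}" for j in range(self.m)]))
        return "\n".join(lines) + "\n"


def rf_similarity(t1: XTree, t2: XTree) -> float:
    """Robinson-Foulds similarity: 2 |T1 ∩ T2| / (|T1| + |T2|).

    Trees are identified with their internal-edge split sets.  Two star
    trees have identical (empty) split sets, so their similarity is
    defined as 1 rather than 0/0.
    """
    if t1.leaves != t2.leaves:
        raise ValueError("trees are over different leaf sets")
    denom = t1.internal_edge_count + t2.internal_edge_count
    if denom == 0:
        return 1.0
    return 2.0 * len(t1.splits & t2.splits) / denom


PairKey = Tuple[str, str, str, str]


def _quartet_pairings(tree: XTree) -> Dict[PairKey, FrozenSet[FrozenSet[str]]]:
    """Resolved quartets of a tree, keyed by sorted taxon 4-tuple.

    Quartet {x,y,z,t} resolves as xy|zt iff some internal edge separates
    {x,y} from {z,t}.  Every split A|B resolves the quartets with two taxa
    on each side; splits of one tree never disagree on a quartet.
    Quartets not present in the map are unresolved in the tree.
    """
    out: Dict[PairKey, FrozenSet[FrozenSet[str]]] = {}
    for s in tree.splits:
        for x, y in combinations(sorted(s.side_a), 2):
            pa = frozenset((x, y))
            for z, t in combinations(sorted(s.side_b), 2):
                key = tuple(sorted((x, y, z, t)))
                out[key] = frozenset((pa, frozenset((z, t))))
    return out


def quartet_similarity(t1: XTree, t2: XTree) -> float:
    """Rate of common quartets (QS similarity).

    Per quartet of taxa: 1 point if both trees resolve it to the same
    pairing or both leave it unresolved, half a point if exactly one tree
    resolves it, 0 if both resolve it differently.  The sum is normalized
    by C(n, 4) so the rate lies in [0, 1].
    """
    if t1.leaves != t2.leaves:
        raise ValueError("trees are over different leaf sets")
    n = t1.n
    if n < 4:
        raise ValueError("quartet similarity needs >= 4 leaves")
    q1 = _quartet_pairings(t1)
    q2 = _quartet_pairings(t2)
    return _qs_from_pairings(q1, q2, sorted(t1.leaves))


def _qs_from_pairings(q1, q2, labels) -> float:
    points = 0.0
    total = 0
    for quad in combinations(labels, 4):
        total += 1
        p1 = q1.get(quad)
        p2 = q2.get(quad)
        if p1 is None and p2 is None:
            points += 1.0
        elif p1 is None or p2 is None:
            points += 0.5
        elif p1 == p2:
            points += 1.0
    return points / total


def similarity_matrix(profile: Profile, method: str = "rf") -> SimilarityMatrix:
    """Full symmetric similarity matrix of a profile (m >= 2)."""
    method = method.lower()
    if method not in METHODS:
        raise ValueError(f"method must be one of {METHODS}, got {method!r}")
    m = profile.m
    vals = np.ones((m, m))
    if method == "rf":
        for i, j in combinations(range(m), 2):
            vals[i, j] = vals[j, i] = rf_similarity(profile[i], profile[j])
        for i in range(m):
            vals[i, i] = rf_similarity(profile[i], profile[i])
    else:
        labels = sorted(profile.X)
        tables = [_quartet_pairings(t) for t in profile.trees]
        for i, j in combinations(range(m), 2):
            vals[i, j] = vals[j, i] = _qs_from_pairings(tables[i], tables[j], labels)
    return SimilarityMatrix(values=vals, method=method)
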