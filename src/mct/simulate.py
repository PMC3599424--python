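"""Synthetic tree profiles from simulated sequence evolution.

The generator reproduces a standard validation protocol for gene-tree
heterogeneity methods: fix a rooted 16-leaf topology (balanced, caterpillar
or random), evolve a 1000-nucleotide sequence down it under a
substitution-only model with a 3:1 transition:transversion ratio and an
overall substitution load of 0.25 changes per root character, compute
Kimura two-parameter distances between the tip sequences, and reconstruct
an X-tree with neighbor joining.  Repeating this with fresh random branch
lengths yields a family of gene trees that share a generating topology but
differ in detail; mixing three families gives a profile with a known
three-class structure.  Uniform random resolved topologies provide the
opposite, structure-free, control.

All randomness flows from a single integer seed through
``numpy.random.default_rng``; child generators for independent gene trees
are derived with ``Generator.spawn`` so runs are bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Dict, FrozenSet, List, Optional, Sequence, Tuple, Union

import numpy as np
from skbio import DistanceMatrix as _SkbioDM
from skbio.tree import nj as _skbio_nj

from .splits import Bipartition
from .tree_io import Profile, XTree, parse_newick

__all__ = [
    "SimulationConfig",
    "RootedTopology",
    "make_topology",
    "evolve_sequences",
    "kimura_distance",
    "distance_matrix",
    "nj_tree",
    "simulate_gene_tree",
    "make_three_class_profile",
    "make_random_profile",
    "write_fasta",
]

TOPOLOGY_KINDS = ("balanced", "caterpillar", "random")
NUCLEOTIDES = ("A", "C", "G", "T")
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {
    "A": ("C", "T"),
    "G": ("C", "T"),
    "C": ("A", "G"),
    "T": ("A", "G"),
}
_PURINES = frozenset("AG")

#: relative branch-length laws (rescaled afterwards, so only the shape of
#: the distribution matters).  "exponential" draws Exp(1): edge lengths
#: vary widely, so reconstructed gene trees within a family agree on most
#: but not all splits, as bootstrap-like tree sets do.  "uniform" draws
#: U(0.5, 1.5): every edge receives appreciable length and families become
#: nearly noise-free; useful for isolating topology effects.
BRANCH_LENGTH_MODELS = {
    "exponential": lambda rng, size: rng.exponential(1.0, size=size),
    "uniform": lambda rng, size: rng.uniform(0.5, 1.5, size=size),
}


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the sequence-evolution protocol.

    substitution_rate is the expected fraction of root characters that
    differ at an average tip; branch lengths are rescaled so that, after
    accounting for multiple hits and reversions, the expected observed
    root-to-tip divergence equals this value.  transition_fraction
    is the probability that a substitution is a transition (A<->G, C<->T);
    the default 3/4 encodes the 3:1 transition:transversion ratio.
    trees_per_class is the number of gene trees simulated per topology
    family when assembling a three-class profile.
    """

    n_leaves: int = 16
    trees_per_class: int = 10
    seq_length: int = 1000
    substitution_rate: float = 0.25
    transition_fraction: float = 0.75
    branch_length_model: str = "exponential"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_leaves < 4:
            raise ValueError("n_leaves must be >= 4")
        if self.trees_per_class < 1 or self.seq_length < 1:
            raise ValueError("counts must be positive")
        if not (0 <= self.substitution_rate < 1):
            raise ValueError("substitution_rate must be in [0, 1)")
        if not (0 <= self.transition_fraction <= 1):
            raise ValueError("transition_fraction must be in [0, 1]")
        if self.branch_length_model not in BRANCH_LENGTH_MODELS:
            raise ValueError(
                f"branch_length_model must be one of {tuple(BRANCH_LENGTH_MODELS)}"
            )

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass(frozen=True)
class RootedTopology:
    """A rooted binary shape used to drive sequence evolution.

    ``children`` is empty for a leaf (then ``label`` is set).  Branch
    lengths, when present, are expected substitutions per site on the edge
    above each child.
    """

    children: Tuple["RootedTopology", ...] = ()
    label: Optional[str] = None
    branch_lengths: Tuple[float, ...] = ()

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaf_labels(self) -> List[str]:
        if self.is_leaf:
            return [self.label]
        out: List[str] = []
        for c in self.children:
            out.extend(c.leaf_labels())
        return out

    def cherry_count(self) -> int:
        """Internal nodes whose children are exactly two leaves."""
        if self.is_leaf:
            return 0
        if len(self.children) == 2 and all(c.is_leaf for c in self.children):
            return 1
        return sum(c.cherry_count() for c in self.children)

    def to_xtree(self) -> XTree:
        """The unrooted X-tree induced by the rooted shape."""
        leaves = frozenset(self.leaf_labels())
        n = len(leaves)
        splits = set()

        def walk(node: "RootedTopology") -> FrozenSet[str]:
            if node.is_leaf:
                return frozenset([node.label])
            below = frozenset().union(*(walk(c) for c in node.children))
            if 2 <= len(below) <= n - 2:
                splits.add(Bipartition(below, leaves - below))
            return below

        walk(self)
        return XTree(leaves=leaves, splits=frozenset(splits))


def default_labels(n: int) -> List[str]:
    width = len(str(n))
    return [f"t{str(i + 1).zfill(width)}" for i in range(n)]


def make_topology(
    kind: str,
    n: int,
    seed: Union[int, np.random.Generator, None] = None,
    labels: Optional[Sequence[str]] = None,
) -> RootedTopology:
    """A rooted binary topology of one of the three study families.

    balanced: every subdivision splits the leaves in half (n must be a
    power of two; at n = 16 the tree has 8 cherries).  caterpillar: every
    subdivision is one taxon against the rest (a single cherry).  random:
    recursive uniform random subdivision of the leaf set.

    ``labels`` fixes the order in which taxa fill the shape (default
    t01..tNN in order); passing a permuted order yields the same shape
    with a different taxon arrangement.
    """
    if n < 4:
        raise ValueError("need n >= 4 leaves")
    if kind not in TOPOLOGY_KINDS:
        raise ValueError(f"kind must be one of {TOPOLOGY_KINDS}, got {kind!r}")
    labels = list(labels) if labels is not None else default_labels(n)
    if len(labels) != n:
        raise ValueError(f"expected {n} labels, got {len(labels)}")
    if kind == "balanced":
        if n & (n - 1):
            raise ValueError(f"balanced topology needs a power-of-2 leaf count, got {n}")
        return _balanced(labels)
    if kind == "caterpillar":
        node = RootedTopology(label=labels[0])
        node = RootedTopology(children=(node, RootedTopology(label=labels[1])))
        for lbl in labels[2:]:
            node = RootedTopology(children=(node, RootedTopology(label=lbl)))
        return node
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return _random_subdivision(labels, rng)


def _balanced(labels: Sequence[str]) -> RootedTopology:
    if len(labels) == 1:
        return RootedTopology(label=labels[0])
    h = len(labels) // 2
    return RootedTopology(children=(_balanced(labels[:h]), _balanced(labels[h:])))


def _random_subdivision(labels: Sequence[str], rng: np.random.Generator) -> RootedTopology:
    if len(labels) == 1:
        return RootedTopology(label=labels[0])
    size = int(rng.integers(1, len(labels)))
    idx = rng.permutation(len(labels))
    left = [labels[i] for i in sorted(idx[:size])]
    right = [labels[i] for i in sorted(idx[size:])]
    return RootedTopology(
        children=(_random_subdivision(left, rng), _random_subdivision(right, rng))
    )


def expected_divergence(load: float, ts_fraction: float) -> float:
    """Expected fraction of sites differing from the root after a path
    carrying ``load`` expected substitutions per site.

    The substitution chain (transition with probability ``ts_fraction``,
    otherwise a uniform transversion) is a Kimura two-parameter process
    with transition rate a = ts_fraction and per-transversion rate
    b = (1 - ts_fraction) / 2 per unit load, giving

        p_diff(t) = 3/4 - 1/4 exp(-4bt) - 1/2 exp(-2(a+b)t).
    """
    a = ts_fraction
    b = (1.0 - ts_fraction) / 2.0
    return 0.75 - 0.25 * math.exp(-4 * b * load) - 0.5 * math.exp(-2 * (a + b) * load)


def _load_for_divergence(rate: float, ts_fraction: float) -> float:
    """Invert :func:`expected_divergence`: the per-site substitution load at
    which the expected observed root-to-tip divergence equals ``rate``."""
    if rate == 0:
        return 0.0
    ceiling = 0.75 - (0.25 if ts_fraction >= 1.0 else 0.0)
    if rate >= ceiling:
        raise ValueError(
            f"divergence {rate} unreachable (saturation ceiling {ceiling})"
        )
    lo, hi = 0.0, 1.0
    while expected_divergence(hi, ts_fraction) < rate:
        hi *= 2.0
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if expected_divergence(mid, ts_fraction) < rate:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _with_random_lengths(
    topo: RootedTopology,
    load: float,
    rng: np.random.Generator,
    sampler=BRANCH_LENGTH_MODELS["exponential"],
) -> RootedTopology:
    """Attach i.i.d. random branch lengths, rescaled so the mean
    root-to-tip path carries ``load`` expected substitutions per site."""

    def attach(node: RootedTopology) -> RootedTopology:
        if node.is_leaf:
            return node
        kids = tuple(attach(c) for c in node.children)
        bls = tuple(float(x) for x in np.atleast_1d(sampler(rng, len(kids))))
        return replace(node, children=kids, branch_lengths=bls)

    drawn = attach(topo)

    # mean over leaves of the root-to-tip branch-length sum
    def tip_paths(node: RootedTopology, acc: float) -> List[float]:
        if node.is_leaf:
            return [acc]
        out: List[float] = []
        for c, bl in zip(node.children, node.branch_lengths):
            out.extend(tip_paths(c, acc + bl))
        return out

    paths = tip_paths(drawn, 0.0)
    mean_path = sum(paths) / len(paths)
    if load == 0 or mean_path == 0:
        scale = 0.0
    else:
        scale = load / mean_path

    def rescale(node: RootedTopology) -> RootedTopology:
        if node.is_leaf:
            return node
        return replace(
            node,
            children=tuple(rescale(c) for c in node.children),
            branch_lengths=tuple(bl * scale for bl in node.branch_lengths),
        )

    return rescale(drawn)


def _mutate(seq: List[str], n_subs: int, ts_fraction: float, rng: np.random.Generator) -> None:
    L = len(seq)
    for _ in range(n_subs):
        pos = int(rng.integers(L))
        base = seq[pos]
        if rng.random() < ts_fraction:
            seq[pos] = _TRANSITION[base]
        else:
            seq[pos] = _TRANSVERSIONS[base][int(rng.integers(2))]


def evolve_sequences(
    topology: RootedTopology,
    config: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
    include_root: bool = False,
):
    """Evolve a random root sequence down a topology; return tip sequences.

    Branch lengths are drawn fresh (i.i.d. from the configured law,
    rescaled so the mean root-to-tip path yields the configured expected
    divergence) unless the topology already carries them.  On each branch
    the substitution count is Poisson(length x L);
    substitutions hit uniform random positions, the new base being the
    transition of the old one with probability ``transition_fraction`` and
    otherwise one of its two transversions, uniformly.  Multiple hits at a
    site are allowed and may revert earlier changes.

    Returns the map leaf label -> sequence; with ``include_root`` the
    root sequence is returned as a second value.
    """
    if rng is None:
        rng = config.rng()
    has_lengths = bool(topology.branch_lengths) or topology.is_leaf
    if not has_lengths:
        load = _load_for_divergence(
            config.substitution_rate, config.transition_fraction
        )
        topology = _with_random_lengths(
            topology, load, rng, BRANCH_LENGTH_MODELS[config.branch_length_model]
        )
    L = config.seq_length
    root_seq = [NUCLEOTIDES[i] for i in rng.integers(4, size=L)]
    tips: Dict[str, str] = {}

    def walk(node: RootedTopology, seq: List[str]) -> None:
        if node.is_leaf:
            tips[node.label] = "".join(seq)
            return
        for child, bl in zip(node.children, node.branch_lengths):
            child_seq = list(seq)
            n_subs = int(rng.poisson(bl * L))
            _mutate(child_seq, n_subs, config.transition_fraction, rng)
            walk(child, child_seq)

    walk(topology, root_seq)
    if include_root:
        return tips, "".join(root_seq)
    return tips


def kimura_distance(s1: str, s2: str) -> float:
    """Kimura two-parameter distance between two aligned sequences.

    With P and Q the observed proportions of transition- and
    transversion-type differences, d = -1/2 ln[(1 - 2P - Q) sqrt(1 - 2Q)].
    Raises on saturation (non-positive logarithm argument).
    """
    if len(s1) != len(s2):
        raise ValueError("sequences must have equal length")
    L = len(s1)
    if L == 0:
        raise ValueError("empty sequences")
    ts = tv = 0
    for a, b in zip(s1, s2):
        if a == b:
            continue
        if (a in _PURINES) == (b in _PURINES):
            ts += 1
        else:
            tv += 1
    P, Q = ts / L, tv / L
    x = 1.0 - 2.0 * P - Q
    y = 1.0 - 2.0 * Q
    if x <= 0 or y <= 0:
        raise ValueError(
            f"saturated pair (P={P:.3f}, Q={Q:.3f}): Kimura distance undefined"
        )
    return -0.5 * math.log(x * math.sqrt(y))


def distance_matrix(sequences: Dict[str, str]) -> Tuple[List[str], np.ndarray]:
    """Pairwise Kimura distance matrix of a set of labelled sequences."""
    labels = sorted(sequences)
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = kimura_distance(sequences[labels[i]], sequences[labels[j]])
    return labels, d


def nj_tree(d: np.ndarray, labels: Sequence[str]) -> XTree:
    """Neighbor-joining tree from a distance matrix, as an unrooted X-tree."""
    if len(labels) < 4:
        raise ValueError("need >= 4 taxa")
    sk_tree = _skbio_nj(_SkbioDM(d, ids=list(labels)))
    return parse_newick(str(sk_tree))


def simulate_gene_tree(
    topology: RootedTopology,
    config: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
) -> XTree:
    """One gene tree: fresh branch lengths, sequence evolution, K2P, NJ."""
    if rng is None:
        rng = config.rng()
    seqs = evolve_sequences(topology, config, rng)
    labels, d = distance_matrix(seqs)
    return nj_tree(d, labels)


def _distinct_family_topologies(
    n: int, rng: np.random.Generator, max_tries: int = 200
) -> List[RootedTopology]:
    """One balanced, one caterpillar and one random topology, pairwise
    sharing no split.

    Each family fills its shape with an independent random arrangement of
    the taxa, and the trio is redrawn until the three unrooted topologies
    are split-disjoint.  Without this the shapes can coincidentally share
    cherries, which blurs the class structure the protocol is meant to
    produce: the profile is supposed to be clearly composed of three
    classes.
    """
    base = default_labels(n)
    for _ in range(max_tries):
        def permuted():
            return [base[i] for i in rng.permutation(n)]

        topologies = [
            make_topology("balanced", n, labels=permuted()),
            make_topology("caterpillar", n, labels=permuted()),
            make_topology("random", n, rng, labels=permuted()),
        ]
        xtrees = [t.to_xtree() for t in topologies]
        if (
            not (xtrees[0].splits & xtrees[1].splits)
            and not (xtrees[0].splits & xtrees[2].splits)
            and not (xtrees[1].splits & xtrees[2].splits)
        ):
            return topologies
    raise RuntimeError(f"no split-disjoint topology trio found in {max_tries} tries")


def iter_three_class_genes(config: SimulationConfig):
    """Yield (class_index, tip_sequences, gene_tree) for the three-class protocol.

    For each of the balanced, caterpillar and random topologies on
    ``n_leaves`` leaves, ``trees_per_class`` genes are simulated with
    independent branch lengths, root sequences and substitution histories;
    each yields its reconstructed NJ tree together with the tip sequences
    it came from.
    """
    rng = config.rng()
    topo_rng, *gene_rngs = rng.spawn(1 + 3 * config.trees_per_class)
    topologies = _distinct_family_topologies(config.n_leaves, topo_rng)
    gi = 0
    for cls, topo in enumerate(topologies):
        for _ in range(config.trees_per_class):
            seqs = evolve_sequences(topo, config, gene_rngs[gi])
            labels, d = distance_matrix(seqs)
            yield cls, seqs, nj_tree(d, labels)
            gi += 1


def make_three_class_profile(
    config: SimulationConfig,
) -> Tuple[Profile, List[int]]:
    """A profile of three gene-tree families with known class labels.

    For each of the balanced, caterpillar and random 16-leaf topologies,
    ``trees_per_class`` gene trees are reconstructed from independent
    sequence simulations; the concatenated profile (default 30 trees) and
    the ground-truth class index (0, 1, 2) of every tree are returned.
    """
    trees: List[XTree] = []
    labels: List[int] = []
    for cls, _seqs, tree in iter_three_class_genes(config):
        trees.append(tree)
        labels.append(cls)
    return Profile.from_trees(trees), labels


def make_random_profile(
    m: int, n: int, seed: Union[int, np.random.Generator, None] = None
) -> Profile:
    """m independent uniform random resolved topologies on n leaves.

    Uniformity over labelled resolved topologies is obtained by sequential
    random edge addition: leaf k+1 is attached to an edge chosen uniformly
    among the 2k - 3 edges of the current k-leaf tree.
    """
    if m < 1 or n < 4:
        raise ValueError("need m >= 1 trees and n >= 4 leaves")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    labels = default_labels(n)
    return Profile.from_trees(_random_resolved_tree(labels, rng) for _ in range(m))


def _random_resolved_tree(labels: Sequence[str], rng: np.random.Generator) -> XTree:
    # adjacency-list construction; node ids: 0..n-1 leaves, internals >= n
    n = len(labels)
    adj: Dict[int, set] = {0: {n}, 1: {n}, 2: {n}, n: {0, 1, 2}}
    edges: List[Tuple[int, int]] = [(0, n), (1, n), (2, n)]
    next_id = n + 1
    for leaf in range(3, n):
        u, v = edges[int(rng.integers(len(edges)))]
        w = next_id
        next_id += 1
        adj[u].discard(v)
        adj[v].discard(u)
        adj[u].add(w)
        adj[v].add(w)
        adj[w] = {u, v, leaf}
        adj[leaf] = {w}
        edges.remove((u, v))
        edges.extend([(u, w), (v, w), (leaf, w)])

    leaves = frozenset(labels)
    splits = set()
    for u, v in edges:
        if u < n or v < n:
            continue  # pendant edge
        # leaves on u's side of edge (u, v)
        seen = {v}
        stack = [u]
        side = set()
        while stack:
            x = stack.pop()
            if x in seen:
                continue
            seen.add(x)
            if x < n:
                side.add(labels[x])
            else:
                stack.extend(adj[x])
        splits.add(Bipartition(frozenset(side), leaves - frozenset(side)))
    return XTree(leaves=leaves, splits=frozenset(splits))


def write_fasta(sequences: Dict[str, str], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for label in sorted(sequences):
            fh.write(f">{label}\n{sequences[label]}\n")
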