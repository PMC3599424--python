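# Methods

## Model

A profile is an ordered list of m unrooted trees leaf-labelled by the
same taxon set X (|X| = n ≥ 4). Each tree is reduced to its split set:
one bipartition of X per internal edge, both sides of size ≥ 2. Branch
lengths and internal labels are parsed and discarded; multifurcating
trees are accepted everywhere, and rooted input is collapsed at the root
(which changes no split).

For a class of p trees, the support m_i of a split is the number of class
trees containing it. The majority consensus keeps the splits with
m_i > p/2 — strictly, for even and odd p alike — which are always
pairwise compatible and hence realized by a unique tree. Its weight is
W = Σ m_i over those splits. The generalized score of a partition of the
profile into k classes is Σ p_i·W_i. All scores are exact integers; no
floating point enters the criterion, so there are no tolerance questions
in the decision rule. The verdict is *single* when the one-class
partition attains the maximum observed score (ties resolve toward the
single class: homogeneity is the null position, and more structure is
only claimed on a strict improvement), *atomic* when the partition into
singletons wins, and *multiple* otherwise.

For two trees with n1 and n2 internal edges sharing k splits, the
single-class score is 4k (each shared split has support 2 and the class
has 2 members) against an atomic score n1 + n2, so a pair admits a single
consensus iff 4k > n1 + n2 — more than half of each tree's edges shared,
when both trees are equally resolved.

## Partition search

Scoring all set partitions is infeasible (Bell numbers), so nested
partition series with m, m−1, …, 1 classes are built by three
agglomerations and every level of every series is scored:

* **AL(RF)** — average linkage on Robinson-Foulds similarity
  S = 2·|shared splits| / (n1 + n2), with S ≡ 1 for two star trees
  (identical empty split sets, avoiding 0/0);
* **AL(QS)** — average linkage on the quartet-share rate: per leaf
  quartet, 1 point if both trees resolve it identically or both leave it
  unresolved, ½ if exactly one resolves it, 0 otherwise, normalized by
  C(n,4). A quartet is resolved xy|zt in a tree iff some split separates
  {x,y} from {z,t}; the scorer enumerates, per split, the pairs on each
  side (O(Σ |A|²|B|²/4), comfortably fast at the n this method targets);
* **GA** — greedy ascending: at each step, among all C(k,2) class
  fusions, perform the one whose (k−1)-class partition scores highest.
  Only the merged class's term changes, so candidates are evaluated from
  cached class weights.

Average linkage merges the pair of classes with the maximal unweighted
mean of cross-class pairwise similarities (UPGMA on dissimilarity 1−S).
Both agglomerations break ties deterministically: among equal-valued
merges, the pair whose class representatives (smallest member indices)
are lexicographically smallest wins, with the full sorted class contents
as a final tie-break. On the worked five-tree example this rule takes the
{T1,T5} merge first, and the greedy path proceeds {T1,T5} → +T2 →
{T3,T4}, ending at the two-class optimum with score 39.

The hierarchical best is a lower bound on the true optimum; an exhaustive
Bell-number enumeration (`exhaustive_best_partition`, refused for m > 10)
certifies optimality on small profiles and anchors randomized tests.

The extended majority consensus (reported alongside, never scored)
completes the majority tree greedily with minority splits in decreasing
support order, accepting a split iff compatible with everything already
accepted. The completion is ambiguous at equal support; the documented
tie rule is order of first appearance in the profile (trees in input
order, splits in canonical lexicographic order within a tree). On the
worked example this completes the majority tree back to the first input
tree; other tie rules produce the other completions, all equally legal.

## Synthetic data

The simulator reproduces the standard validation protocol for this class
of methods. Defaults (all overridable in `SimulationConfig`):

| parameter | default | meaning |
|---|---|---|
| n_leaves | 16 | taxa per tree |
| trees_per_class | 10 | gene trees per topology family |
| seq_length | 1000 | nucleotides |
| substitution_rate | 0.25 | expected observed root-to-tip divergence |
| transition_fraction | 0.75 | P(substitution is a transition), i.e. ts:tv = 3:1 |
| branch_length_model | exponential | relative edge-length law |

Three rooted family topologies are drawn once per run: balanced (8
cherries at n = 16), caterpillar (1 cherry), and a recursive uniform
random subdivision. Each family fills its shape with an independent
random arrangement of the taxa, and the trio is redrawn until the three
unrooted topologies share no split — the protocol is meant to produce a
profile clearly composed of three classes, and coincidentally shared
cherries would blur exactly the structure being planted.

Per gene tree: i.i.d. relative branch lengths (Exp(1) by default) are
rescaled so the mean root-to-tip path carries the substitution load at
which the *observed* divergence equals `substitution_rate` (for rate 0.25
and ts:tv 3:1 the load is 0.3178 substitutions/site — the inversion of
the K2P divergence curve accounts for multiple hits and reversions, so
on average 25% of root characters differ at the tips). Substitution
counts per branch are Poisson(length × L) at uniform positions; each
substitution is the transition of the current base with probability 3/4,
else one of its two transversions. Kimura two-parameter distances
d = −½ ln[(1−2P−Q)√(1−2Q)] between the tips feed neighbor joining
(scikit-bio), and the reconstructed topology joins the profile.
`make_random_profile` instead samples uniform random resolved topologies
by sequential random edge addition. All randomness flows from one integer
seed through `numpy.random.default_rng`, with per-gene child generators
spawned from it.

What the generator does *not* emulate: alignment uncertainty and indels
(sequences evolve without gaps, as in the original protocol), rate
heterogeneity across sites, and saturation (the K2P distance raises on a
non-positive log argument rather than capping). Passing simulation tests
therefore show that the score criterion separates topologically planted
classes under substitution noise — not that it is robust to alignment
error or model misspecification on real data.

## Numerical and degenerate-input choices

* Majority threshold is strictly greater than p/2 for all p.
* Two star trees: RF similarity 1; quartet similarity of two stars is 1
  by the both-unresolved rule.
* Saturated sequence pairs make the K2P distance undefined and raise.
* A profile of one tree is legal (its consensus is the tree itself, with
  weight = internal-edge count); similarity matrices and hierarchies
  require m ≥ 2.
* Leaf labels are matched as exact strings; duplicate or empty labels are
  rejected at parse time, and leaf-set mismatches report the offending
  tree index and the symmetric difference of labels.

## Known limitations

* The hierarchical search is heuristic: the best score over the three
  hierarchies can be below the true optimum over all partitions (the
  exhaustive oracle is limited to m ≤ 10).
* The greedy hierarchy can *exceed* the score of a planted partition by
  absorbing trees of a weakly cohesive class into another class: once a
  class is large, adding a foreign tree raises the score by roughly the
  class weight, and the rising majority threshold only penalizes this
  when the donor class has many mid-support splits. On simulated
  three-class profiles with exponential branch lengths this occasionally
  makes a two-class absorbing partition the top scorer even though
  average-linkage hierarchies alone recover the planted three classes;
  the acceptance test for the simulation study measures exactly this
  behavior. With near-noise-free families (uniform branch lengths) the
  planted and absorbing partitions tie exactly, which is why `uniform`
  is not the default.
* Scores grow quadratically with class sizes, so the criterion favors
  large classes; near-ties between partitions of different k are decided
  by the documented preferences, not by any significance measure.
* Profiles over non-identical taxon sets (supertree setting) are out of
  scope.
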