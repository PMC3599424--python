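"""Independent brute-force oracles used by the tests."""

import itertools


def quartet_topology_bruteforce(tree, quad):
    """Independent quartet oracle: try each of the three pairings against
    every split of the tree; None if no split separates any pairing."""
    for pairing in ((0, 1, 2, 3), (0, 2, 1, 3), (0, 3, 1, 2)):
        a = {quad[pairing[0]], quad[pairing[1]]}
        b = {quad[pairing[2]], quad[pairing[3]]}
        for s in tree.splits:
            if (a <= s.side_a and b <= s.side_b) or (a <= s.side_b and b <= s.side_a):
                return frozenset((frozenset(a), frozenset(b)))
    return None


def quartet_similarity_bruteforce(t1, t2):
    """Naive O(n^4) quartet-share rate used as the reference oracle."""
    points, total = 0.0, 0
    for quad in itertools.combinations(sorted(t1.leaves), 4):
        total += 1
        a = quartet_topology_bruteforce(t1, quad)
        b = quartet_topology_bruteforce(t2, quad)
        if a is None and b is None:
            points += 1.0
        elif a is None or b is None:
            points += 0.5
        elif a == b:
            points += 1.0
    return points / total
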