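"""Small built-in datasets used in the documentation and tests."""

from __future__ import annotations

from .tree_io import Profile, parse_profile

#: A five-tree, seven-leaf profile whose best partition splits it into two
#: classes, {T1, T2, T5} and {T3, T4}, each with a well-resolved majority
#: consensus.  It is small enough that every quantity (split counts,
#: consensus weights, generalized scores, the exhaustive optimum over all
#: 52 partitions) can be checked by hand, and it is used as the worked
#: example throughout the documentation.
EXAMPLE_NEWICKS = (
    "((1,2),3,((4,5),(6,7)));",
    "((1,2),3,((4,6),(5,7)));",
    "((((1,3),5),2),4,(6,7));",
    "((((1,5),3),2),4,(6,7));",
    "(((1,3),2),(4,5),(6,7));",
)


def example_profile() -> Profile:
    """The five-tree worked-example profile (m = 5, n = 7)."""
    return parse_profile("\n".join(EXAMPLE_NEWICKS))
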