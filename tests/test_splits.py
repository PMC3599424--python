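import pytest

from mct.simulate import make_random_profile
from mct.splits import (
    Bipartition,
    are_compatible,
    extended_majority_consensus,
    extract_splits,
    majority_consensus,
    split_counts,
    strict_consensus,
    tree_from_splits,
)
from mct.tree_io import parse_newick

X7 = frozenset("1234567")


def bip(side, universe=X7):
    side = set(side)
    return Bipartition(side, set(universe) - side)


# the ten distinct splits of the worked five-tree profile, in table order
ROWS = {
    1: bip("12"),
    2: bip("123"),
    3: bip("12345"),
    4: bip("12367"),
    5: bip("12346"),
    6: bip("12357"),
    7: bip("13"),
    8: bip("135"),
    9: bip("1235"),
    10: bip("15"),
}
TREE_ROWS = {0: {1, 2, 3, 4}, 1: {1, 2, 5, 6}, 2: {3, 7, 8, 9}, 3: {3, 8, 9, 10}, 4: {2, 3, 4, 7}}


class TestBipartition:
    def test_canonical_orientation(self):
        a = Bipartition({"3", "4"}, {"1", "2"})
        b = Bipartition({"1", "2"}, {"3", "4"})
        assert a == b and hash(a) == hash(b)
        assert "1" in a.side_a

    def test_rejects_trivial_sides(self):
        with pytest.raises(ValueError):
            Bipartition({"1"}, {"2", "3"})

    def test_rejects_overlap(self):
        with pytest.raises(ValueError):
            Bipartition({"1", "2"}, {"2", "3"})


class TestExtractSplits:
    @pytest.mark.parametrize("tree_idx", range(5))
    def test_example_trees_match_split_table(self, profile5, tree_idx):
        expected = {ROWS[r] for r in TREE_ROWS[tree_idx]}
        assert extract_splits(profile5[tree_idx]) == expected

    def test_star_tree(self):
        assert extract_splits(parse_newick("(1,2,3,4,5);")) == set()


class TestSplitCounts:
    def test_example_profile_counts(self, profile5):
        wss = split_counts(profile5)
        expected = {r: sum(r in rows for rows in TREE_ROWS.values()) for r in ROWS}
        assert len(wss.counts) == 10
        assert wss.counts == {ROWS[r]: c for r, c in expected.items()}
        assert wss.counts[ROWS[2]] == 3
        assert wss.counts[ROWS[3]] == 4

    def test_single_tree_counts_are_one(self, profile5):
        wss = split_counts(profile5.subprofile([0]))
        assert set(wss.counts.values()) == {1}

    def test_identical_trees_count_m(self, profile5):
        from mct.tree_io import Profile

        prof = Profile.from_trees([profile5[0]] * 4)
        wss = split_counts(prof)
        assert set(wss.counts.values()) == {4}
        assert sum(wss.counts.values()) == sum(
            t.internal_edge_count for t in prof.trees
        )


class TestCompatibility:
    def test_disjoint_small_sides_compatible(self):
        assert are_compatible(ROWS[3], ROWS[4])

    def test_self_compatible(self):
        assert are_compatible(ROWS[1], ROWS[1])

    def test_conflicting_cherries_incompatible(self):
        assert not are_compatible(ROWS[1], ROWS[7])

    def test_mismatched_taxa_raise(self):
        other = Bipartition({"a", "b"}, {"c", "d"})
        with pytest.raises(ValueError):
            are_compatible(ROWS[1], other)


class TestMajorityConsensus:
    def test_full_example_profile(self, profile5):
        cons = majority_consensus(profile5)
        assert cons.splits == frozenset({ROWS[2], ROWS[3]})
        assert cons.support == {ROWS[2]: 3, ROWS[3]: 4}
        assert cons.weight == 7

    def test_two_tree_class(self, profile5):
        cons = majority_consensus(profile5.subprofile([2, 3]))
        assert cons.splits == frozenset({ROWS[3], ROWS[8], ROWS[9]})
        assert cons.weight == 6

    def test_three_tree_class(self, profile5):
        cons = majority_consensus(profile5.subprofile([0, 1, 4]))
        assert cons.splits == frozenset({ROWS[1], ROWS[2], ROWS[3], ROWS[4]})
        assert cons.weight == 9

    def test_singleton_class_is_tree_itself(self, profile5):
        cons = majority_consensus(profile5.subprofile([0]))
        assert cons.splits == profile5[0].splits
        assert cons.weight == profile5[0].internal_edge_count

    @pytest.mark.parametrize("seed", range(30))
    def test_majority_splits_pairwise_compatible_on_random_profiles(self, seed):
        # majority splits are mutually compatible for any profile; the
        # consensus constructor verifies this and would raise otherwise
        prof = make_random_profile(5 + seed % 4, 6 + seed % 3, seed)
        cons = majority_consensus(prof)
        assert all(c > prof.m / 2 for c in cons.support.values())


class TestStrictConsensus:
    def test_two_tree_class_equals_majority(self, profile5):
        sub = profile5.subprofile([2, 3])
        assert strict_consensus(sub).splits == majority_consensus(sub).splits

    def test_three_tree_class_single_common_edge(self, profile5):
        cons = strict_consensus(profile5.subprofile([0, 1, 4]))
        assert cons.splits == frozenset({ROWS[2]})

    def test_profile_with_star_gives_star(self, profile5):
        from mct.tree_io import Profile, XTree

        star = XTree(leaves=X7, splits=frozenset())
        prof = Profile.from_trees([profile5[0], star])
        assert strict_consensus(prof).tree.is_star


class TestExtendedMajorityConsensus:
    def test_example_profile_extension(self, profile5):
        cons = extended_majority_consensus(profile5)
        # majority core is kept and completed to a fully resolved tree by
        # two compatible support-2 splits; several completions are legal
        # (the greedy is ambiguous at equal support) and the documented
        # first-appearance tie rule picks rows 1 and 4
        assert {ROWS[2], ROWS[3]} <= cons.splits
        assert cons.splits == frozenset({ROWS[1], ROWS[2], ROWS[3], ROWS[4]})
        assert cons.weight == 7  # scoring weight stays majority-only
        assert cons.total_weight == 7 + 2 + 2
        assert cons.tree.is_resolved

    def test_extension_adds_only_compatible_minority_splits(self, profile5):
        wss = split_counts(profile5)
        cons = extended_majority_consensus(profile5)
        for s in cons.splits - {ROWS[2], ROWS[3]}:
            assert wss.counts[s] <= profile5.m / 2
            assert all(are_compatible(s, t) for t in cons.splits)

    def test_identical_resolved_trees_give_tree_itself(self, profile5):
        from mct.tree_io import Profile

        prof = Profile.from_trees([profile5[2]] * 3)
        cons = extended_majority_consensus(prof)
        assert cons.splits == profile5[2].splits
        assert cons.weight == cons.total_weight == 3 * 4


class TestTreeFromSplits:
    def test_empty_set_gives_star(self):
        t = tree_from_splits(set(), X7)
        assert t.is_star

    def test_two_tree_consensus_shape(self, profile5):
        t = tree_from_splits({ROWS[3], ROWS[8], ROWS[9]}, X7)
        assert t.splits == frozenset({ROWS[3], ROWS[8], ROWS[9]})

    def test_round_trip_with_extract(self, profile5):
        t = tree_from_splits(profile5[0].splits, X7)
        assert extract_splits(t) == set(profile5[0].splits)

    def test_incompatible_pair_rejected(self):
        with pytest.raises(ValueError, match="incompatible"):
            tree_from_splits({ROWS[1], ROWS[7]}, X7)
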