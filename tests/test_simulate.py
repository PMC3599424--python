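import numpy as np
import pytest

from mct.simulate import (
    SimulationConfig,
    default_labels,
    distance_matrix,
    evolve_sequences,
    expected_divergence,
    kimura_distance,
    make_random_profile,
    make_three_class_profile,
    make_topology,
    nj_tree,
)


class TestSimulationConfig:
    def test_defaults_match_protocol(self):
        cfg = SimulationConfig()
        assert (cfg.n_leaves, cfg.seq_length) == (16, 1000)
        assert cfg.substitution_rate == 0.25
        assert cfg.transition_fraction == 0.75
        assert cfg.trees_per_class == 10

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_leaves": 3},
            {"seq_length": 0},
            {"substitution_rate": 1.5},
            {"transition_fraction": -0.1},
            {"branch_length_model": "gamma"},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SimulationConfig(**kwargs)


class TestMakeTopology:
    def test_balanced_16_has_8_cherries(self):
        topo = make_topology("balanced", 16)
        assert topo.cherry_count() == 8
        assert topo.to_xtree().is_resolved

    def test_caterpillar_has_single_cherry(self):
        topo = make_topology("caterpillar", 16)
        assert topo.cherry_count() == 1
        assert topo.to_xtree().is_resolved

    def test_balanced_rejects_non_power_of_two(self):
        with pytest.raises(ValueError, match="power"):
            make_topology("balanced", 12)

    @pytest.mark.parametrize("kind", ["balanced", "caterpillar", "random"])
    def test_four_leaves_valid(self, kind):
        topo = make_topology(kind, 4, seed=0)
        assert sorted(topo.leaf_labels()) == default_labels(4)

    def test_random_topology_seeded_reproducible(self):
        a = make_topology("random", 16, seed=5).to_xtree()
        b = make_topology("random", 16, seed=5).to_xtree()
        assert a.splits == b.splits


class TestEvolveSequences:
    def test_rate_zero_returns_root_everywhere(self):
        cfg = SimulationConfig(substitution_rate=0.0, seq_length=200, seed=3)
        topo = make_topology("balanced", 8)
        tips, root = evolve_sequences(topo, cfg, include_root=True)
        assert len(tips) == 8
        assert all(s == root for s in tips.values())

    def test_mean_tip_divergence_near_quarter(self):
        # with rate 0.25 and L=1000 the mean observed tip-root Hamming
        # distance should sit near 250 (calibrated for multiple hits)
        cfg = SimulationConfig(seed=11)
        topo = make_topology("balanced", 16)
        rng = np.random.default_rng(11)
        means = []
        for _ in range(25):
            tips, root = evolve_sequences(topo, cfg, rng, include_root=True)
            means.append(
                np.mean([sum(a != b for a, b in zip(s, root)) for s in tips.values()])
            )
        assert 230 <= np.mean(means) <= 270

    def test_fixed_seed_bit_identical(self):
        cfg = SimulationConfig(seq_length=100, seed=9)
        topo = make_topology("caterpillar", 8)
        assert evolve_sequences(topo, cfg) == evolve_sequences(topo, cfg)

    def test_divergence_curve_monotone_and_saturating(self):
        loads = [0.0, 0.1, 0.5, 2.0, 50.0]
        vals = [expected_divergence(t, 0.75) for t in loads]
        assert vals[0] == 0.0
        assert all(a < b for a, b in zip(vals, vals[1:]))
        assert vals[-1] < 0.75


class TestKimuraDistance:
    def test_identical_sequences(self):
        assert kimura_distance("ACGT" * 10, "ACGT" * 10) == 0.0

    def test_closed_form_frozen_value(self):
        # P = 0.1 (transitions), Q = 0.05 (transversions) on L = 100:
        # d = -1/2 ln[(1 - 0.25) sqrt(0.9)]
        s1 = "A" * 100
        s2 = "G" * 10 + "C" * 5 + "A" * 85
        assert kimura_distance(s1, s2) == pytest.approx(0.1701811651403471)

    def test_saturation_raises(self):
        with pytest.raises(ValueError, match="[Ss]aturat"):
            kimura_distance("A" * 50, "G" * 50)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            kimura_distance("ACGT", "ACG")


class TestNJTree:
    def make_additive(self, internal=1.0, noise=0.0, seed=0):
        # tree ((a,b),(c,d),e) with unit pendant edges
        import itertools

        paths = {
            ("a", "b"): 2.0,
            ("c", "d"): 2.0,
            ("a", "c"): 2.0 + internal * 2,
            ("a", "d"): 2.0 + internal * 2,
            ("b", "c"): 2.0 + internal * 2,
            ("b", "d"): 2.0 + internal * 2,
            ("a", "e"): 2.0 + internal,
            ("b", "e"): 2.0 + internal,
            ("c", "e"): 2.0 + internal,
            ("d", "e"): 2.0 + internal,
        }
        labels = list("abcde")
        rng = np.random.default_rng(seed)
        d = np.zeros((5, 5))
        for i, j in itertools.combinations(range(5), 2):
            key = tuple(sorted((labels[i], labels[j])))
            d[i, j] = d[j, i] = paths[key] + rng.uniform(-noise, noise)
        return labels, d

    def test_exact_recovery_on_additive_matrix(self):
        labels, d = self.make_additive()
        tree = nj_tree(d, labels)
        sides = {frozenset(min(s.side_a, s.side_b, key=len)) for s in tree.splits}
        assert sides == {frozenset("ab"), frozenset("cd")}

    @pytest.mark.parametrize("seed", range(5))
    def test_robust_to_small_noise(self, seed):
        labels, d = self.make_additive(internal=1.0, noise=0.05, seed=seed)
        tree = nj_tree(d, labels)
        sides = {frozenset(min(s.side_a, s.side_b, key=len)) for s in tree.splits}
        assert sides == {frozenset("ab"), frozenset("cd")}


class TestProfiles:
    def test_three_class_profile_shape(self):
        cfg = SimulationConfig(seed=4)
        prof, labels = make_three_class_profile(cfg)
        assert prof.m == 30
        assert prof.n == 16
        assert labels == [0] * 10 + [1] * 10 + [2] * 10

    def test_three_class_profile_seeded_reproducible(self):
        cfg = SimulationConfig(seed=5)
        a, _ = make_three_class_profile(cfg)
        b, _ = make_three_class_profile(cfg)
        assert all(x.splits == y.splits for x, y in zip(a.trees, b.trees))

    def test_random_profile_properties(self):
        prof = make_random_profile(10, 16, 2)
        assert prof.m == 10
        assert all(t.is_resolved for t in prof.trees)

    def test_random_profile_seeded_reproducible(self):
        a = make_random_profile(5, 10, 7)
        b = make_random_profile(5, 10, 7)
        assert all(x.splits == y.splits for x, y in zip(a.trees, b.trees))

    def test_single_tree_profile(self):
        prof = make_random_profile(1, 8, 0)
        assert prof.m == 1

    def test_kimura_matrix_symmetric_zero_diagonal(self):
        cfg = SimulationConfig(n_leaves=8, seq_length=500, seed=6)
        topo = make_topology("balanced", 8)
        seqs = evolve_sequences(topo, cfg)
        labels, d = distance_matrix(seqs)
        assert np.allclose(d, d.T)
        assert np.allclose(np.diag(d), 0.0)
        assert (d >= 0).all() and np.isfinite(d).all()
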