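"""Synthetic survey generator: determinism, limits, calibration, recovery."""

import dataclasses

import numpy as np
import pytest
from scipy import stats

from bilesalts.errors import ConfigurationError
from bilesalts.profiles import assign_class, is_complex
from bilesalts.simulate import (
    SimulationConfig,
    evolve_mk,
    generate_profile_table,
    simulate_tree_and_characters,
    yule_tree,
)


class TestYuleTree:
    def test_tip_count_labels_and_height(self, rng):
        tree = yule_tree(16, rng=rng, height=1.0)
        leaves = list(tree.leaf_node_iter())
        assert len(leaves) == 16
        assert {n.taxon.label for n in leaves} == {f"t{i+1}" for i in range(16)}
        depths = tree.calc_node_root_distances(return_leaf_distances_only=True)
        assert np.allclose(depths, 1.0)

    def test_invalid_configs(self):
        with pytest.raises(ConfigurationError):
            yule_tree(0)
        with pytest.raises(ConfigurationError):
            yule_tree(4, birth_rate=0.0)


class TestMkEvolution:
    def test_rate_zero_freezes_the_root_state(self, rng):
        tree = yule_tree(32, rng=rng)
        tips, nodes = evolve_mk(tree, ["A", "B", "C"], rate=0.0, rng=rng)
        assert len(set(tips.values())) == 1
        assert set(tips.values()) == {nodes[tree.seed_node]}

    def test_high_rate_approaches_uniform_tip_distribution(self):
        # at 50 expected changes per unit height ancestry is forgotten;
        # tip states should be indistinguishable from uniform
        rng = np.random.default_rng(7)
        tree = yule_tree(1000, rng=rng, height=1.0)
        tips, _ = evolve_mk(tree, ["A", "B", "C", "D"], rate=50.0, rng=rng)
        counts = [sum(1 for v in tips.values() if v == s) for s in "ABCD"]
        p = stats.chisquare(counts).pvalue
        assert p > 0.01

    def test_expected_number_of_changes_scales_with_rate(self):
        rng = np.random.default_rng(11)
        tree = yule_tree(2, rng=rng, height=1.0)
        total_length = sum(
            n.edge.length for n in tree.preorder_node_iter() if n.edge.length
        )
        n_changes = []
        for _ in range(400):
            _, nodes = evolve_mk(tree, ["A", "B"], rate=1.0, rng=rng)
            # count changes along edges
            c = sum(
                1
                for n in tree.preorder_node_iter()
                if n.parent_node is not None and nodes[n] != nodes[n.parent_node]
            )
            n_changes.append(c)
        # each Poisson event flips a 2-state chain, so realized changes track
        # events modulo back-mutation; the mean must be positive and bounded
        # by the event rate
        assert 0.1 * total_length < np.mean(n_changes) <= 1.05 * total_length


class TestDeterminism:
    def test_identical_seed_identical_output(self):
        cfg = SimulationConfig(n_families=4, species_per_family=2, seed=42)
        a = simulate_tree_and_characters(cfg)
        b = simulate_tree_and_characters(cfg)
        assert a.matrix.characters == b.matrix.characters
        assert a.tree.as_string(schema="newick") == b.tree.as_string(schema="newick")
        pa = generate_profile_table(cfg, a.matrix, a.family_of)
        pb = generate_profile_table(cfg, b.matrix, b.family_of)
        assert pa == pb

    def test_different_seed_differs(self):
        cfg = SimulationConfig(n_families=6, species_per_family=3, seed=1)
        other = dataclasses.replace(cfg, seed=2)
        a = simulate_tree_and_characters(cfg)
        b = simulate_tree_and_characters(other)
        assert a.tree.as_string(schema="newick") != b.tree.as_string(schema="newick")

    def test_config_round_trips_through_flat_form(self):
        cfg = SimulationConfig(n_families=7, seed=9,
                               class_alphabet=("I", "II", "VI"))
        assert SimulationConfig.from_flat(cfg.to_flat()) == cfg


class TestProfileGeneration:
    def test_generated_profiles_satisfy_invariants_and_recover_classes(self):
        cfg = SimulationConfig(n_families=25, species_per_family=6, seed=5)
        tc = simulate_tree_and_characters(cfg)
        profiles = generate_profile_table(cfg, tc.matrix, tc.family_of)
        truth = tc.matrix.column("profile_class")
        assert len(profiles) == 150
        for p in profiles:
            total = sum(c.percent for c in p.components)
            assert total == pytest.approx(100.0, abs=1e-6)
            assert assign_class(p).value == truth[p.species]

    def test_six_class_alphabet_recovery_rate(self):
        cfg = SimulationConfig(
            n_families=30, species_per_family=6, seed=17,
            class_alphabet=("I", "II", "III", "IV", "V", "VI"),
        )
        tc = simulate_tree_and_characters(cfg)
        profiles = generate_profile_table(cfg, tc.matrix, tc.family_of)
        truth = tc.matrix.column("profile_class")
        hits = sum(
            assign_class(p).value == truth[p.species] for p in profiles
        )
        assert hits / len(profiles) >= 0.95

    def test_two_type_classes_are_complex_by_construction(self):
        cfg = SimulationConfig(n_families=10, species_per_family=5, seed=3,
                               class_alphabet=("II", "III", "V"))
        tc = simulate_tree_and_characters(cfg)
        profiles = generate_profile_table(cfg, tc.matrix, tc.family_of)
        assert all(is_complex(p) for p in profiles)

    def test_high_concentration_limit_concentrates_on_dominant_compound(self):
        cfg = SimulationConfig(n_families=5, species_per_family=4, seed=8,
                               concentration=1e7,
                               complexity_q=(("carnivore", 0.0),
                                             ("herbivore", 0.0),
                                             ("omnivore", 0.0)))
        tc = simulate_tree_and_characters(cfg)
        profiles = generate_profile_table(cfg, tc.matrix, tc.family_of)
        for p in profiles:
            dominant = max(c.percent for c in p.components)
            assert dominant == pytest.approx(97.0, abs=0.5)

    def test_zero_species_config_rejected(self):
        with pytest.raises(ConfigurationError):
            SimulationConfig(n_families=0)
        with pytest.raises(ConfigurationError):
            SimulationConfig(species_per_family=0)

    def test_unknown_class_menu_rejected(self):
        with pytest.raises(ConfigurationError):
            SimulationConfig(class_alphabet=("I", "VII"))


class TestFamilyConservation:
    def test_zero_rates_give_uniform_classes(self):
        cfg = SimulationConfig(n_families=8, species_per_family=5, seed=2,
                               character_rate=0.0, within_family_flip_prob=0.0)
        tc = simulate_tree_and_characters(cfg)
        states = set(tc.matrix.column("profile_class").values())
        assert states == {tc.root_state}

    def test_low_rates_keep_families_mostly_homogeneous(self):
        from bilesalts.phylo import conservation_report

        cfg = SimulationConfig(n_families=30, species_per_family=6, seed=13)
        tc = simulate_tree_and_characters(cfg)
        profiles = generate_profile_table(cfg, tc.matrix, tc.family_of)
        report = conservation_report(profiles, rank="family")
        heterogeneous = sum(g.heterogeneous for g in report)
        assert heterogeneous <= 6  # a handful at most, mirroring real surveys
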