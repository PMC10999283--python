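"""Generators: Yule trees, bootstrap replicates, traits, placements, profiles."""

import dendropy
import numpy as np
import pytest

from nirtools import (
    PlacementConfig,
    ProfileConfig,
    SimConfig,
    adjust_zero_branches,
    delta_nir,
    evolve_trait,
    extract_supported_clades,
    perturb_bootstrap_trees,
    read_jplace,
    simulate_placements,
    simulate_profiles,
    simulate_tree,
    write_fixture_dir,
)
from nirtools.community import read_profiles
from nirtools.tree import Clade, CladeSet, OUTGROUP


def clades_with_outgroup(tree, k_min=2):
    """Unsupervised clades on a simulated tree, last one renamed outgroup."""
    cs = extract_supported_clades(tree, sh_min=0.0, uf_min=0.0)
    assert len(cs.names) >= k_min
    last = cs.clades.pop(cs.names[-1])
    cs.clades[OUTGROUP] = Clade(OUTGROUP, last.tips, last.support)
    return cs


class TestSimulateTree:
    def test_two_tips_is_a_cherry(self):
        t = simulate_tree(SimConfig(seed=0, n_tips=2))
        assert t.n_tips == 2 and len(t.root.children) == 2

    def test_fewer_than_two_tips_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(seed=0, n_tips=1)

    def test_determinism_identical_newick(self):
        a = simulate_tree(SimConfig(seed=42, n_tips=100)).to_newick()
        b = simulate_tree(SimConfig(seed=42, n_tips=100)).to_newick()
        assert a == b
        c = simulate_tree(SimConfig(seed=43, n_tips=100)).to_newick()
        assert a != c

    def test_mean_height_tracks_yule_expectation(self):
        # E[height] = sum_{k=2..n} 1/(k * birth_rate) for a Yule tree
        means = []
        for n in (8, 32, 128):
            expect = sum(1.0 / k for k in range(2, n + 1))
            heights = [
                simulate_tree(SimConfig(seed=1000 * n + r, n_tips=n)).height()
                for r in range(200)
            ]
            m = np.mean(heights)
            se = np.std(heights) / np.sqrt(len(heights))
            assert abs(m - expect) < 4 * se
            means.append(m)
        assert means[0] < means[1] < means[2]


class TestBootstrapReplicates:
    def test_identity_when_unperturbed(self):
        tree = simulate_tree(SimConfig(seed=5, n_tips=30))
        (rep,) = perturb_bootstrap_trees(tree, 1, seed=0, jitter_sd=0.0, nni_count=0)
        assert rep.to_newick() == tree.to_newick()

    def test_hundred_replicates_preserve_tip_set(self):
        tree = simulate_tree(SimConfig(seed=5, n_tips=40))
        reps = perturb_bootstrap_trees(tree, 100, seed=1)
        assert len(reps) == 100
        assert all(sorted(r.tip_labels) == sorted(tree.tip_labels) for r in reps)

    @pytest.mark.parametrize("nni", [1, 2, 5])
    def test_rf_distance_bounded_by_twice_nni_count(self, nni):
        tree = simulate_tree(SimConfig(seed=6, n_tips=40))
        reps = perturb_bootstrap_trees(tree, 20, seed=2, nni_count=nni)
        tns = dendropy.TaxonNamespace()
        ref = dendropy.Tree.get(
            data=tree.to_newick(support_format="none"), schema="newick",
            taxon_namespace=tns,
        )
        ref.encode_bipartitions()
        for rep in reps:
            other = dendropy.Tree.get(
                data=rep.to_newick(support_format="none"), schema="newick",
                taxon_namespace=tns,
            )
            rf = dendropy.calculate.treecompare.symmetric_difference(ref, other)
            assert rf <= 2 * nni


class TestEvolveTrait:
    def test_markov_no_switching_keeps_root_state(self):
        cfg = SimConfig(
            seed=3, n_tips=20, trait_mode="markov_switch",
            gain_rate=0.0, loss_rate=0.0, root_state=1,
        )
        tree = adjust_zero_branches(simulate_tree(cfg))
        trait = evolve_trait(tree, cfg)
        assert all(v == 1 for v in trait.values())

    def test_clade_gain_positives_form_whole_clades(self):
        cfg = SimConfig(seed=4, n_tips=60, conservation_depth=0.8, noise_rate=0.0)
        tree = adjust_zero_branches(simulate_tree(cfg))
        trait = evolve_trait(tree, cfg)
        positives = {t for t, v in trait.items() if v == 1}
        assert positives
        below = tree.descendant_tips()
        # maximal all-positive clades must tile the positive set exactly
        covered = set()
        stack = [tree.root]
        while stack:
            node = stack.pop()
            tips = below[node]
            if tips <= positives:
                covered |= tips
                continue
            stack.extend(node.children)
        assert covered == positives

    def test_depth_beyond_tree_height_rejected(self):
        cfg = SimConfig(seed=4, n_tips=20, conservation_depth=1e6)
        tree = adjust_zero_branches(simulate_tree(cfg))
        with pytest.raises(ValueError, match="height"):
            evolve_trait(tree, cfg)

    def test_markov_stationary_frequency_matches_closed_form(self):
        # two-state chain: pi_1 = gain / (gain + loss)
        gain, loss = 1.5, 0.5
        expect = gain / (gain + loss)
        freqs = []
        for rep in range(500):
            cfg = SimConfig(
                seed=9000 + rep, n_tips=20, trait_mode="markov_switch",
                gain_rate=gain, loss_rate=loss,
            )
            tree = adjust_zero_branches(simulate_tree(cfg))
            trait = evolve_trait(tree, cfg)
            freqs.append(np.mean(list(trait.values())))
        se = np.std(freqs) / np.sqrt(len(freqs))
        assert abs(np.mean(freqs) - expect) < 3 * se + 1e-12


class TestSimulatePlacements:
    def test_certainty_one_puts_all_mass_on_one_edge(self):
        cfg = SimConfig(seed=8, n_tips=30, placement=PlacementConfig(n_reads=25))
        tree = simulate_tree(cfg)
        pset = simulate_placements(tree, clades_with_outgroup(tree), cfg)
        assert all(len(r.placements) == 1 for r in pset.reads)
        assert all(r.placements[0].like_weight_ratio == 1.0 for r in pset.reads)

    def test_degenerate_simplex_gives_single_true_label(self):
        cfg = SimConfig(seed=8, n_tips=30)
        tree = simulate_tree(cfg)
        cs = clades_with_outgroup(tree)
        name = [n for n in cs.names if n != OUTGROUP][0]
        cfg = SimConfig(
            seed=8, n_tips=30,
            placement=PlacementConfig(n_reads=50, clade_weights={name: 1.0}),
        )
        pset = simulate_placements(tree, cs, cfg)
        assert all(r.true_label == name for r in pset.reads)

    def test_leaky_mass_sums_to_one(self):
        cfg = SimConfig(
            seed=9, n_tips=30,
            placement=PlacementConfig(n_reads=40, mass_concentration=0.8),
        )
        tree = simulate_tree(cfg)
        pset = simulate_placements(tree, clades_with_outgroup(tree), cfg)
        for read in pset.reads:
            assert read.total_mass == pytest.approx(1.0, abs=1e-9)

    def test_empty_clade_in_weights_rejected(self):
        cfg = SimConfig(seed=8, n_tips=30)
        tree = simulate_tree(cfg)
        cs = clades_with_outgroup(tree)
        cfg = SimConfig(
            seed=8, n_tips=30,
            placement=PlacementConfig(n_reads=10, clade_weights={"ghost": 1.0}),
        )
        with pytest.raises(ValueError, match="ghost"):
            simulate_placements(tree, cs, cfg)

    def test_determinism(self):
        cfg = SimConfig(seed=10, n_tips=30, placement=PlacementConfig(n_reads=30))
        tree = simulate_tree(cfg)
        cs = clades_with_outgroup(tree)
        a = simulate_placements(tree, cs, cfg)
        b = simulate_placements(tree, cs, cfg)
        assert [(r.name, r.true_label, r.placements) for r in a.reads] == [
            (r.name, r.true_label, r.placements) for r in b.reads
        ]


class TestSimulateProfiles:
    def test_depth_floor_and_determinism(self):
        cfg = SimConfig(seed=11, profile=ProfileConfig(n_samples_per_biome=40))
        profs = simulate_profiles(cfg)
        assert all(p.total_reads >= 100_000 for p in profs)
        again = simulate_profiles(cfg)
        assert [(p.sample_id, p.total_reads, p.counts) for p in profs] == [
            (p.sample_id, p.total_reads, p.counts) for p in again
        ]

    def test_equal_effects_give_median_delta_nir_near_zero(self):
        cfg = SimConfig(
            seed=12,
            profile=ProfileConfig(
                n_samples_per_biome=500,
                biome_effects={"b": {"nirK": 50.0, "nirS": 50.0}},
            ),
        )
        dn = np.array([delta_nir(p) for p in simulate_profiles(cfg)])
        se = np.std(dn) / np.sqrt(len(dn))
        assert abs(np.median(dn)) < 2 * se

    def test_effect_ratio_recovered(self):
        cfg = SimConfig(
            seed=13,
            profile=ProfileConfig(
                n_samples_per_biome=200,
                biome_effects={"b": {"nirK": 190.0, "nirS": 10.0}},
            ),
        )
        profs = simulate_profiles(cfg)
        per_gb_k = np.mean([p.counts["nirK"] / p.gigabases for p in profs])
        per_gb_s = np.mean([p.counts["nirS"] / p.gigabases for p in profs])
        assert per_gb_k / per_gb_s == pytest.approx(19.0, rel=0.25)


class TestFixtureDir:
    def test_materialised_fixture_parses_back(self, tmp_path):
        cfg = SimConfig(
            seed=14, n_tips=24, n_bootstrap_trees=5, conservation_depth=0.6,
            placement=PlacementConfig(n_reads=30),
            profile=ProfileConfig(n_samples_per_biome=5),
        )
        paths = write_fixture_dir(cfg, tmp_path / "fx")
        pset = read_jplace(paths["placements"])
        assert len(pset.reads) == 30
        profs = read_profiles(paths["profiles"])
        assert len(profs) == 15
        cs = CladeSet.from_tsv(paths["clades"])
        assert OUTGROUP in cs
        boots = (tmp_path / "fx" / "bootstraps.nwk").read_text().strip().split("\n")
        assert len(boots) == 5
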