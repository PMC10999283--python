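"""jplace I/O, mass filtering, classifier metrics, BWPD, rarefaction."""

import json

import numpy as np
import pytest
from scipy.stats import hypergeom

from nirtools import (
    EdgeMassProfile,
    PlacementConfig,
    SimConfig,
    bwpd,
    classifier_metrics,
    edge_correlations,
    filter_placements,
    parse_newick,
    rarefied_composition,
    read_jplace,
    simulate_placements,
    simulate_tree,
    write_jplace,
)
from nirtools.placement import Placement, PlacementSet, ReadPlacement
from nirtools.tree import Clade, CladeSet, OUTGROUP

from conftest import spanning_subtree_pd
from test_simulate import clades_with_outgroup

MINIMAL_JPLACE = {
    "version": 3,
    "tree": "((A:1{0},B:1{1}):1{2},C:2{3});",
    "fields": ["edge_num", "like_weight_ratio"],
    "placements": [{"p": [[0, 1.0]], "n": ["read1"]}],
    "metadata": {},
}


@pytest.fixture
def six_tip_setup():
    """Tree with two 2-tip ingroup clades and a 2-tip outgroup."""
    tree = parse_newick("(((A:1,B:1):1,(C:1,D:1):1):1,(X:1,Y:1):1);")
    clades = CladeSet(
        clades={
            "cladeA": Clade("cladeA", frozenset({"A", "B"})),
            "cladeC": Clade("cladeC", frozenset({"C", "D"})),
            OUTGROUP: Clade(OUTGROUP, frozenset({"X", "Y"})),
        },
        tree_tips=frozenset(tree.tip_labels),
    )
    emap = {}
    below = tree.descendant_tips()
    for node in tree.preorder():
        if not node.is_root:
            emap[frozenset(below[node])] = node.edge_num
    return tree, clades, emap


def one_read(name, mass_by_edge, true_label=None):
    return ReadPlacement(
        name=name,
        placements=[Placement(edge_num=e, like_weight_ratio=m) for e, m in mass_by_edge.items()],
        true_label=true_label,
    )


class TestJplaceIO:
    def test_minimal_file(self, tmp_path):
        path = tmp_path / "min.jplace"
        path.write_text(json.dumps(MINIMAL_JPLACE))
        pset = read_jplace(path)
        assert len(pset.reads) == 1
        (p,) = pset.reads[0].placements
        assert p.edge_num == 0 and p.like_weight_ratio == 1.0

    def test_old_version_rejected(self, tmp_path):
        doc = dict(MINIMAL_JPLACE, version=2)
        path = tmp_path / "v2.jplace"
        path.write_text(json.dumps(doc))
        with pytest.raises(ValueError, match="version"):
            read_jplace(path)

    def test_unknown_field_rejected(self, tmp_path):
        doc = dict(MINIMAL_JPLACE, fields=["edge_num", "like_weight_ratio", "mystery"])
        path = tmp_path / "bad.jplace"
        path.write_text(json.dumps(doc))
        with pytest.raises(ValueError, match="mystery"):
            read_jplace(path)

    def test_edge_absent_from_tree_rejected(self, tmp_path):
        doc = dict(MINIMAL_JPLACE, placements=[{"p": [[9, 1.0]], "n": ["r"]}])
        path = tmp_path / "edge.jplace"
        path.write_text(json.dumps(doc))
        with pytest.raises(ValueError, match="9"):
            read_jplace(path)

    def test_write_read_identity(self, tmp_path):
        cfg = SimConfig(seed=1, n_tips=20, placement=PlacementConfig(n_reads=15))
        tree = simulate_tree(cfg)
        pset = simulate_placements(tree, clades_with_outgroup(tree), cfg)
        p1 = tmp_path / "a.jplace"
        p2 = tmp_path / "b.jplace"
        write_jplace(pset, p1)
        write_jplace(read_jplace(p1), p2)
        assert p1.read_text() == p2.read_text()

    def test_simulated_mass_sums_survive_round_trip(self, tmp_path):
        cfg = SimConfig(
            seed=2, n_tips=20,
            placement=PlacementConfig(n_reads=20, mass_concentration=0.7),
        )
        tree = simulate_tree(cfg)
        pset = simulate_placements(tree, clades_with_outgroup(tree), cfg)
        path = tmp_path / "leaky.jplace"
        write_jplace(pset, path)
        back = read_jplace(path)
        for read in back.reads:
            assert read.total_mass == pytest.approx(1.0, abs=1e-9)


class TestFilterPlacements:
    def test_confident_in_clade_counted(self, six_tip_setup):
        tree, clades, emap = six_tip_setup
        eA = emap[frozenset({"A"})]
        eAB = emap[frozenset({"A", "B"})]
        pset = PlacementSet(tree, [one_read("r", {eA: 0.96, eAB: 0.04})])
        res = filter_placements(pset, clades, min_mass=0.95, level="clade")
        assert res.counts["cladeA"] == 1

    def test_any_outgroup_mass_excludes(self, six_tip_setup):
        tree, clades, emap = six_tip_setup
        eA = emap[frozenset({"A"})]
        eX = emap[frozenset({"X"})]
        pset = PlacementSet(tree, [one_read("r", {eA: 0.96, eX: 0.01})])
        res = filter_placements(pset, clades, min_mass=0.95, level="ingroup")
        assert res.counts["ingroup"] == 0
        assert res.unassigned_reads == ["r"]

    def test_min_mass_zero_counts_every_zero_outgroup_read(self, six_tip_setup):
        tree, clades, emap = six_tip_setup
        eA = emap[frozenset({"A"})]
        eC = emap[frozenset({"C"})]
        reads = [one_read("r1", {eA: 0.5, eC: 0.5}), one_read("r2", {eC: 1.0})]
        res = filter_placements(PlacementSet(tree, reads), clades, min_mass=0.0, level="ingroup")
        assert res.counts["ingroup"] == 2

    def test_outgroup_definition_mandatory(self, six_tip_setup):
        tree, clades, _ = six_tip_setup
        no_out = CladeSet(
            clades={k: v for k, v in clades.clades.items() if k != OUTGROUP},
            tree_tips=clades.tree_tips,
        )
        pset = PlacementSet(tree, [])
        with pytest.raises(ValueError, match="outgroup"):
            filter_placements(pset, no_out)

    def test_counts_monotone_in_min_mass_and_clade_le_ingroup(self):
        cfg = SimConfig(
            seed=3, n_tips=40,
            placement=PlacementConfig(n_reads=150, mass_concentration=0.85),
        )
        tree = simulate_tree(cfg)
        clades = clades_with_outgroup(tree)
        pset = simulate_placements(tree, clades, cfg)
        prev_total = None
        for mm in (0.5, 0.7, 0.9, 0.95, 1.0):
            res_in = filter_placements(pset, clades, min_mass=mm, level="ingroup")
            res_cl = filter_placements(pset, clades, min_mass=mm, level="clade")
            clade_total = sum(v for k, v in res_cl.counts.items() if k != OUTGROUP)
            assert clade_total <= res_in.counts["ingroup"]
            if prev_total is not None:
                assert res_in.counts["ingroup"] <= prev_total
            prev_total = res_in.counts["ingroup"]

    def test_boundary_edge_mass_counts_to_ingroup_not_clade(self, six_tip_setup):
        tree, clades, emap = six_tip_setup
        e_boundary = emap[frozenset({"A", "B", "C", "D"})]  # spans two clades
        pset = PlacementSet(tree, [one_read("r", {e_boundary: 1.0})])
        res_cl = filter_placements(pset, clades, min_mass=0.95, level="clade")
        assert all(v == 0 for v in res_cl.counts.values())
        res_in = filter_placements(pset, clades, min_mass=0.95, level="ingroup")
        assert res_in.counts["ingroup"] == 1


class TestClassifierMetrics:
    def test_direct_fractions(self, six_tip_setup):
        tree, clades, emap = six_tip_setup
        eA = emap[frozenset({"A"})]
        eX = emap[frozenset({"X"})]
        reads = [
            one_read("i1", {eA: 1.0}, "cladeA"),
            one_read("i2", {eA: 1.0}, "cladeA"),
            one_read("i3", {eA: 1.0}, "cladeA"),
            one_read("i4", {eA: 0.5, eX: 0.5}, "cladeA"),  # fails filter
            one_read("o1", {eX: 1.0}, OUTGROUP),
            one_read("o2", {eX: 1.0}, OUTGROUP),
        ]
        pset = PlacementSet(tree, reads)
        res = filter_placements(pset, clades, min_mass=0.95, level="ingroup")
        m = classifier_metrics(pset, res)
        assert m["sensitivity"] == pytest.approx(0.75)
        assert m["specificity"] == 1.0

    def test_undefined_without_true_outgroup_reads(self, six_tip_setup):
        tree, clades, emap = six_tip_setup
        eA = emap[frozenset({"A"})]
        pset = PlacementSet(tree, [one_read("i", {eA: 1.0}, "cladeA")])
        res = filter_placements(pset, clades)
        assert classifier_metrics(pset, res)["specificity"] is None

    def test_certainty_one_simulation_is_perfect(self):
        cfg = SimConfig(
            seed=4, n_tips=40,
            placement=PlacementConfig(n_reads=120, mass_concentration=1.0),
        )
        tree = simulate_tree(cfg)
        clades = clades_with_outgroup(tree)
        pset = simulate_placements(tree, clades, cfg)
        res = filter_placements(pset, clades, min_mass=0.95, level="clade")
        m = classifier_metrics(pset, res)
        assert m["sensitivity"] == 1.0 and m["specificity"] == 1.0
        # and the filter recovers the planted per-clade counts exactly
        truth = {}
        for r in pset.reads:
            truth[r.true_label] = truth.get(r.true_label, 0) + 1
        for name, n in truth.items():
            assert res.counts[name] == n


class TestBwpd:
    def test_all_mass_on_one_tip_is_zero_at_theta_one(self):
        tree = parse_newick("((A:1,B:1):1,C:2);")
        assert bwpd(EdgeMassProfile({0: 1.0}), tree) == 0.0

    def test_balanced_cherry_equals_two(self):
        tree = parse_newick("(A:1,B:1);")
        assert bwpd(EdgeMassProfile({0: 0.5, 1: 0.5}), tree) == pytest.approx(2.0)

    def test_zero_mass_undefined(self):
        tree = parse_newick("(A:1,B:1);")
        with pytest.raises(ValueError, match="mass"):
            bwpd(EdgeMassProfile({}, total_mass=0.0), tree)

    @pytest.mark.parametrize("seed", range(10))
    def test_theta_zero_matches_spanning_subtree_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 17))
        tree = simulate_tree(SimConfig(seed=100 + seed, n_tips=n))
        edges = list(tree.edge_map())
        chosen = rng.choice(edges, size=min(4, len(edges)), replace=False)
        masses = {int(e): float(rng.random() + 0.05) for e in chosen}
        total = sum(masses.values())
        masses = {e: m / total for e, m in masses.items()}
        profile = EdgeMassProfile(masses)
        assert bwpd(profile, tree, theta=0) == pytest.approx(
            spanning_subtree_pd(tree, masses), abs=1e-9
        )

    def test_scales_linearly_with_branch_lengths(self):
        tree = simulate_tree(SimConfig(seed=5, n_tips=12))
        profile = EdgeMassProfile({0: 0.3, 5: 0.5, 9: 0.2})
        base = bwpd(profile, tree)
        for n in tree.preorder():
            if not n.is_root:
                n.length *= 2.5
        assert bwpd(profile, tree) == pytest.approx(2.5 * base)


class TestEdgeCorrelations:
    def _profiles(self, rng, n_samples, n_edges=6):
        out = {}
        for i in range(n_samples):
            m = rng.random(n_edges)
            m /= m.sum()
            out[f"s{i}"] = EdgeMassProfile({e: m[e] for e in range(n_edges)})
        return out

    def test_self_correlation_is_one(self):
        rng = np.random.default_rng(0)
        profiles = self._profiles(rng, 12)
        cov = {s: p.masses[2] for s, p in profiles.items()}
        res = edge_correlations(profiles, cov)
        assert res.loc[2, "rho"] == pytest.approx(1.0)

    def test_monotone_transform_of_covariate_invariant(self):
        rng = np.random.default_rng(1)
        profiles = self._profiles(rng, 15)
        cov = {s: p.masses[0] + 0.3 * rng.random() for s, p in profiles.items()}
        a = edge_correlations(profiles, cov)
        b = edge_correlations(profiles, {s: np.exp(4 * v) for s, v in cov.items()})
        assert np.allclose(a["rho"], b["rho"])
        assert ((a["rho"] >= -1) & (a["rho"] <= 1)).all()

    def test_constant_covariate_undefined_everywhere(self):
        rng = np.random.default_rng(2)
        profiles = self._profiles(rng, 8)
        res = edge_correlations(profiles, {s: 1.0 for s in profiles})
        assert res["rho"].isna().all()

    def test_samples_missing_covariate_excluded_pairwise(self):
        rng = np.random.default_rng(3)
        profiles = self._profiles(rng, 10)
        cov = {s: p.masses[1] for s, p in profiles.items()}
        cov.pop("s0")
        cov["s1"] = np.nan
        res = edge_correlations(profiles, cov)
        assert (res["n"] == 8).all()

    def test_null_covariate_mean_correlation_near_zero(self):
        rng = np.random.default_rng(4)
        rhos = []
        for _ in range(100):
            profiles = self._profiles(rng, 50)
            cov = {s: rng.normal() for s in profiles}
            rhos.extend(edge_correlations(profiles, cov)["rho"].tolist())
        assert abs(np.nanmean(rhos)) < 0.1

    def test_too_few_samples_errors(self):
        rng = np.random.default_rng(5)
        profiles = self._profiles(rng, 3)
        with pytest.raises(ValueError, match="fewer"):
            edge_correlations(profiles, {s: 1.0 for s in profiles})


class TestRarefiedComposition:
    def test_shallow_sample_excluded(self):
        res = rarefied_composition({"a": 10, "b": 4}, depth=15, seed=0)
        assert res.excluded and res.proportions is None

    def test_single_clade_composition_trivial(self):
        res = rarefied_composition({"a": 30, "b": 0}, depth=15, seed=0)
        assert res.proportions["a"] == 1.0 and res.proportions["b"] == 0.0

    def test_depth_equal_total_reproduces_raw_proportions(self):
        counts = {"a": 12, "b": 6, "c": 2}
        res = rarefied_composition(counts, depth=20, n_rare=50, seed=1)
        assert res.proportions["a"] == pytest.approx(0.6)
        assert res.proportions["b"] == pytest.approx(0.3)
        assert res.proportions["c"] == pytest.approx(0.1)

    def test_matches_hypergeometric_expectation(self):
        counts = {"a": 30, "b": 10, "c": 5}
        N, depth, n_rare = 45, 15, 100
        res = rarefied_composition(counts, depth=depth, n_rare=n_rare, seed=2)
        assert res.proportions.sum() == pytest.approx(1.0)
        for clade, k in counts.items():
            expect = k / N  # E[X/depth] for hypergeometric X
            var_draw = hypergeom(N, k, depth).var() / depth**2
            se = np.sqrt(var_draw / n_rare)
            assert abs(res.proportions[clade] - expect) < 3 * se

    def test_nonpositive_depth_rejected(self):
        with pytest.raises(ValueError):
            rarefied_composition({"a": 5}, depth=0)
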