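"""Synthetic trees, traits, placements and metagenome profiles.

Every downstream statistic in this package is testable without any
external download: this module generates (a) pure-birth (Yule) trees with
attachable node supports, (b) bootstrap-like tree replicates (branch-length
jitter plus bounded NNI rearrangements, standing in for trees inferred
from resampled alignments), (c) binary traits evolved either by planting
gains at a target conservation depth or by a two-state Markov process,
(d) read placements with controllable clade abundances and placement
certainty, and (e) metagenome profiles with biome-structured,
overdispersed gene counts and environmental covariates.

All generators are deterministic under a fixed ``SimConfig.seed``; each
operation derives its own independent stream from that seed, so e.g.
regenerating placements never perturbs the profile draw.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .community import SampleProfile
from .placement import Placement, PlacementSet, ReadPlacement, write_jplace
from .tree import Clade, CladeSet, Node, OUTGROUP, Phylogeny

__all__ = [
    "SimConfig",
    "PlacementConfig",
    "ProfileConfig",
    "simulate_tree",
    "perturb_bootstrap_trees",
    "evolve_trait",
    "simulate_placements",
    "simulate_profiles",
    "write_fixture_dir",
]

# fixed spawn keys: one independent RNG stream per generator
_STREAM = {"tree": 0, "bootstrap": 1, "trait": 2, "placement": 3, "profile": 4}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(_STREAM[stream],)))


@dataclass
class PlacementConfig:
    """Read-placement generation: clade abundances and certainty.

    ``mass_concentration`` is the like_weight_ratio fraction placed on the
    read's focal edge; the remainder leaks to topologically adjacent
    edges, which may sit outside the true clade — the minimal mechanism
    that exercises a mass-fraction filter.
    """

    n_reads: int = 100
    clade_weights: dict[str, float] = field(default_factory=dict)
    mass_concentration: float = 1.0

    def __post_init__(self):
        if self.n_reads < 1:
            raise ValueError("n_reads must be >= 1")
        if not 0 < self.mass_concentration <= 1:
            raise ValueError("mass_concentration must lie in (0, 1]")
        if self.clade_weights:
            total = sum(self.clade_weights.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"clade_weights must sum to 1 (got {total})")
            if any(w < 0 for w in self.clade_weights.values()):
                raise ValueError("clade_weights must be non-negative")


@dataclass
class ProfileConfig:
    """Metagenome-profile generation.

    ``biome_effects`` maps biome -> {gene: expected count per Gb}; the
    defaults mirror the reported global abundance structure of the two
    nitrite reductases (terrestrial nirK:nirS around 19:1, marine around
    34:1, engineered habitats with a slight nirS excess).  Counts are
    negative-binomial (``dispersion`` = NB size parameter; ``None`` gives
    the Poisson limit).  Sequencing depth is log-uniform with a floor of
    100 000 reads, the inclusion threshold for analysed metagenomes.
    ``covariate_effects`` maps covariate -> {gene: slope on log-counts};
    covariates are standard-normal per sample.
    """

    n_samples_per_biome: int = 50
    biome_effects: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "terrestrial": {"nirK": 190.0, "nirS": 10.0},
            "marine": {"nirK": 340.0, "nirS": 10.0},
            "engineered": {"nirK": 100.0, "nirS": 120.0},
        }
    )
    covariate_effects: dict[str, dict[str, float]] = field(default_factory=dict)
    dispersion: float | None = 2.0
    read_length: int = 150
    min_reads: int = 100_000
    max_reads: int = 30_000_000

    def __post_init__(self):
        if not self.biome_effects:
            raise ValueError("biome_effects must define at least one biome")
        if self.dispersion is not None and self.dispersion <= 0:
            raise ValueError("dispersion must be positive (or None for Poisson)")
        if self.min_reads < 1 or self.max_reads < self.min_reads:
            raise ValueError("need 1 <= min_reads <= max_reads")


@dataclass
class SimConfig:
    """One reproducible study condition for the whole synthetic pipeline."""

    seed: int = 0
    n_tips: int = 100
    birth_rate: float = 1.0
    n_bootstrap_trees: int = 100  # mirrors the 100 alignment bootstraps
    support_range: tuple[tuple[float, float], tuple[float, float]] = ((0.0, 100.0), (0.0, 100.0))
    trait_mode: str = "clade_gain"
    conservation_depth: float | None = None
    n_trait_clades: int = 3
    noise_rate: float = 0.0
    gain_rate: float | None = None  # markov_switch: 0 -> 1 events per unit length
    loss_rate: float | None = None  # markov_switch: 1 -> 0
    root_state: int | None = None  # None: draw from the stationary distribution
    placement: PlacementConfig = field(default_factory=PlacementConfig)
    profile: ProfileConfig = field(default_factory=ProfileConfig)

    def __post_init__(self):
        if self.n_tips < 2:
            raise ValueError("n_tips must be >= 2")
        if self.birth_rate <= 0:
            raise ValueError("birth_rate must be positive")
        if self.trait_mode not in ("clade_gain", "markov_switch"):
            raise ValueError("trait_mode must be 'clade_gain' or 'markov_switch'")
        if not 0 <= self.noise_rate < 1:
            raise ValueError("noise_rate must lie in [0, 1)")

    @property
    def switch_rate(self) -> float | None:
        return self.gain_rate


# ---------------------------------------------------------------------------
# trees
# ---------------------------------------------------------------------------


def simulate_tree(config: SimConfig) -> Phylogeny:
    """Pure-birth (Yule) tree with ``n_tips`` tips.

    Waiting times between speciations are exponential with rate
    ``birth_rate * k`` for ``k`` extant lineages; a uniformly chosen tip
    splits at each event, so the tree is ultrametric.  Internal non-root
    nodes receive (SH-aLRT, UFboot) supports drawn uniformly from
    ``support_range``.
    """
    rng = _rng(config.seed, "tree")
    root = Node()
    active: list[Node] = [root.add_child(Node(length=0.0)), root.add_child(Node(length=0.0))]
    while len(active) < config.n_tips:
        k = len(active)
        dt = rng.exponential(1.0 / (config.birth_rate * k))
        for tip in active:
            tip.length += dt
        idx = rng.integers(k)
        parent = active.pop(idx)
        left, right = Node(length=0.0), Node(length=0.0)
        parent.add_child(left)
        parent.add_child(right)
        active.extend([left, right])
    dt = rng.exponential(1.0 / (config.birth_rate * len(active)))
    for tip in active:
        tip.length += dt
    width = len(str(config.n_tips))
    tree = Phylogeny(root, validate=False)
    for i, tip in enumerate(tree.tips(), start=1):
        tip.label = f"t{i:0{width}d}"
    (sh_lo, sh_hi), (uf_lo, uf_hi) = config.support_range
    for node in tree.internal_nodes(include_root=False):
        node.sh_alrt = float(np.round(rng.uniform(sh_lo, sh_hi), 1))
        node.ufboot = float(np.round(rng.uniform(uf_lo, uf_hi), 1))
    tree.assign_edge_numbers()
    tree._validate()
    return tree


def perturb_bootstrap_trees(
    tree: Phylogeny,
    n: int,
    seed: int,
    jitter_sd: float = 0.10,
    nni_count: int = 2,
) -> list[Phylogeny]:
    """Bootstrap-like replicates: length jitter plus bounded NNI moves.

    Each replicate multiplies every branch length by a lognormal factor
    (sigma = ``jitter_sd``) and applies ``nni_count`` random
    nearest-neighbour interchanges, so the Robinson-Foulds distance to the
    source tree is at most ``2 * nni_count``.  Tip sets are preserved.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        rep = tree.copy()
        if jitter_sd > 0:
            # mean-one lognormal: jitter must not systematically lengthen
            # the replicates relative to the source tree
            mu = -0.5 * jitter_sd**2
            for node in rep.preorder():
                if not node.is_root and node.length is not None:
                    node.length *= float(rng.lognormal(mu, jitter_sd))
        for _ in range(nni_count):
            _random_nni(rep, rng)
        rep.assign_edge_numbers()
        out.append(rep)
    return out


def _random_nni(tree: Phylogeny, rng: np.random.Generator) -> None:
    """One nearest-neighbour interchange across a random internal edge."""
    candidates = [
        n for n in tree.preorder()
        if not n.is_leaf and not n.is_root and n.parent is not None and len(n.parent.children) >= 2
    ]
    if not candidates:
        return
    v = candidates[rng.integers(len(candidates))]
    u = v.parent
    siblings = [c for c in u.children if c is not v]
    x = v.children[rng.integers(len(v.children))]
    y = siblings[rng.integers(len(siblings))]
    # swap subtree x (child of v) with subtree y (child of u)
    v.children[v.children.index(x)] = y
    u.children[u.children.index(y)] = x
    x.parent, y.parent = u, v
    v.sh_alrt = v.ufboot = None  # topology under v changed; support no longer applies


# ---------------------------------------------------------------------------
# traits
# ---------------------------------------------------------------------------


def evolve_trait(tree: Phylogeny, config: SimConfig) -> dict[str, int]:
    """One binary trait column over the tree's tips.

    ``clade_gain`` mode plants the trait in up to ``n_trait_clades``
    disjoint clades whose mean node-to-tip depth is nearest
    ``conservation_depth``, then flips each tip with probability
    ``noise_rate``.  ``markov_switch`` mode runs a two-state Markov chain
    (rates ``gain_rate``/``loss_rate`` per unit branch length) from the
    root state down every branch.
    """
    rng = _rng(config.seed, "trait")
    for node in tree.preorder():
        if not node.is_root and (node.length is None or node.length <= 0):
            raise ValueError("branch lengths must be positive; apply adjust_zero_branches first")
    if config.trait_mode == "clade_gain":
        return _trait_clade_gain(tree, config, rng)
    return _trait_markov(tree, config, rng)


def _trait_clade_gain(tree: Phylogeny, config: SimConfig, rng) -> dict[str, int]:
    depth = config.conservation_depth
    if depth is None:
        raise ValueError("clade_gain mode requires conservation_depth")
    if depth > tree.height():
        raise ValueError(
            f"conservation_depth {depth} exceeds tree height {tree.height():.4f}"
        )
    internal = tree.internal_nodes(include_root=False)
    node_depth = {n: tree.mean_node_to_tip_depth(n) for n in internal}
    tips_below = tree.descendant_tips()
    chosen: list[Node] = []
    used: set[str] = set()
    for node in sorted(internal, key=lambda n: abs(node_depth[n] - depth)):
        if len(chosen) >= config.n_trait_clades:
            break
        if tips_below[node] & used:
            continue
        chosen.append(node)
        used |= tips_below[node]
    trait = {t: 0 for t in tree.tip_labels}
    for node in chosen:
        for tip in tips_below[node]:
            trait[tip] = 1
    if config.noise_rate > 0:
        for tip in tree.tip_labels:
            if rng.random() < config.noise_rate:
                trait[tip] = 1 - trait[tip]
    return trait


def _trait_markov(tree: Phylogeny, config: SimConfig, rng) -> dict[str, int]:
    a = config.gain_rate
    b = config.loss_rate if config.loss_rate is not None else a
    if a is None:
        raise ValueError("markov_switch mode requires gain_rate (and optionally loss_rate)")
    if a < 0 or b < 0:
        raise ValueError("switch rates must be non-negative")
    total = a + b
    stationary1 = a / total if total > 0 else 0.0
    if config.root_state is not None:
        state = {tree.root: int(config.root_state)}
    else:
        state = {tree.root: int(rng.random() < stationary1)}
    for node in tree.preorder():
        if node.is_root:
            continue
        s = state[node.parent]
        if total == 0:
            state[node] = s
            continue
        # two-state chain transition probabilities over branch length t
        decay = np.exp(-total * node.length)
        p1 = stationary1 + ((1.0 if s == 1 else 0.0) - stationary1) * decay
        state[node] = int(rng.random() < p1)
    return {t.label: state[t] for t in tree.tips()}


# ---------------------------------------------------------------------------
# placements
# ---------------------------------------------------------------------------


def simulate_placements(tree: Phylogeny, clades: CladeSet, config: SimConfig) -> PlacementSet:
    """Reads with known clade origins placed on the reference tree.

    Each read's true clade is drawn from ``placement.clade_weights``
    (defaulting to uniform over the named clades); a focal edge is chosen
    uniformly among the edges fully inside that clade and receives
    ``mass_concentration`` of the read's likelihood mass; the remainder is
    split equally over the focal edge's topological neighbours (parent and
    child edges), which can leak mass outside the clade.  True labels are
    stored on the reads for sensitivity/specificity validation.
    """
    pc = config.placement
    rng = _rng(config.seed, "placement")
    weights = pc.clade_weights or {name: 1.0 / len(clades.names) for name in clades.names}
    tip_to_clade = clades.tip_to_clade()
    below = tree.descendant_tips()
    edges_by_clade: dict[str, list[Node]] = {}
    for node in tree.preorder():
        if node.is_root:
            continue
        groups = {tip_to_clade.get(t) for t in below[node]}
        if len(groups) == 1:
            g = groups.pop()
            if g is not None:
                edges_by_clade.setdefault(g, []).append(node)
    empty = [g for g in weights if g not in edges_by_clade]
    if empty:
        raise ValueError(f"clades named in weights but holding no edges: {sorted(empty)}")

    names = list(weights)
    probs = np.array([weights[g] for g in names])
    choices = rng.choice(len(names), size=pc.n_reads, p=probs)
    width = len(str(pc.n_reads))
    reads = []
    for i, ci in enumerate(choices, start=1):
        clade = names[ci]
        edges = edges_by_clade[clade]
        focal = edges[rng.integers(len(edges))]
        placements = [
            Placement(
                edge_num=focal.edge_num,
                like_weight_ratio=pc.mass_concentration,
                likelihood=float(np.log(pc.mass_concentration) - 100.0),
                distal_length=(focal.length or 0.0) / 2.0,
                pendant_length=0.01,
            )
        ]
        leak = 1.0 - pc.mass_concentration
        if leak > 0:
            neighbours = [c for c in focal.children]
            if not focal.parent.is_root:
                neighbours.append(focal.parent)
            neighbours.extend(c for c in focal.parent.children if c is not focal)
            share = leak / len(neighbours)
            for nb in neighbours:
                placements.append(
                    Placement(
                        edge_num=nb.edge_num,
                        like_weight_ratio=share,
                        likelihood=float(np.log(max(share, 1e-300)) - 100.0),
                        distal_length=(nb.length or 0.0) / 2.0,
                        pendant_length=0.01,
                    )
                )
        reads.append(
            ReadPlacement(name=f"read_{i:0{width}d}", placements=placements, true_label=clade)
        )
    return PlacementSet(tree=tree, reads=reads)


# ---------------------------------------------------------------------------
# metagenome profiles
# ---------------------------------------------------------------------------


def simulate_profiles(config: SimConfig) -> list[SampleProfile]:
    """Biome-structured metagenome profiles with overdispersed counts.

    Per sample: sequencing depth log-uniform on
    ``[min_reads, max_reads]``; per gene, expected count = (per-Gb biome
    effect) x (gigabases sequenced) x exp(covariate terms); realised
    counts negative-binomial around that mean.
    """
    pc = config.profile
    rng = _rng(config.seed, "profile")
    genes = sorted({g for eff in pc.biome_effects.values() for g in eff})
    out: list[SampleProfile] = []
    i = 0
    for biome in sorted(pc.biome_effects):
        effects = pc.biome_effects[biome]
        for _ in range(pc.n_samples_per_biome):
            i += 1
            total_reads = int(
                np.floor(10 ** rng.uniform(np.log10(pc.min_reads), np.log10(pc.max_reads)))
            )
            gb = total_reads * pc.read_length / 1e9
            covs = {c: float(rng.normal()) for c in pc.covariate_effects}
            counts = {}
            for gene in genes:
                mu = effects.get(gene, 0.0) * gb
                if mu > 0:
                    shift = sum(
                        pc.covariate_effects[c].get(gene, 0.0) * covs[c]
                        for c in pc.covariate_effects
                    )
                    mu *= float(np.exp(shift))
                if mu <= 0:
                    counts[gene] = 0
                elif pc.dispersion is None:
                    counts[gene] = int(rng.poisson(mu))
                else:
                    k = pc.dispersion
                    counts[gene] = int(rng.negative_binomial(k, k / (k + mu)))
            out.append(
                SampleProfile(
                    sample_id=f"s{i:04d}", biome=biome, total_reads=total_reads,
                    read_length=pc.read_length, counts=counts, covariates=covs,
                )
            )
    return out


# ---------------------------------------------------------------------------
# fixture materialisation
# ---------------------------------------------------------------------------


def write_fixture_dir(config: SimConfig, outdir, clades: CladeSet | None = None) -> dict[str, str]:
    """Materialise a complete fixture directory from one config.

    Writes: ``tree.nwk`` (with supports), ``bootstraps.nwk`` (one tree per
    line), ``traits.tsv``, ``clades.tsv``, ``placements.jplace``,
    ``profiles.tsv``, ``truth.tsv`` (true read labels) and ``config.json``.
    Returns the mapping of artefact name -> path.
    """
    from .tree import extract_supported_clades
    from .community import write_profiles
    import pandas as pd

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tree = simulate_tree(config)
    boots = perturb_bootstrap_trees(tree, config.n_bootstrap_trees, seed=config.seed + 1)
    if config.conservation_depth is None and config.trait_mode == "clade_gain":
        config_depth = 0.5 * tree.height()
        cfg = SimConfig(**{**config.__dict__, "conservation_depth": config_depth})
    else:
        cfg = config
    trait = evolve_trait(tree, cfg)
    if clades is None:
        clades = extract_supported_clades(tree, sh_min=0.0, uf_min=0.0)
        if OUTGROUP not in clades and clades.names:
            # dedicate the last extracted clade to the outgroup role
            last = clades.clades.pop(clades.names[-1])
            clades.clades[OUTGROUP] = Clade(name=OUTGROUP, tips=last.tips, support=last.support)
    pset = simulate_placements(tree, clades, cfg)
    profiles = simulate_profiles(cfg)

    paths = {}
    p = outdir / "tree.nwk"
    p.write_text(tree.to_newick() + "\n")
    paths["tree"] = str(p)
    p = outdir / "bootstraps.nwk"
    p.write_text("".join(t.to_newick() + "\n" for t in boots))
    paths["bootstraps"] = str(p)
    p = outdir / "traits.tsv"
    pd.DataFrame({"trait_1": pd.Series(trait)}).to_csv(p, sep="\t", index_label="tip_label")
    paths["traits"] = str(p)
    p = outdir / "clades.tsv"
    clades.to_tsv(p)
    paths["clades"] = str(p)
    p = outdir / "placements.jplace"
    write_jplace(pset, p)
    paths["placements"] = str(p)
    p = outdir / "truth.tsv"
    pd.DataFrame(
        [(r.name, r.true_label) for r in pset.reads], columns=["read", "true_label"]
    ).to_csv(p, sep="\t", index=False)
    paths["truth"] = str(p)
    p = outdir / "profiles.tsv"
    write_profiles(profiles, p)
    paths["profiles"] = str(p)
    p = outdir / "config.json"
    p.write_text(json.dumps(_config_to_dict(config), indent=2) + "\n")
    paths["config"] = str(p)
    return paths


def _config_to_dict(config: SimConfig) -> dict:
    d = dict(config.__dict__)
    d["placement"] = dict(config.placement.__dict__)
    d["profile"] = dict(config.profile.__dict__)
    return d
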