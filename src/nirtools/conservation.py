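"""Trait-conservation depth (consenTRAIT) and bootstrap effect sizes.

The consenTRAIT statistic :math:`\\tau_D` is the mean phylogenetic depth of
the clades in which at least 90% of tips share a binary trait: deeper
clades mean the trait is conserved over longer evolutionary distances.
Comparing the observed :math:`\\tau_D` across bootstrap trees with the
values obtained when the same trait is shuffled uniformly over the tips
yields a Glass'-D effect size (observed-minus-null mean in null-standard-
deviation units), which is comparable across phylogenies with different
depth scales.  Contrasting the effect size on a gene phylogeny against the
effect size of the same trait on the organism phylogeny singles out traits
that track the gene's evolution rather than shared organismal ancestry.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .tree import Node, Phylogeny

__all__ = [
    "consentrait_tau",
    "tau_null",
    "glass_d",
    "contrast_trees",
    "ConservationResult",
    "TreeContrast",
    "read_trait_matrix",
    "write_trait_matrix",
]


def _as_trait_map(trait, tip_labels: Sequence[str]) -> dict[str, float]:
    """Normalise a trait vector to {tip: 0/1}, dropping missing entries."""
    if isinstance(trait, pd.Series):
        items = trait.items()
    elif isinstance(trait, Mapping):
        items = trait.items()
    else:
        if len(trait) != len(tip_labels):
            raise ValueError("positional trait vector length must equal number of tips")
        items = zip(tip_labels, trait)
    out: dict[str, float] = {}
    for tip, val in items:
        if val is None or (isinstance(val, float) and math.isnan(val)):
            continue
        v = int(val)
        if v not in (0, 1):
            raise ValueError(f"trait values must be binary; got {val!r} for tip {tip!r}")
        out[str(tip)] = v
    return out


def consentrait_tau(
    tree: Phylogeny,
    trait,
    share_threshold: float = 0.90,
    include_singletons: bool = True,
) -> float:
    """Mean depth of the maximal clades in which the trait is (near-)fixed.

    A clade qualifies when at least ``share_threshold`` of its non-missing
    tips are trait-positive and it holds at least two positive tips; each
    maximal qualifying clade contributes its mean node-to-tip distance.
    Positive tips outside every qualifying clade are treated as singleton
    clades contributing half their terminal branch length (the convention
    of the original reference implementation; disable with
    ``include_singletons=False``).  Tips with missing trait values are
    pruned before any depth is computed.

    Parameters
    ----------
    trait
        Mapping/Series tip label -> {0, 1, missing}, or a positional
        sequence aligned to ``tree.tip_labels``.

    Returns
    -------
    float
        :math:`\\tau_D` in branch-length units.
    """
    if not 0 < share_threshold <= 1:
        raise ValueError("share_threshold must lie in (0, 1]")
    tmap = _as_trait_map(trait, tree.tip_labels)
    scored = {t for t in tree.tip_labels if t in tmap}
    if not scored:
        raise ValueError("trait absent: no tips with non-missing trait values")
    if len(scored) < tree.n_tips:
        tree = tree.prune_to(scored)
    n_pos_total = sum(tmap[t] for t in scored)
    if n_pos_total == 0:
        raise ValueError("trait absent: no positive tips")

    # per-node positive / total counts, bottom-up
    counts: dict[Node, tuple[int, int]] = {}
    for node in tree.postorder():
        if node.is_leaf:
            counts[node] = (tmap[node.label], 1)
        else:
            p = sum(counts[c][0] for c in node.children)
            n = sum(counts[c][1] for c in node.children)
            counts[node] = (p, n)

    contributions: list[float] = []
    covered: set[Node] = set()

    def qualifies(node: Node) -> bool:
        p, n = counts[node]
        return p >= 2 and p / n >= share_threshold

    # root-ward scan: take qualifying nodes with no qualifying ancestor
    stack = [tree.root]
    while stack:
        node = stack.pop()
        if not node.is_leaf and qualifies(node):
            contributions.append(tree.mean_node_to_tip_depth(node))
            covered.add(node)
            continue
        stack.extend(node.children)

    if include_singletons:
        in_clade: set[str] = set()
        tips_below = tree.descendant_tips()
        for node in covered:
            in_clade |= tips_below[node]
        for tip in tree.tips():
            if tmap[tip.label] == 1 and tip.label not in in_clade:
                if tip.length is None:
                    raise ValueError(f"missing terminal branch length for tip {tip.label!r}")
                contributions.append(tip.length / 2.0)

    if not contributions:
        raise ValueError(
            "no conserved clades and singletons disabled: tau_D undefined"
        )
    tau = float(np.mean(contributions))
    if tau == 0.0:
        raise ValueError("tau_D is zero: tree has no height under the trait")
    return tau


def tau_null(
    tree: Phylogeny,
    trait,
    n_perm: int = 1000,
    seed: int | np.random.Generator | None = None,
    share_threshold: float = 0.90,
    include_singletons: bool = True,
) -> np.ndarray:
    """Null distribution of :math:`\\tau_D` under uniform tip shuffles.

    Trait values are permuted uniformly across the scored tips, preserving
    prevalence; missing entries stay missing (their tips are pruned exactly
    as in the observed computation).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    tmap = _as_trait_map(trait, tree.tip_labels)
    tips = [t for t in tree.tip_labels if t in tmap]
    values = np.array([tmap[t] for t in tips])
    out = np.empty(n_perm)
    for i in range(n_perm):
        shuffled = values[rng.permutation(len(values))]
        out[i] = consentrait_tau(
            tree,
            dict(zip(tips, shuffled)),
            share_threshold=share_threshold,
            include_singletons=include_singletons,
        )
    return out


def glass_d(tau_obs: Sequence[float], tau_null_values: Sequence[float]) -> float | None:
    """Glass' D: (mean observed − mean null) / null standard deviation.

    The *null* SD is the denominator (Glass' convention: the control
    group sets the scale).  Returns ``None`` when the null SD is zero —
    the effect size is undefined there, not infinite.
    """
    obs = np.asarray(tau_obs, dtype=float)
    null = np.asarray(tau_null_values, dtype=float)
    if obs.size == 0 or null.size == 0:
        raise ValueError("tau_obs and tau_null must be non-empty")
    sd = float(np.std(null, ddof=1)) if null.size > 1 else 0.0
    # a numerically constant null (sd at float-rounding scale) is still
    # degenerate: report undefined rather than a noise ratio
    if sd <= 1e-12 * max(1.0, abs(float(null.mean()))):
        return None
    return float((obs.mean() - null.mean()) / sd)


@dataclass
class ConservationResult:
    """Per-trait conservation summary on one phylogeny (plus bootstraps)."""

    trait: str
    tree_id: str
    tau_obs: np.ndarray
    tau_null: np.ndarray
    glass_d: float | None
    n_positive_tips: int

    def to_long_frame(self) -> pd.DataFrame:
        rows = [
            {"trait": self.trait, "tree_id": self.tree_id, "replicate": i, "tau": t, "kind": "obs"}
            for i, t in enumerate(self.tau_obs)
        ] + [
            {"trait": self.trait, "tree_id": self.tree_id, "replicate": i, "tau": t, "kind": "null"}
            for i, t in enumerate(self.tau_null)
        ]
        return pd.DataFrame(rows)


def conservation_result(
    tree: Phylogeny,
    bootstraps: Sequence[Phylogeny],
    trait,
    trait_name: str = "trait",
    tree_id: str = "tree",
    n_perm: int = 1000,
    seed: int | np.random.Generator | None = None,
    share_threshold: float = 0.90,
) -> ConservationResult:
    """Observed :math:`\\tau_D` over bootstrap trees, null on the best tree.

    The null is computed on the best (non-bootstrap) tree only; bootstrap
    trees enter the observed side, capturing topological uncertainty.
    """
    tmap = _as_trait_map(trait, tree.tip_labels)
    obs = np.array(
        [consentrait_tau(bt, tmap, share_threshold=share_threshold) for bt in bootstraps]
        if bootstraps
        else [consentrait_tau(tree, tmap, share_threshold=share_threshold)]
    )
    null = tau_null(tree, tmap, n_perm=n_perm, seed=seed, share_threshold=share_threshold)
    return ConservationResult(
        trait=trait_name,
        tree_id=tree_id,
        tau_obs=obs,
        tau_null=null,
        glass_d=glass_d(obs, null),
        n_positive_tips=int(sum(tmap.values())),
    )


@dataclass
class TreeContrast:
    """Gene-tree vs organism-tree conservation contrast for one trait."""

    trait: str
    d_gene: float | None
    d_org: float | None
    gene_associated: bool
    margin: float = 0.0
    note: str | None = None


def contrast_trees(
    trait,
    gene_tree: Phylogeny,
    org_tree: Phylogeny,
    gene_bootstraps: Sequence[Phylogeny] = (),
    org_bootstraps: Sequence[Phylogeny] = (),
    n_perm: int = 1000,
    seed: int | None = None,
    trait_name: str = "trait",
    margin: float = 0.0,
    share_threshold: float = 0.90,
) -> TreeContrast:
    """Is a trait more conserved along the gene phylogeny than the organisms'?

    Both trees must be tip-labelled by genome id so the trait maps onto
    each; the trait is restricted to the tip intersection.  The trait is
    flagged gene-associated when ``D_gene > D_org + margin`` and
    ``D_gene > 0``.  Fixed (invariant) traits give an undefined effect size
    on both trees and are flagged ``False`` with an explanatory note.
    """
    shared = set(gene_tree.tip_labels) & set(org_tree.tip_labels)
    tmap = {t: v for t, v in _as_trait_map(trait, list(shared)).items() if t in shared}
    if len(tmap) < 4:
        raise ValueError("insufficient overlap: fewer than 4 shared tips with trait data")
    rng = np.random.default_rng(seed)

    def one_side(best: Phylogeny, boots: Sequence[Phylogeny], tree_id: str):
        keep = set(tmap) & set(best.tip_labels)
        sub_best = best.prune_to(keep)
        sub_boots = [bt.prune_to(keep & set(bt.tip_labels)) for bt in boots]
        return conservation_result(
            sub_best, sub_boots, tmap, trait_name=trait_name, tree_id=tree_id,
            n_perm=n_perm, seed=rng, share_threshold=share_threshold,
        )

    try:
        res_gene = one_side(gene_tree, gene_bootstraps, "gene")
        res_org = one_side(org_tree, org_bootstraps, "organism")
    except ValueError as exc:
        return TreeContrast(trait_name, None, None, False, margin, note=str(exc))

    d_gene, d_org = res_gene.glass_d, res_org.glass_d
    if d_gene is None or d_org is None:
        return TreeContrast(
            trait_name, d_gene, d_org, False, margin,
            note="undefined: zero null variance (trait effectively fixed)",
        )
    flag = (d_gene > d_org + margin) and (d_gene > 0)
    return TreeContrast(trait_name, d_gene, d_org, flag, margin)


# ---------------------------------------------------------------------------
# trait matrix I/O
# ---------------------------------------------------------------------------


def read_trait_matrix(path) -> pd.DataFrame:
    """Tips x binary-traits TSV; first column is the tip label."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    bad = [c for c in df.columns if not df[c].dropna().isin([0, 1]).all()]
    if bad:
        raise ValueError(f"non-binary trait columns: {bad}")
    return df


def write_trait_matrix(traits: pd.DataFrame, path) -> None:
    traits.to_csv(path, sep="\t", index_label="tip_label")
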