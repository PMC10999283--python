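"""Phylogenetic placements: jplace I/O, mass filtering and diversity.

Environmental reads are placed onto an edge-numbered reference tree and
each placement carries a like_weight_ratio — the fraction of the read's
total placement likelihood assigned to one edge.  This module consumes
such placements (the jplace standard), applies the mass-based filter used
for clade counting (at least ``min_mass`` of the likelihood inside the
target group and exactly zero mass in the outgroup), validates the
classifier against known read origins, and summarises samples by
balance-weighted phylogenetic diversity (BWPD), rarefied clade
composition and per-edge environmental correlations.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .tree import CladeSet, Node, OUTGROUP, Phylogeny, UNASSIGNED, parse_newick, write_newick

__all__ = [
    "Placement",
    "ReadPlacement",
    "PlacementSet",
    "read_jplace",
    "write_jplace",
    "filter_placements",
    "FilterResult",
    "classifier_metrics",
    "EdgeMassProfile",
    "bwpd",
    "edge_correlations",
    "rarefied_composition",
    "RarefactionResult",
]

_REQUIRED_FIELDS = ("edge_num", "like_weight_ratio")
_CANONICAL_FIELDS = ("edge_num", "likelihood", "like_weight_ratio", "distal_length", "pendant_length")


@dataclass(frozen=True)
class Placement:
    """One candidate edge for a read, with its likelihood mass."""

    edge_num: int
    like_weight_ratio: float
    likelihood: float = 0.0
    distal_length: float = 0.0
    pendant_length: float = 0.0


@dataclass
class ReadPlacement:
    name: str
    placements: list[Placement]
    true_label: str | None = None  # known origin, for classifier validation

    @property
    def total_mass(self) -> float:
        return sum(p.like_weight_ratio for p in self.placements)


@dataclass
class PlacementSet:
    """Reads placed on an edge-numbered reference tree."""

    tree: Phylogeny
    reads: list[ReadPlacement]
    fields: tuple[str, ...] = _CANONICAL_FIELDS
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        valid_edges = set(self.tree.edge_map())
        for read in self.reads:
            for p in read.placements:
                if p.edge_num not in valid_edges:
                    raise ValueError(
                        f"read {read.name!r} placed on edge {p.edge_num} absent from the tree"
                    )
            if read.total_mass > 1 + 1e-9:
                raise ValueError(f"read {read.name!r} has like_weight_ratio sum > 1")

    def mass_profile(self) -> "EdgeMassProfile":
        """Aggregate all reads into per-edge mass fractions."""
        masses: dict[int, float] = {}
        total = 0.0
        for read in self.reads:
            for p in read.placements:
                masses[p.edge_num] = masses.get(p.edge_num, 0.0) + p.like_weight_ratio
                total += p.like_weight_ratio
        if total > 0:
            masses = {e: m / total for e, m in masses.items()}
        return EdgeMassProfile(masses=masses, total_mass=total)


# ---------------------------------------------------------------------------
# jplace I/O
# ---------------------------------------------------------------------------


def read_jplace(path_or_file) -> PlacementSet:
    """Parse a jplace (version >= 3) file.

    The ``fields`` array must name at least ``edge_num`` and
    ``like_weight_ratio``; unknown field names are an error.  Edge numbers
    must exist in the reference tree.
    """
    if hasattr(path_or_file, "read"):
        doc = json.load(path_or_file)
    else:
        with open(path_or_file) as fh:
            doc = json.load(fh)
    version = int(doc.get("version", 0))
    if version < 3:
        raise ValueError(f"jplace version {version} unsupported; need >= 3")
    fields = tuple(doc["fields"])
    unknown = set(fields) - set(_CANONICAL_FIELDS)
    if unknown:
        raise ValueError(f"unknown jplace field names: {sorted(unknown)}")
    for req in _REQUIRED_FIELDS:
        if req not in fields:
            raise ValueError(f"jplace fields must include {req!r}")
    tree = parse_newick(doc["tree"], support_format="none")
    idx = {f: i for i, f in enumerate(fields)}
    reads = []
    for entry in doc.get("placements", []):
        if "n" in entry:
            names = entry["n"]
        elif "nm" in entry:
            names = [nm[0] for nm in entry["nm"]]
        else:
            raise ValueError("placement entry lacks both 'n' and 'nm'")
        placements = [
            Placement(
                edge_num=int(row[idx["edge_num"]]),
                like_weight_ratio=float(row[idx["like_weight_ratio"]]),
                likelihood=float(row[idx["likelihood"]]) if "likelihood" in idx else 0.0,
                distal_length=float(row[idx["distal_length"]]) if "distal_length" in idx else 0.0,
                pendant_length=float(row[idx["pendant_length"]]) if "pendant_length" in idx else 0.0,
            )
            for row in entry["p"]
        ]
        for name in names:
            reads.append(ReadPlacement(name=name, placements=list(placements)))
    pset = PlacementSet(tree=tree, reads=reads, fields=fields, metadata=doc.get("metadata", {}))
    truth = doc.get("metadata", {}).get("true_labels")
    if truth:
        for read in pset.reads:
            read.true_label = truth.get(read.name)
    return pset


def write_jplace(pset: PlacementSet, path_or_file) -> None:
    """Write jplace v3 preserving the set's field ordering bit-exactly."""
    idx_fields = pset.fields
    placements = []
    for read in pset.reads:
        rows = []
        for p in read.placements:
            row = []
            for f in idx_fields:
                val = getattr(p, "edge_num" if f == "edge_num" else f)
                row.append(val)
            rows.append(row)
        placements.append({"p": rows, "n": [read.name]})
    metadata = dict(pset.metadata)
    truths = {r.name: r.true_label for r in pset.reads if r.true_label is not None}
    if truths:
        metadata["true_labels"] = truths
    doc = {
        "version": 3,
        "tree": write_newick(pset.tree, support_format="none", edge_numbers=True),
        "fields": list(idx_fields),
        "placements": placements,
        "metadata": metadata,
    }
    if hasattr(path_or_file, "write"):
        json.dump(doc, path_or_file, indent=1)
    else:
        with open(path_or_file, "w") as fh:
            json.dump(doc, fh, indent=1)


# ---------------------------------------------------------------------------
# mass filtering and classifier validation
# ---------------------------------------------------------------------------


def edge_group_map(tree: Phylogeny, clades: CladeSet) -> dict[int, str | None]:
    """Assign each edge to a clade, the outgroup, or neither.

    An edge belongs to a group iff *all* tips below it are in that group;
    boundary edges (descendants spanning groups) belong to no group —
    their mass counts toward the ingroup total but toward no clade.
    """
    tip_to_clade = clades.tip_to_clade()
    below = tree.descendant_tips()
    out: dict[int, str | None] = {}
    for node in tree.preorder():
        if node.is_root:
            continue
        groups = {tip_to_clade.get(t, UNASSIGNED) for t in below[node]}
        out[node.edge_num] = groups.pop() if len(groups) == 1 else None
    return out


@dataclass
class FilterResult:
    """Outcome of the likelihood-mass filter."""

    level: str
    min_mass: float
    counts: dict[str, int]
    retained: dict[str, list[str]]  # group -> read names
    unassigned_reads: list[str]

    def assignment(self) -> dict[str, str]:
        out = {name: grp for grp, names in self.retained.items() for name in names}
        for name in self.unassigned_reads:
            out[name] = UNASSIGNED
        return out


def filter_placements(
    pset: PlacementSet,
    clades: CladeSet,
    min_mass: float = 0.95,
    level: str = "clade",
) -> FilterResult:
    """Retain reads whose placement mass is confidently inside one group.

    A read counts toward group G iff the like_weight_ratio mass on edges
    fully inside G is at least ``min_mass`` *and* its mass on outgroup
    edges is exactly zero (within 1e-12).  ``level="ingroup"`` pools every
    non-outgroup clade (plus unassigned and boundary edges) into a single
    ingroup; ``level="clade"`` counts per named clade.  The outgroup
    itself is reported as a group: reads with ``min_mass`` of their mass
    on outgroup edges count toward ``"outgroup"``.
    """
    if OUTGROUP not in clades:
        raise ValueError("the zero-outgroup rule is mandatory: define an 'outgroup' clade")
    if level not in ("clade", "ingroup"):
        raise ValueError("level must be 'clade' or 'ingroup'")
    egroup = edge_group_map(pset.tree, clades)
    group_names = [n for n in clades.names if n != OUTGROUP]
    counts: dict[str, int] = {g: 0 for g in (group_names if level == "clade" else ["ingroup"])}
    counts[OUTGROUP] = 0
    retained: dict[str, list[str]] = {g: [] for g in counts}
    unassigned: list[str] = []

    for read in pset.reads:
        mass: dict[str | None, float] = {}
        total = 0.0
        for p in read.placements:
            g = egroup[p.edge_num]
            mass[g] = mass.get(g, 0.0) + p.like_weight_ratio
            total += p.like_weight_ratio
        if total <= 0:
            unassigned.append(read.name)
            continue
        out_mass = mass.get(OUTGROUP, 0.0)
        in_mass = total - out_mass
        target: str | None = None
        if out_mass <= 1e-12:  # zero-outgroup rule gates every ingroup count
            if level == "ingroup":
                if in_mass / total >= min_mass:
                    target = "ingroup"
            else:
                # at most one clade can hold >=min_mass when min_mass > 0.5;
                # the max-mass clade breaks ties deterministically below that
                best = max(group_names, key=lambda g: (mass.get(g, 0.0), g), default=None)
                if (
                    best is not None
                    and mass.get(best, 0.0) > 0
                    and mass.get(best, 0.0) / total >= min_mass
                ):
                    target = best
        elif out_mass / total >= min_mass:
            target = OUTGROUP
        if target is None:
            unassigned.append(read.name)
        else:
            counts[target] += 1
            retained[target].append(read.name)
    return FilterResult(
        level=level, min_mass=min_mass, counts=counts, retained=retained,
        unassigned_reads=unassigned,
    )


def classifier_metrics(pset: PlacementSet, result: FilterResult) -> dict[str, float | None]:
    """Sensitivity and specificity of the placement-plus-filter pipeline.

    Sensitivity: fraction of true ingroup reads detected (retained for any
    ingroup group).  Specificity: fraction of true outgroup reads
    correctly placed in the outgroup (i.e. not retained for any ingroup
    group).  A metric with no eligible reads is reported as ``None``.
    """
    missing = [r.name for r in pset.reads if r.true_label is None]
    if missing:
        raise ValueError(f"reads without true labels: {missing[:5]}")
    assigned = result.assignment()
    ingroup_true = [r for r in pset.reads if r.true_label != OUTGROUP]
    outgroup_true = [r for r in pset.reads if r.true_label == OUTGROUP]
    sens = None
    if ingroup_true:
        detected = sum(
            1 for r in ingroup_true if assigned.get(r.name, UNASSIGNED) not in (UNASSIGNED, OUTGROUP)
        )
        sens = detected / len(ingroup_true)
    spec = None
    if outgroup_true:
        correct = sum(
            1 for r in outgroup_true if assigned.get(r.name, UNASSIGNED) in (UNASSIGNED, OUTGROUP)
        )
        spec = correct / len(outgroup_true)
    return {"sensitivity": sens, "specificity": spec}


# ---------------------------------------------------------------------------
# diversity and composition
# ---------------------------------------------------------------------------


@dataclass
class EdgeMassProfile:
    """Per-sample fraction of total placement mass on each edge."""

    masses: dict[int, float]
    total_mass: float = 1.0

    def __post_init__(self):
        if any(m < -1e-12 for m in self.masses.values()):
            raise ValueError("edge masses must be non-negative")

    def as_series(self, edges: Sequence[int]) -> pd.Series:
        return pd.Series({e: self.masses.get(e, 0.0) for e in edges})


def bwpd(profile: EdgeMassProfile, tree: Phylogeny, theta: float = 1.0) -> float:
    """Balance-weighted phylogenetic diversity of one sample.

    ``BWPD_theta = sum_e  lambda_e * (2 * min(m_e, 1 − m_e)) ** theta``
    where ``m_e`` is the fraction of total placement mass on the distal
    (root-away) side of edge e and ``lambda_e`` its length.  At
    ``theta=0`` the statistic reduces to the classical phylogenetic
    diversity of the mass-spanning subtree: every edge with mass strictly
    on both sides (``0 < m_e < 1``) counts fully.
    """
    if profile.total_mass <= 0 or not profile.masses:
        raise ValueError("zero total placement mass: BWPD undefined")
    total = sum(profile.masses.values())
    if total <= 0:
        raise ValueError("zero total placement mass: BWPD undefined")
    # distal mass below each edge = mass on the edge itself + its subtree
    distal: dict[Node, float] = {}
    for node in tree.postorder():
        if node.is_root:
            continue
        m = profile.masses.get(node.edge_num, 0.0)
        for c in node.children:
            m += distal[c]
        distal[node] = m
    out = 0.0
    for node, m in distal.items():
        if node.length is None:
            raise ValueError(f"missing branch length on edge {node.edge_num}")
        frac = m / total
        if theta == 0:
            # tolerance guards the membership test against float rounding of
            # mass sums (an all-mass-below edge must read exactly 1)
            if 1e-12 < frac < 1.0 - 1e-12:
                out += node.length
        else:
            out += node.length * (2.0 * min(frac, 1.0 - frac)) ** theta
    return out


def edge_correlations(
    profiles: Mapping[str, EdgeMassProfile],
    covariate: Mapping[str, float] | pd.Series,
    min_n: int = 5,
) -> pd.DataFrame:
    """Per-edge Spearman correlation of mass fraction with a covariate.

    Samples missing the covariate are excluded pairwise, so different
    edges may rest on different sample subsets; edges with fewer than
    ``min_n`` complete pairs are flagged ``insufficient_data`` (reported,
    not dropped).  A constant covariate leaves every correlation
    undefined.
    """
    cov = pd.Series(covariate, dtype=float)
    samples = [s for s in profiles if s in cov.index and not np.isnan(cov[s])]
    if len(samples) < min_n:
        raise ValueError(f"fewer than {min_n} samples with both mass and covariate")
    edges = sorted({e for s in samples for e in profiles[s].masses})
    mass = pd.DataFrame({s: profiles[s].as_series(edges) for s in samples}).T
    x = cov[samples]
    rows = []
    constant_cov = x.nunique() <= 1
    for e in edges:
        y = mass[e]
        n = int(len(y))
        if n < min_n or constant_cov or y.nunique() <= 1:
            rows.append({"edge_num": e, "rho": np.nan, "n": n, "insufficient_data": n < min_n})
            continue
        rho = spearmanr(x.to_numpy(), y.to_numpy()).statistic
        rows.append({"edge_num": e, "rho": float(rho), "n": n, "insufficient_data": False})
    return pd.DataFrame(rows).set_index("edge_num")


@dataclass
class RarefactionResult:
    proportions: pd.Series | None
    excluded: bool
    depth: int
    n_rare: int


def rarefied_composition(
    counts: Mapping[str, int] | pd.Series,
    depth: int = 15,
    n_rare: int = 100,
    seed: int | np.random.Generator | None = None,
) -> RarefactionResult:
    """Mean clade proportions over repeated subsampling without replacement.

    Each rarefaction draws ``depth`` placements without replacement
    (multivariate hypergeometric); the mean per-clade proportion over
    ``n_rare`` draws is returned.  Samples with fewer than ``depth``
    placements are flagged excluded rather than extrapolated.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    ser = pd.Series(counts, dtype=int)
    if (ser < 0).any():
        raise ValueError("negative counts")
    total = int(ser.sum())
    if total < depth:
        return RarefactionResult(None, True, depth, n_rare)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    draws = rng.multivariate_hypergeometric(ser.to_numpy(), depth, size=n_rare)
    props = draws.mean(axis=0) / depth
    return RarefactionResult(pd.Series(props, index=ser.index), False, depth, n_rare)
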