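"""Rooted phylogenies with dual node supports and stable edge numbering.

Trees produced by modern maximum-likelihood workflows carry two support
values per internal node — the SH approximate likelihood-ratio test
(SH-aLRT) and the ultrafast bootstrap (UFboot) — written as a single
slash-joined internal label (``"80/95"``).  This module parses and writes
that dialect, computes cophenetic (tip-to-tip path) distances, applies the
zero-length-branch adjustment required by depth-based trait statistics, and
extracts well-supported clades.

Edges are numbered depth-first in preorder from the root (the root itself
has no edge), matching the curly-brace edge tags used by the jplace
placement standard, so synthetic jplace files are deterministic.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Node",
    "Phylogeny",
    "Clade",
    "CladeSet",
    "NewickError",
    "NewickFormatError",
    "parse_newick",
    "write_newick",
    "cophenetic_distances",
    "adjust_zero_branches",
    "extract_supported_clades",
    "UNASSIGNED",
    "OUTGROUP",
]

UNASSIGNED = "unassigned"
OUTGROUP = "outgroup"


class NewickError(ValueError):
    """Malformed newick structure (parentheses, commas, semicolon)."""


class NewickFormatError(ValueError):
    """Structurally valid newick whose support labels violate the dialect."""


class Node:
    """One node of a rooted tree.

    ``length`` is the length of the edge above the node (expected
    substitutions per site); ``sh_alrt``/``ufboot`` are percent supports in
    [0, 100] and are meaningful only on internal non-root nodes;
    ``edge_num`` identifies the edge above the node for jplace interop.
    """

    __slots__ = ("parent", "children", "length", "label", "sh_alrt", "ufboot", "edge_num")

    def __init__(self, label=None, length=None):
        self.parent: Node | None = None
        self.children: list[Node] = []
        self.length: float | None = length
        self.label: str | None = label
        self.sh_alrt: float | None = None
        self.ufboot: float | None = None
        self.edge_num: int | None = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    @property
    def is_root(self) -> bool:
        return self.parent is None

    @property
    def support(self) -> tuple[float | None, float | None] | None:
        if self.sh_alrt is None and self.ufboot is None:
            return None
        return (self.sh_alrt, self.ufboot)

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        kind = "leaf" if self.is_leaf else "internal"
        return f"<Node {kind} label={self.label!r} length={self.length!r}>"


class Phylogeny:
    """A rooted tree with branch lengths, supports and numbered edges."""

    def __init__(self, root: Node, validate: bool = True):
        self.root = root
        if any(n.edge_num is None for n in self.preorder() if not n.is_root):
            self.assign_edge_numbers()
        if validate:
            self._validate()

    # -- traversal -------------------------------------------------------

    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def postorder(self) -> Iterator[Node]:
        out = list(self.preorder())
        return iter(reversed(out))

    def tips(self) -> list[Node]:
        return [n for n in self.preorder() if n.is_leaf]

    def internal_nodes(self, include_root: bool = True) -> list[Node]:
        nodes = [n for n in self.preorder() if not n.is_leaf]
        if not include_root:
            nodes = [n for n in nodes if not n.is_root]
        return nodes

    @property
    def tip_labels(self) -> list[str]:
        return [n.label for n in self.tips()]

    @property
    def n_tips(self) -> int:
        return len(self.tips())

    # -- structure -------------------------------------------------------

    def assign_edge_numbers(self) -> None:
        """Number edges 0..E-1 depth-first in preorder from the root."""
        counter = 0
        for node in self.preorder():
            if node.is_root:
                node.edge_num = None
                continue
            node.edge_num = counter
            counter += 1

    def edge_map(self) -> dict[int, Node]:
        """Map edge number -> node below that edge."""
        return {n.edge_num: n for n in self.preorder() if not n.is_root}

    def node_depths(self) -> dict[Node, float]:
        """Root-to-node path lengths (missing lengths treated as 0)."""
        depths: dict[Node, float] = {self.root: 0.0}
        for node in self.preorder():
            if node.is_root:
                continue
            depths[node] = depths[node.parent] + (node.length or 0.0)
        return depths

    def height(self) -> float:
        depths = self.node_depths()
        return max(depths[t] for t in self.tips())

    def descendant_tips(self) -> dict[Node, frozenset[str]]:
        """For every node, the set of tip labels below it (tips map to themselves)."""
        out: dict[Node, frozenset[str]] = {}
        for node in self.postorder():
            if node.is_leaf:
                out[node] = frozenset([node.label])
            else:
                acc: set[str] = set()
                for c in node.children:
                    acc |= out[c]
                out[node] = frozenset(acc)
        return out

    def mean_node_to_tip_depth(self, node: Node) -> float:
        """Mean path length from ``node`` to each tip below it."""
        total, count = _sum_tip_distances(node)
        return total / count

    def copy(self) -> "Phylogeny":
        def _clone(node: Node) -> Node:
            new = Node(node.label, node.length)
            new.sh_alrt, new.ufboot, new.edge_num = node.sh_alrt, node.ufboot, node.edge_num
            for c in node.children:
                new.add_child(_clone(c))
            return new

        return Phylogeny(_clone(self.root), validate=False)

    def prune_to(self, keep: set[str]) -> "Phylogeny":
        """Restrict to the tips in ``keep``, suppressing unifurcations.

        Branch lengths along suppressed paths are summed; supports on removed
        nodes are dropped.  Edge numbers are re-assigned in preorder.
        """
        missing = keep - set(self.tip_labels)
        if missing:
            raise ValueError(f"tips absent from tree: {sorted(missing)}")
        tree = self.copy()

        def _prune(node: Node) -> Node | None:
            if node.is_leaf:
                return node if node.label in keep else None
            kept = []
            for c in node.children:
                sub = _prune(c)
                if sub is not None:
                    kept.append(sub)
            if not kept:
                return None
            if len(kept) == 1 and not node.is_root:
                child = kept[0]
                if node.length is not None or child.length is not None:
                    child.length = (node.length or 0.0) + (child.length or 0.0)
                return child
            node.children = []
            for c in kept:
                node.add_child(c)
            return node

        root = _prune(tree.root)
        if root is None:
            raise ValueError("pruning removed every tip")
        # collapse a unifurcating root into its single child
        while len(root.children) == 1 and not root.children[0].is_leaf:
            child = root.children[0]
            child.length = None
            child.parent = None
            root = child
        root.parent = None
        new = Phylogeny(root, validate=False)
        new.assign_edge_numbers()
        return new

    def to_newick(self, support_format: str = "slash_pair", edge_numbers: bool = False) -> str:
        return write_newick(self, support_format=support_format, edge_numbers=edge_numbers)

    # -- validation ------------------------------------------------------

    def _validate(self) -> None:
        labels = self.tip_labels
        if any(not lab for lab in labels):
            raise ValueError("every tip must carry a non-empty label")
        if len(set(labels)) != len(labels):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise ValueError(f"duplicate tip labels: {dupes}")
        for node in self.preorder():
            if node.length is not None and node.length < 0:
                raise ValueError(f"negative branch length on node {node.label or node.edge_num}")
        nums = [n.edge_num for n in self.preorder() if not n.is_root]
        if len(set(nums)) != len(nums):
            raise ValueError("edge numbering is not a bijection onto edges")

    def __repr__(self) -> str:  # pragma: no cover
        return f"<Phylogeny with {self.n_tips} tips>"


def _sum_tip_distances(node: Node) -> tuple[float, int]:
    total = 0.0
    count = 0
    stack = [(node, 0.0)]
    while stack:
        cur, dist = stack.pop()
        if cur.is_leaf:
            total += dist
            count += 1
        for c in cur.children:
            stack.append((c, dist + (c.length or 0.0)))
    return total, count


# ---------------------------------------------------------------------------
# newick reader / writer
# ---------------------------------------------------------------------------

_TOKEN = re.compile(r"\s*([(),;:]|\{\d+\}|'[^']*'|[^\s(),;:{}\[\]]+)")


def parse_newick(text: str, support_format: str = "slash_pair") -> Phylogeny:
    """Parse a newick string into a :class:`Phylogeny`.

    ``support_format`` controls how internal-node labels are interpreted:

    ``slash_pair``
        labels of the form ``"A/B"`` with A = SH-aLRT percent and
        B = UFboot percent (the dialect emitted when both measures are
        requested from the tree-inference tool);
    ``single``
        a single numeric support, stored in the UFboot slot;
    ``none``
        internal labels kept verbatim as names, never parsed as support.

    Curly-brace edge tags (``{12}``, the jplace habit) are accepted after
    the branch length and recorded as edge numbers; when absent, edges are
    numbered depth-first in preorder.
    """
    if support_format not in ("slash_pair", "single", "none"):
        raise ValueError(f"unknown support_format: {support_format!r}")
    tokens = []
    pos = 0
    while pos < len(text):
        m = _TOKEN.match(text, pos)
        if m is None:
            if text[pos:].strip():
                raise NewickError(f"unexpected character at position {pos}: {text[pos]!r}")
            break
        tokens.append((m.group(1), m.start(1)))
        pos = m.end()
    if not tokens:
        raise NewickError("empty newick string")

    idx = 0
    has_edge_tags = False

    def peek() -> str | None:
        return tokens[idx][0] if idx < len(tokens) else None

    def take() -> tuple[str, int]:
        nonlocal idx
        if idx >= len(tokens):
            raise NewickError("unexpected end of newick string")
        tok = tokens[idx]
        idx += 1
        return tok

    def parse_subtree() -> Node:
        nonlocal has_edge_tags
        tok = peek()
        if tok == "(":
            take()
            node = Node()
            node.add_child(parse_subtree())
            while peek() == ",":
                take()
                node.add_child(parse_subtree())
            closer, cpos = take()
            if closer != ")":
                raise NewickError(f"expected ')' at position {cpos}, found {closer!r}")
            if peek() not in ("(", ")", ",", ":", ";", None) and not _is_edge_tag(peek()):
                label, _ = take()
                node.label = _unquote(label)
        else:
            label, lpos = take()
            if label in ("(", ")", ",", ":", ";") or _is_edge_tag(label):
                raise NewickError(f"expected a tip label at position {lpos}, found {label!r}")
            node = Node(label=_unquote(label))
        if peek() == ":":
            take()
            raw, rpos = take()
            try:
                node.length = float(raw)
            except ValueError:
                raise NewickError(f"invalid branch length {raw!r} at position {rpos}") from None
            if node.length < 0:
                raise NewickError(f"negative branch length {raw!r} at position {rpos}")
        if _is_edge_tag(peek()):
            tag, _ = take()
            node.edge_num = int(tag[1:-1])
            has_edge_tags = True
        return node

    root = parse_subtree()
    tok = peek()
    if tok != ";":
        where = tokens[idx][1] if idx < len(tokens) else len(text)
        raise NewickError(f"expected ';' at position {where}, found {tok!r}")
    take()
    if idx < len(tokens):
        raise NewickError(f"trailing content after ';' at position {tokens[idx][1]}")

    if support_format != "none":
        for node in _preorder_from(root):
            if node.is_leaf or node.is_root or node.label is None:
                continue
            node.sh_alrt, node.ufboot = _parse_support(node.label, support_format)
            node.label = None

    tree = Phylogeny(root, validate=False)
    if not has_edge_tags:
        tree.assign_edge_numbers()
    else:
        nums = [n.edge_num for n in tree.preorder() if not n.is_root]
        if None in nums or len(set(nums)) != len(nums):
            raise NewickError("edge tags present but not a bijection onto edges")
    tree._validate()
    return tree


def _preorder_from(root: Node) -> Iterator[Node]:
    stack = [root]
    while stack:
        node = stack.pop()
        yield node
        stack.extend(reversed(node.children))


def _is_edge_tag(tok: str | None) -> bool:
    return tok is not None and tok.startswith("{") and tok.endswith("}")


def _unquote(label: str) -> str:
    if label.startswith("'") and label.endswith("'"):
        return label[1:-1]
    return label


def _parse_support(label: str, support_format: str) -> tuple[float | None, float | None]:
    if support_format == "slash_pair":
        parts = label.split("/")
        if len(parts) != 2:
            raise NewickFormatError(
                f"internal label {label!r} is not an 'SH-aLRT/UFboot' pair"
            )
        try:
            sh, uf = float(parts[0]), float(parts[1])
        except ValueError:
            raise NewickFormatError(f"non-numeric support token in {label!r}") from None
    else:  # single
        try:
            uf = float(label)
        except ValueError:
            raise NewickFormatError(f"non-numeric support token {label!r}") from None
        sh = None
    for val in (sh, uf):
        if val is not None and not (0.0 <= val <= 100.0):
            raise NewickFormatError(f"support {val} outside [0, 100] in label {label!r}")
    return sh, uf


def _fmt_length(x: float) -> str:
    s = f"{x:.6f}".rstrip("0").rstrip(".")
    return s or "0"


def _fmt_support(v: float) -> str:
    return _fmt_length(v)


def write_newick(
    tree: Phylogeny, support_format: str = "slash_pair", edge_numbers: bool = False
) -> str:
    """Serialise to canonical newick (lengths trimmed to 6 decimals).

    ``edge_numbers=True`` appends jplace-style ``{n}`` tags after each
    branch length.
    """

    def render(node: Node) -> str:
        if node.is_leaf:
            core = node.label
        else:
            core = "(" + ",".join(render(c) for c in node.children) + ")"
            if not node.is_root:
                if support_format == "slash_pair" and node.support is not None:
                    sh = _fmt_support(node.sh_alrt) if node.sh_alrt is not None else ""
                    uf = _fmt_support(node.ufboot) if node.ufboot is not None else ""
                    core += f"{sh}/{uf}"
                elif support_format == "single" and node.ufboot is not None:
                    core += _fmt_support(node.ufboot)
                elif support_format == "none" and node.label is not None:
                    core += node.label
            elif node.label is not None:
                core += node.label
        if node.length is not None:
            core += f":{_fmt_length(node.length)}"
        if edge_numbers and not node.is_root:
            core += f"{{{node.edge_num}}}"
        return core

    return render(tree.root) + ";"


# ---------------------------------------------------------------------------
# distances and branch adjustment
# ---------------------------------------------------------------------------


def cophenetic_distances(tree: Phylogeny) -> pd.DataFrame:
    """Tip-to-tip path-length matrix (substitutions/site), tips as labels.

    Every edge below the root must carry a branch length.
    """
    for node in tree.preorder():
        if not node.is_root and node.length is None:
            raise ValueError(
                f"missing branch length on node {node.label or f'edge {node.edge_num}'}"
            )
    labels = tree.tip_labels
    index = {lab: i for i, lab in enumerate(labels)}
    n = len(labels)
    dist = np.zeros((n, n))
    # postorder merge: keep (tip index, distance to current node) per subtree
    carry: dict[Node, list[tuple[int, float]]] = {}
    for node in tree.postorder():
        if node.is_leaf:
            carry[node] = [(index[node.label], 0.0)]
            continue
        merged: list[tuple[int, float]] = []
        for child in node.children:
            lifted = [(i, d + child.length) for i, d in carry.pop(child)]
            for i, di in lifted:
                for j, dj in merged:
                    dist[i, j] = dist[j, i] = di + dj
            merged.extend(lifted)
        carry[node] = merged
    return pd.DataFrame(dist, index=labels, columns=labels)


def adjust_zero_branches(tree: Phylogeny) -> Phylogeny:
    """Replace zero-length edges by one tenth of the smallest positive edge.

    Depth-based statistics (trait conservation depth in particular) break on
    zero-length edges; this is the standard floor.  Idempotent, and positive
    edges are never touched.
    """
    lengths = [n.length for n in tree.preorder() if not n.is_root and n.length is not None]
    positive = [x for x in lengths if x > 0]
    if not positive:
        raise ValueError("all branch lengths are zero: no reference scale for adjustment")
    floor = min(positive) / 10.0
    out = tree.copy()
    for node in out.preorder():
        if not node.is_root and node.length == 0.0:
            node.length = floor
    return out


# ---------------------------------------------------------------------------
# clades
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Clade:
    """A named clade: its tips, and the support pair of its defining node."""

    name: str
    tips: frozenset[str]
    support: tuple[float | None, float | None] | None = None

    def __len__(self) -> int:
        return len(self.tips)


@dataclass
class CladeSet:
    """Named clades over a tree's tips.

    ``"outgroup"`` is an ordinary (reserved) clade name marking the
    non-target homologues; ``"unassigned"`` is reserved for tips outside
    every clade and can never name a clade.
    """

    clades: dict[str, Clade] = field(default_factory=dict)
    tree_tips: frozenset[str] | None = None

    def __post_init__(self):
        if UNASSIGNED in self.clades:
            raise ValueError(f"{UNASSIGNED!r} is a reserved name, not a clade")

    def __getitem__(self, name: str) -> Clade:
        return self.clades[name]

    def __contains__(self, name: str) -> bool:
        return name in self.clades

    def __iter__(self):
        return iter(self.clades.values())

    @property
    def names(self) -> list[str]:
        return list(self.clades)

    def tip_to_clade(self) -> dict[str, str]:
        """Partition map tip -> clade name, with leftovers ``"unassigned"``."""
        mapping: dict[str, str] = {}
        for clade in self:
            for tip in clade.tips:
                if tip in mapping:
                    raise ValueError(f"tip {tip!r} claimed by both {mapping[tip]!r} and {clade.name!r}")
                mapping[tip] = clade.name
        if self.tree_tips is not None:
            for tip in self.tree_tips:
                mapping.setdefault(tip, UNASSIGNED)
        return mapping

    def to_tsv(self, path) -> None:
        rows = sorted(self.tip_to_clade().items())
        pd.DataFrame(rows, columns=["tip_label", "clade_name"]).to_csv(
            path, sep="\t", index=False
        )

    @classmethod
    def from_tsv(cls, path, tree: Phylogeny | None = None) -> "CladeSet":
        df = pd.read_csv(path, sep="\t", dtype=str)
        if not {"tip_label", "clade_name"} <= set(df.columns):
            raise ValueError("clade TSV needs columns tip_label, clade_name")
        clades = {}
        for name, grp in df.groupby("clade_name"):
            if name == UNASSIGNED:
                continue
            clades[name] = Clade(name=name, tips=frozenset(grp["tip_label"]))
        tips = frozenset(tree.tip_labels) if tree is not None else frozenset(df["tip_label"])
        return cls(clades=clades, tree_tips=tips)


def extract_supported_clades(
    tree: Phylogeny,
    sh_min: float | None = 80.0,
    uf_min: float | None = 95.0,
    seeds: Mapping[str, Sequence[str]] | None = None,
) -> CladeSet:
    """Clades at internal nodes passing both support thresholds.

    Without seeds, returns the *maximal* qualifying nodes (no qualifying
    ancestor also qualifies) named ``clade_1``, ``clade_2``, ... in preorder.
    With ``seeds`` (clade name -> tip set), each named clade is the smallest
    qualifying node containing its seed tips; a seed whose only containing
    node is the root is rejected (it spans the root).  Thresholds set to
    ``None`` skip that component of the support pair.
    """

    def qualifies(node: Node) -> bool:
        if node.is_leaf or node.is_root:
            return False
        if sh_min is not None and (node.sh_alrt is None or node.sh_alrt < sh_min):
            return False
        if uf_min is not None and (node.ufboot is None or node.ufboot < uf_min):
            return False
        return True

    tips_below = tree.descendant_tips()
    all_tips = frozenset(tree.tip_labels)

    if seeds is None:
        named: dict[str, Clade] = {}
        counter = 0
        stack = [tree.root]
        while stack:
            node = stack.pop(0)
            if qualifies(node):
                counter += 1
                named[f"clade_{counter}"] = Clade(
                    name=f"clade_{counter}", tips=tips_below[node], support=node.support
                )
                continue  # maximality: do not descend into a qualifying node
            stack.extend(node.children)
        return CladeSet(clades=named, tree_tips=all_tips)

    named = {}
    for name, seed_tips in seeds.items():
        seed = frozenset(seed_tips)
        missing = seed - all_tips
        if missing:
            raise ValueError(f"seed {name!r} names tips absent from the tree: {sorted(missing)}")
        best: Node | None = None
        for node in tree.postorder():  # postorder: smallest containing node found first
            if qualifies(node) and seed <= tips_below[node]:
                best = node
                break
        if best is None:
            raise ValueError(
                f"seed {name!r} spans the root or lies in no supported clade"
            )
        named[name] = Clade(name=name, tips=tips_below[best], support=best.support)
    _check_disjoint(named)
    return CladeSet(clades=named, tree_tips=all_tips)


def _check_disjoint(named: dict[str, Clade]) -> None:
    items = list(named.items())
    for i, (na, ca) in enumerate(items):
        for nb, cb in items[i + 1 :]:
            if ca.tips & cb.tips:
                raise ValueError(f"clades {na!r} and {nb!r} overlap; nesting must be explicit")
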