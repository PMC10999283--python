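import numpy as np
import pytest

from nirtools import SimConfig, parse_newick, simulate_tree


@pytest.fixture
def four_tip_tree():
    """Balanced 4-tip tree with unit branches: ((A:1,B:1):1,(C:1,D:1):1);"""
    return parse_newick("((A:1,B:1):1,(C:1,D:1):1);")


@pytest.fixture
def supported_tree():
    return parse_newick("(((A:1,B:1)80/95:1,C:1)90/99:1,(D:1,E:1)70/99:1);")


def random_tree(seed: int, n_tips: int):
    return simulate_tree(SimConfig(seed=seed, n_tips=n_tips))


# ---------------------------------------------------------------------------
# independent oracles (kept free of the implementation paths they check)
# ---------------------------------------------------------------------------


def brute_force_cophenetic(tree):
    """All-pairs tip distance via explicit root-to-tip path intersection."""
    paths = {}
    for tip in tree.tips():
        path = []
        node = tip
        while node is not None:
            path.append(node)
            node = node.parent
        paths[tip.label] = list(reversed(path))  # root ... tip
    labels = sorted(paths)
    out = {}
    for i, a in enumerate(labels):
        for b in labels[i + 1 :]:
            pa, pb = paths[a], paths[b]
            k = 0
            while k < min(len(pa), len(pb)) and pa[k] is pb[k]:
                k += 1

            def tip_up(path_tail):
                # accumulate from the tip upward so float rounding matches
                # any correct tip-up summation exactly
                acc = 0.0
                for n in reversed(path_tail):
                    acc += n.length
                return acc

            out[(a, b)] = out[(b, a)] = tip_up(pa[k:]) + tip_up(pb[k:])
    return out


def spanning_subtree_pd(tree, masses):
    """Branch-length sum of the minimal subtree spanning mass-bearing edges.

    Mass-bearing edges are represented by their child nodes; the subtree is
    the union of node-to-node paths between all pairs of those nodes.
    """
    emap = tree.edge_map()
    points = [emap[e] for e, m in masses.items() if m > 0]

    def path_to_root(node):
        out = []
        while node is not None:
            out.append(node)
            node = node.parent
        return list(reversed(out))

    edges = set()
    for i, a in enumerate(points):
        for b in points[i + 1 :]:
            pa, pb = path_to_root(a), path_to_root(b)
            k = 0
            while k < min(len(pa), len(pb)) and pa[k] is pb[k]:
                k += 1
            edges.update(pa[k:])
            edges.update(pb[k:])
    return sum(n.length for n in edges)
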