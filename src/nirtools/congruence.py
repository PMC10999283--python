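"""Functional-dissimilarity matrices and phylogenetic Mantel tests.

To ask whether a gene's sequence divergence tracks whole-genome functional
divergence, the cophenetic distance matrix of the gene tree is compared
with a Sorensen dissimilarity matrix over gene/pathway presence-absence
profiles.  Significance comes from a Mantel permutation test using
Spearman's rho (robust to monotone nonlinear association); when an
organism phylogeny is supplied, the permutations are phylogenetically
restricted so closely related taxa swap labels more readily — removing
signal that is explained by shared organismal ancestry alone.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .tree import Phylogeny, cophenetic_distances

__all__ = [
    "sorensen_matrix",
    "mantel",
    "MantelResult",
    "constrained_permutation",
    "read_distance_matrix",
    "write_distance_matrix",
]


def validate_distance_matrix(d: pd.DataFrame, name: str = "matrix") -> pd.DataFrame:
    """Check symmetry (1e-12), zero diagonal and unique labels."""
    if list(d.index) != list(d.columns):
        raise ValueError(f"{name}: row and column labels differ")
    if len(set(d.index)) != len(d.index):
        raise ValueError(f"{name}: duplicate labels")
    a = d.to_numpy(dtype=float)
    if not np.allclose(a, a.T, atol=1e-12, equal_nan=True):
        raise ValueError(f"{name}: not symmetric")
    if not np.all(np.abs(np.diag(a)) <= 1e-12):
        raise ValueError(f"{name}: diagonal must be zero")
    if np.nanmin(a) < -1e-12:
        raise ValueError(f"{name}: negative entries")
    return d


def sorensen_matrix(presence: pd.DataFrame, completeness_min: float | None = None) -> pd.DataFrame:
    """Pairwise Sorensen dissimilarity over binary presence/absence rows.

    ``d(i, j) = 1 − 2|A_i ∩ A_j| / (|A_i| + |A_j|)``.  Pairs of all-zero
    rows are undefined and reported as NaN (never as 0); downstream
    comparisons exclude them.  When the table carries a ``completeness``
    column (e.g. KEGG pathway completeness) and ``completeness_min`` is
    given, rows below the cutoff are dropped before the dissimilarity is
    formed; without ``completeness_min`` the column is simply ignored.
    """
    df = presence.copy()
    if completeness_min is not None:
        if "completeness" not in df.columns:
            raise ValueError("completeness_min given but no 'completeness' column present")
        df = df.loc[df["completeness"] >= completeness_min].drop(columns="completeness")
    elif "completeness" in df.columns:
        df = df.drop(columns="completeness")
    x = df.to_numpy(dtype=float)
    if x.shape[0] < 2:
        raise ValueError("need at least two rows to form a dissimilarity matrix")
    if not np.isin(x[~np.isnan(x)], (0, 1)).all():
        raise ValueError("presence matrix must be binary")
    x = np.nan_to_num(x)
    sizes = x.sum(axis=1)
    inter = x @ x.T
    denom = sizes[:, None] + sizes[None, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        d = 1.0 - 2.0 * inter / denom
    d[denom == 0] = np.nan  # two all-zero profiles: undefined, not identical
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=df.index, columns=df.index)


@dataclass
class MantelResult:
    """Spearman Mantel statistic with its permutation p-value."""

    rho: float | None
    p_value: float | None
    n_perm: int
    constrained: bool
    n: int
    alternative: str = "greater"


def _upper(a: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(a.shape[0], k=1)
    return a[iu]


def constrained_permutation(
    rng: np.random.Generator,
    proximity_weights: np.ndarray,
    n_swaps: int | None = None,
) -> np.ndarray:
    """One restricted permutation built from weighted transpositions.

    ``proximity_weights[i, j]`` is the propensity of labels i and j to
    swap; a permutation is assembled by ``n_swaps`` (default
    ``ceil(N log2 N)``) transpositions, each picking i uniformly and j
    with probability proportional to the weights of row i.
    """
    n = proximity_weights.shape[0]
    w = proximity_weights.astype(float).copy()
    np.fill_diagonal(w, 0.0)
    row_sums = w.sum(axis=1)
    if np.any(row_sums <= 0):
        raise ValueError("each label needs a positive swap weight to at least one partner")
    probs = w / row_sums[:, None]
    if n_swaps is None:
        n_swaps = int(np.ceil(n * np.log2(max(n, 2))))
    perm = np.arange(n)
    picks_i = rng.integers(0, n, size=n_swaps)
    u = rng.random(size=n_swaps)
    cum = np.cumsum(probs, axis=1)
    for i, ui in zip(picks_i, u):
        j = int(np.searchsorted(cum[i], ui))
        perm[i], perm[j] = perm[j], perm[i]
    return perm


def _proximity_from_tree(tree: Phylogeny, labels: list[str], strength: float) -> np.ndarray:
    """Swap weights w = 1 − s·ĉ with ĉ the min-max-scaled cophenetic distance."""
    coph = cophenetic_distances(tree).loc[labels, labels].to_numpy()
    off = coph[np.triu_indices_from(coph, k=1)]
    lo, hi = off.min(), off.max()
    scaled = np.zeros_like(coph) if hi == lo else (coph - lo) / (hi - lo)
    return 1.0 - strength * scaled


def mantel(
    d1: pd.DataFrame,
    d2: pd.DataFrame,
    n_perm: int = 999,
    seed: int | None = None,
    constraint_tree: Phylogeny | None = None,
    restriction_strength: float = 0.9,
    alternative: str = "greater",
) -> MantelResult:
    """Mantel test with Spearman's rho between two distance matrices.

    The statistic is the Spearman correlation of the vectorised upper
    triangles.  The p-value is permutational with the add-one correction,
    ``p = (1 + #{rho_perm >= rho_obs}) / (n_perm + 1)`` for the default
    one-sided (positive-association) alternative; ``alternative`` may be
    ``"greater"`` or ``"two-sided"``.  With ``constraint_tree`` the label
    permutations are phylogenetically restricted (Lapointe–Garland-style
    weighted transpositions, weight ``1 − s·ĉ(i,j)``, ``s`` =
    ``restriction_strength``), so closely related taxa switch more often.

    NaN entries (undefined pairs) are excluded from both the observed and
    every permuted correlation.
    """
    if alternative not in ("greater", "two-sided"):
        raise ValueError("alternative must be 'greater' or 'two-sided'")
    validate_distance_matrix(d1, "d1")
    validate_distance_matrix(d2, "d2")
    s1, s2 = set(d1.index), set(d2.index)
    if s1 != s2:
        diff = sorted(s1 ^ s2)
        raise ValueError(f"label mismatch between matrices: {diff}")
    labels = list(d1.index)
    n = len(labels)
    if n < 4:
        raise ValueError("need at least 4 shared labels")
    a1 = d1.to_numpy(dtype=float)
    a2 = d2.loc[labels, labels].to_numpy(dtype=float)

    mask = ~(np.isnan(a1) | np.isnan(a2))
    np.fill_diagonal(mask, True)
    iu = np.triu_indices(n, k=1)
    valid = mask[iu]

    def ranked(a: np.ndarray) -> np.ndarray:
        """Square matrix of condensed-vector ranks (NaN-safe)."""
        v = a[iu]
        r = np.full(v.shape, np.nan)
        r[valid] = rankdata(v[valid])
        sq = np.zeros_like(a)
        sq[iu] = r
        sq.T[iu] = r
        return sq

    r1sq, r2sq = ranked(a1), ranked(a2)
    v1, v2 = r1sq[iu], r2sq[iu]

    complete = bool(valid.all())

    def corr(x: np.ndarray, y: np.ndarray) -> float:
        if not complete:
            ok = ~(np.isnan(x) | np.isnan(y))
            # masking invalidates the global ranks; re-rank the survivors
            x, y = rankdata(x[ok]), rankdata(y[ok])
        xc, yc = x - x.mean(), y - y.mean()
        sxx, syy = xc @ xc, yc @ yc
        if sxx == 0 or syy == 0:
            return np.nan
        r = float((xc @ yc) / np.sqrt(sxx * syy))
        # tied-rank vectors are identical up to float noise; pin the bounds
        if abs(r) > 1.0 - 1e-12:
            r = float(np.sign(r))
        return r

    rho = corr(v1, v2)
    if np.isnan(rho):
        return MantelResult(None, None, n_perm, constraint_tree is not None, n, alternative)

    rng = np.random.default_rng(seed)
    if constraint_tree is not None:
        missing = set(labels) - set(constraint_tree.tip_labels)
        if missing:
            raise ValueError(f"constraint tree lacks labels: {sorted(missing)}")
        weights = _proximity_from_tree(constraint_tree, labels, restriction_strength)

    count = 0
    for _ in range(n_perm):
        if constraint_tree is None:
            perm = rng.permutation(n)
        else:
            perm = constrained_permutation(rng, weights)
        assert np.array_equal(np.sort(perm), np.arange(n))
        p2 = r2sq[np.ix_(perm, perm)][iu]
        rho_p = corr(v1, p2)
        if np.isnan(rho_p):
            continue
        if alternative == "greater":
            count += rho_p >= rho
        else:
            count += abs(rho_p) >= abs(rho)
    p = (1 + count) / (n_perm + 1)
    return MantelResult(rho, p, n_perm, constraint_tree is not None, n, alternative)


def read_distance_matrix(path) -> pd.DataFrame:
    d = pd.read_csv(path, sep="\t", index_col=0)
    d.columns = d.columns.astype(str)
    d.index = d.index.astype(str)
    return validate_distance_matrix(d)


def write_distance_matrix(d: pd.DataFrame, path) -> None:
    d.to_csv(path, sep="\t", index_label="label")
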