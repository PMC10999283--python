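"""Biome-level abundance and diversity statistics for paired marker genes.

The central index is

    delta_nir = 1e9 * (nirK - nirS) / (total_reads * 150 bp)

the per-gigabase difference in filtered read counts between the two
nitrite-reductase genes.  It is defined for every metagenome — including
those where one or both genes are undetected — and positive values mean
nirK dominance.  Around it sit per-gigabase normalisation, biome
comparisons (Kruskal-Wallis followed by Dunn's pairwise rank test with
Benjamini-Hochberg correction), nirK:nirS diversity ratios, the
clade-by-trait enrichment test (global chi-square plus post hoc adjusted
standardized residuals) and abundance-diversity rank correlations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "SampleProfile",
    "delta_nir",
    "per_gb",
    "biome_compare",
    "BiomeComparison",
    "diversity_ratio",
    "clade_trait_enrichment",
    "EnrichmentResult",
    "abundance_diversity_correlation",
    "read_profiles",
    "write_profiles",
]

DEFAULT_READ_LENGTH = 150  # nt; queries are truncated to this length upstream


@dataclass
class SampleProfile:
    """One metagenome: sequencing effort, biome, gene counts, covariates."""

    sample_id: str
    biome: str
    total_reads: int
    counts: dict[str, int] = field(default_factory=dict)
    read_length: int = DEFAULT_READ_LENGTH
    bwpd: dict[str, float] = field(default_factory=dict)
    covariates: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.total_reads < 1:
            raise ValueError(f"{self.sample_id}: total_reads must be >= 1")
        if self.read_length <= 0:
            raise ValueError(f"{self.sample_id}: read_length must be positive")
        if any(c < 0 for c in self.counts.values()):
            raise ValueError(f"{self.sample_id}: negative counts")

    @property
    def gigabases(self) -> float:
        return self.total_reads * self.read_length / 1e9


def per_gb(count: float, total_reads: int, read_length: int = DEFAULT_READ_LENGTH) -> float:
    """Gene copies per gigabase sequenced: count * 1e9 / (reads * length)."""
    if total_reads <= 0:
        raise ValueError("total_reads must be positive")
    return count * 1e9 / (total_reads * read_length)


def delta_nir(
    profile: SampleProfile,
    gene_k: str = "nirK",
    gene_s: str = "nirS",
    read_length: int = DEFAULT_READ_LENGTH,
) -> float:
    """Signed per-Gb dominance of nirK over nirS.

    ``1e9 * (nirK − nirS) / (total_reads * read_length)`` with the read
    length fixed at 150 nt by default (the truncation length applied to
    queries), not the sample's native read length.  Zero counts are valid:
    the index is defined even when neither gene is detected.
    """
    k = profile.counts.get(gene_k, 0)
    s = profile.counts.get(gene_s, 0)
    return per_gb(k - s, profile.total_reads, read_length)


# ---------------------------------------------------------------------------
# biome comparisons
# ---------------------------------------------------------------------------


@dataclass
class BiomeComparison:
    h_statistic: float
    p_global: float
    pairwise_p: pd.DataFrame  # BH-adjusted, symmetric
    method: str
    excluded_biomes: list[str]
    n_per_biome: dict[str, int]


def _dunn_pairwise(values: np.ndarray, groups: np.ndarray) -> pd.DataFrame:
    """Dunn's z-tests on joint ranks with tie correction, raw p-values."""
    n = len(values)
    ranks = stats.rankdata(values)
    names = sorted(set(groups))
    mean_rank = {g: ranks[groups == g].mean() for g in names}
    sizes = {g: int((groups == g).sum()) for g in names}
    _, tie_counts = np.unique(values, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / (12.0 * (n - 1))
    var_base = n * (n + 1) / 12.0 - tie_term
    rows = []
    for a, b in combinations(names, 2):
        se = np.sqrt(var_base * (1.0 / sizes[a] + 1.0 / sizes[b]))
        z = (mean_rank[a] - mean_rank[b]) / se if se > 0 else 0.0
        p = 2.0 * stats.norm.sf(abs(z))
        rows.append({"a": a, "b": b, "z": z, "p": p})
    return pd.DataFrame(rows)


def biome_compare(
    values: Sequence[float],
    biomes: Sequence[str],
    alpha: float = 0.05,
    method: str = "dunn",
    min_samples: int | None = None,
) -> BiomeComparison:
    """Kruskal-Wallis across biomes with BH-corrected pairwise rank tests.

    ``method`` is ``"dunn"`` (joint-rank z-tests, the default reading of a
    "pairwise comparison of ranks") or ``"mannwhitney"`` (pairwise
    rank-sum tests).  ``min_samples`` (e.g. 10) drops under-sampled biomes
    before testing and reports them.  Ties are handled by the usual rank
    corrections, never as an error.
    """
    if method not in ("dunn", "mannwhitney"):
        raise ValueError("method must be 'dunn' or 'mannwhitney'")
    vals = np.asarray(values, dtype=float)
    grp = np.asarray(biomes, dtype=object)
    if len(vals) != len(grp):
        raise ValueError("values and biome labels differ in length")
    ok = ~np.isnan(vals)
    vals, grp = vals[ok], grp[ok]
    sizes = pd.Series(grp).value_counts()
    excluded = []
    if min_samples is not None:
        excluded = sorted(sizes[sizes < min_samples].index)
        keep = ~np.isin(grp, excluded)
        vals, grp = vals[keep], grp[keep]
        sizes = pd.Series(grp).value_counts()
    names = sorted(sizes.index)
    if len(names) < 2 or any(sizes[g] < 2 for g in names):
        raise ValueError("need at least 2 biomes with at least 2 samples each")

    groups = [vals[grp == g] for g in names]
    h, p_global = stats.kruskal(*groups)

    if method == "dunn":
        table = _dunn_pairwise(vals, grp)
    else:
        rows = []
        for a, b in combinations(names, 2):
            u = stats.mannwhitneyu(vals[grp == a], vals[grp == b], alternative="two-sided")
            rows.append({"a": a, "b": b, "z": np.nan, "p": u.pvalue})
        table = pd.DataFrame(rows)

    adj = multipletests(table["p"].to_numpy(), method="fdr_bh")[1]
    mat = pd.DataFrame(np.nan, index=names, columns=names)
    for (_, row), q in zip(table.iterrows(), adj):
        mat.loc[row["a"], row["b"]] = q
        mat.loc[row["b"], row["a"]] = q
    np.fill_diagonal(mat.values, 1.0)
    return BiomeComparison(
        h_statistic=float(h), p_global=float(p_global), pairwise_p=mat, method=method,
        excluded_biomes=excluded, n_per_biome={g: int(sizes[g]) for g in names},
    )


def diversity_ratio(
    profiles: Sequence[SampleProfile], gene_k: str = "nirK", gene_s: str = "nirS"
) -> tuple[pd.DataFrame, pd.Series, int]:
    """Per-sample nirK:nirS BWPD ratio and per-biome medians.

    Samples missing either BWPD value or with a zero/negative denominator
    are excluded; the count of exclusions is returned alongside.
    """
    rows, excluded = [], 0
    for p in profiles:
        k, s = p.bwpd.get(gene_k), p.bwpd.get(gene_s)
        if k is None or s is None or s <= 0:
            excluded += 1
            continue
        rows.append({"sample_id": p.sample_id, "biome": p.biome, "ratio": k / s})
    df = pd.DataFrame(rows, columns=["sample_id", "biome", "ratio"])
    medians = df.groupby("biome")["ratio"].median() if len(df) else pd.Series(dtype=float)
    return df, medians, excluded


# ---------------------------------------------------------------------------
# clade-trait enrichment
# ---------------------------------------------------------------------------


@dataclass
class EnrichmentResult:
    chi2: float
    df: int
    p_global: float
    residuals: pd.DataFrame  # adjusted standardized residuals
    cell_p: pd.DataFrame  # BH-adjusted two-sided p per cell
    flags: pd.DataFrame  # enriched cells (adjusted p < alpha, residual > 0)
    alpha: float
    low_expected_warning: bool


def clade_trait_enrichment(table: pd.DataFrame, alpha: float = 0.05) -> EnrichmentResult:
    """Which clades carry a trait more often than expected by chance?

    Global Pearson chi-square on the clade-by-trait contingency table,
    then post hoc adjusted standardized residuals
    ``(O − E) / sqrt(E (1 − row/N)(1 − col/N))`` with two-sided normal
    p-values, BH-corrected across all cells of the table.  Cells with
    adjusted p < alpha and positive residual are flagged enriched.
    """
    obs = table.to_numpy(dtype=float)
    if obs.min() < 0:
        raise ValueError("contingency counts must be non-negative")
    n = obs.sum()
    row = obs.sum(axis=1, keepdims=True)
    col = obs.sum(axis=0, keepdims=True)
    expected = row @ col / n
    if (expected == 0).any():
        raise ValueError("a cell has zero expected count: merge sparse categories first")
    low_expected = bool((expected < 5).mean() > 0.20)

    chi2, p_global, df, _ = stats.chi2_contingency(obs, correction=False)
    with np.errstate(invalid="ignore"):
        denom = np.sqrt(expected * (1 - row / n) * (1 - col / n))
    resid = (obs - expected) / denom
    raw_p = 2.0 * stats.norm.sf(np.abs(resid))
    adj_p = multipletests(raw_p.ravel(), method="fdr_bh")[1].reshape(raw_p.shape)
    flags = (adj_p < alpha) & (resid > 0)
    idx, cols = table.index, table.columns
    return EnrichmentResult(
        chi2=float(chi2),
        df=int(df),
        p_global=float(p_global),
        residuals=pd.DataFrame(resid, index=idx, columns=cols),
        cell_p=pd.DataFrame(adj_p, index=idx, columns=cols),
        flags=pd.DataFrame(flags, index=idx, columns=cols),
        alpha=alpha,
        low_expected_warning=low_expected,
    )


# ---------------------------------------------------------------------------
# abundance vs diversity
# ---------------------------------------------------------------------------


def abundance_diversity_correlation(
    profiles: Sequence[SampleProfile], genes: Sequence[str] = ("nirK", "nirS")
) -> pd.DataFrame:
    """Spearman rho between per-Gb abundance and BWPD, per gene.

    Pairwise-complete: a sample enters a gene's correlation only when it
    has both the count and the BWPD value.  Constant vectors give an
    undefined (NaN) rho, reported with the n used.
    """
    rows = []
    for gene in genes:
        ab, dv = [], []
        for p in profiles:
            d = p.bwpd.get(gene)
            if d is None or gene not in p.counts:
                continue
            ab.append(per_gb(p.counts[gene], p.total_reads, p.read_length))
            dv.append(d)
        n = len(ab)
        if n < 5:
            raise ValueError(f"{gene}: need at least 5 samples with both quantities")
        if len(set(ab)) <= 1 or len(set(dv)) <= 1:
            rows.append({"gene": gene, "rho": np.nan, "n": n})
            continue
        rho = stats.spearmanr(ab, dv).statistic
        rows.append({"gene": gene, "rho": float(rho), "n": n})
    return pd.DataFrame(rows).set_index("gene")


# ---------------------------------------------------------------------------
# profile I/O
# ---------------------------------------------------------------------------

_CORE_COLUMNS = ("sample_id", "biome", "total_reads", "read_length")


def write_profiles(profiles: Sequence[SampleProfile], path) -> None:
    """Tidy TSV: one row per sample; counts, bwpd and covariates as columns."""
    genes = sorted({g for p in profiles for g in p.counts})
    bw = sorted({g for p in profiles for g in p.bwpd})
    covs = sorted({c for p in profiles for c in p.covariates})
    rows = []
    for p in profiles:
        row = {
            "sample_id": p.sample_id, "biome": p.biome,
            "total_reads": p.total_reads, "read_length": p.read_length,
        }
        row.update({f"count_{g}": p.counts.get(g, 0) for g in genes})
        row.update({f"bwpd_{g}": p.bwpd.get(g, np.nan) for g in bw})
        row.update({f"cov_{c}": p.covariates.get(c, np.nan) for c in covs})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_profiles(path) -> list[SampleProfile]:
    df = pd.read_csv(path, sep="\t")
    missing = set(_CORE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"profile TSV lacks columns: {sorted(missing)}")
    out = []
    for _, r in df.iterrows():
        counts = {
            c[len("count_"):]: int(r[c]) for c in df.columns if c.startswith("count_")
        }
        bw = {
            c[len("bwpd_"):]: float(r[c])
            for c in df.columns
            if c.startswith("bwpd_") and not pd.isna(r[c])
        }
        covs = {
            c[len("cov_"):]: float(r[c])
            for c in df.columns
            if c.startswith("cov_") and not pd.isna(r[c])
        }
        out.append(
            SampleProfile(
                sample_id=str(r["sample_id"]), biome=str(r["biome"]),
                total_reads=int(r["total_reads"]), read_length=int(r["read_length"]),
                counts=counts, bwpd=bw, covariates=covs,
            )
        )
    return out
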