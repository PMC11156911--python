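"""Joining binding peaks, m6A sites and proteomics into stratified statistics.

The central object is a per-gene integration record: how many binding peaks a
gene carries, how many of those overlap an m6A site (its "m6A-peak" count),
the resulting class (0, 1-2, 3-5, 6+), and the knockdown log2 fold change of
the encoded protein.  Classes are compared to the 0-peak reference class via
two-sample Kolmogorov-Smirnov tests on the protein log2FC distributions;
category-wise peak counts are compared with Mann-Whitney U tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

#: class labels for per-gene peak counts, in increasing order
CLASS_ORDER = ["0", "1-2", "3-5", "6+"]
CLASS_RANK = {label: i for i, label in enumerate(CLASS_ORDER)}

#: pseudocount used wherever expression values are divided
EXPRESSION_PSEUDOCOUNT = 0.001

#: product n*m above which the KS p-value switches to the asymptotic method
KS_EXACT_LIMIT = 10_000

#: smaller-sample size at or below which Mann-Whitney p-values are exact
MW_EXACT_LIMIT = 8


def peak_class(n: int) -> str:
    """Class label for a per-gene peak count: {0}, {1,2}, {3,4,5}, {>=6}."""
    if n < 0:
        raise ValueError("peak count must be non-negative")
    if n == 0:
        return "0"
    if n <= 2:
        return "1-2"
    if n <= 5:
        return "3-5"
    return "6+"


# ---------------------------------------------------------------------------
# Proteomics differential expression
# ---------------------------------------------------------------------------

def proteomics_differential(
    ratios: pd.DataFrame,
    lfc_threshold: float = 1.0,
    p_threshold: float = 0.05,
    z_transform: bool = True,
) -> pd.DataFrame:
    """Z-score replicate log2 ratios per column and t-test each protein vs 0.

    ``ratios`` is proteins x replicate columns of knockdown-vs-control log2
    ratios.  Each column is standardized over all proteins (mean 0, sd 1)
    unless ``z_transform`` is off, then a two-sided one-sample t-test across
    replicates is run per protein.  Proteins with zero replicate variance
    get an undefined p and are never significant.
    """
    if ratios.shape[1] < 2:
        raise ValueError("need >= 2 replicate columns")
    if z_transform:
        z = (ratios - ratios.mean(axis=0)) / ratios.std(axis=0, ddof=1)
    else:
        z = ratios.copy()
    vals = z.to_numpy(float)
    mean = vals.mean(axis=1)
    sd = vals.std(axis=1, ddof=1)
    n = vals.shape[1]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 1)
    undefined = sd <= 1e-12 * max(1.0, np.abs(vals).max())
    p[undefined] = np.nan
    out = pd.DataFrame(
        {
            "log2fc": mean,
            "t": np.where(undefined, np.nan, t),
            "p": p,
            "zero_variance": undefined,
        },
        index=ratios.index,
    )
    out["significant"] = (~undefined) & (np.abs(mean) > lfc_threshold) & (p < p_threshold)
    return pd.concat([z.add_suffix("_z"), out], axis=1)


# ---------------------------------------------------------------------------
# Peak / m6A intersection
# ---------------------------------------------------------------------------

def intersect_peaks_m6a(
    peaks: pd.DataFrame,
    m6a_sites: pd.DataFrame,
    window: int = 0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Superimpose binding peaks and m6A sites.

    A peak [start, end) on a strand overlaps a site at ``pos`` iff
    ``start - window <= pos < end + window`` on the same chrom and strand.
    Returns (peaks with a boolean ``has_m6a`` column, per-gene counts of
    distinct m6A sites covered by at least one of the gene's peaks — the
    per-gene "m6A peak" count used for class stratification).
    """
    peaks = peaks.copy()
    flags = np.zeros(len(peaks), dtype=bool)
    by_key: dict[tuple[str, str], np.ndarray] = {}
    if len(m6a_sites):
        for (chrom, strand), sub in m6a_sites.groupby(["chrom", "strand"]):
            by_key[(chrom, strand)] = np.unique(sub["pos"].to_numpy(int))
    covered_per_gene: dict[str, set[int]] = {g: set() for g in peaks["gene_id"].unique()}
    for i, row in enumerate(peaks.itertuples()):
        positions = by_key.get((row.chrom, row.strand))
        if positions is None:
            continue
        lo = np.searchsorted(positions, row.start - window, side="left")
        hi = np.searchsorted(positions, row.end + window, side="left")
        flags[i] = hi > lo
        if hi > lo:
            covered_per_gene[row.gene_id].update(positions[lo:hi].tolist())
    peaks["has_m6a"] = flags
    per_gene = pd.Series(
        {g: len(s) for g, s in covered_per_gene.items()}, dtype=int, name="n_m6a_peaks"
    )
    return peaks, per_gene


def build_integration(
    per_gene_peaks: pd.Series,
    per_gene_m6a_peaks: pd.Series,
    protein_log2fc: pd.Series,
) -> pd.DataFrame:
    """Per-gene joined record over the union of genes with proteomics data.

    Genes present in proteomics but absent from the peak tables get count 0
    (class "0"); genes without a protein measurement are dropped.
    """
    genes = protein_log2fc.dropna().index
    out = pd.DataFrame(index=genes)
    out["n_peaks"] = per_gene_peaks.reindex(genes, fill_value=0).astype(int)
    out["n_m6a_peaks"] = per_gene_m6a_peaks.reindex(genes, fill_value=0).astype(int)
    out["protein_log2fc"] = protein_log2fc.loc[genes]
    out["class_peaks"] = out["n_peaks"].map(peak_class)
    out["class_m6a_peaks"] = out["n_m6a_peaks"].map(peak_class)
    return out


# ---------------------------------------------------------------------------
# Stratified ecdf / KS
# ---------------------------------------------------------------------------

@dataclass
class StratTestResult:
    class_label: str
    n: int
    statistic: float
    p: float


def ecdf_table(values: np.ndarray) -> pd.DataFrame:
    """Sorted values with their empirical CDF (monotone, ending at 1)."""
    x = np.sort(np.asarray(values, float))
    return pd.DataFrame({"x": x, "ecdf": np.arange(1, len(x) + 1) / len(x)})


def ks_two_sample(a: np.ndarray, b: np.ndarray, exact_limit: int = KS_EXACT_LIMIT):
    """Two-sided two-sample KS; exact p for small problems, asymptotic above."""
    method = "exact" if len(a) * len(b) <= exact_limit else "asymp"
    res = stats.ks_2samp(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def stratify_and_test(
    integration: pd.DataFrame,
    count_field: str = "n_m6a_peaks",
    value_field: str = "protein_log2fc",
) -> tuple[dict[str, pd.DataFrame], list[StratTestResult]]:
    """Per-class ecdfs of protein log2FC plus KS tests of each class vs "0".

    Classes follow :data:`CLASS_ORDER`; each non-reference class is compared
    with the 0-peak class by a two-sided two-sample KS test.
    """
    classes = integration[count_field].map(peak_class)
    groups = {
        label: integration.loc[classes == label, value_field].to_numpy(float)
        for label in CLASS_ORDER
    }
    ref = groups["0"]
    if len(ref) == 0:
        raise ValueError("reference class '0' is empty")
    ecdfs = {label: ecdf_table(vals) for label, vals in groups.items() if len(vals)}
    results = []
    for label in CLASS_ORDER[1:]:
        vals = groups[label]
        if len(vals) == 0:
            continue
        d, p = ks_two_sample(vals, ref)
        results.append(StratTestResult(label, len(vals), d, p))
    return ecdfs, results


# ---------------------------------------------------------------------------
# Category comparisons (Mann-Whitney)
# ---------------------------------------------------------------------------

def category_peak_comparison(
    per_gene_counts: pd.Series,
    categories: dict[str, list[str]],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Mann-Whitney U tests of per-gene peak counts across categories.

    Returns (per-category summaries, pairwise test table).  U is exact for
    min(n, m) <= 8 and a tie-corrected normal approximation otherwise.
    """
    if len(categories) < 2:
        raise ValueError("need >= 2 categories")
    values = {}
    for name, genes in categories.items():
        missing = [g for g in genes if g not in per_gene_counts.index]
        if len(missing) == len(genes):
            raise KeyError(f"category {name!r} has no genes in the counts table")
        values[name] = per_gene_counts.reindex(genes).dropna().to_numpy(float)
    summaries = pd.DataFrame(
        {
            "n": {k: len(v) for k, v in values.items()},
            "median": {k: float(np.median(v)) for k, v in values.items()},
            "mean": {k: float(np.mean(v)) for k, v in values.items()},
        }
    )
    rows = []
    names = list(values)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            x, y = values[a], values[b]
            method = "exact" if min(len(x), len(y)) <= MW_EXACT_LIMIT else "asymptotic"
            res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
            rows.append({"category_a": a, "category_b": b, "U": float(res.statistic),
                         "p": float(res.pvalue), "method": method})
    return summaries, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Nested-filter percentages and windowed overlap
# ---------------------------------------------------------------------------

def nested_filter_percentages(
    protein_sets: dict[str, set[str]],
    term_members: set[str],
) -> pd.DataFrame:
    """Percentage of each protein set belonging to a functional term.

    pct(set) = 100 * |set & term| / |set|.  Empty sets get NaN and a flag
    rather than an error, mirroring how an empty filter stage is reported.
    """
    rows = []
    for name, members in protein_sets.items():
        n = len(members)
        pct = 100.0 * len(members & term_members) / n if n else np.nan
        rows.append({"set": name, "n": n, "in_term": len(members & term_members),
                     "pct": pct, "undefined": n == 0})
    return pd.DataFrame(rows)


def windowed_overlap_fraction(
    sites: pd.DataFrame,
    reference: pd.DataFrame,
    window: int = 0,
) -> float:
    """Percentage of ``sites`` lying within ``window`` nt of a reference site.

    Both inputs need chrom/strand/pos columns; a site at p matches a reference
    at q iff |p - q| <= window on the same chrom and strand.
    """
    if len(sites) == 0:
        raise ValueError("empty query site set")
    by_key: dict[tuple[str, str], np.ndarray] = {}
    for (chrom, strand), sub in reference.groupby(["chrom", "strand"]):
        by_key[(chrom, strand)] = np.sort(sub["pos"].to_numpy(int))
    hits = 0
    for row in sites.itertuples():
        positions = by_key.get((row.chrom, row.strand))
        if positions is None:
            continue
        lo = np.searchsorted(positions, row.pos - window, side="left")
        hi = np.searchsorted(positions, row.pos + window, side="right")
        hits += hi > lo
    return 100.0 * hits / len(sites)
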