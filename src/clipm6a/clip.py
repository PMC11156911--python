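"""From aligned truncation-type reads to crosslink sites, peaks and counts.

Pipeline order: collapse PCR duplicates by UMI, assign each unique cDNA to
its crosslink position (one nucleotide 5' of the cDNA 5' end), call
positions whose event count exceeds a within-gene permutation null, cluster
significant positions into peaks with a fixed nucleotide window, and count
events per peak or per gene.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .annotation import GenomeAnnotation

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Duplicate collapse
# ---------------------------------------------------------------------------

def collapse_duplicates(reads: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, float | None]]:
    """Collapse reads sharing (sample, chrom, strand, start, umi) to molecules.

    The 5' end surrogate is ``start`` for + reads and ``end`` for - reads;
    both are kept on the collapsed record, so the collapse key uses the
    strand-aware 5' coordinate.  Returns the unique molecules (first read of
    each group) and the per-sample PCR duplication ratio (reads / molecules),
    ``None`` for samples with no reads.
    """
    if len(reads) == 0:
        return reads.copy(), {}
    five_prime = np.where(reads["strand"] == "+", reads["start"], reads["end"])
    key_cols = ["sample", "chrom", "strand", "_p5", "umi"]
    tmp = reads.assign(_p5=five_prime)
    molecules = tmp.drop_duplicates(subset=key_cols, keep="first").drop(columns="_p5")
    ratios: dict[str, float | None] = {}
    n_reads = reads.groupby("sample").size()
    n_mols = molecules.groupby("sample").size()
    for sample in n_reads.index:
        ratios[str(sample)] = float(n_reads[sample] / n_mols[sample])
    return molecules.reset_index(drop=True), ratios


# ---------------------------------------------------------------------------
# Crosslink assignment
# ---------------------------------------------------------------------------

def assign_crosslinks(molecules: pd.DataFrame) -> pd.DataFrame:
    """Aggregate unique molecules into per-position crosslink event counts.

    The crosslink is the nucleotide immediately 5' of the molecule's 5' end:
    start - 1 on the + strand, end on the - strand.  Molecules whose
    crosslink would fall before position 0 are dropped with a warning.
    Output columns: chrom, strand, pos, sample, count (long format);
    the count total equals the number of retained molecules.
    """
    cols = ["chrom", "strand", "pos", "sample", "count"]
    if len(molecules) == 0:
        return pd.DataFrame(columns=cols)
    pos = np.where(molecules["strand"] == "+", molecules["start"] - 1, molecules["end"])
    keep = pos >= 0
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.warning("dropped %d molecule(s) with crosslink before position 0", n_dropped)
    tmp = molecules.loc[keep, ["chrom", "strand", "sample"]].assign(pos=pos[keep])
    out = (
        tmp.groupby(["chrom", "strand", "pos", "sample"], sort=True)
        .size()
        .rename("count")
        .reset_index()
    )
    return out.loc[:, cols]


def pooled_site_counts(sites: pd.DataFrame) -> pd.DataFrame:
    """Sum crosslink counts over samples -> chrom, strand, pos, count."""
    return (
        sites.groupby(["chrom", "strand", "pos"], sort=True)["count"]
        .sum()
        .reset_index()
    )


# ---------------------------------------------------------------------------
# Significant site calling (within-gene permutation FDR)
# ---------------------------------------------------------------------------

def call_significant_sites(
    sites: pd.DataFrame,
    annotation: GenomeAnnotation,
    fdr_threshold: float = 0.05,
    n_permutations: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Crosslink positions with more events than a uniform within-gene null.

    Per gene, the gene's total event count is re-scattered uniformly over the
    gene span ``n_permutations`` times.  For an observed per-position count c,
    FDR(c) = (mean permuted number of positions with count >= c) /
    (observed number of positions with count >= c), capped at 1; positions
    with FDR(count) < ``fdr_threshold`` are significant.  Positions not
    assignable to any gene are skipped and logged.
    """
    if n_permutations < 10:
        raise ValueError("n_permutations < 10 gives unstable FDR estimates")
    pooled = pooled_site_counts(sites)
    if len(pooled) == 0:
        return pd.DataFrame(columns=["chrom", "strand", "pos", "count", "gene_id", "fdr"])
    genes = [
        annotation.assign_gene(row.chrom, row.strand, int(row.pos))
        for row in pooled.itertuples()
    ]
    pooled = pooled.assign(gene_id=genes)
    n_skipped = int(pooled["gene_id"].isna().sum())
    if n_skipped:
        logger.warning("skipped %d site(s) outside any gene", n_skipped)
    pooled = pooled.dropna(subset=["gene_id"])

    rng = np.random.default_rng(seed)
    out_frames = []
    for gene_id, sub in pooled.groupby("gene_id", sort=True):
        chrom, strand, g0, g1 = annotation.gene_span(str(gene_id))
        length = g1 - g0
        if length <= 0:
            raise ValueError(f"gene {gene_id} has zero length")
        observed = sub["count"].to_numpy(int)
        total = int(observed.sum())
        perm = rng.multinomial(total, np.full(length, 1.0 / length), size=n_permutations)
        fdr = np.empty(len(sub))
        for c in np.unique(observed):
            exp_ge = (perm >= c).sum(axis=1).mean()
            obs_ge = int((observed >= c).sum())
            fdr[observed == c] = min(1.0, exp_ge / obs_ge)
        out_frames.append(sub.assign(fdr=fdr))
    if not out_frames:
        return pd.DataFrame(columns=["chrom", "strand", "pos", "count", "gene_id", "fdr"])
    scored = pd.concat(out_frames, ignore_index=True)
    sig = scored[scored["fdr"] < fdr_threshold].reset_index(drop=True)
    return sig.loc[:, ["chrom", "strand", "pos", "count", "gene_id", "fdr"]]


# ---------------------------------------------------------------------------
# Peak clustering
# ---------------------------------------------------------------------------

@dataclass
class Peak:
    chrom: str
    strand: str
    start: int
    end: int
    gene_id: str
    summit: int
    count: int


def cluster_peaks(significant: pd.DataFrame, window: int = 20) -> pd.DataFrame:
    """Merge significant sites separated by <= ``window`` intervening nt.

    The gap between consecutive sites is the number of nucleotides strictly
    between them, so adjacent positions merge even at window 0.  Peaks never
    span genes.  The summit is the max-count position; ties break
    toward the 5' end of the gene (lowest coordinate on +, highest on -).
    Output columns: chrom, strand, start, end, gene_id, summit, count.
    """
    cols = ["chrom", "strand", "start", "end", "gene_id", "summit", "count"]
    if len(significant) == 0:
        return pd.DataFrame(columns=cols)
    peaks: list[Peak] = []
    for (chrom, strand, gene_id), sub in significant.groupby(
        ["chrom", "strand", "gene_id"], sort=True
    ):
        sub = sub.sort_values("pos")
        positions = sub["pos"].to_numpy(int)
        counts = sub["count"].to_numpy(int)
        block_start = 0
        for i in range(1, len(positions) + 1):
            if i == len(positions) or positions[i] - positions[i - 1] - 1 > window:
                pos_blk = positions[block_start:i]
                cnt_blk = counts[block_start:i]
                best = cnt_blk.max()
                candidates = pos_blk[cnt_blk == best]
                summit = candidates.min() if strand == "+" else candidates.max()
                peaks.append(
                    Peak(chrom, strand, int(pos_blk[0]), int(pos_blk[-1]) + 1,
                         str(gene_id), int(summit), int(cnt_blk.sum()))
                )
                block_start = i
    out = pd.DataFrame([vars(p) for p in peaks])
    return out.sort_values(["chrom", "start"]).reset_index(drop=True).loc[:, cols]


# ---------------------------------------------------------------------------
# Count matrices
# ---------------------------------------------------------------------------

def count_matrix(
    sites: pd.DataFrame,
    features: pd.DataFrame,
    samples: list[str] | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Crosslink event counts per feature per sample, plus the remainder.

    ``sites`` is the long-format per-sample crosslink table; ``features``
    needs chrom/strand/start/end plus a ``feature_id`` (or gene_id) column.
    Events inside several overlapping features are counted in each of them
    (and logged); events outside all features land in the remainder series.
    """
    feat = features.copy()
    if "feature_id" not in feat.columns:
        feat["feature_id"] = feat["gene_id"]
    if samples is None:
        samples = sorted(sites["sample"].unique()) if len(sites) else []
    matrix = pd.DataFrame(0, index=feat["feature_id"], columns=samples, dtype=int)
    remainder = pd.Series(0, index=samples, dtype=int, name="remainder")
    if len(sites) == 0:
        return matrix, remainder

    by_key: dict[tuple[str, str], pd.DataFrame] = {
        key: sub.sort_values("start") for key, sub in feat.groupby(["chrom", "strand"])
    }
    multi = 0
    for row in sites.itertuples():
        sub = by_key.get((row.chrom, row.strand))
        hits = []
        if sub is not None:
            mask = (sub["start"] <= row.pos) & (row.pos < sub["end"])
            hits = list(sub.loc[mask, "feature_id"])
        if not hits:
            remainder[row.sample] += row.count
            continue
        if len(hits) > 1:
            multi += 1
        for fid in hits:
            matrix.loc[fid, row.sample] += row.count
    if multi:
        logger.warning("%d site(s) fell in several overlapping features; counted in each", multi)
    return matrix, remainder


def gene_count_matrix(
    sites: pd.DataFrame, annotation: GenomeAnnotation
) -> tuple[pd.DataFrame, pd.Series]:
    """Per-gene crosslink event counts over transcribed gene spans."""
    feat = annotation.genes.rename(columns={"gene_id": "feature_id"})
    return count_matrix(sites, feat)
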