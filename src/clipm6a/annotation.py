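"""Transcript annotation, region assignment and metagene profiling.

The annotation model is deliberately small: one representative transcript per
gene, with per-region genomic intervals for 5'UTR, CDS and 3'UTR (protein
coding) or a single ncRNA interval.  Gaps between a transcript's feature
intervals are introns; everything outside annotated genes is intergenic.

Region classes used throughout::

    five_prime_utr, CDS, three_prime_utr, intron, ncRNA, intergenic

When transcripts on overlapping loci disagree, a single class is chosen by
the precedence 3'UTR > 5'UTR > CDS > ncRNA > intron, reflecting that the
binding biology studied here concentrates in 3'UTRs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

REGION_CLASSES = ["five_prime_utr", "CDS", "three_prime_utr", "intron", "ncRNA", "intergenic"]

#: smaller rank wins when several transcripts cover one position
_PRECEDENCE = {"three_prime_utr": 0, "five_prime_utr": 1, "CDS": 2, "ncRNA": 3, "intron": 4}

MRNA_REGIONS = ("five_prime_utr", "CDS", "three_prime_utr")


@dataclass
class Transcript:
    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    #: region -> sorted list of genomic (start, end) half-open intervals
    regions: dict[str, list[tuple[int, int]]] = field(default_factory=dict)

    @property
    def span(self) -> tuple[int, int]:
        ivs = [iv for ivs in self.regions.values() for iv in ivs]
        return min(s for s, _ in ivs), max(e for _, e in ivs)

    @property
    def is_coding(self) -> bool:
        return "CDS" in self.regions

    def region_length(self, region: str) -> int:
        return sum(e - s for s, e in self.regions.get(region, []))

    def _ordered_blocks(self) -> list[tuple[str, int, int]]:
        """mRNA blocks as (region, start, end) in transcript 5'->3' order."""
        blocks = [
            (region, s, e)
            for region in MRNA_REGIONS
            for s, e in self.regions.get(region, [])
        ]
        blocks.sort(key=lambda b: b[1], reverse=self.strand == "-")
        return blocks

    def to_transcript_coord(self, pos: int) -> int | None:
        """Spliced transcript coordinate (0-based, 5'->3') of a genomic position.

        Returns None for positions not on an mRNA block (introns, outside).
        """
        offset = 0
        for _, s, e in self._ordered_blocks():
            if s <= pos < e:
                return offset + (pos - s if self.strand == "+" else e - 1 - pos)
            offset += e - s
        return None

    def region_coord(self, pos: int) -> tuple[str, int, int] | None:
        """(region, offset-within-region, region length) for a genomic position."""
        per_region_offset: dict[str, int] = {}
        for region, s, e in self._ordered_blocks():
            off = per_region_offset.get(region, 0)
            if s <= pos < e:
                within = pos - s if self.strand == "+" else e - 1 - pos
                return region, off + within, self.region_length(region)
            per_region_offset[region] = off + (e - s)
        return None

    def anchor(self, which: str) -> int:
        """Transcript coordinate of the first ('start') or last ('stop') CDS nt."""
        l5 = self.region_length("five_prime_utr")
        lc = self.region_length("CDS")
        if which == "start":
            return l5
        if which == "stop":
            return l5 + lc - 1
        raise ValueError(which)


class GenomeAnnotation:
    """Indexed view over a GTF-lite feature table (0-based half-open)."""

    def __init__(self, features: pd.DataFrame, chrom_lengths: Mapping[str, int]):
        self.features = features.reset_index(drop=True)
        self.chrom_lengths = dict(chrom_lengths)
        self.transcripts: dict[str, Transcript] = {}
        for (tid, gid, chrom, strand), sub in features.groupby(
            ["transcript_id", "gene_id", "chrom", "strand"], sort=False
        ):
            regions: dict[str, list[tuple[int, int]]] = {}
            for _, row in sub.iterrows():
                regions.setdefault(row["feature"], []).append((int(row["start"]), int(row["end"])))
            for ivs in regions.values():
                ivs.sort()
            self.transcripts[tid] = Transcript(tid, gid, chrom, strand, regions)

        # gene table: one representative transcript per gene
        rows = []
        for tx in self.transcripts.values():
            s, e = tx.span
            rows.append(
                {
                    "gene_id": tx.gene_id,
                    "transcript_id": tx.transcript_id,
                    "chrom": tx.chrom,
                    "strand": tx.strand,
                    "start": s,
                    "end": e,
                    "coding": tx.is_coding,
                }
            )
        self.genes = pd.DataFrame(rows)

        # interval indexes
        self._feature_trees: dict[str, IntervalTree] = {}
        self._span_trees: dict[str, IntervalTree] = {}
        for tx in self.transcripts.values():
            ftree = self._feature_trees.setdefault(tx.chrom, IntervalTree())
            for region, ivs in tx.regions.items():
                for s, e in ivs:
                    ftree.addi(s, e, (region, tx.strand, tx.transcript_id))
            stree = self._span_trees.setdefault(tx.chrom, IntervalTree())
            s, e = tx.span
            stree.addi(s, e, (tx.strand, tx.transcript_id))

    # -- gene assignment ----------------------------------------------------

    def assign_gene(self, chrom: str, strand: str, pos: int) -> str | None:
        """Gene id whose transcribed span covers (chrom, strand, pos), else None."""
        tree = self._span_trees.get(chrom)
        if tree is None:
            return None
        hits = [iv for iv in tree.at(pos) if iv.data[0] == strand]
        if not hits:
            return None
        # deterministic choice when spans overlap
        hits.sort(key=lambda iv: iv.data[1])
        return self.transcripts[hits[0].data[1]].gene_id

    def gene_span(self, gene_id: str) -> tuple[str, str, int, int]:
        row = self.genes.loc[self.genes["gene_id"] == gene_id].iloc[0]
        return row["chrom"], row["strand"], int(row["start"]), int(row["end"])

    # -- region bookkeeping -------------------------------------------------

    def region_lengths(self) -> dict[str, int]:
        """Total genomic nt per region class, including intron and intergenic."""
        lengths = dict.fromkeys(REGION_CLASSES, 0)
        annotated = 0
        for tx in self.transcripts.values():
            s, e = tx.span
            span_nt = e - s
            feat_nt = 0
            for region, ivs in tx.regions.items():
                nt = sum(ee - ss for ss, ee in ivs)
                lengths[region] += nt
                feat_nt += nt
            lengths["intron"] += span_nt - feat_nt
            annotated += span_nt
        lengths["intergenic"] = max(0, sum(self.chrom_lengths.values()) - annotated)
        return lengths

    def classify(self, chrom: str, strand: str, pos: int) -> str:
        """Region class of a single position (strand-aware for genic classes)."""
        if chrom not in self.chrom_lengths:
            raise KeyError(f"unknown chromosome {chrom!r}")
        ftree = self._feature_trees.get(chrom)
        classes = []
        if ftree is not None:
            classes = [iv.data[0] for iv in ftree.at(pos) if iv.data[1] == strand]
        if classes:
            return min(classes, key=_PRECEDENCE.__getitem__)
        stree = self._span_trees.get(chrom)
        if stree is not None and any(iv.data[0] == strand for iv in stree.at(pos)):
            return "intron"
        return "intergenic"


# ---------------------------------------------------------------------------
# Region statistics
# ---------------------------------------------------------------------------

def annotate_regions(sites: pd.DataFrame, annotation: GenomeAnnotation) -> pd.Series:
    """Region class per site; sites need chrom/strand/pos columns."""
    return pd.Series(
        [
            annotation.classify(row.chrom, row.strand, int(row.pos))
            for row in sites.itertuples()
        ],
        index=sites.index,
        name="region",
    )


def region_percentages(
    counts: Mapping[str, float], lengths: Mapping[str, float]
) -> dict[str, float]:
    """Length-normalized percentage of counts per region class.

    pct_r = 100 * (C_r / L_r) / sum_j (C_j / L_j).  Classes with zero counts
    contribute zero; classes with counts but zero length are rejected.
    """
    dens = {}
    for region, c in counts.items():
        if c == 0:
            dens[region] = 0.0
            continue
        L = lengths.get(region, 0)
        if L <= 0:
            raise ValueError(f"region {region!r} has counts but no annotated length")
        dens[region] = c / L
    total = sum(dens.values())
    if total == 0:
        raise ValueError("no counts in any region class")
    return {region: 100.0 * d / total for region, d in dens.items()}


def region_percentages_from_sites(
    sites: pd.DataFrame, annotation: GenomeAnnotation, weights: str | None = None
) -> dict[str, float]:
    """Convenience: classify sites, tally (optionally weighted) and normalize."""
    classes = annotate_regions(sites, annotation)
    w = sites[weights] if weights else pd.Series(1.0, index=sites.index)
    counts = w.groupby(classes).sum().to_dict()
    return region_percentages(counts, annotation.region_lengths())


# ---------------------------------------------------------------------------
# Metagene profiles
# ---------------------------------------------------------------------------

@dataclass
class MetageneProfile:
    mode: str
    bins: np.ndarray          # bin coordinate (scaled: 0..1 over the mRNA; unscaled: nt offset)
    density: np.ndarray
    region_edges: tuple[float, float] | None  # scaled: 5'UTR|CDS and CDS|3'UTR boundaries
    n_sites: int
    n_skipped: int


def metagene_profile(
    sites: pd.DataFrame,
    annotation: GenomeAnnotation,
    mode: str = "scaled",
    bins_per_region: tuple[int, int, int] = (33, 34, 33),
    window: int = 400,
) -> MetageneProfile:
    """Distribution of sites along a composite 5'UTR|CDS|3'UTR transcript.

    scaled mode: each site's position becomes a fraction of its region's
    length and is binned into that region's share of the axis, so transcripts
    of different lengths are comparable.  unscaled mode: nucleotide-offset
    histograms around the start- and stop-codon anchors (+-window nt), laid
    end to end.  Densities are normalized to sum to 1 over all bins.
    """
    if mode not in ("scaled", "unscaled"):
        raise ValueError(mode)
    n5, nc, n3 = bins_per_region
    n_bins = n5 + nc + n3 if mode == "scaled" else 2 * (2 * window + 1)
    hist = np.zeros(n_bins)
    n_used = n_skipped = 0

    for row in sites.itertuples():
        pos = int(row.pos)
        gene = annotation.assign_gene(row.chrom, row.strand, pos)
        tx = None
        if gene is not None:
            tid = annotation.genes.loc[annotation.genes["gene_id"] == gene, "transcript_id"].iloc[0]
            cand = annotation.transcripts[tid]
            if cand.is_coding:
                tx = cand
        if tx is None:
            n_skipped += 1
            continue
        if mode == "scaled":
            rc = tx.region_coord(pos)
            if rc is None:
                n_skipped += 1
                continue
            region, off, rlen = rc
            frac = (off + 0.5) / rlen
            base = {"five_prime_utr": 0, "CDS": n5, "three_prime_utr": n5 + nc}[region]
            width = {"five_prime_utr": n5, "CDS": nc, "three_prime_utr": n3}[region]
            hist[base + min(width - 1, int(frac * width))] += 1
            n_used += 1
        else:
            tc = tx.to_transcript_coord(pos)
            if tc is None:
                n_skipped += 1
                continue
            hit = False
            for panel, anchor in enumerate(("start", "stop")):
                off = tc - tx.anchor(anchor)
                if -window <= off <= window:
                    hist[panel * (2 * window + 1) + off + window] += 1
                    hit = True
            if hit:
                n_used += 1
            else:
                n_skipped += 1

    total = hist.sum()
    density = hist / total if total > 0 else hist
    if mode == "scaled":
        bins = (np.arange(n_bins) + 0.5) / n_bins
        edges = (n5 / n_bins, (n5 + nc) / n_bins)
    else:
        bins = np.concatenate([np.arange(-window, window + 1)] * 2).astype(float)
        edges = None
    return MetageneProfile(mode, bins, density, edges, n_used, n_skipped)
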