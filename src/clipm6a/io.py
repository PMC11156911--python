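"""Readers and writers for the plain-text formats the pipeline exchanges.

Conventions
-----------
* In memory everything is 0-based, half-open (BED-style).
* The GTF-lite annotation file is 1-based, closed (GTF convention); the
  conversion happens on read/write.
* Aligned reads travel as a TSV with one row per read; mismatches are encoded
  as a semicolon-separated ``pos:ref>alt`` list in genomic (reference-strand)
  terms.
"""

from __future__ import annotations

import os
from typing import Mapping

import pandas as pd

READS_COLUMNS = ["read_id", "sample", "chrom", "start", "end", "strand", "umi", "mismatches"]

GTF_COLUMNS = ["chrom", "source", "feature", "start", "end", "strand", "gene_id", "transcript_id"]

BED6_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def write_fasta(sequences: Mapping[str, str], path: str, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name in sequences:
            fh.write(f">{name}\n")
            seq = sequences[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path: str) -> dict[str, str]:
    """Load a FASTA file fully into memory as ``{name: sequence}``.

    For the genome sizes this package works with (a few Mb of synthetic
    sequence) an eager dict is simpler than an indexed handle.
    """
    sequences: dict[str, str] = {}
    name = None
    chunks: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                if name is not None:
                    sequences[name] = "".join(chunks)
                name = line[1:].split()[0]
                chunks = []
            elif line:
                chunks.append(line)
    if name is not None:
        sequences[name] = "".join(chunks)
    return sequences


# ---------------------------------------------------------------------------
# GTF-lite annotation
# ---------------------------------------------------------------------------

def write_gtf(features: pd.DataFrame, path: str) -> None:
    """Write an annotation table (0-based half-open) as 1-based closed GTF-lite."""
    out = features.loc[:, GTF_COLUMNS].copy()
    out["start"] = out["start"] + 1  # to 1-based closed
    out.to_csv(path, sep="\t", index=False, header=False)


def read_gtf(path: str) -> pd.DataFrame:
    feats = pd.read_csv(path, sep="\t", names=GTF_COLUMNS, dtype={"chrom": str})
    feats["start"] = feats["start"] - 1  # to 0-based half-open
    return feats


# ---------------------------------------------------------------------------
# Aligned reads
# ---------------------------------------------------------------------------

def encode_mismatches(mismatches: list[tuple[int, str, str]]) -> str:
    return ";".join(f"{pos}:{ref}>{alt}" for pos, ref, alt in mismatches)


def decode_mismatches(text: str) -> list[tuple[int, str, str]]:
    if not text or text != text:  # empty or NaN
        return []
    out = []
    for token in text.split(";"):
        pos, change = token.split(":")
        ref, alt = change.split(">")
        out.append((int(pos), ref, alt))
    return out


def write_reads(reads: pd.DataFrame, path: str) -> None:
    out = reads.loc[:, READS_COLUMNS].copy()
    if len(out) and not isinstance(out["mismatches"].iloc[0], str):
        out["mismatches"] = out["mismatches"].map(encode_mismatches)
    out.to_csv(path, sep="\t", index=False)


def read_reads(path: str) -> pd.DataFrame:
    reads = pd.read_csv(path, sep="\t", dtype={"chrom": str, "umi": str, "mismatches": str})
    reads["mismatches"] = reads["mismatches"].fillna("").map(decode_mismatches)
    return reads


# ---------------------------------------------------------------------------
# BED6 / bedGraph
# ---------------------------------------------------------------------------

def write_bed6(intervals: pd.DataFrame, path: str) -> None:
    intervals.loc[:, BED6_COLUMNS].to_csv(path, sep="\t", index=False, header=False)


def read_bed6(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", names=BED6_COLUMNS, dtype={"chrom": str, "name": str})


def write_bedgraph(sites: pd.DataFrame, path: str, value_col: str = "count") -> None:
    """Write single-nucleotide values as bedGraph (chrom, pos, pos+1, value)."""
    out = pd.DataFrame(
        {
            "chrom": sites["chrom"],
            "start": sites["pos"],
            "end": sites["pos"] + 1,
            "value": sites[value_col],
        }
    )
    out.to_csv(path, sep="\t", index=False, header=False)


# ---------------------------------------------------------------------------
# Count tables
# ---------------------------------------------------------------------------

def write_counts(counts: pd.DataFrame, path: str) -> None:
    counts.to_csv(path, sep="\t", index=True, index_label="feature")


def read_counts(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="feature")


def ensure_dir(path: str) -> str:
    os.makedirs(path, exist_ok=True)
    return path
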