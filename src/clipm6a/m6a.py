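"""Single-nucleotide m6A calling from antibody-CLIP reads.

Two evidence channels are combined:

* CIMS (crosslinking-induced mutation sites): per transcript-strand C
  position, the unique tag coverage k and the C->T transition count m are
  tallied; positions pass with m >= min_m, a transition frequency m/k inside
  [freq_min, freq_max], and (by default) a DRACH context whose adenosine —
  one nucleotide 5' of the transition C — becomes the reported coordinate.
* CITS (crosslinking-induced truncation sites): per gene, cDNA 5'-truncation
  events are tested against a uniform binomial null over the gene span; the
  reported coordinate is the inferred crosslinked residue one nucleotide 5'
  of the truncation.

Sites called by both channels at the same coordinate merge with method
"both".
"""

from __future__ import annotations

import logging
import re
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import GenomeAnnotation
from .clip import assign_crosslinks, pooled_site_counts

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: DRACH with the methylated A at position 3 (DNA alphabet, U == T)
_DRACH_RE = re.compile(r"[AGT][AG]AC[TAC]")

M6A_COLUMNS = ["chrom", "strand", "pos", "method", "k", "m", "freq", "p", "motif"]


def match_drach(sequence: str, pos: int, strand: str) -> tuple[bool, str]:
    """Whether the strand-oriented 5-mer with ``pos`` as its third base is DRACH.

    ``sequence`` is the reference-strand chromosome sequence; for - strand
    sites the window is reverse-complemented before matching.  Positions with
    less than 2 nt of flank return (False, "").
    """
    if pos < 2 or pos + 3 > len(sequence):
        logger.debug("position %d too close to the sequence end for a 5-mer", pos)
        return False, ""
    window = sequence[pos - 2 : pos + 3].upper()
    if strand == "-":
        window = window.translate(_COMPLEMENT)[::-1]
    return bool(_DRACH_RE.fullmatch(window)), window


# ---------------------------------------------------------------------------
# Mismatch tallies
# ---------------------------------------------------------------------------

def tally_mismatches(molecules: pd.DataFrame) -> pd.DataFrame:
    """Per-position unique-tag coverage k and C->T transition count m.

    Strand-aware: a transcript-strand C->T appears as a C>T mismatch record
    on + molecules and as G>A on - molecules (reference-strand terms).
    Tallies are produced for every position carrying >= 1 such transition;
    positions never mismatched have m = 0 and are not enumerated.
    Columns: chrom, strand, pos, k, m, freq.
    """
    cols = ["chrom", "strand", "pos", "k", "m", "freq"]
    if len(molecules) == 0:
        return pd.DataFrame(columns=cols)

    mm_rows = []
    for row in molecules.itertuples():
        want = ("C", "T") if row.strand == "+" else ("G", "A")
        for pos, ref, alt in row.mismatches:
            if (ref, alt) == want:
                mm_rows.append((row.chrom, row.strand, pos))
    if not mm_rows:
        return pd.DataFrame(columns=cols)
    mm = pd.DataFrame(mm_rows, columns=["chrom", "strand", "pos"])
    m_counts = mm.groupby(["chrom", "strand", "pos"]).size().rename("m").reset_index()

    # coverage: number of molecules of the same chrom/strand spanning pos
    out_frames = []
    for (chrom, strand), sub in m_counts.groupby(["chrom", "strand"]):
        mols = molecules[(molecules["chrom"] == chrom) & (molecules["strand"] == strand)]
        starts = np.sort(mols["start"].to_numpy(int))
        ends = np.sort(mols["end"].to_numpy(int))
        pos = sub["pos"].to_numpy(int)
        k = np.searchsorted(starts, pos, side="right") - np.searchsorted(ends, pos, side="right")
        out_frames.append(sub.assign(k=k))
    out = pd.concat(out_frames, ignore_index=True)
    out["freq"] = out["m"] / out["k"]
    return out.sort_values(["chrom", "strand", "pos"]).reset_index(drop=True).loc[:, cols]


# ---------------------------------------------------------------------------
# CIMS
# ---------------------------------------------------------------------------

def call_cims(
    tallies: pd.DataFrame,
    genome: Mapping[str, str],
    min_m: int = 2,
    freq_min: float = 0.01,
    freq_max: float = 0.5,
    require_drach: bool = True,
) -> pd.DataFrame:
    """m6A sites from C->T tallies: m >= min_m, freq band, DRACH context.

    The transition C is DRACH position 4; the reported site is the adenosine
    one nucleotide 5' of it (pos - 1 on +, pos + 1 on -).  ``min_m`` presets
    2 (permissive) and 5 (strict) mirror common practice.
    """
    if min_m < 1:
        raise ValueError("min_m must be >= 1")
    if not 0 <= freq_min <= freq_max:
        raise ValueError("frequency bounds out of order")
    rows = []
    for row in tallies.itertuples():
        if row.m < min_m:
            continue
        freq = row.m / row.k
        if not (freq_min <= freq <= freq_max):
            continue
        a_pos = row.pos - 1 if row.strand == "+" else row.pos + 1
        ok, motif = match_drach(genome[row.chrom], a_pos, row.strand)
        if require_drach and not ok:
            continue
        rows.append({"chrom": row.chrom, "strand": row.strand, "pos": int(a_pos),
                     "method": "CIMS", "k": int(row.k), "m": int(row.m),
                     "freq": freq, "p": np.nan, "motif": motif if ok else ""})
    out = pd.DataFrame(rows, columns=M6A_COLUMNS)
    return out.sort_values(["chrom", "strand", "pos"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# CITS
# ---------------------------------------------------------------------------

def call_cits(
    molecules: pd.DataFrame,
    annotation: GenomeAnnotation,
    p_threshold: float = 0.05,
) -> pd.DataFrame:
    """m6A sites from truncation pileups against a uniform within-gene null.

    Per gene with N truncation events over a span of L nt, a position with t
    events gets p = P(X >= t), X ~ Binomial(N, 1/L); positions with
    p < ``p_threshold`` are reported at the inferred crosslinked residue
    (truncation position - 1, strand-aware), which the crosslink-assignment
    convention already produces.
    """
    events = pooled_site_counts(assign_crosslinks(molecules))
    if len(events) == 0:
        return pd.DataFrame(columns=M6A_COLUMNS)
    genes = [
        annotation.assign_gene(row.chrom, row.strand, int(row.pos))
        for row in events.itertuples()
    ]
    events = events.assign(gene_id=genes).dropna(subset=["gene_id"])
    rows = []
    for gene_id, sub in events.groupby("gene_id", sort=True):
        chrom, strand, g0, g1 = annotation.gene_span(str(gene_id))
        length = g1 - g0
        if length <= 0:
            raise ValueError(f"gene {gene_id} has zero length")
        total = int(sub["count"].sum())
        t = sub["count"].to_numpy(int)
        p = stats.binom.sf(t - 1, total, 1.0 / length)
        called = sub.assign(p=p)
        called = called[called["p"] < p_threshold]
        for row in called.itertuples():
            rows.append({"chrom": row.chrom, "strand": row.strand, "pos": int(row.pos),
                         "method": "CITS", "k": np.nan, "m": np.nan, "freq": np.nan,
                         "p": float(row.p), "motif": ""})
    out = pd.DataFrame(rows, columns=M6A_COLUMNS)
    return out.sort_values(["chrom", "strand", "pos"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# Merge
# ---------------------------------------------------------------------------

def merge_m6a_sites(cims: pd.DataFrame, cits: pd.DataFrame) -> pd.DataFrame:
    """Union of CIMS and CITS calls; identical coordinates merge as "both"."""
    both = pd.concat([cims, cits], ignore_index=True)
    if len(both) == 0:
        return pd.DataFrame(columns=M6A_COLUMNS)
    rows = []
    for (chrom, strand, pos), sub in both.groupby(["chrom", "strand", "pos"], sort=True):
        methods = set(sub["method"])
        method = "both" if len(methods) > 1 else methods.pop()
        cims_row = sub[sub["method"] == "CIMS"]
        cits_row = sub[sub["method"] == "CITS"]
        rows.append({
            "chrom": chrom, "strand": strand, "pos": int(pos), "method": method,
            "k": float(cims_row["k"].iloc[0]) if len(cims_row) else np.nan,
            "m": float(cims_row["m"].iloc[0]) if len(cims_row) else np.nan,
            "freq": float(cims_row["freq"].iloc[0]) if len(cims_row) else np.nan,
            "p": float(cits_row["p"].iloc[0]) if len(cits_row) else np.nan,
            "motif": cims_row["motif"].iloc[0] if len(cims_row) else "",
        })
    out = pd.DataFrame(rows, columns=M6A_COLUMNS)
    return out.sort_values(["chrom", "strand", "pos"]).reset_index(drop=True)


def m6a_bed(sites: pd.DataFrame) -> pd.DataFrame:
    """BED6 view: name = method; score = round(1000*freq) for CIMS-backed
    sites, capped -10*log10(p) for CITS-only sites."""
    score = np.where(
        sites["freq"].notna(),
        np.round(1000 * sites["freq"].fillna(0)),
        np.minimum(1000, np.round(-10 * np.log10(np.maximum(sites["p"].fillna(1.0), 1e-300)))),
    ).astype(int)
    return pd.DataFrame({
        "chrom": sites["chrom"],
        "start": sites["pos"],
        "end": sites["pos"] + 1,
        "name": sites["method"],
        "score": score,
        "strand": sites["strand"],
    })
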