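"""Synthetic genomes, truth sites, CLIP/miCLIP reads and quantitative tables.

The generator emulates the data-generating process the downstream analysis
assumes:

* protein-coding transcript models (5'UTR | CDS | 3'UTR) and ncRNA genes laid
  out with intergenic spacers on one synthetic chromosome, alternating strand;
* m6A sites realized as adenosines of planted DRACH 5-mers, placed with a
  Gaussian bias around the stop codon, and present in the second condition
  more often than in the first (methylation gain during differentiation);
* protein binding sites biased to 3'UTRs, a configurable fraction of which
  co-locate with m6A sites (methylation-driven target selection);
* truncation-type reads: a cDNA starts one nucleotide 3' of its crosslink,
  carries a random UMI, and is re-observed as PCR duplicates;
* miCLIP reads additionally carry C->T transitions at the C immediately 3' of
  a methylated A (transcript strand) plus a uniform background mismatch rate;
* gene-level expression counts (negative binomial) and knockdown proteomics
  log2 ratios whose expected effect scales with the per-gene number of
  binding-site/m6A co-occurrences.

Everything is driven by a single integer seed; identical configurations give
bit-identical outputs.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from . import io as cio
from .annotation import GenomeAnnotation
from .integrate import peak_class, CLASS_RANK

_BASES = np.array(list("ACGT"))
_COMPLEMENT = str.maketrans("ACGT", "TGCA")
DRACH_RE = re.compile(r"(?=([AGT][AG]AC[TAC]))")
PLANT_MOTIF = "GGACT"


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class SimConfig:
    """Study-condition parameters of the synthetic dataset."""

    seed: int = 0
    n_genes: int = 100
    utr5_mean: int = 200
    cds_mean: int = 1500
    utr3_mean: int = 800
    n_ncrna_genes: int = 10
    ncrna_mean: int = 600
    intergenic_spacer: int = 300
    intron_mean: int = 0            # >0 turns on one CDS intron in half the genes
    drach_methylation_fraction: float = 0.10
    stop_proximal_sd: float = 100.0
    neuron_methylation_gain: float = 1.5
    binding_sites_per_gene_mean: float = 5.0
    binding_site_heterogeneity: float = 1.0   # lognormal sigma of the per-gene rate
    utr3_weight: float = 5.0
    m6a_colocation_prob: float = 0.5
    term_base_rate: float = 0.1               # functional-term membership at class 0
    term_rate_per_class: float = 0.15         # added membership probability per class rank
    reads_per_site_mean: float = 30.0
    read_length: int = 50
    ct_transition_rate: float = 0.15
    truncation_rate: float = 0.7
    background_mismatch_rate: float = 0.001
    pcr_duplication_ratio: float = 2.0
    umi_length: int = 7
    n_replicates: int = 3
    expression_dispersion: float = 0.05
    kd_effect_per_class: float = 0.4
    proteomics_noise_sd: float = 0.3
    condition_labels: tuple[str, str] = ("NPC", "neuron")

    def validate(self) -> None:
        probs = {
            "drach_methylation_fraction": self.drach_methylation_fraction,
            "m6a_colocation_prob": self.m6a_colocation_prob,
            "ct_transition_rate": self.ct_transition_rate,
            "truncation_rate": self.truncation_rate,
            "background_mismatch_rate": self.background_mismatch_rate,
        }
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        for name in ("n_genes", "utr5_mean", "cds_mean", "utr3_mean", "ncrna_mean",
                     "intergenic_spacer", "read_length", "umi_length", "n_replicates"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_ncrna_genes < 0:
            raise ValueError("n_ncrna_genes must be >= 0")
        if self.pcr_duplication_ratio < 1.0:
            raise ValueError("pcr_duplication_ratio must be >= 1")
        if self.neuron_methylation_gain < 1.0:
            raise ValueError("neuron_methylation_gain must be >= 1")
        eff = self.drach_methylation_fraction * self.neuron_methylation_gain
        if eff > 1.0:
            raise ValueError(
                "requested methylated sites exceed available DRACH positions "
                f"(effective fraction {eff:.3f} > 1)"
            )


@dataclass
class TruthSet:
    """Ground truth emitted alongside the genome, for recovery testing."""

    m6a_sites: pd.DataFrame          # gene_id, chrom, strand, pos, in_<cond> flags
    binding_sites: pd.DataFrame      # gene_id, chrom, strand, pos, affinity, is_m6a_colocated
    gene_expression_means: pd.DataFrame  # index gene_id, one column per condition
    protein_true_effect: pd.DataFrame    # gene_id, n_coloc, class_label, expected_log2fc, in_term


# ---------------------------------------------------------------------------
# Genome
# ---------------------------------------------------------------------------

def _draw_length(rng: np.random.Generator, mean: int, floor: int = 30) -> int:
    return max(floor, int(round(rng.normal(mean, 0.15 * mean))))


def simulate_genome(config: SimConfig) -> tuple[dict[str, str], GenomeAnnotation, TruthSet]:
    """Build the synthetic chromosome, annotation and truth set."""
    config.validate()
    rng = np.random.default_rng([config.seed, 1])
    chrom = "chrS"

    # -- gene layout --------------------------------------------------------
    gene_plan = [("coding", f"G{i + 1:04d}") for i in range(config.n_genes)]
    gene_plan += [("ncRNA", f"NC{i + 1:03d}") for i in range(config.n_ncrna_genes)]
    order = rng.permutation(len(gene_plan))
    gene_plan = [gene_plan[i] for i in order]

    features = []
    cursor = config.intergenic_spacer
    gene_meta: dict[str, dict] = {}
    for idx, (kind, gid) in enumerate(gene_plan):
        strand = "+" if idx % 2 == 0 else "-"
        tid = gid + ".t1"
        if kind == "coding":
            l5 = _draw_length(rng, config.utr5_mean)
            lc = _draw_length(rng, config.cds_mean, floor=300)
            l3 = _draw_length(rng, config.utr3_mean)
            intron = 0
            if config.intron_mean > 0 and rng.random() < 0.5:
                intron = _draw_length(rng, config.intron_mean, floor=60)
            span = l5 + lc + l3 + intron
            g0 = cursor
            # genomic order of regions depends on strand
            if strand == "+":
                r5 = (g0, g0 + l5)
                if intron:
                    half = lc // 2
                    cds = [(g0 + l5, g0 + l5 + half),
                           (g0 + l5 + half + intron, g0 + l5 + lc + intron)]
                else:
                    cds = [(g0 + l5, g0 + l5 + lc)]
                r3 = (g0 + l5 + lc + intron, g0 + span)
            else:
                r3 = (g0, g0 + l3)
                if intron:
                    half = lc // 2
                    cds = [(g0 + l3, g0 + l3 + half),
                           (g0 + l3 + half + intron, g0 + l3 + lc + intron)]
                else:
                    cds = [(g0 + l3, g0 + l3 + lc)]
                r5 = (g0 + l3 + lc + intron, g0 + span)
            features.append((chrom, "sim", "five_prime_utr", r5[0], r5[1], strand, gid, tid))
            for s, e in cds:
                features.append((chrom, "sim", "CDS", s, e, strand, gid, tid))
            features.append((chrom, "sim", "three_prime_utr", r3[0], r3[1], strand, gid, tid))
            gene_meta[gid] = {"kind": "coding", "strand": strand, "start": g0, "end": g0 + span}
        else:
            ln = _draw_length(rng, config.ncrna_mean, floor=100)
            span = ln
            features.append((chrom, "sim", "ncRNA", cursor, cursor + ln, strand, gid, tid))
            gene_meta[gid] = {"kind": "ncRNA", "strand": strand, "start": cursor, "end": cursor + ln}
        cursor += span + config.intergenic_spacer

    genome_len = cursor
    seq = _BASES[rng.integers(0, 4, genome_len)]

    feat_df = pd.DataFrame(features, columns=cio.GTF_COLUMNS)

    # -- m6A truth: plant DRACH motifs around the stop codon ----------------
    cond_a, cond_b = config.condition_labels
    m6a_rows = []
    for gid, meta in gene_meta.items():
        if meta["kind"] != "coding":
            continue
        strand, g0, g1 = meta["strand"], meta["start"], meta["end"]
        gene_seq = "".join(seq[g0:g1])
        tx_seq = gene_seq if strand == "+" else revcomp(gene_seq)
        n_drach = len(DRACH_RE.findall(tx_seq))
        eff = config.drach_methylation_fraction * config.neuron_methylation_gain
        n_meth = rng.binomial(n_drach, eff) if n_drach else 0
        if n_meth == 0:
            continue
        # stop codon position in transcript coordinates
        sub = feat_df[(feat_df["gene_id"] == gid)]
        l5 = int((sub.loc[sub["feature"] == "five_prime_utr", "end"]
                  - sub.loc[sub["feature"] == "five_prime_utr", "start"]).sum())
        lc = int((sub.loc[sub["feature"] == "CDS", "end"]
                  - sub.loc[sub["feature"] == "CDS", "start"]).sum())
        tx_len = g1 - g0  # genomic span (introns off by default)
        stop_t = l5 + lc - 1
        used: list[int] = []
        for _ in range(n_meth):
            placed = False
            for _attempt in range(100):
                t = int(round(rng.normal(stop_t, config.stop_proximal_sd)))
                t = min(max(t, 2), tx_len - 3)
                if all(abs(t - u) >= 5 for u in used):
                    placed = True
                    break
            if not placed:
                raise RuntimeError(
                    f"could not place {n_meth} methylated DRACH sites in gene {gid}; "
                    "lower drach_methylation_fraction or raise stop_proximal_sd"
                )
            used.append(t)
            # plant motif so the A (motif position 3) sits at transcript coord t
            if strand == "+":
                p = g0 + t
                seq[p - 2 : p + 3] = list(PLANT_MOTIF)
            else:
                p = g1 - 1 - t
                seq[p - 2 : p + 3] = list(revcomp(PLANT_MOTIF))
            in_a = bool(rng.random() < 1.0 / config.neuron_methylation_gain)
            m6a_rows.append({"gene_id": gid, "chrom": chrom, "strand": strand, "pos": p,
                             f"in_{cond_a}": in_a, f"in_{cond_b}": True})

    m6a_cols = ["gene_id", "chrom", "strand", "pos", f"in_{cond_a}", f"in_{cond_b}"]
    m6a_df = pd.DataFrame(m6a_rows, columns=m6a_cols)
    if len(m6a_df):
        m6a_df = m6a_df.sort_values(["pos"]).reset_index(drop=True)

    # -- binding-site truth -------------------------------------------------
    bind_rows = []
    for gid, meta in gene_meta.items():
        if meta["kind"] != "coding":
            continue
        strand, g0, g1 = meta["strand"], meta["start"], meta["end"]
        gene_m6a = m6a_df[m6a_df["gene_id"] == gid] if len(m6a_df) else m6a_df
        sub = feat_df[feat_df["gene_id"] == gid]
        utr3 = sub[sub["feature"] == "three_prime_utr"].iloc[0]
        # heavy-tailed per-gene site numbers: lognormal rate x Poisson
        het = config.binding_site_heterogeneity
        rate = config.binding_sites_per_gene_mean * rng.lognormal(-het**2 / 2, het)
        n_sites = rng.poisson(rate)
        unused_m6a = list(gene_m6a["pos"]) if len(gene_m6a) else []
        for _ in range(n_sites):
            coloc = len(unused_m6a) > 0 and rng.random() < config.m6a_colocation_prob
            if coloc:
                pos = int(unused_m6a.pop(rng.integers(0, len(unused_m6a))))
            else:
                # per-nt placement weight: 3'UTR vs rest of the transcript
                l3 = int(utr3["end"] - utr3["start"])
                rest = (g1 - g0) - l3
                w3 = config.utr3_weight * l3
                if rng.random() < w3 / (w3 + rest):
                    pos = int(rng.integers(utr3["start"], utr3["end"]))
                else:
                    pos = int(rng.integers(g0, g1))
                    while utr3["start"] <= pos < utr3["end"]:
                        pos = int(rng.integers(g0, g1))
            affinity = float(rng.lognormal(0.0, 0.5))
            bind_rows.append({"gene_id": gid, "chrom": chrom, "strand": strand,
                              "pos": pos, "affinity": affinity, "is_m6a_colocated": coloc})
    bind_df = pd.DataFrame(
        bind_rows,
        columns=["gene_id", "chrom", "strand", "pos", "affinity", "is_m6a_colocated"],
    )

    # -- expression means and proteomics truth ------------------------------
    coding = [g for g, m in gene_meta.items() if m["kind"] == "coding"]
    base = rng.lognormal(np.log(200.0), 0.6, size=len(coding))
    expr = pd.DataFrame({cond_a: base, cond_b: base}, index=pd.Index(coding, name="gene_id"))

    n_coloc = (
        bind_df[bind_df["is_m6a_colocated"]].groupby("gene_id").size()
        if len(bind_df) else pd.Series(dtype=int)
    )
    effect_rows = []
    for gid in coding:
        n = int(n_coloc.get(gid, 0))
        cls = peak_class(n)
        rank = CLASS_RANK[cls]
        # functional-term membership enriched with the m6A-peak class
        p_term = min(1.0, config.term_base_rate + config.term_rate_per_class * rank)
        effect_rows.append({"gene_id": gid, "n_coloc": n, "class_label": cls,
                            "expected_log2fc": -config.kd_effect_per_class * rank,
                            "in_term": bool(rng.random() < p_term)})
    effect_df = pd.DataFrame(effect_rows)

    truth = TruthSet(m6a_df, bind_df, expr, effect_df)
    genome = {chrom: "".join(seq)}
    annotation = GenomeAnnotation(feat_df, {chrom: genome_len})
    return genome, annotation, truth


# ---------------------------------------------------------------------------
# Reads
# ---------------------------------------------------------------------------

def _umis(rng: np.random.Generator, n: int, length: int) -> list[str]:
    codes = rng.integers(0, 4, size=(n, length))
    return ["".join(row) for row in _BASES[codes]]


def _expr_scale(truth: TruthSet, condition: str) -> pd.Series:
    means = truth.gene_expression_means[condition]
    return means / 200.0  # relative to the configured baseline mean


def _pcr_expand(
    rng: np.random.Generator,
    rows: list[dict],
    ratio: float,
    counter: list[int],
) -> list[dict]:
    """Replicate unique molecules into PCR-duplicated read records."""
    out = []
    dups = 1 + rng.poisson(ratio - 1.0, size=len(rows))
    for row, d in zip(rows, dups):
        for _ in range(int(d)):
            rec = dict(row)
            rec["read_id"] = f"r{counter[0]:08d}"
            counter[0] += 1
            out.append(rec)
    return out


def simulate_clip_reads(
    genome: Mapping[str, str],
    truth: TruthSet,
    config: SimConfig,
) -> pd.DataFrame:
    """Protein-CLIP reads: truncation at binding-site crosslinks, no mismatches.

    Each unique molecule starts one nucleotide 3' of its crosslink position
    (strand-aware); molecule multiplicity per site is Poisson with mean
    proportional to expression x affinity.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 2])
    counter = [0]
    records: list[dict] = []
    L = config.read_length
    for cond in config.condition_labels:
        scale = _expr_scale(truth, cond)
        for rep in range(1, config.n_replicates + 1):
            sample = f"{cond}_rep{rep}"
            mol_rows: list[dict] = []
            for site in truth.binding_sites.itertuples():
                active = True
                if site.is_m6a_colocated:
                    # a methylation-dependent site binds only where the m6A exists
                    m = truth.m6a_sites
                    hit = m[(m["gene_id"] == site.gene_id) & (m["pos"] == site.pos)]
                    active = bool(len(hit)) and bool(hit[f"in_{cond}"].iloc[0])
                if not active:
                    continue
                lam = config.reads_per_site_mean * site.affinity * float(scale[site.gene_id])
                n_mol = rng.poisson(lam)
                if n_mol == 0:
                    continue
                x = site.pos
                if site.strand == "+":
                    start, end = x + 1, x + 1 + L
                else:
                    start, end = x - L, x
                if start < 0:
                    continue
                for umi in _umis(rng, n_mol, config.umi_length):
                    mol_rows.append({"sample": sample, "chrom": site.chrom,
                                     "start": start, "end": end, "strand": site.strand,
                                     "umi": umi, "mismatches": []})
            records.extend(_pcr_expand(rng, mol_rows, config.pcr_duplication_ratio, counter))
    reads = pd.DataFrame(records, columns=[c for c in cio.READS_COLUMNS])
    return reads.loc[:, cio.READS_COLUMNS]


def simulate_miclip_reads(
    genome: Mapping[str, str],
    truth: TruthSet,
    config: SimConfig,
) -> pd.DataFrame:
    """Antibody-CLIP reads around m6A sites with C->T transitions.

    Reads covering a methylated A carry a C->T at the immediately 3' C on the
    transcript strand with probability ``ct_transition_rate`` (recorded in
    reference-strand terms: C>T on +, G>A on -) and truncate at the site with
    probability ``truncation_rate``.  All covered transcript-strand C
    positions additionally mutate at ``background_mismatch_rate``.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 3])
    counter = [0]
    records: list[dict] = []
    L = config.read_length
    for cond in config.condition_labels:
        scale = _expr_scale(truth, cond)
        present = truth.m6a_sites[truth.m6a_sites[f"in_{cond}"]] if len(truth.m6a_sites) else truth.m6a_sites
        for rep in range(1, config.n_replicates + 1):
            sample = f"{cond}_rep{rep}"
            mol_rows: list[dict] = []
            for site in present.itertuples():
                lam = config.reads_per_site_mean * float(scale[site.gene_id])
                n_mol = rng.poisson(lam)
                if n_mol == 0:
                    continue
                p = site.pos
                chrom_seq = genome[site.chrom]
                trunc = rng.random(n_mol) < config.truncation_rate
                if site.strand == "+":
                    starts = np.where(
                        trunc,
                        p + 1,
                        rng.integers(max(0, p - L + 2), p, size=n_mol),
                    )
                    ends = starts + L
                    signal_c = p + 1
                else:
                    ends = np.where(
                        trunc,
                        p,
                        rng.integers(p + 2, p + L, size=n_mol),
                    )
                    starts = ends - L
                    signal_c = p - 1
                # transcript-strand C positions in the local window (reference C
                # on +, reference G on -), excluding the signal C itself
                w0, w1 = int(starts.min()), int(ends.max())
                ref_base = "C" if site.strand == "+" else "G"
                alt_base = "T" if site.strand == "+" else "A"
                cand = np.array(
                    [q for q in range(max(0, w0), min(len(chrom_seq), w1))
                     if chrom_seq[q] == ref_base and q != signal_c],
                    dtype=int,
                )
                covered = (cand[None, :] >= starts[:, None]) & (cand[None, :] < ends[:, None]) \
                    if len(cand) else np.zeros((n_mol, 0), dtype=bool)
                bg_hits = covered & (rng.random(covered.shape) < config.background_mismatch_rate)
                sig_hits = rng.random(n_mol) < config.ct_transition_rate
                umis = _umis(rng, n_mol, config.umi_length)
                for i in range(n_mol):
                    mm = [(int(q), ref_base, alt_base) for q in cand[bg_hits[i]]]
                    if sig_hits[i] and starts[i] <= signal_c < ends[i]:
                        mm.append((int(signal_c), ref_base, alt_base))
                    mm.sort()
                    mol_rows.append({"sample": sample, "chrom": site.chrom,
                                     "start": int(starts[i]), "end": int(ends[i]),
                                     "strand": site.strand, "umi": umis[i],
                                     "mismatches": mm})
            records.extend(_pcr_expand(rng, mol_rows, config.pcr_duplication_ratio, counter))
    reads = pd.DataFrame(records, columns=[c for c in cio.READS_COLUMNS])
    return reads.loc[:, cio.READS_COLUMNS]


# ---------------------------------------------------------------------------
# Expression counts and proteomics ratios
# ---------------------------------------------------------------------------

def _nb_draw(rng: np.random.Generator, mean: np.ndarray, alpha: float) -> np.ndarray:
    if alpha <= 0:
        return rng.poisson(mean)
    r = 1.0 / alpha
    return rng.negative_binomial(r, r / (r + mean))


def simulate_quant(
    truth: TruthSet, config: SimConfig
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Gene-level expression counts and knockdown proteomics log2 ratios.

    Returns (expression counts genes x samples, sample sheet, proteomics
    ratios genes x clones).  The expected knockdown log2 fold change of a
    gene's protein is -delta x w(class) with w linear in the class rank of the
    gene's binding-site/m6A co-occurrence count.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 4])
    genes = truth.gene_expression_means.index
    cols, col_meta = {}, []
    for cond in config.condition_labels:
        mu = truth.gene_expression_means[cond].to_numpy(float)
        for rep in range(1, config.n_replicates + 1):
            name = f"{cond}_rna{rep}"
            cols[name] = _nb_draw(rng, mu, config.expression_dispersion)
            col_meta.append({"sample": name, "condition": cond})
    counts = pd.DataFrame(cols, index=genes)
    sample_sheet = pd.DataFrame(col_meta)

    effect = truth.protein_true_effect.set_index("gene_id")["expected_log2fc"].reindex(genes)
    ratios = {
        f"clone{rep}": effect.to_numpy(float)
        + rng.normal(0.0, config.proteomics_noise_sd, size=len(genes))
        for rep in range(1, config.n_replicates + 1)
    }
    proteomics = pd.DataFrame(ratios, index=genes)
    return counts, sample_sheet, proteomics


# ---------------------------------------------------------------------------
# Differential-binding calibration scenarios
# ---------------------------------------------------------------------------

def simulate_binding_experiment(
    n_peaks: int = 2000,
    n_confounded: int = 0,
    expression_fold: float = 2.0,
    n_replicates: int = 3,
    binding_mean: float = 50.0,
    binding_dispersion: float = 0.05,
    rna_mean: float = 500.0,
    rna_dispersion: float = 0.005,
    biological_sd: float = 0.5,
    seed: int = 0,
) -> dict:
    """Peak-count scenario for the differential-binding machinery.

    Each biological replicate (clone) carries its own per-gene expression
    level (log2-normal around the gene mean, sd ``biological_sd``), measured
    twice: by RNA counts (technical dispersion ``rna_dispersion``) and by
    binding counts proportional to expression (dispersion
    ``binding_dispersion``).  The last ``n_confounded`` peaks sit on genes
    whose expression is multiplied by ``expression_fold`` in condition B
    while binding per transcript is unchanged — the classic
    expression-driven confound an expression covariate should absorb.  With
    ``n_confounded=0`` the experiment is a pure null.

    Returns a dict with peak counts, conditions, peak->gene map, RNA counts
    and conditions, and the confounded gene ids.
    """
    rng = np.random.default_rng([seed, 5])
    genes = [f"g{i:05d}" for i in range(n_peaks)]
    n = 2 * n_replicates
    clip_samples = [f"clip_{c}{r}" for c in "AB" for r in range(1, n_replicates + 1)]
    rna_samples = [f"rna_{c}{r}" for c in "AB" for r in range(1, n_replicates + 1)]
    cond = np.array([0.0] * n_replicates + [1.0] * n_replicates)
    conditions = pd.Series(["A"] * n_replicates + ["B"] * n_replicates, index=clip_samples)
    rna_conditions = pd.Series(["A"] * n_replicates + ["B"] * n_replicates, index=rna_samples)

    log2_expr = rng.normal(0.0, biological_sd, size=(n_peaks, n))
    confounded = genes[n_peaks - n_confounded :] if n_confounded else []
    if n_confounded:
        log2_expr[n_peaks - n_confounded :, :] += np.log2(expression_fold) * cond
    expr_level = 2.0 ** log2_expr
    peak_counts = pd.DataFrame(
        _nb_draw(rng, binding_mean * expr_level, binding_dispersion),
        index=genes, columns=clip_samples,
    )
    rna_counts = pd.DataFrame(
        _nb_draw(rng, rna_mean * expr_level, rna_dispersion),
        index=genes, columns=rna_samples,
    )
    return {
        "peak_counts": peak_counts,
        "conditions": conditions,
        "peak_genes": pd.Series(genes, index=genes),
        "rna_counts": rna_counts,
        "rna_conditions": rna_conditions,
        "confounded_genes": confounded,
    }


# ---------------------------------------------------------------------------
# Whole-dataset convenience
# ---------------------------------------------------------------------------

def write_dataset(outdir: str, config: SimConfig) -> None:
    """Generate everything and write the on-disk dataset under ``outdir``."""
    cio.ensure_dir(outdir)
    genome, annotation, truth = simulate_genome(config)
    cio.write_fasta(genome, f"{outdir}/genome.fa")
    cio.write_gtf(annotation.features, f"{outdir}/annotation.gtf")
    clip = simulate_clip_reads(genome, truth, config)
    miclip = simulate_miclip_reads(genome, truth, config)
    cio.write_reads(clip, f"{outdir}/clip_reads.tsv")
    cio.write_reads(miclip, f"{outdir}/miclip_reads.tsv")
    counts, sample_sheet, proteomics = simulate_quant(truth, config)
    cio.write_counts(counts, f"{outdir}/expression_counts.tsv")
    sample_sheet.to_csv(f"{outdir}/expression_samples.tsv", sep="\t", index=False)
    cio.write_counts(proteomics, f"{outdir}/proteomics_ratios.tsv")
    # truth as BED6 for the two site types
    if len(truth.m6a_sites):
        bed = pd.DataFrame({
            "chrom": truth.m6a_sites["chrom"],
            "start": truth.m6a_sites["pos"],
            "end": truth.m6a_sites["pos"] + 1,
            "name": truth.m6a_sites["gene_id"],
            "score": 0,
            "strand": truth.m6a_sites["strand"],
        })
        cio.write_bed6(bed, f"{outdir}/truth_m6a.bed")
    if len(truth.binding_sites):
        bed = pd.DataFrame({
            "chrom": truth.binding_sites["chrom"],
            "start": truth.binding_sites["pos"],
            "end": truth.binding_sites["pos"] + 1,
            "name": truth.binding_sites["gene_id"],
            "score": truth.binding_sites["affinity"].round(3),
            "strand": truth.binding_sites["strand"],
        })
        cio.write_bed6(bed, f"{outdir}/truth_binding.bed")
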