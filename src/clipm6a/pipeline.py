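"""End-to-end orchestration: from a simulated study to integrated statistics.

Runs the full analysis the package implements on one synthetic dataset:
CLIP reads -> unique molecules -> crosslink sites -> significant sites ->
peaks; miCLIP reads -> mismatch tallies -> DRACH-filtered CIMS m6A sites;
superimposition of the two; knockdown proteomics -> z-scored differential
table; and the peak-class-stratified ecdf/KS analysis plus nested-filter
percentages.

The m6A set used for superimposition is the CIMS set: at the raw truncation
p-value thresholds the CITS channel is deliberately sensitive and would
dilute the intersection with low-precision calls (see docs).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .annotation import GenomeAnnotation
from .clip import assign_crosslinks, call_significant_sites, cluster_peaks, collapse_duplicates
from .integrate import (
    CLASS_ORDER,
    StratTestResult,
    build_integration,
    intersect_peaks_m6a,
    nested_filter_percentages,
    peak_class,
    proteomics_differential,
    stratify_and_test,
)
from .m6a import call_cims, tally_mismatches
from .simulate import (
    SimConfig,
    TruthSet,
    simulate_clip_reads,
    simulate_genome,
    simulate_miclip_reads,
    simulate_quant,
)


def run_full_analysis(config: SimConfig) -> dict:
    """Simulate one study under ``config`` and run every analysis stage.

    Returns a dict with the intermediate products (annotation, truth, peaks,
    m6A calls, integration table) and the headline statistics (per-class
    mean protein log2FC, KS results vs the 0-class, nested-filter
    percentages, per-sample duplication ratios).
    """
    genome, annotation, truth = simulate_genome(config)

    clip_reads = simulate_clip_reads(genome, truth, config)
    molecules, dup_ratios = collapse_duplicates(clip_reads)
    sites = assign_crosslinks(molecules)
    significant = call_significant_sites(sites, annotation, seed=config.seed)
    peaks = cluster_peaks(significant)

    miclip_reads = simulate_miclip_reads(genome, truth, config)
    mi_molecules, _ = collapse_duplicates(miclip_reads)
    tallies = tally_mismatches(mi_molecules)
    m6a_sites = call_cims(tallies, genome)

    peaks, per_gene_m6a = intersect_peaks_m6a(peaks, m6a_sites)
    per_gene_peaks = peaks.groupby("gene_id").size()

    expr_counts, expr_samples, proteomics = simulate_quant(truth, config)
    protein_table = proteomics_differential(proteomics)
    integration = build_integration(per_gene_peaks, per_gene_m6a, protein_table["log2fc"])
    ecdfs, ks_results = stratify_and_test(integration, count_field="n_m6a_peaks")

    class_means = (
        integration.groupby("class_m6a_peaks")["protein_log2fc"].mean()
        .reindex(CLASS_ORDER)
    )
    class_sizes = (
        integration.groupby("class_m6a_peaks").size().reindex(CLASS_ORDER, fill_value=0)
    )

    # nested filters: downregulated proteins, then bound, then m6A-bound
    term = set(truth.protein_true_effect.loc[truth.protein_true_effect["in_term"], "gene_id"])
    down = set(protein_table.index[protein_table["significant"]
                                   & (protein_table["log2fc"] < 0)])
    bound = set(per_gene_peaks.index[per_gene_peaks > 0])
    m6a_bound = set(per_gene_m6a.index[per_gene_m6a > 0])
    nested = nested_filter_percentages(
        {"down": down, "down_bound": down & bound, "down_m6a_bound": down & m6a_bound},
        term,
    )

    return {
        "config": config,
        "annotation": annotation,
        "truth": truth,
        "dup_ratios": dup_ratios,
        "crosslink_sites": sites,
        "significant_sites": significant,
        "peaks": peaks,
        "m6a_sites": m6a_sites,
        "per_gene_peaks": per_gene_peaks,
        "per_gene_m6a": per_gene_m6a,
        "protein_table": protein_table,
        "integration": integration,
        "ecdfs": ecdfs,
        "ks_results": ks_results,
        "class_means": class_means,
        "class_sizes": class_sizes,
        "nested": nested,
    }


def m6a_recovery(truth: TruthSet, called: pd.DataFrame) -> dict[str, float]:
    """Recall and precision of called m6A sites against the truth set."""
    truth_keys = set(zip(truth.m6a_sites["chrom"], truth.m6a_sites["strand"],
                         truth.m6a_sites["pos"]))
    called_keys = set(zip(called["chrom"], called["strand"], called["pos"]))
    tp = len(truth_keys & called_keys)
    return {
        "n_truth": len(truth_keys),
        "n_called": len(called_keys),
        "recall": tp / len(truth_keys) if truth_keys else float("nan"),
        "precision": tp / len(called_keys) if called_keys else float("nan"),
    }
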