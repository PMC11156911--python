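"""Shared synthetic datasets, generated once per session."""

from __future__ import annotations

import pytest

from clipm6a import (
    SimConfig,
    simulate_genome,
    simulate_clip_reads,
    simulate_miclip_reads,
    simulate_quant,
    simulate_binding_experiment,
    collapse_duplicates,
    assign_crosslinks,
    differential_binding_lrt,
    expression_covariate,
)
from clipm6a.m6a import tally_mismatches


def _run_binding(exp):
    cov = expression_covariate(
        exp["rna_counts"], exp["rna_conditions"],
        list(exp["peak_counts"].columns), exp["conditions"],
    )
    return differential_binding_lrt(
        exp["peak_counts"], exp["peak_genes"], exp["conditions"], cov
    )


@pytest.fixture(scope="session")
def default_config() -> SimConfig:
    return SimConfig(seed=1, n_genes=60)


@pytest.fixture(scope="session")
def dataset(default_config):
    """Default synthetic genome, annotation and truth set (60 genes)."""
    genome, annotation, truth = simulate_genome(default_config)
    return {"genome": genome, "annotation": annotation, "truth": truth,
            "config": default_config}


@pytest.fixture(scope="session")
def clip_pipeline(dataset):
    """CLIP reads pushed through collapse and crosslink assignment."""
    reads = simulate_clip_reads(dataset["genome"], dataset["truth"], dataset["config"])
    molecules, ratios = collapse_duplicates(reads)
    sites = assign_crosslinks(molecules)
    return {"reads": reads, "molecules": molecules, "ratios": ratios, "sites": sites}


@pytest.fixture(scope="session")
def miclip_pipeline(dataset):
    """miCLIP reads with their collapsed molecules and mismatch tallies."""
    reads = simulate_miclip_reads(dataset["genome"], dataset["truth"], dataset["config"])
    molecules, ratios = collapse_duplicates(reads)
    tallies = tally_mismatches(molecules)
    return {"reads": reads, "molecules": molecules, "ratios": ratios, "tallies": tallies}


@pytest.fixture(scope="session")
def null_lrt_results():
    """LRT results on 2000 null peaks (no condition effect, covariate fitted)."""
    return _run_binding(simulate_binding_experiment(n_peaks=2000, n_confounded=0, seed=42))


@pytest.fixture(scope="session")
def confounded_lrt_results():
    """Expression-confound scenario: 200 of 2000 peaks double with expression."""
    exp = simulate_binding_experiment(n_peaks=2000, n_confounded=200, seed=43)
    with_cov = _run_binding(exp)
    without_cov = differential_binding_lrt(
        exp["peak_counts"], exp["peak_genes"], exp["conditions"], None
    )
    return {"with_cov": with_cov, "without_cov": without_cov,
            "confounded": exp["confounded_genes"]}


@pytest.fixture(scope="session")
def quant_tables(dataset):
    counts, sample_sheet, proteomics = simulate_quant(dataset["truth"], dataset["config"])
    return {"counts": counts, "samples": sample_sheet, "proteomics": proteomics}
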