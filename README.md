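# clipm6a

Analysis pipeline for studying how N6-methyladenosine (m6A) shapes the
target selection of an RNA-binding protein (RBP): iCLIP-style
crosslink-site and peak calling, miCLIP single-nucleotide m6A detection,
expression-aware differential binding, and peak-count-stratified
integration with knockdown proteomics. It is aimed at computational
biologists who want each of these stages as a tested, composable library
(plus a thin CLI), exercisable end to end on a bundled synthetic-data
generator with ground truth.

## What it computes

**Crosslink sites and peaks.** Truncation-type CLIP reads collapse to
unique cDNAs by UMI; the crosslink is the nucleotide immediately 5' of the
cDNA 5' end. Per gene, positions whose event count beats a uniform
permutation null at FDR < 0.05 are significant; sites within a 20-nt window
cluster into peaks.

**m6A sites.** Antibody crosslinking induces C→T transitions at the C
immediately 3' of the methylated adenosine. Per C position the unique-tag
coverage *k* and transition count *m* are tallied; a site is called (CIMS)
when *m* ≥ 2 (or 5), 0.01 ≤ *m*/*k* ≤ 0.5, and the C is position 4 of a
DRACH motif (D=A/G/U, R=A/G, H=U/A/C) — the reported coordinate is the
motif's A. A truncation-based caller (CITS, Binomial(N, 1/L) null per
gene) and a merge are also provided.

**Differential binding.** Per-peak counts follow an NB2 GLM,
log μ = β₀ + β_cond·cond + β_expr·x, with a median-of-ratios-normalized
expression covariate x (log2(x + 0.001), standardized, replicate-paired);
β_cond is tested by a 1-df likelihood-ratio test so binding changes that
merely track transcript abundance are absorbed. Differential expression
uses a two-condition Wald test on the same engine. BH correction over
tested features.

**Integration.** Knockdown proteomics log2 ratios are column z-scored and
tested per protein (one-sample t). Genes are classified by the number of
m6A sites covered by their binding peaks (0, 1–2, 3–5, 6+); each class's
protein log2FC distribution is compared to the 0-class by a two-sided
two-sample Kolmogorov–Smirnov test (exact for small problems), with
Mann–Whitney U for category comparisons and nested-filter percentages for
functional-term enrichment.

The synthetic generator plants methylated DRACH motifs with stop-proximal
Gaussian placement, binding sites biased to 3'UTRs and to m6A sites, reads
with UMIs/PCR duplicates/C→T transitions, expression counts, and knockdown
ratios whose effect grows with the per-gene m6A–binding co-occurrence
class. See `docs/methods.md` for the model, defaults and limitations.

## Worked example

```python
from clipm6a import SimConfig
from clipm6a.pipeline import run_full_analysis, m6a_recovery

cfg = SimConfig(seed=1, n_genes=200)
out = run_full_analysis(cfg)

rec = m6a_recovery(out["truth"], out["m6a_sites"])
print(f"m6A sites: {rec['n_called']} called / {rec['n_truth']} true "
      f"(recall {rec['recall']:.1%}, precision {rec['precision']:.1%})")
print(f"binding peaks: {len(out['peaks'])} across "
      f"{out['per_gene_peaks'].gt(0).sum()} genes")
print("mean protein log2FC by m6A-peak class:")
for label, mean in out["class_means"].items():
    print(f"  {label:>3}: {mean:+.2f}  (n={out['class_sizes'][label]})")
for r in out["ks_results"]:
    print(f"KS {r.class_label} vs 0: D={r.statistic:.2f}, p={r.p:.2e}")
```

prints

```
m6A sites: 1325 called / 1325 true (recall 99.6%, precision 99.6%)
binding peaks: 937 across 175 genes
mean protein log2FC by m6A-peak class:
    0: +0.99  (n=53)
  1-2: +0.20  (n=72)
  3-5: -0.63  (n=55)
   6+: -1.63  (n=20)
KS 1-2 vs 0: D=0.82, p=4.51e-21
KS 3-5 vs 0: D=1.00, p=8.19e-32
KS 6+ vs 0: D=1.00, p=4.65e-18
```

The DRACH-filtered mutation caller recovers essentially all simulated m6A
sites, and the knockdown effect on protein output deepens monotonically
with the number of methylated binding sites per gene — the methylation-
dose-dependent regulation the pipeline is built to expose. (The 0-class
mean is positive because log2 ratios are z-scored across proteins, which
centres the globally downshifted distribution.)

A command-line interface mirrors the library:

```bash
clipm6a simulate --seed 1 --outdir ds/
clipm6a sites --reads ds/clip_reads.tsv --annotation ds/annotation.gtf \
        --genome ds/genome.fa --out-prefix ds/imp1
clipm6a m6a --reads ds/miclip_reads.tsv --genome ds/genome.fa \
        --annotation ds/annotation.gtf --out-prefix ds/m6a
clipm6a annotate --sites ds/m6a.m6a.bed --annotation ds/annotation.gtf \
        --genome ds/genome.fa --metagene scaled --out-prefix ds/ann
clipm6a diffexpr --counts ds/expression_counts.tsv \
        --samples ds/expression_samples.tsv --out ds/de.tsv
```

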