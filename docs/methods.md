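# Methods

`clipm6a` implements the computational core of a CLIP/miCLIP study of how
N6-methyladenosine (m6A) steers an RNA-binding protein's target selection
during neuronal differentiation: crosslink-site and peak calling from
truncation-type CLIP reads, single-nucleotide m6A calling from antibody CLIP
(miCLIP), expression-aware differential binding, and the integration of
per-gene binding/methylation counts with knockdown proteomics. Every stage
is exercisable without external data through a synthetic-data generator
whose outputs carry a machine-readable truth set.

## The synthetic study

The generator builds one chromosome of uniform random sequence carrying
protein-coding transcript models (5'UTR | CDS | 3'UTR, single exon by
default; an optional intron inserter exists only so the six-class region
annotation has intron territory to classify) and ncRNA genes, alternating
strand, separated by intergenic spacers. Defaults: 5'UTR 200 nt, CDS
1500 nt, 3'UTR 800 nt, ncRNA 600 nt, spacer 300 nt, lengths jittered by a
15% Gaussian.

**m6A truth.** Methylated positions are realized by planting a DRACH 5-mer
(`GGACT`, reverse-complemented on minus-strand genes) so that its adenosine
sits at a transcript coordinate drawn from a Gaussian centred on the stop
codon (`stop_proximal_sd`, default 100 nt) — the stop-proximal enrichment
characteristic of m6A maps. The number of sites per gene is binomial in the
gene's DRACH count with probability `drach_methylation_fraction x
neuron_methylation_gain` (defaults 0.10 and 1.5); each site is present in
the precursor condition with probability 1/gain and always in the neuron
condition, emulating the methylation increase during differentiation.
Configurations whose effective fraction exceeds 1, or where planted motifs
cannot be placed without overlap, are rejected.

**Binding truth.** Per-gene binding-site numbers are Poisson with a
lognormal gene-level rate (sigma 1.0 around a mean of 5 sites/gene),
reproducing the heavy-tailed per-gene peak counts seen in CLIP data; without
the heavy tail the 6-or-more-peaks stratum of the integration analysis would
be essentially empty at any realistic gene count. Sites co-locate with a
distinct m6A site of the same gene with probability 0.5 (sampling without
replacement), otherwise they fall in the transcript with the 3'UTR weighted
5x per nucleotide. A methylation-dependent (co-located) site is active only
in conditions where its m6A exists — this coupling is the mechanism under
study. Affinities are lognormal (sigma 0.5).

**Reads.** A unique cDNA starts one nucleotide 3' of its crosslink
(strand-aware) and carries a random UMI (7 nt). Unique molecules are
re-observed as PCR duplicates with multiplicity 1 + Poisson(ratio - 1),
expected ratio 2.0. miCLIP molecules covering a methylated A carry a C->T
transition at the immediately 3' C of the transcript strand (recorded in
reference-strand terms, so G>A on minus-strand genes) with probability
`ct_transition_rate` = 0.15, truncate at the site with probability 0.7, and
accumulate background C->T at 0.001 per covered C — a false-positive
population for the mutation filters to reject. Reads are emitted
pre-aligned as a tabular format (0-based half-open coordinates with
mismatch records); sequence-level alignment is out of scope.

**Quantities.** Expression counts are negative binomial (dispersion 0.05)
around lognormal gene means (median 200). Knockdown proteomics log2 ratios
have expectation `-delta x w(class)` with `delta = 0.4`, where class is the
gene's count of binding/m6A co-occurrences binned as 0 / 1–2 / 3–5 / 6+ and
`w` is the class rank (0..3) — the simplest monotone effect model consistent
with a dose-dependent regulation by methylated binding sites. Replicate
noise is Gaussian (sd 0.3). A functional-term membership ("microtubule-like"
annotation) is injected with probability 0.1 + 0.15 x rank so that term
enrichment propagates through nested filters.

What the generator does **not** emulate: splice-aware reads, sequencing
error beyond the C->T channel, batch effects, isoform structure, antibody
off-target binding, and fragment-length distributions. Passing recovery
tests therefore demonstrate the correctness of the analysis logic under the
stated statistical model, not performance on real libraries.

## Crosslink sites and peaks

Reads collapse to unique molecules on (sample, chromosome, strand,
strand-aware 5' coordinate, UMI); the duplication ratio reads/molecules is
reported per sample. The crosslink is the nucleotide immediately 5' of the
molecule's 5' end: start - 1 on plus, end on minus (half-open coordinates).
Molecules whose crosslink would precede position 0 are dropped and counted.

Significant sites are called per gene against a uniform permutation null:
the gene's total event count is re-scattered uniformly over the gene span
(default 100 permutations, seeded); for an observed per-position count c,
FDR(c) is the mean permuted number of positions with count >= c divided by
the observed number, capped at 1; positions with FDR < 0.05 pass. This is a fully specified within-gene
permutation procedure in the spirit of the significant-site callers common
in CLIP toolchains, whose exact formulas are not documented; no
flanking-window smoothing is applied.

Significant sites merge into peaks when separated by at most `window`
(default 20) intervening nucleotides — adjacent positions therefore merge
even at window 0. Summits are the max-count position, ties broken toward
the gene's 5' end for determinism. Count matrices tally crosslink events
per peak or per gene, with events outside all features reported as a
remainder and events in overlapping features counted in each (logged).

## m6A calling

**CIMS.** Per transcript-strand C position the unique-tag coverage k and
C->T count m are tallied (only positions with at least one transition are
enumerated). A position is called when m >= `min_m` (presets 2 permissive /
5 strict), 0.01 <= m/k <= 0.5, and — by default — the transition C is
position 4 of a DRACH motif; the reported coordinate is the motif's
adenosine, one nucleotide 5' of the C. The frequency band's lower bound
removes background transitions at high coverage; the upper bound removes
genetic variants and systematic miscalls.

**CITS.** Truncation events (molecule 5' ends, i.e. crosslink positions)
are tested per gene against Binomial(N, 1/L) where N is the gene's event
total and L its span; positions with p below the threshold (0.05, or 0.001
strict) are reported at the crosslinked residue. P-values are deliberately
raw (no multiple-testing correction), following common practice for this
channel.

Merging unions the two callers, marking coincident coordinates as `both`.
The end-to-end integration uses the DRACH-filtered CIMS set: measured on
default synthetic data, CIMS achieves ~99% recall and precision, while CITS
at p < 0.05 is a sensitive, low-precision channel (~11% precision here)
because clustered read starts near true sites violate the gene-wide uniform
null; merging it into the superimposition would dilute the per-gene counts
with false positives.

## Region annotation and metagenes

Regions are 5'UTR, CDS, 3'UTR, intron (within-span gaps), ncRNA and
intergenic, with per-class genomic lengths tracked (intergenic = genome
minus annotated spans). When transcripts disagree at a position the class
precedence is 3'UTR > 5'UTR > CDS > ncRNA > intron, reflecting where the
biology under study concentrates. Length-normalized percentages are
pct_r = 100 (C_r/L_r) / sum_j (C_j/L_j).

Metagene profiles come in two modes: *scaled* (per-region fractional
coordinates binned 33/34/33 across 5'UTR|CDS|3'UTR) and *unscaled*
(nucleotide-offset histograms in a +-400 nt window around the start- and
stop-codon anchors; the window must be fixed for reproducibility and 400 nt
covers the stop-proximal m6A bulk). Densities are normalized to sum to 1.

## Differential models

The engine is an NB2 GLM (variance mu + alpha mu^2) with log link, fitted by
Fisher-scoring IRLS (convergence max |delta beta| < 1e-8, <= 100 iterations;
alpha = 0 is the Poisson limit; all-zero rows and divergence are flagged,
never raised). Library size is normalized with median-of-ratios size
factors over features nonzero in every sample.

Two design choices matter and were made deliberately:

* **Models are fitted on size-factor-normalized counts**, not on raw counts
  with offsets. With offsets, rescaling one sample changes that sample's
  GLM weight and the estimates drift (up to ~0.05 log2 units when a sample
  is doubled); on normalized counts the rescaling is absorbed exactly,
  which is the invariance the pipeline promises.
* **Dispersion is pooled across features**: per-feature Pearson estimates
  (moment equation sum((y-mu)^2/(mu+alpha mu^2)) = n - p, solved by Brent's
  method after a Poisson mean fit) are averaged over all tested features.
  With 3–4 residual df a per-feature estimate is noise-dominated and breaks
  the chi-square calibration of the likelihood-ratio test (null rejection
  drifts and p-values are grossly non-uniform); the pooled mean restores
  both (measured null rejection 0.05, KS-vs-uniform p = 0.26 on 2000 null
  peaks). The mean, not the median, is pooled because the per-feature
  estimates are strongly right-skewed at few df. A per-feature
  method-of-moments helper remains available, as does a fixed `dispersion`
  argument.

**Differential binding** models per-peak counts as
`log mu = b0 + b_cond cond + b_expr x` and tests `b_cond` with a 1-df LRT.
The expression covariate x is built from an RNA count matrix: size-factor
normalization, log2(x + 0.001) (the pseudocount guards division/logs at
zero), global standardization, and pairing of each CLIP replicate with an
RNA replicate of the same condition in replicate order. Pairing per
replicate (rather than per-condition means) is essential: a covariate that
is constant within condition is an affine function of the condition
indicator and makes the full model rank-deficient, and biological
replicate-level expression variation is exactly what lets the model separate
abundance-driven binding changes from genuine occupancy changes. Features
with counts below 10 in at least 5 samples (configurable, row-sum variant
available) are excluded before testing and from BH adjustment. Significance
is |log2FC| > 1 and BH-adjusted p < 0.05.

**Differential expression** is a two-condition Wald test on the condition
coefficient (z = beta/SE from the observed information), zero-count genes
excluded, significance at raw p < 0.05 and |log2FC| > 1.5, BH-adjusted
values also reported.

## Integration

Knockdown proteomics log2 ratios are z-scored per replicate column across
proteins, then tested per protein with a two-sided one-sample t-test
(significant: |z-scored log2FC| > 1, p < 0.05; zero-variance proteins are
flagged and never significant). Peaks and m6A sites superimpose by
strand-aware half-open interval containment (optional window); the per-gene
quantity is the number of distinct m6A sites covered by the gene's peaks.
Genes with proteomics but no peaks enter class "0"; genes without a protein
measurement are dropped and counted.

Classes {0}, {1–2}, {3–5}, {6+} are each compared to class 0 with a
two-sided two-sample Kolmogorov–Smirnov test (exact when n x m <= 10,000,
asymptotic above; the switch is configurable). Category-wise peak counts
use two-sided Mann–Whitney U (exact when min(n, m) <= 8, tie-corrected
normal approximation above). Nested-filter percentages are
100 |set ∩ term| / |set| with empty sets flagged rather than raised, plus a
windowed site-overlap utility (100 x fraction of query sites within a window
of any reference site).

## Problem sizes and runtime

The test suite and the acceptance script use: 60 genes for generator and
recovery checks (~10^4 unique CLIP molecules, ~400 true m6A sites); 400
genes for the stop-proximal placement moment check; 2000 peaks for LRT
calibration (3 vs 3 replicates, binding mean 50, RNA mean 500, biological
sd 0.5 log2); 500 features for GLM recovery; and 1500 genes for the
end-to-end stratified reproduction, sized so that every peak class retains
at least ~100 genes. The full suite runs in a few minutes on one CPU.

## Known limitations

* The significant-site permutation null ignores within-gene coverage
  structure (uniformity is assumed), so heavily 3'UTR-biased genes are
  tested against a slightly misspecified null.
* CITS inherits the same uniform-null assumption and is low-precision at
  raw p < 0.05 by construction; it is reported but not used for the
  superimposition.
* The dispersion pooling assumes features are exchangeable; datasets with
  strongly feature-dependent dispersion would need the trended/shrunken
  estimators of dedicated DE packages.
* One representative transcript per gene; multi-isoform collapse, splice
  reads and real alignment are out of scope.
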