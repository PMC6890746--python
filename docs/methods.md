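# Methods

This note records the statistical models, parameter choices and numerical
conventions behind `ccmlnc`, and states precisely what the synthetic
benchmarks do and do not demonstrate.

## Differential expression

Counts are modelled per gene as negative binomial with mean `μ` and
dispersion `α`, in the `Var = μ + α·μ²` parameterisation. Normalisation is
the median-of-ratios rule: each sample's size factor is the median, over
genes with no zero count in any sample, of that sample's count divided by
the gene's geometric mean across samples. When no such gene exists the
function refuses and points to an explicit `allow_pseudo_reference` flag
(geometric means over positive counts only), rather than silently changing
the estimator.

Dispersion is estimated per gene by method of moments on normalised counts
— the pooled within-group variance plugged into `α = (s² − μ̄)/μ̄²`,
floored at 1e-8 — with no shrinkage across genes and no independent
filtering. These are deliberate simplifications: they keep every gene's
test self-contained and auditable, and an importer for externally produced
DE tables (`ccmlnc.io.read_de_table` with a column-mapping) lets users
substitute any DE engine without touching the rest of the pipeline.

The test statistic is a Wald ratio on the fold change,
`log2FC = log2((μ̂₁ + c)/(μ̂₀ + c))` with pseudocount `c = 0.5` normalised
counts (finite fold changes at zero means without shrinkage machinery),
and a delta-method standard error from the model variance of each group
mean. **The p-value uses a Student-t reference with `n₁ + n₂ − 2` degrees
of freedom, not a normal reference.** With 14 samples the statistic
behaves like a pooled two-sample t; a normal reference is anti-conservative
in exactly the far tail that BH selection at `padj < 0.01` probes. In our
calibration runs (10 vs 4, 500 null genes), the normal reference produced
at least one false BH call in 42% of all-null cohorts, the t reference in
none, with raw type-I error 0.072 vs 0.052 at the 0.05 level. Under the t
reference the all-null mean false-discovery proportion is held at its
nominal level, which the acceptance suite verifies.

Significance uses strict thresholds: `padj < 0.01` and `|log2FC| > 1.5`.
The fold-change cut is interpreted on the log2 scale (the convention of
NB-based DE tools); both cut-offs are configuration knobs, as is the
alternative `padj < 0.05` sometimes used for visualisation. Genes with all
counts zero are reported `untested` with undefined p, and undefined
p-values pass through BH adjustment untouched (m counts defined p-values
only). Swapping the group labels negates every fold change and leaves all
p-values unchanged.

## Co-expression and hubs

Correlation is Spearman's ρ — the Pearson correlation of average ranks,
well-defined under ties — computed on `log2(normalised count + 1)` across
all samples, cases and controls pooled. Pairs are kept at signed
`ρ > 0.9` and `p < 0.05`, both strict; an absolute-value mode exists but
signed is the default because co-expression is read as "similar expression
patterns". Raw p-values are used for pair retention (a BH column is
available but off by default); the screen's error control comes from the
extreme ρ cut-off, not from multiple-testing correction. Constant genes
are dropped with a logged count rather than producing undefined
correlations.

P-values are exact for n ≤ 9: the full n! permutation distribution of the
rank correlation is enumerated (valid under ties, since average ranks are
permuted), counting permutations with `|ρ| ≥ |ρ_obs|` within 1e-12. Above
n = 9 the classical approximation `t = ρ·sqrt((n−2)/(1−ρ²))` with n−2
degrees of freedom is used; at n = 9 the two agree within 0.02 for
`|ρ| ≤ 0.8`. A hub is a lncRNA with strictly more than 100 retained
partners; partner-set intersection and the bipartite network (SIF and
GraphML with ρ and p edge attributes) follow directly.

A consequence of the small design worth stating: with 10 + 4 samples, two
fully separated same-direction DE genes already have rank correlation
≈ 0.6 from the group contrast alone, and the chance that independent
within-group noise lifts a given pair above 0.9 is of order 1%. Among
thousands of same-direction DE genes, every correct implementation will
therefore retain some chance pairs. Hub calls are robust to this (the
>100-partner rule sits far above the chance background — a few dozen at
most per lncRNA), but individual retained pairs at this sample size are
screening hypotheses, not validated interactions.

## Coding-potential screen

The screen is fully deterministic and transparent. Three features are
computed from the stranded transcript sequence: the longest ATG-to-stop
open reading frame over the three forward frames (length includes the stop
codon; ORFs containing N are skipped; reverse-strand frames are not
scanned), its coverage of the transcript, and the Fickett TESTCODE
statistic from the published position-asymmetry and composition lookup
tables (shipped as `data/fickett_tables.json`). A fixed logistic model
(coefficients versioned in `data/coding_model.json`: intercept −5,
0.004 per ORF nt, 4.5 per unit coverage, 2.0 per TESTCODE unit) converts
the features to a coding probability; a transcript is `noncoding` when the
probability is strictly below 0.37. The threshold is applied to our
probability and exposed as configuration. No trained SVM is reproduced:
the logistic surrogate keeps the screen monotone in each feature,
bit-reproducible, and auditable, at the cost of not matching any external
tool's scores numerically.

## Genomic context

All internal coordinates are 0-based half-open; GTF (1-based inclusive)
and BED (0-based half-open) are converted at the I/O boundary only. Locus
definitions like `7q11-q22` are resolved against a cytoband table: each
endpoint token matches bands by exact name or sub-band prefix
(`q25.2` matches `q25.2*`; a second token without an arm inherits the
first arm), and the locus spans the minimum start to the maximum end over
both endpoint groups. A gene maps to a locus when they overlap by at least
`min_overlap_bp` (default 1 bp, half-open arithmetic, strand ignored);
chromosome-name styles (`chr7` vs `7`) are normalised. The packaged band
table covering chr3 and chr7 is **synthetic** — an internally consistent
constructed layout whose band names cover the three susceptibility loci —
because real genome-build coordinates are not redistributable here; any
UCSC-format cytoband file can be supplied instead, and locus resolution is
exercised against toy tables in the tests.

## Tissue specificity, enrichment, qPCR

TPM divides each count by transcript length in kb and scales each column
to sum to 1e6; all-zero columns and missing lengths are errors, not
warnings. Z-scores are per gene across all tissue columns (replicates as
separate columns, not averaged) with sample standard deviation; constant
genes become zero rows with a logged warning. The brain contrast is the
mean z over brain replicate columns for the DE-up and DE-down lncRNA sets
separately, undefined (NaN) for empty sets.

Enrichment is the one-sided upper-tail hypergeometric test of a query set
against each GMT term, both intersected with a configurable universe
(default: all genes in the count matrix, since the tool the analysis style
derives from does not state its background). Significance is raw
`p < 0.05`, strict; a BH column is reported for information but does not
drive the flag, mirroring the screening convention.

qPCR fold change is `2^(−ΔΔCt)` with `ΔCt = Ct_target − Ct_reference` per
sample and `ΔΔCt = mean ΔCt(case) − mean ΔCt(control)`. The test on ΔCt is
Welch's two-tailed t-test — chosen over the pooled-variance variant
because group sizes are unbalanced (10 vs 4); the pooled option exists.
With fewer than two samples in a group the fold change is still reported
but p is undefined.

## The synthetic generator

The generator's defaults are the study conditions every benchmark runs
under; they are chosen once, for separability, and are not fitted to data.

* **Cohort shape** — 10 cases vs 4 controls; per-sample depth factors
  log-normal with sd 0.15 (log scale).
* **Counts** — gamma-Poisson (NB) draws; baseline means log-uniform on
  [50, 2000]; global dispersion 0.02, a value typical of well-powered
  human bulk data. Dispersion may also be supplied per gene.
* **Planted DE** — case-group means multiplied by `2^log2FC`. Background
  DE genes draw `|log2FC| ~ U(2.5, 4)`; module genes (hubs and partners)
  draw `U(7, 9)` and are re-based into the 500–2000 count range. The split
  matters: an extreme *down* effect zeroes case counts, which silently
  removes the gene from the median-of-ratios reference set and biases the
  size factors between groups. For the same reason planted directions are
  kept balanced (counter-direction planting) whenever the partner
  requirement allows.
* **Modules** — each hub lncRNA carries a per-sample latent factor, drawn
  Gaussian, centred within each group (so modules never alias the disease
  contrast), and standardised to a fixed realised spread of 1.2 log2
  units; partners follow the factor with gene-level noise of sd 0.05 and
  module genes use a low dispersion of 0.002 (tight co-regulation).
  Standardising the factor and letting the hub carry it exactly removes
  the two heavy-tailed failure modes of a naive construction — a weak
  factor realisation, or a noisy hub draw, silently failing an entire
  module. Factors of consecutive modules are antithetic (negated pairs) so
  that summed over modules the per-sample shifts cancel instead of leaking
  into size-factor estimation as a spurious global factor. Partner sets of
  different hubs are disjoint: a gene driven by two independent factors
  could not exceed ρ 0.9 with either hub, so shared membership would
  contradict the planted-pair contract.
* **Transcripts** — protein-coding sequences get an ATG..stop ORF covering
  ~70% of the transcript, built from codon-position-biased base
  frequencies (high TESTCODE); lncRNA sequences are uniform random with
  chance ORFs disrupted down to min(0.25 × length, 400 nt), since
  unconstrained random sequence of a few kb typically contains a
  500–700 nt ORF that a coding screen would rightly flag.
* **Loci** — ~6% of genes are placed uniformly across the three
  susceptibility loci (resolved from the synthetic band table), the rest
  scattered on other chromosomes; transcript lengths are uniform on
  [500, 5000] nt and double as genomic extents.
* **Tissue panel** — 16 tissues × 2 replicates including brain; disease-up
  genes are drawn brain-low and disease-down genes brain-high by 2.5 log2
  units; Poisson counting noise; TPM-normalised.
* **qPCR** — reference Ct ≈ 20, control ΔCt ≈ 6 cycles, case ΔCt shifted
  by the planted ΔΔCt (default −2, i.e. 4-fold up), Gaussian ΔCt noise
  (default sd 0.2 cycles).
* **Determinism** — one top-level seed spawns a fixed, named substream per
  stage (genes, DE, counts, modules, tissue, qPCR, gene sets,
  transcripts), so outputs are byte-identical across runs and adding a
  stage never perturbs earlier draws.

In the hub-recovery benchmark (20 hubs × 120 partners among 5,000 PCGs,
plus 200 decoys), decoy lncRNAs carry **no planted effect**. This is
deliberate: a strongly DE decoy shares the full group separation with
every same-direction DE gene, and at n = 14 it genuinely exceeds ρ 0.9
with ~1% of them by rank chance — occasionally, by normalisation-coupled
noise alignment, with more than 100. Such "false hubs" are a property of
the sample size, not of an implementation, so a zero-false-hub check is
only meaningful for unaffected decoys. When hubs are planted, any
remaining DE lncRNAs outside the modules take the direction opposite the
hubs for the same reason.

## What the benchmarks show — and what they do not

Passing the planted-truth suite demonstrates that the machinery is
correct: normalisation, the NB Wald test with honest error control at
10 vs 4, exact small-n Spearman inference, strict threshold semantics,
interval arithmetic, enrichment probabilities to enumeration accuracy, and
byte-level reproducibility. It does not demonstrate performance on real
patient data: real cohorts have gene–gene correlation beyond clean latent
factors, dispersion far more heterogeneous than a global 0.02, batch
structure, overlapping and weak modules, effect sizes well below 8-fold,
and annotation ambiguity — all outside the generator by design
(read-level simulation, isoforms and batch effects are explicit
non-goals). The planted effects are set well above detection thresholds so
that any recovery failure indicates a defect rather than sampling noise;
sensitivity at marginal effect sizes is characterised separately by the
power benchmark (|log2FC| = 3, mean 500, dispersion 0.05), not by the
recovery benchmark.

## Degenerate inputs and tie-breaks

Readers reject malformed input with the offending record named, never
repairing silently. Duplicate gene or sample ids, negative or non-integer
counts, GMT lines with fewer than three fields, BED intervals with
`end ≤ start`, unknown cytobands and unparseable band ranges are all hard
errors. Constant series yield undefined ρ (and undefined p) rather than a
value; empty query sets yield undefined means; an empty combined gene set
makes the overlap fraction undefined rather than zero. Hubs are ordered by
degree then id; pair tables preserve input gene order; all floating-point
output is written with a fixed `%.10g` format so equal runs are
byte-equal. The run manifest contains the wall time as its only volatile
field; determinism checks compare it after dropping that field.
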