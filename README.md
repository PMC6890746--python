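# ccmlnc

Hub lncRNA discovery in cerebral cavernous malformation (CCM) transcriptomes
by lncRNA–mRNA co-expression network analysis — implemented as a tested,
reusable pipeline that runs end to end on synthetic cohorts with planted
ground truth.

CCMs are low-flow vascular brain lesions; transcriptome profiling of
resected lesions against control brain tissue (typically ~10 cases vs ~4
controls) identifies long non-coding RNAs whose expression tracks large
sets of disease-regulated protein-coding genes (PCGs). Such "hub" lncRNAs
are candidate regulators of the disease program. This package implements
every computational stage of that analysis from the count matrix onward,
and a synthetic-data generator that plants recoverable versions of every
signal the analysis looks for.

## The analysis

For a genes × samples count matrix with case/control labels:

1. **Normalisation** — median-of-ratios size factors
   `s_j = median_g ( K_gj / (∏_j K_gj)^{1/n} )` over genes with no zero count.
2. **Differential expression** — per-gene negative-binomial model
   (Var = μ + αμ², α by method of moments), Wald statistic on
   `log2FC = log2((μ̂_case + c)/(μ̂_ctrl + c))` with a delta-method standard
   error and a Student-t reference (n−2 df), Benjamini–Hochberg FDR.
   A gene is DE when `padj < 0.01` and `|log2FC| > 1.5` (both strict).
3. **Coding screen** — DE lncRNA candidates are confirmed noncoding from
   transcript sequence: longest forward-frame ORF, ORF coverage, and the
   Fickett TESTCODE statistic, combined by a fixed logistic model; a
   transcript is noncoding when its coding probability is below 0.37.
4. **Co-expression** — all DE-lncRNA × DE-PCG pairs are scored by Spearman
   correlation on `log2(normalised count + 1)` across the pooled samples;
   a pair is kept when `ρ > 0.9` and `p < 0.05` (exact permutation p for
   n ≤ 9, t approximation above).
5. **Hubs and networks** — a lncRNA with more than 100 retained partners is
   a hub; the bipartite network is exported as SIF/GraphML, and the top two
   hubs' partner sets are intersected.
6. **Genomic context** — DE transcripts are mapped onto the three CCM
   susceptibility loci (CCM1: 7q11-q22, CCM2: 7p15-13, CCM3: 3q25.2-q27),
   resolved from cytoband ranges by interval arithmetic.
7. **Tissue specificity** — TPM-normalised multi-tissue panels, per-gene
   z-scores, and the brain-vs-rest contrast of DE-up and DE-down lncRNAs.
8. **Enrichment** — one-sided hypergeometric tests of hub partner sets
   against GMT collections (significant at raw `p < 0.05`).
9. **qPCR validation** — relative quantification by `2^(−ΔΔCt)` against a
   housekeeping reference with a two-tailed Welch t-test on per-sample ΔCt.

## Worked example

Simulate a 10 vs 4 cohort with two planted hub lncRNAs (40 partners each)
and run the full pipeline:

```yaml
# demo.yaml
seed: 7
outdir: demo_out
simulate:
  n_lncRNA: 60
  n_PCG: 400
  n_hubs: 2
  partners_per_hub: 40
  de_fraction_lnc: 0.3
  de_fraction_pcg: 0.3
thresholds:
  min_partners: 30
```

```
$ ccmlnc run --config demo.yaml
pipeline complete; outputs in demo_out
  input: {'genes': 460, 'samples': 14, 'case': 10, 'control': 4}
  differential_expression: {'tested': 460, 'de_lncRNA': 18, 'de_PCG': 120, 'up': 82, 'down': 56}
  coding_screen: {'screened': 18, 'noncoding': 18}
  coexpression: {'pairs_retained': 85}
  hubs: {'hubs': 2, 'hub_ids': ['LNC00029', 'LNC00041']}
  partner_intersection: {'hub_a': 'LNC00029', 'hub_b': 'LNC00041', 'common': 0}
  locus_summary: {'CCM1': {'de_lncRNA': 0, 'de_PCG': 3}, 'CCM3': {'de_lncRNA': 0, 'de_PCG': 4}, 'CCM2': {'de_lncRNA': 0, 'de_PCG': 3}}
  tissue_specificity: {'mean_brain_z_up': -2.622209, 'mean_brain_z_down': 3.390216}
  enrichment: {'queries': 3, 'significant_terms': 4}
  qpcr: {'fold_change': 4.738273, 'p': 0.0}
```

Reading the output: 138 of 460 genes are called DE; all 18 DE lncRNAs pass
the noncoding screen; 85 lncRNA–PCG pairs exceed ρ 0.9, and exactly the two
planted hubs (`LNC00029`, `LNC00041` — check `demo_out/inputs/truth_hubs.tsv`)
collect more than 30 partners. Disease-up lncRNAs are brain-depleted in the
tissue panel (mean brain z −2.6) and disease-down lncRNAs brain-enriched
(+3.4), the planted enrichment terms are flagged, and the qPCR stage
recovers a fold change of 4.74 (planted ΔΔCt −2, i.e. 4-fold, with Ct
noise). Every stage writes its table (`de_table.tsv`, `pairs.tsv`,
`hubs.tsv`, `network.sif`, `enrichment.tsv`, ...) plus `manifest.json`, and
the simulated inputs and truth ledger land in `demo_out/inputs/`.

The same stages are available as library functions
(`ccmlnc.differential_expression`, `ccmlnc.coexpression`, ...) and as
focused CLI subcommands (`simulate`, `de`, `coexpress`, `enrich`,
`validate`).

## Limitations

The synthetic generator defines favourable, unambiguous study conditions
(strong planted effects, tightly co-regulated modules); see
`docs/methods.md` for the model, the parameter choices and what passing
these benchmarks does and does not say about real patient data.
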