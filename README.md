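# tcellscreen

A tested, reusable reimplementation of the analysis chain behind pooled
CRISPR-activation (CRISPRa) screens for tumor resistance to T cell
cytotoxicity — from raw sgRNA counts to candidate resistance genes and
their downstream association with patient tumor immune activity and
immunotherapy response. Every stage runs end-to-end on synthetic data with
planted, recoverable signal, so the statistical machinery can be validated
without the original deposited sequencing data.

## Who this is for

Computational biologists analyzing pooled enrichment screens (especially
survival/selection screens with noisy primary-cell co-cultures) who need:
guide-to-gene rank aggregation with a permutation null, an empirical FDR
measured against housekeeping negative-control genes, replicate-overlap hit
calling, redundancy-pruned pathway enrichment, and expression-cohort
follow-up analyses (cytolytic-activity correlation, single-sample GSEA
responder stratification).

## The statistics at the core

**Gene scoring (α-RRA).** Per replicate, guide counts are median-ratio
normalized and each guide gets an enrichment log-fold change
`lfc = log2((sel + 1)/(ctl + 1))` and a normalized rank `r ∈ (0, 1]` by
descending lfc. For a gene with sorted guide ranks `r(1) ≤ … ≤ r(k)`,
guides beyond the aggregation percentile α are skipped and

    ρ = min over retained j of P( Beta(j, k−j+1) ≤ r(j) ),

the minimum order-statistic tail probability, with significance from a
permutation null that draws k ranks from the pooled rank list per gene
size class: `perm_p = (1 + #{ρ_null ≤ ρ}) / (1 + n_perm)`.

**Hit calling.** A gene's empirical FDR is the fraction of designated
housekeeping negative-control genes whose mean guide lfc strictly exceeds
its own. Candidates are genes ranked in the top 1% of at least two pooled
screening replicates (acute and chronic screens combined).

**Pathway enrichment.** Upper-tail hypergeometric tests over gene sets with
5–200 members in the screened universe, Benjamini–Hochberg control
(FDR < 0.05), and exclusion of any pathway sharing > 30% of its genes with
a lower-FDR pathway.

**Tumor association.** Cytolytic activity `CYT = sqrt(GZMA · PRF1)` per
sample; per-tumor-type Pearson correlation of each gene with CYT, tested by
the Fisher transformation `z = atanh(r)·√(n−3)` with BH control. Responder
analysis: per-sample ssGSEA of the candidate signature (rank-weighted ECDF
difference, weight 0.25; NES = ES / ES-range across samples), z-scored per
dataset, compared between responders and nonresponders with a two-tailed
t test.

## Worked example

The `analysis/` scripts run the whole chain on a simulated study: a
10,000-gene × 3-guide library with 300 housekeeping negative controls and
50 planted resistance genes (per-round fitness effect 2.0), screened
acutely (1 round) and chronically (3 rounds) with 2 replicates each.

```sh
python analysis/01_simulate_screen.py
python analysis/02_score_replicates.py
python analysis/03_call_candidates.py
python analysis/04_pathway_enrichment.py
python analysis/05_tumor_association.py
python analysis/06_auxiliary_metrics.py
```

Output from an actual run (seed 7):

```
chronic_rep1: 50/50 planted genes in the top 1%
top-1000 overlap chronic_rep1 vs chronic_rep2: 15.2%
chronic selected-arm Gini by round: ['0.366', '0.368', '0.374', '0.385']
50 candidates from 4 pooled replicates (top 1%, >= 2 replicates)
planted-gene recovery: 50/50 (100%)
candidates with empirical FDR < 0.1: 50/50
3 pathways enriched at FDR < 0.05; 1 retained after 30%-overlap pruning
mean r of signature genes vs cytolytic activity: 0.496
ssGSEA z higher in nonresponders (t = -25.61, p = 3.57e-78)
```

Reading this: chronic selection concentrates the library (the Gini
coefficient of the selected arm rises every round), the rank-aggregation
scores place all 50 planted genes in the chronic top 1%, the
top-1%/≥2-replicate rule calls exactly the planted set with empirical FDR
below 0.1, pruning collapses three overlapping enriched gene sets to the
planted resistance program, the tumor cohorts recover the planted r = 0.5
cytolytic correlation, and the candidate signature is significantly higher
in immunotherapy nonresponders — the direction expected for resistance
genes. Small summary tables land in `results/`; bulky intermediates go to
`scratch/`.

The same operations are scriptable via the CLI (`tcellscreen --help`):
`simulate-screen`, `simulate-cohort`, `score`, `call-hits`,
`enrich-pathways`, `cytolytic`, `ssgsea`, `de`, `promoter-calls`.

## Layout

- `src/tcellscreen/` — the library: `simulate` (generators), `enrichment`
  (normalization, LFC, α-RRA, Gini), `hits` (empirical FDR, candidate
  rule, overlap), `pathways` (GMT, hypergeometric, BH, pruning), `tumor`
  (CYT, correlation, ssGSEA, response comparison), `metrics` (percent
  survival, tumor volume, differential expression, promoter-overlap
  calls), `io`, `cli`.
- `analysis/` — numbered narrative drivers over the library.
- `tests/` — unit, property, and end-to-end acceptance tests with
  independent brute-force oracles.
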