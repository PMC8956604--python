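# Methods

## Scope and model

The package reconstructs the computational chain of a gain-of-function
(CRISPRa) selection screen against T cell cytotoxicity and its downstream
patient-cohort analyses. The chain is: sgRNA counts → per-replicate gene
enrichment scores → candidate calling → pathway enrichment → expression-
cohort association. Because the original sequencing and consortium data are
not required, a first-class synthetic-data module generates every input
with planted signal whose recovery the tests measure.

## Screen simulator

Per replicate, baseline guide abundances are log-normal with σ = 0.5 on the
natural-log scale (reproducing the right-skewed plasmid-library
distributions typical of pooled screens) and normalized to sum 1. Each
selection round multiplies the selected arm's abundance of every guide by
its gene's per-round fitness effect (dimensionless, ≥ 1; exactly 1 for all
non-resistance genes and, by construction, for every negative-control gene)
and renormalizes; the unselected control arm keeps the baseline. Sequencing
counts are negative binomial with mean `abundance × depth × n_guides` and
variance `μ + αμ²`, dispersion α = 0.2 (standard overdispersion for screen
sequencing), mean depth 500 reads per guide. Acute exposure is modeled as
1 selection round and chronic exposure as 3; effector-to-target ratios and
exposure times are biological settings outside the count model. The
magnitude of true resistance effects is a free parameter; the study
conditions used throughout tests and drivers are 50 planted genes at
per-round effect 2.0. All randomness derives from one integer seed through
`numpy.random.SeedSequence` spawning with a fixed stream order
(effect-gene choice, then per-replicate baseline and count streams), so any
replicate can be regenerated independently.

What the simulator does not model: multiplicity-of-infection effects and
multiple integrations, guide efficiency differences, off-target activity,
read-level errors, or cell-cycle/fitness interactions. Passing tests
therefore demonstrate correctness and calibration of the statistics under a
clean overdispersed count model, not robustness to those real-data
artifacts.

## Gene scoring

Counts are normalized by median-of-ratios size factors (each sample divided
by the median of count/geometric-row-mean over guides positive in every
sample), falling back to total-count scaling when no all-positive row
exists; median-ratio is the default because strong selection shifts library
composition. Guide enrichment is `log2((sel + pc)/(ctl + pc))` with
pseudocount 1.0, and normalized ranks use midranks for ties divided by the
number of guides.

The gene score is the α-RRA statistic: with sorted guide ranks
`r(1) ≤ … ≤ r(k)`, guides with `r(j) > α` are skipped and
`ρ = min_j P(Beta(j, k−j+1) ≤ r(j))` over retained j; genes with no
retained guide score 1. The default α = 0.05 suits a 3-guide library where
resistance requires consistent guide behavior; it is configurable. The
permutation null draws k ranks with replacement from the pooled observed
rank list, once per gene size class (default 10,000 draws), and
`perm_p = (1 + hits)/(1 + n_perm)` so p is never 0. Ranking is the total
order (perm_p, ρ, −mean lfc, symbol), gap-free and deterministic under row
permutation. Scoring operates at the library target (isoform) level when
targets are distinguished; `collapse_to_genes` keeps the best target per
gene symbol by minimum perm_p. Only positive selection (enrichment) is
scored: the screen reads out survival, so depletion is out of scope.

## Hit calling

The empirical FDR of a gene is the fraction of housekeeping negative-
control genes whose mean guide lfc strictly exceeds the gene's ("average
sgRNA enrichment" is read as the arithmetic mean of guide log2 fold
changes; ties do not inflate the FDR and are logged). Candidate selection
takes, per replicate, the genes with rank ≤ ceil(top_fraction × n_genes) —
the inclusive reading of "top 1%" — and keeps genes present in at least
`min_replicates` top sets, pooling acute and chronic replicates into one
list. On an all-null screen the expected candidate count is approximately
`top_fraction² × n_genes × replicate_pairs`, which the acceptance tests
verify (≈ 1 for 10,000 genes, 2 replicates, top 1%).

## Pathway enrichment

Upper-tail hypergeometric p-values over sets restricted to 5–200 members in
the universe of all genes scored in the screen (enrichment should condition
on what could have been a candidate); BH over the tested family only;
FDR < 0.05. Redundancy pruning sorts by (FDR, p, set id) and excludes a
pathway when more than 30% of its in-universe members overlap *any*
earlier (lower-FDR) pathway — the literal reading; a greedy variant that
compares only against already-retained pathways is available behind
`retained_only=True` since both readings are defensible. The overlap
denominator is the examined (higher-FDR) pathway's in-universe size.

## Cohort analyses

Cytolytic activity is computed on the linear expression scale,
`CYT = sqrt((GZMA + 0.01)(PRF1 + 0.01))`; log2(TPM+1) input is
back-transformed as `2^x − 1` (floored at 0) and the 0.01 offset tolerates
zeros. Correlations are computed on the cohort's stored (log) scale; by
default CYT is put on the same scale (`log2(CYT + 1)`) before correlating,
because correlating a log-scale matrix against a linear score mixes scales
— the linear-score variant is available via `log_cyt=False`. Significance
uses the Fisher transformation (`z = atanh(r)·√(n−3)`, two-sided normal
p, floored at the smallest positive float for |r| → 1) with BH applied
within tumor type, the family a per-type analysis implies; "positively
correlated" is the conjunction r > 0 and FDR < 0.05. Zero-variance genes
yield r = NaN, p = 1, with a log note.

ssGSEA follows the defaults of the commonly used implementation: per-sample
expression values are replaced by their ranks, genes are ordered by
descending value (ties broken by gene name for determinism), and
`ES = Σ_positions (P_in − P_out)` with in-set steps proportional to
|rank value|^0.25 and out-of-set steps `1/(N − m)`;
`NES = ES / (max ES − min ES)` across the samples of the run (hence at
least two samples are required). The implementation is verified against
both a brute-force double-loop reimplementation (to 1e-9) and the external
reference implementation. NES is z-scored within each dataset (ddof = 1)
before datasets are aggregated, removing per-dataset location/scale.
Response groups are compared with an equal-variance two-tailed t test
(Welch behind a flag). Clinical labels map to the responder dichotomy via a
fixed dictionary (complete/partial response, clinical benefit, no
progression → responder; stable/progressive disease, no benefit,
progression → nonresponder) in the cohort loader.

The cohort simulator drives GZMA and PRF1 almost deterministically
(noise SD 0.1) from one latent immune-activity factor per sample and gives
each signature gene correlation r with that factor on the log2 scale, so
the planted correlation survives the CYT computation to within the ±0.1
contract at n ≥ 200. The nonresponder shift is a standardized mean
difference added to signature genes; per-dataset offsets emulate batch
scale. Log2 values are clipped at 0 to keep the linear scale non-negative;
the clip is negligible at the default gene-mean location (4 ± 1).

## Auxiliary metrics

Percent survival is `100 × viability_with_T / viability_without_T` (may
exceed 100); tumor volume is `L·W²/2` with L the longest dimension (width
> length is rejected). Differential expression on log2(TPM+1) matrices
filters to genes detected at TPM ≥ 10 — the threshold is read on the TPM
scale, since a log2 threshold of 10 would demand TPM ≥ 1023; a flag selects
the log reading — in ≥ 3 libraries pooled across conditions, applies an
equal-variance t test per gene, BH at 0.01, and flags significance only
when additionally |log2 FC| > 1 (the fold-change rule is applied as a
separate post-FDR flag). Promoter windows span 2000 bp upstream to 500 bp
downstream of the TSS, strand-aware (upstream extends toward larger
coordinates on the − strand); BED peaks are 0-based half-open and are
converted to 1-based closed intervals, and overlap is closed-interval with
≥ 1 bp, so a peak ending exactly at the window start counts.

## Problem sizes and numerical choices

The standard spike-in condition is 1,000 genes × 3 guides with 50 planted
resistance genes; the top-1%/≥2-replicate candidate rule is exercised on a
10,000-gene screen (where the top 1% of 10,000 can hold the 50-gene
planted set, as in a genome-scale library), with all per-gene parameters
unchanged. Null-screen calibration uses 10,000 genes × 300 controls over
20 seeds; statistical calibration uses 1,000 direct null simulations of the
Fisher-z and t tests. Beta/hypergeometric/normal tail probabilities come
from scipy; BH from statsmodels. Tie-breaks are lexicographic everywhere a
total order is needed (gene ranking, ssGSEA ordering, pathway sort) so
results are bit-reproducible across runs and platforms.

## Known limitations

The permutation null pools ranks across genes and assumes exchangeability
under the null; genes with unusual guide-count classes get their own null
but share the pooled rank list. The empirical FDR inherits the assumption
that housekeeping controls are selection-neutral. The simulator's planted
effects are homogeneous per gene (all guides of a gene share one effect),
which favors rank aggregation relative to real screens with variable guide
efficacy. NES depends on the sample set through its range normalization, so
scores are comparable only within a run — the per-dataset z-score exists
precisely to absorb this.
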