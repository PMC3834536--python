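# Methods

This note documents the statistical procedures, their tunable parameters,
the synthetic-data model the tests rely on, and the numerical and design
choices made where more than one reasonable option existed.

## Detection and preprocessing

A probe on an array is called *detected* when its intensity is strictly
above the array's threshold, defined as the mean plus k standard
deviations (sample SD, n−1) of the negative-control probe intensities on
that same array — k = 3 for the spotted-cDNA design, k = 2 for the
strand-specific oligo design, where detection additionally requires a
minimum number of arrays (3 of 4) above threshold in at least one sample
group. Strictness follows the rule's wording ("higher than", "above");
at least two negative controls are required or the SD is undefined.
Local-background subtraction of the original scanner pipeline is not
modeled: synthetic intensities carry no spatial background, so the
negative-control threshold is the operative filter.

Prevalence filtering keeps a probe only when its detection fraction
reaches `min_frac` (default 0.9) in **both** compared groups — a probe
below 90% in either group is excluded, the reading most consistent with
excluding probes "detected in less than 90% of the arrays in any of the
two groups".

Quantile normalization forces every array onto the common distribution
(the row-wise mean of the sorted columns), preserving within-array ranks.
Ties map to the target distribution interpolated at the average rank. The
transform is idempotent on tie-free data; missing values are rejected
rather than imputed (the synthetic generator produces complete matrices,
and no imputation scheme is part of the modeled analysis). Log-ratios are
log2(T) − log2(N) per probe per patient pair; nonpositive intensities
raise an error naming the probe and sample.

## SAM signatures

The relative difference is d_i = r_i / (s_i + s0): for the paired
one-class design r_i is the mean per-pair log-ratio and s_i its standard
error (SD/√n); for the unpaired two-class design r_i is the group mean
difference and s_i the pooled standard error. The fudge factor s0 is
chosen from the {0, 5, …, 100}-th percentiles of the s_i distribution as
the candidate minimizing the coefficient of variation of the windowed
median-absolute-deviation spread of d (probes windowed by s_i quantiles,
MAD scaled by 1/0.64) — the published tuning recipe. Degenerate inputs:
all s_i zero yields a small positive floor (logged); a spread-free s_i
distribution yields the 0th percentile (logged).

The permutation null flips the sign of each pair's ratio (one-class; all
2^n assignments enumerated when 2^n ≤ n_perm, otherwise n_perm draws) or
shuffles class labels (two-class). Significance uses the order-statistic
construction: observed d sorted against the permutation-averaged sorted
d̄; for a threshold Δ the upper cut is the smallest observed d among
probes with d − d̄ ≥ Δ on the d̄ ≥ 0 side (mirrored below), and every
probe beyond a cut is called. The estimated FDR at Δ is the **average**
across permutations of the count of permuted d values beyond the cuts,
divided by the observed count, with the null proportion π0 fixed at 1
(conservative). The mean — rather than the per-permutation median — is
deliberate: the median estimator returns 0 for any single-probe selection
whose cuts exceed the typical permutation extreme, which lets lone
null-tail probes through at "FDR 0"; the averaged count penalizes exactly
those selections, and is what the original published recipe computes. The
selection threshold is the smallest Δ (over the full set of |d − d̄|
values, located by a coarse quantile scan plus exact refinement within
the bracketing interval) whose estimated FDR is at or below the cutoff;
when no probe is selectable the selection is empty, not an error.

The malignancy signature wraps this in a leave-one-pair-out consensus:
SAM runs on the full matrix and on each n−1-pair submatrix (independent
sub-seeds from one seed), and the final call requires selection in 100%
of the leave-one-out runs **and** a mean linear fold change of at least
1.5. Fold change is the geometric mean of the per-pair T/N ratios,
reported as a signed linear value (−2 means 2-fold down). The full-data
run is reported alongside but does not gate the final set.

The survival signature intersects a two-class SAM run (FDR < 10%) with
the Golub score P(g) = (μ1 − μ2)/(σ1 + σ2) (sample SDs; genes with zero
pooled SD are excluded and logged). The Golub permutation p-value uses
(b + 1)/(m + 1) smoothing so p is never zero. Samples are ordered by the
Pearson correlation of their signature-gene profile with the mean profile
of the deceased group.

## Co-expression

Spearman ρ is the Pearson correlation of average ranks (tie-aware), with
the two-sided p from the t approximation at n − 2 df; constant vectors
are flagged and skipped. The cis screen pairs each lncRNA with its own
host-locus mRNA and passes at strictly |ρ| > 0.5 with p < 0.05; the trans
screen pairs the top-20% most abundant lncRNAs (abundance = mean
normalized intensity; ⌊0.2·N⌋ kept, boundary ties broken by id order and
logged) against all mRNAs of other loci and passes at inclusively
|ρ| ≥ 0.7 with p < 0.05. The asymmetric strict/inclusive conventions
follow the printed inequalities literally. Same-locus pairs are excluded
from trans testing, so cis and trans record sets are disjoint by
construction.

The module map tests, per (lncRNA, GO term), the hypergeometric
upper-tail probability of the overlap between the lncRNA's correlated
mRNAs and the term's genes within the background universe, Bonferroni-
corrected over the terms tested for that lncRNA. An enriched cell is
signed +1/−1 by the majority correlation direction of the overlapping
mRNAs; direction ties resolve to the side with the larger mean |ρ| and
are logged. Annotation is a flat gene→terms map — no ontology-graph
propagation.

With only 4 tissue values a rank correlation cannot reach p < 0.05 under
the t approximation except at |ρ| = 1, where the approximation degenerates
(p → 0 although a random tie-free pair is perfectly monotone with
probability 2/4! = 1/12). The pipeline accepts n = 4 inputs unchanged,
but the synthetic panel generates 16 pseudo-tissue columns (4 tissues ×
4 pools, matching the pooled hybridization design) so that power and
null-calibration tests are statistically meaningful.

## TSS-proximity mark enrichment

Coordinates are 0-based half-open throughout (BED native); printed
1-based inclusive tables are converted on ingestion. The TSS of a +
strand interval is its start, of a − strand interval its last covered
base (end − 1); unstranded intervals have no TSS. For each query TSS the
unsigned distance to the nearest mark on the same chromosome is recorded
(0 when a mark covers the TSS), capped at `max_dist` = 10 kb; queries
with no mark in range are tallied separately. Distances are binned at
1 kb for reporting, and a 5-kb re-capped view is reported alongside the
10-kb window since both appear in practice. KS tests run on the raw
distances, not the binned histograms; the binning is reporting only.

Controls are 10 random interval sets carrying exactly the query length
multiset, placed uniformly over the genome (chromosomes weighted by
length) with rejection of any interval touching an exclusion zone (e.g.
1 kb upstream of known gene starts); placement failure after bounded
retries is an error naming the offending length. Scored (CAGE-like)
tracks are pre-filtered to score ≥ 1 before distance computation.
Enrichment is claimed only when the two-sample KS test (asymptotic
p-values) rejects against **all** control sets at the stated α.

## Specificity and conservation

F.E.T. is a transcript's FPKM in one tissue divided by its summed FPKM
across tissues; max F.E.T. ≥ 0.5 (boundary inclusive) flags tissue
specificity, all-zero rows are flagged not-expressed, and the vector is
invariant to rescaling the row. Specificity rates of lncRNAs vs mRNAs,
conserved-element overlap vs each random control set, and syntenic
overlap vs a null query set are all compared with two-sided Fisher exact
tests (sidedness is unstated in the modeled analysis; two-sided is the
conservative choice, and per-control testing with an all-controls verdict
is used rather than pooling). Overlap calls require ≥ 1 bp half-open
intersection; per-query overlap lengths are the clipped union of
overlapping elements. Cross-species expression conservation is a boolean
hit matrix (query × species) summarized as the fraction of queries hit in
at least one species; syntenic overlap consumes intervals already lifted
to the query assembly — coordinate mapping itself is out of scope.

## Concordance bookkeeping

Fold changes are signed linear values (sign = direction in tumor) and are
never mixed with log2 ratios implicitly. Host genes count as altered only
at strictly |FC| > 1.5; concordance means equal sign with the lncRNA;
missing hosts are skipped, and the "(x/y)" study-count suffixes and
bold/star markup of the transcribed table are parsed into metadata
without entering the rule. Percentages round half-away-from-zero by
default; a truncation mode exists because one published figure (142/170 →
83%) is reproducible only by truncation, and silently changing the global
rounding would misreport the rest.

## Synthetic cohort

The generator emulates the study design: 11 tumor/nontumor pairs measured
on a 4k-style array (722 intronic-lncRNA, 262 lincRNA, 2371
protein-coding probes and 100 negative controls by default), log2
intensities Normal(μ_class, noise_sd) with μ = 10 for expressed probe
classes (per-probe baseline SD 1), μ = 6 for negative controls, a
patient random effect (SD 0.3) shared by both members of a pair, and
noise_sd = 0.5. Planted differential expression shifts tumor columns of a
chosen lncRNA fraction by ±planted_log2fc (default 1.0, i.e. 2-fold — the
scale of the stronger half of the published signature; the smallest
allowed value is log2(1.5), the selection rule's own floor). Survival
association shifts the deceased group's tumor columns for a disjoint
probe subset. For survival power tests the emulated cohort is 16 tumors
(8 dead / 8 alive, the published outcome design) with a 1.5 log2 effect
(2.8-fold): at a 2-fold effect the Golub p < 0.01 filter has theoretical
power near 0.67 at n = 8 + 8, so a cohort of that size can only have
yielded a signature from larger effects.

The toy genome is interval-only (no sequence — no stage reads
nucleotides): host genes laid out on a configurable number of
chromosomes, each with a central intron wholly containing its antisense
lncRNA (250–600 bp, opposite strand); a genome too small to hold one gene
per lncRNA raises a generation error. Mark tracks (CAGE-like with RPKM
scores, CpG-like, histone-like) place one mark per marked TSS at an
Exponential(mark_decay_bp = 500 bp) distance plus one uniform background
mark per lncRNA; cis pairs share a latent cross-tissue profile (sign ±1)
with SD-0.5 noise; trans modules share a common factor between one lncRNA
and its member mRNAs (members never host cis-planted pairs, which would
overwrite the planted correlation); tissue-specific FPKM rows give one
tissue a 0.6–0.95 share; conserved lncRNAs contain a conserved element,
others at a 5% background rate, plus sparse scattered elements; species
cDNA tracks hit conserved lncRNAs at 0.5 (0.15 for the mouse track used
in synteny) versus half the background rate otherwise.

One global seed drives ordered per-stage sub-seeds, so identical configs
are byte-identical after serialization and each generator is reproducible
in isolation.

What the generator does **not** emulate — and hence what passing tests do
not establish about real arrays: spatial/image artifacts, dye effects and
intensity-dependent (loess-type) bias, probe cross-hybridization,
heavy-tailed intensity noise, correlated probe blocks beyond the planted
structure, realistic GO term-size distributions, and clustered genomic
features (CpG islands near real promoters, conserved-element clustering).
Results on real data depend on those properties; the tests establish
correctness of the statistics, not robustness to them.

## Problem sizes used in the test suite

Statistical tests run at reduced but honest scales chosen for stable
estimates: null calibration of the leave-one-out signature uses 20
replicates of 1000 lncRNA probes × 11 pairs at 1000 permutations; KS null
calibration uses 200 replicates of 200 + 200 distances; planted-recovery
runs use 400–1000 probes with sensitivity and false-discovery proportion
averaged over seeded replicates (a mean over 8 replicates estimates
sensitivity to about ±0.01, where a single replicate varies by ±0.04).
The acceptance script mirrors these sizes.

## Known limitations

- The t-approximation p-value for Spearman ρ is coarse below n ≈ 10 and
  degenerate at |ρ| = 1; an exact permutation p would be preferable for
  n = 4 inputs but is not what the modeled analysis used.
- The asymptotic two-sample KS p-value is approximate for small samples
  and conservative in the extreme tail; verdicts are made at α far above
  the approximation error.
- π0 = 1 makes the SAM FDR estimate conservative when many probes are
  truly changed.
- Quantile normalization's tie handling is exactly idempotent only on
  tie-free data; intensity data in floating point is effectively tie-free.
- The module map treats GO as a flat annotation; term relationships and
  annotation propagation are intentionally out of scope.
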