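# Methods

This note records the statistical procedures the package implements, the
defaults and why they were chosen, what the simulator does and does not
emulate, and the numerical conventions that a maintainer would otherwise
have to reverse-engineer from the code.

## Data model and coordinates

Genotypes are diploid dosages of `allele_b` in {0, 1, 2} with a `MISSING`
sentinel (-1) in an int8 samples × variants matrix, restricted to the 29
bovine autosomes. Positions are 1-based; intervals are closed; a
segment's length is `end_bp − start_bp`, the span between its first and
last SNP. This convention reproduces published consensus-region lengths
from their printed coordinates at two decimals (e.g. a 1.97 Mb segment
from 36,318,731 − 34,352,857 = 1,965,874 bp), which is how it was fixed.

PED/MAP text cannot carry allele orientation (the MAP file has no allele
columns), so the text writer also emits `<prefix>.alleles.tsv`; the reader
uses it when present and otherwise falls back to first-appearance
ordering. Sample metadata that FAM cannot hold (subgroup, herd, sire,
birth year, original chip density) travels in `<prefix>.meta.tsv`. Both
sidecars are optional, so foreign PLINK files read fine; round trips
through either format are exact.

## Quality control

Defaults follow standard SNP-chip practice for cattle panels: drop samples
with more than 10 % missing calls first, then variants with more than 10 %
missingness, minor allele frequency below 0.01, or exact Hardy–Weinberg
P below 1e-4. Filtering samples first makes the variant statistics — and
hence the attrition report — deterministic functions of the retained
cohort. A variant failing several tests is attributed to the first failure
in the order missingness → MAF → HWE.

The HWE test is the exact conditional test: given the observed allele
counts, the heterozygote count follows a known distribution over counts of
one parity; the two-sided p-value sums every configuration whose
probability does not exceed the observed one. Probabilities are built by a
vectorised ratio recurrence and cached per (n, minor-allele count);
configurations within a relative 1e-12 of the observed probability count
as ties. Agreement with a log-factorial full-enumeration oracle is below
1e-13 for every configuration with n ≤ 200.

LD pruning slides a 50-SNP window in 5-SNP steps along each chromosome;
while any retained pair in the window has r² > 0.6 (pairwise-complete
Pearson², undefined values treated as no-LD since a monomorphic column
carries no signal), the member with the smaller MAF is removed, ties going
to the later map position. The procedure is deterministic; an audit
re-scan of the output windows is part of the acceptance suite.

## Runs of homozygosity

Detection is the sliding-window method standard for array data. A 40-SNP
window moves one SNP at a time; a window is homozygous when it has at most
one heterozygote **and** at most one missing call (the two allowances are
independent — a window with one of each still passes). A SNP is in the
homozygous state when at least 5 % of the windows overlapping it are
homozygous; edge SNPs use only their existing windows in the denominator
(no padding). The 5 % incidence threshold is not fixed by the window
rules themselves; it is the convention of the sliding-window tools this
detector mirrors, and it is exposed as a parameter.

Maximal homozygous stretches are split at inter-SNP gaps above 500 kb
*before* the emission filters — a large gap interrupts the
identity-by-descent evidence, so each side must qualify on its own — and
kept when they span at least 40 SNPs and 1 Mb with on average at least one
SNP per 50 kb (`length/n_snps ≤ 50,000`). Heterozygous or missing SNPs
whose window proportion passes stay inside runs and count toward the SNP
total, which is what the per-window allowance implies for run content.
At 1 Mb, 40 SNPs and 50 kb/SNP these thresholds are mutually consistent
for panels of ≥ 40 SNPs/Mb (~100 K SNPs genome-wide and up); on sparser
maps the SNP-count floor binds first and short ROH become undetectable —
relevant when scaling simulations down.

`F_ROH` divides total ROH length by the map-covered autosome length
(per-chromosome last-minus-first SNP position, summed). Using map-covered
length rather than a fixed 2.5 Gb keeps the coefficient consistent across
panels and with the per-chromosome decomposition, which satisfies
`froh_genome · L_total = Σ_c froh_chrom[c] · L_c` exactly. Length classes
are left-closed right-open: [1,2), [2,4), [4,8), [8,16), [16,∞) Mb — the
boundary convention is ours, as printed class labels overlap at integers.

Consensus regions are computed per subgroup on the intervals between
consecutive SNP positions: an interval counts as covered for an individual
when one of their ROH spans it, and maximal stretches covered in strictly
more than 30 % of the subgroup ("more than" is strict — 3 of 10 does not
qualify) are emitted, snapped to SNP positions. Identical regions arising
in several subgroups merge into one record.

## Substructure

Genotypes are mean-imputed per variant, mean-centred and not scaled (the
default of the classical DAPC formulation; scaling is a flag). PCA is an
SVD of the centred matrix; eigenvalues are score variances (divisor
n − 1); loading signs are fixed so each column's largest-magnitude entry
is positive, making results reproducible to the byte.

The cluster-number scan runs K-means (Lloyd) for K = 1..20 with ten
seeded random-data-point initialisations per K plus one warm start from
the previous K's centers augmented by the farthest point — the warm start
guarantees WSS(K) is non-increasing. The criterion is the
spherical-Gaussian profile likelihood `BIC(K) = n·ln(WSS_K/n) + K·ln(n)`,
with consecutive differences ΔBIC and ΔBIC > 2 read as strong evidence.
This penalty is calibrated for the many-PC regime the scan actually runs
in (about 100 retained PCs); in very low-dimensional score spaces K-means
can chase noise faster than `ln n` penalises it, so the scan should not be
fed fewer than a few dozen components.

DAPC solves the generalized eigenproblem of between- versus pooled
within-group scatter in the retained-PC space; a singular within matrix is
ridge-regularised (ε = 1e-8 · trace/d) with a warning. Reported
eigenvalues are between/within scatter ratios (scale-free); axes are
scaled so the pooled within-group covariance in discriminant space is the
identity, which reduces the assignment posterior to softmax of
`log prior − ½‖z − μ_g‖²`. Priors are proportional to training group
sizes — equal priors in a balanced design, sensible behaviour otherwise.
Held-out samples are always centred with the *training* variant means and
projected through the training basis; the PC count for prediction is
chosen by stratified cross-validation (RMSE of 1 − assignment success over
replicates, ties to the smaller count), and pairwise separability is
scored by stratified 80:20 splits repeated 10 times with a single
discriminant axis.

## Simulator

`simulate_subpopulations` draws ancestral frequencies Uniform(0.05, 0.95),
subgroup frequencies Beta(p(1−F)/F, (1−p)(1−F)/F) with F the divergence
parameter (the Balding–Nichols model; F = 0 short-circuits the Beta), and
genotypes Binomial(2, p_pop), independent across SNPs. A
Weir–Cockerham multilocus estimate on the simulated data recovers F
within ±0.01 in the test suite. `inject_autozygosity` places
non-overlapping exponential-length tracts uniformly on the map-covered
spans until a target genome fraction is reached, making every in-tract SNP
homozygous for an allele drawn from the subgroup frequency (so allele
structure inside ROH is preserved). `perturb` adds missingness and
hom→het genotyping errors, the error mode that interrupts runs.
`simulate_herd_cohort` combines these with breeding metadata (herds,
sires, birth years, chip densities, including filter-ineligible records)
targeting Normal(0.065, 0.015) autozygous fractions with 2.11 Mb mean
tracts — genomic inbreeding and mostly-short ROH in the range typical of
intensively selected dairy cows. Defaults mirror the cohort design the
pipeline targets (five subgroups of 200 on 29 autosomes totalling
~2.5 Gb); the default SNP count (15,000) and the divergence default
(F = 0.03, chosen once as "subtle but detectable" since no within-breed
F_ST is established for this design) are package choices.

What the simulator does **not** emulate: linkage disequilibrium within
subgroups (SNPs are independent given frequencies), pedigree or
sire-sharing structure, allele-frequency clines, and genotyping batch
effects. Passing tests therefore demonstrate correctness of the
algorithms and their calibration under the stated generative model, not
performance on real LD-structured data; in particular LD pruning removes
almost nothing from simulated panels unless LD is manufactured.

## Numerical and procedural choices

- All stochastic operations take explicit seeds; repeated runs are
  byte-identical, which the acceptance suite verifies end to end.
- Cohort filters apply strictly in order: subgroup defined → chip density
  ≥ 50 K → birth year 2014–2018 → drop herd-years with < 10 genotyped
  cows, cap 10 per herd × subgroup (seeded draw), then a seeded draw of
  200 per subgroup. Capping precedes the final draw.
- The one-way ANOVA of F_ROH uses the classical sums-of-squares
  decomposition; identical zero-spread inputs raise rather than return an
  undefined F, and the pipeline skips the statistic with a warning in
  that case (e.g. a cohort with no ROH at all).
- Sire-count summaries report an integer-rounded mean and the population
  (divide-by-n) standard deviation; animals-per-herd uses two decimals.
  These conventions reproduce reported breed-report values exactly.
- The ROH branch of the pipeline consumes the full post-QC panel; only
  the structure branch sees the LD-pruned panel.
- Test problem sizes (scaled 1/10 maps at ≥ 40 SNPs/Mb, 3–5 subgroups of
  15–100, 2,000–12,000 SNPs) were chosen so each property is measured in
  the regime where its thresholds are meaningful; full 310 K-scale panels
  are supported but not exercised by the suite.

## Known limitations

- The sliding-window detector is not an HMM; very short or mutation-
  interrupted autozygous segments below the SNP-count/length floors are
  invisible by design.
- At zero divergence the pairwise hold-out repetitions share one dataset,
  so their accuracies are positively correlated; a single run's mean can
  sit slightly outside a naive independent-binomial band around 0.5 even
  though it is unbiased across datasets.
- The spherical BIC is a model-selection heuristic; with strong
  non-spherical structure (e.g. admixture clines) it can over- or
  under-count clusters, which is why DAPC validation accompanies it.
- `descriptive_report` assumes complete metadata; records with missing
  herd or sire identifiers should be resolved upstream.
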