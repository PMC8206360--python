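# rohstruct

Runs-of-homozygosity and within-breed population-structure analysis for
SNP-chip genotypes.

Intensively selected livestock breeds can quietly split into genetic
subgroups when different production contexts (for dairy cattle: drinkable
milk versus the various protected-origin cheese consortia) steer breeders
toward different sire lines. The divergence is far too subtle for
classical between-breed tools, so detecting it takes two complementary
lenses on dense genotype data:

- **Autozygosity.** A run of homozygosity (ROH) is a contiguous stretch of
  homozygous SNP calls, evidence that both haplotypes descend from a
  recent common ancestor. Summing ROH length over the 29 bovine autosomes
  gives the genomic inbreeding coefficient
  `F_ROH = Σ length(ROH) / L_autosomes`, and intervals homozygous in a
  large fraction of a subgroup ("consensus regions") flag shared selection
  targets.
- **Substructure.** After LD pruning, genotypes are projected onto
  principal components; the number of clusters K is scanned with K-means
  under `BIC(K) = n·ln(WSS_K/n) + K·ln(n)` (ΔBIC > 2 between consecutive
  K read as strong evidence), and the subgroup labels are assessed with
  discriminant analysis of principal components (DAPC): a linear
  discriminant classifier in the retained-PC subspace, validated by
  stratified 80:20 hold-out splits for every subgroup pair.

The package implements the full pipeline — PLINK PED/MAP and BED/BIM/FAM
I/O, variant/sample QC (MAF, missingness, exact Hardy–Weinberg test),
windowed r² pruning, sliding-window ROH detection, F_ROH, consensus
regions, PCA/K-means-BIC/DAPC, cohort-sampling filters and one-way ANOVA
of F_ROH — plus a seeded Balding–Nichols herd simulator, so every stage
can be exercised and calibrated against known ground truth even though
real breed-association genotypes are typically access-restricted.

## Worked example

```python
import rohstruct as rs
from rohstruct.simulate import CATTLE_CHROM_LENGTHS_BP

# three subgroups of 60 cows, scaled 29-autosome map, subtle divergence
scaled = tuple(l // 10 for l in CATTLE_CHROM_LENGTHS_BP)
params = rs.SimParams(n_pops=3, n_per_pop=60, n_snps=8000, fst=0.04,
                      seed=42, chrom_lengths_bp=scaled)
dataset, truth = rs.simulate_herd_cohort(params)

dataset, report = rs.apply_qc(dataset)
segments = rs.detect_roh(dataset)
froh = rs.froh_table(segments, dataset)

labels = dataset.samples["subgroup"].to_numpy()
_, scores = rs.pca_genotypes(dataset, n_components=80)
scan = rs.kmeans_bic_scan(scores, k_max=10, seed=42)
model = rs.dapc_fit(scores, labels, n_pcs=40)
assign = rs.reassignment_accuracy(
    rs.dapc_predict(model, scores, kind="scores"), labels)
pair = rs.pairwise_external_validation(dataset, labels, ("AS", "DM"),
                                       n_pcs=30, seed=42)
```

Output:

```
QC: 7929 SNPs retained (6 failed MAF, 65 failed HWE)
ROH: 968 segments, mean F_ROH = 0.068
BIC scan: k_best = 3
DAPC reassignment accuracy = 1.000
AS vs DM hold-out accuracy = 1.00 (sd 0.000)
```

The simulator injected autozygous tracts targeting a mean genome fraction
of 0.065, and the detector recovers a mean F_ROH of 0.068 on the dense
map. The BIC scan finds exactly the three simulated subgroups, and DAPC
separates them perfectly at this divergence and SNP count — on real
within-breed data both statistics sit far lower, which is precisely what
they are designed to quantify.

The same stages are available from the shell:

```sh
rohstruct simulate --out-prefix herd --n-pops 5 --n-per-pop 200 --seed 1
rohstruct qc --prefix herd
rohstruct roh --prefix herd
rohstruct structure --prefix herd --k-max 20
rohstruct validate --prefix herd --n-pcs 50
rohstruct run --config pipeline.yaml --seed 1
```

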