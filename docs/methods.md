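# Methods

This note documents the statistical models implemented in `rnapopstruct`,
the parameter defaults and why they were chosen, what the synthetic-data
generator does and does not emulate, and the numerical decisions that a
maintainer would otherwise have to reverse-engineer from the code.

## Genotype model and I/O

Genotypes are biallelic SNP dosages (copies of the alternate allele,
{0, 1, 2}) with a single missingness sentinel. Only biallelic SNP records
with FILTER `PASS` or `.` are read from VCF; multi-allelic records, indels
and soft-filtered records are skipped and counted. Half-calls (`./1`) are
treated as missing — the conservative choice, since a half-call carries no
usable dosage. Phase is ignored. Chromosome labels are normalized by
stripping a leading `chr`; positions are 1-based throughout.

## Quality control

Filters apply in a fixed order (autosomal SNP, duplicate, palindromic,
excluded region, call rate, MAF, HWE), each variant counted once at the
first rule that removes it, which makes removal counts conserve:
removals + kept = input. Defaults:

| parameter | default | meaning |
|---|---|---|
| `maf_min` | 0.05 | keep MAF strictly > 0.05 (PC stage; 0.01 for the calling-stage filter) |
| `geno_max` | 0.1 | max per-variant missing fraction |
| `mind_max` | 0.2 | max per-sample missing fraction; removal is strict (> 20%) |
| `hwe_min_p` | 0 | 0 disables the HWE filter (PLINK semantics) |
| `window`, `step` | 1000, 50 | LD-pruning window/step in **variant counts** |
| `r2_max` | 0.05 | pairwise r² threshold |
| excluded region | chr6:25,000,000–34,000,000 | extended MHC/HLA, half-open (GRCh38); the region is conventionally named without exact coordinates, so these are fixed here |

MAF comparisons are strict (`>`), matching the "MAF > 0.05" convention;
the sample-missingness rule removes only samples *above* the threshold.
These boundary semantics are tested explicitly.

The Hardy–Weinberg test is the two-sided exact test: conditional on the
genotype total and minor-allele count, heterozygote counts whose conditional
probability is no larger than the observed one are summed. Probabilities are
computed in log space; a 1e-10 relative guard absorbs floating-point ties
between symmetric configurations. The implementation agrees with an
exact-rational full enumeration to < 1e-12 for all configurations with
total ≤ 50.

LD pruning slides a window of `window` variants by `step` per chromosome;
within a window the highest-r² pair above threshold is found repeatedly and
the lower-MAF member removed (tie: the later-positioned variant). r² is the
squared Pearson correlation of dosages on the pairwise-complete (both
non-missing) support. The guaranteed post-condition — no kept pair
co-occurring in any window exceeds the threshold — is scanned directly in
tests. The greedy victim rule is a fixed, documented choice, not a claim of
maximum-cardinality optimality: on chain structures where the middle variant
has the lowest MAF it coincides with the exhaustive optimum (tested), but
adversarial MAF orderings can make it keep fewer variants than the best
subset.

## Harmonization

Matching is by (chrom, pos) only; the allele pairs then decide orientation:
direct, swap (dosage recode d → 2−d), strand flip (Watson–Crick
complement), or flip+swap. Palindromic (A/T, C/G) variants are categorically
excluded — flip and swap are indistinguishable for them without allele-
frequency heuristics, which are deliberately not used. Concordance uses the
genotype-level comparison (heterozygote equals heterozygote regardless of
phase) over calls non-missing in both sources; sample pairs with no
comparable call are flagged and excluded from the cohort mean. Panel
intersection keeps variants whose position and allele pair match a panel
entry under any of the four orientations, without reorienting (orientation
does not affect PCA of dosages on the matched set).

## PCA and the GRM

Standardization is binomial: z = (g − 2p)/√(2p(1−p)) with p the cohort
alternate-allele frequency from non-missing calls; missing calls are
mean-imputed to z = 0 (the standard genotype-PCA choice). Monomorphic
variants are an error by contract — the MAF filter must run first.
Eigenvalues are those of (1/m)ZZᵀ from an exact dense SVD; per-sample scores
are eigenvectors scaled by √(n·eigenvalue). Score scaling is cosmetic for
all downstream analyses here (Spearman and CCA are scale-invariant) but is
fixed and documented so outputs are stable. The sign convention — the
largest-magnitude loading of each component is made positive — makes reruns
bit-identical. Joint PCA of two cohorts harmonizes the variant intersection,
stacks the samples and re-estimates frequencies on the merged cohort (rather
than projecting one cohort onto the other's axes; a projection mode is out
of scope). GRM = ZZᵀ/m on the same standardization.

## PC-set agreement

Spearman correlations use mid-ranks and the t approximation for p-values
(exact permutation is unnecessary at the n of interest). CCA is computed
through orthonormal bases of the centered blocks (SVD of the cross-product
of the bases), which makes it invariant to invertible re-mixing of either
block and numerically stable; rank-deficient blocks reduce the number of
canonical dimensions with a warning. Sequential significance uses Wilks'
Λₖ = Π_{i≥k}(1−R²_ci) with Bartlett's chi-square approximation
−(n − 1 − (p+q+1)/2)·ln Λₖ on (p−k+1)(q−k+1) df — the simplest standard
form; Rao's F would differ negligibly at these sample sizes. Λₖ = 0
(a perfect correlation) is reported as an underflow-flagged minimal p-value.

"Shared variance" is operationalized as the redundancy index: for variate i,
Rd_i = R²_ci × mean squared correlation between Y's standardized columns and
Y's i-th canonical variate, accumulated over variates. This is the main
interpretive decision in the module — the quantity is conventionally
reported but has no unique definition — so the raw R²_ci are always reported
alongside, and the direction of interest (how much array-PC structure the
RNAseq-derived variates capture) is the documented default in the pipeline.

## Expression association and inflation

Gene filtering keeps genes with CPM strictly above 0.05 in at least
ceil(0.2·n) samples (library sizes from the unfiltered matrix), optionally
autosomal-only. The association engine is a per-gene OLS on
log2((count + 0.5)/(libsize + 1)·10⁶) with [intercept, trait, covariates,
PCs] — a deliberate, documented divergence from negative-binomial GLM
engines: the claims here concern the PC-adjustment contract and the m
statistic, which are engine-agnostic, and the per-gene chi-square is defined
from the two-sided p-value (z² convention) precisely so that m is comparable
across engines. Multiple testing uses Benjamini–Hochberg.

The inflation metric is m = median(χ² with PCs)/median(χ² without PCs) on
the identical gene set. m < 1 after adjustment indicates stratification was
inflating the statistics. Two subtleties observed on synthetic truth and
worth knowing:

- m < 1 requires the trait to actually be confounded with ancestry; with a
  perfectly balanced trait and no ancestry-affected genes, m ≈ 1.
- With ancestry-affected genes present but the trait balanced, m rises
  *above* 1: the PCs absorb ancestry variance in those genes, shrinking
  their residuals and sharpening their trait statistics. That is a precision
  gain, not stratification, which is why the "balanced null" reference
  scenario in the acceptance experiments sets both the sex–ancestry
  imbalance and the confounded-gene fraction to zero.

## Mixed model

y = Xβ + g + ε with g ~ N(0, σ²_g·GRM), ε ~ N(0, σ²_e·I). The GRM is
eigendecomposed once; in the eigenbasis the REML log-likelihood is profiled
over the variance ratio λ = σ²_g/σ²_e on a log-spaced grid (1e-4…1e4, plus
the λ = 0 boundary) refined by golden-section search to 1e-6 on the
log-likelihood. Fixed effects and Wald statistics come from GLS at the
optimum. In the GRM = I limit σ²_g and σ²_e are not separately identifiable;
the implemented contract is that their sum equals the OLS residual variance
and the Wald statistics equal OLS (tested to 1e-6). The association scan
estimates variance components once under the null model and tests each
(mean-imputed) variant by GLS with components fixed. PCs enter the scan as
fixed effects — the conventional usage — even though they are sometimes
described as random effects; the discrepancy is noted rather than silently
resolved.

## Synthetic-data generator

Balding–Nichols: ancestral frequency p ~ Uniform(0.05, 0.95) per variant;
per-population p_k ~ Beta(p(1−F)/F, (1−p)(1−F)/F) (F = 0 degenerates to
shared frequencies, no Beta draw); genotypes Binomial(2, p_k); positions
uniform on chromosomes 1–22; 5% palindromic variants by default to exercise
the QC path. Defaults for the paired views: the array view is a 60% variant
subset with 1% missingness; the RNAseq view is a 20% "transcribed" subset
with 5% base per-call missingness scaled by a per-sample log-normal depth
factor, 2% dosage-level genotype error (an erroneous call becomes one of the
other two dosages uniformly), and 10% of variants reported on the
complementary strand (half of those also ref/alt-swapped). Expression counts
are negative-binomial (gamma–Poisson, dispersion 0.2) with log-normal
library sizes (~2M reads), 10% ancestry-confounded genes and 5%
sex-associated genes at |log2FC| = 1, with truth labels recorded.

What this emulates: discrete subpopulations at a stated Fst, transcribed-
region ascertainment, depth-dependent missingness, dosage-level genotype
error, strand ambiguity, and ancestry-confounded expression. What it does
not: admixture or continuous clines, LD from shared haplotypes (variants are
independent given population frequencies, so LD pruning on simulated data
removes only structure-induced correlation), read-level error processes, and
eQTL architecture. Passing tests therefore demonstrate the correctness of
the statistical machinery under the stated model, not performance on real
read data.

## Problem sizes in the reference experiments

The reference experiments (`rnapopstruct.experiments`, driven by
`scripts/acceptance.py` and the acceptance tests) use: 3 populations ×
50–100 samples at Fst 0.1 with 2000–5000 variants for concordance,
structure-recovery and CCA; 2000 genes × 200 samples for the inflation
scenarios; 50 replicates at n = 200 with a 2000-variant GRM for the
variance-ratio recovery; and full enumeration to genotype totals of 50 for
the HWE oracle. These sizes give stable statistics at interactive runtimes
on a single core.

## Known limitations

- The LD pruner's greedy rule is deterministic and tested, but other tools'
  internal tie-breaking may keep a slightly different variant set at equal
  thresholds.
- The DGE engine is a log-CPM linear model; dispersion-aware NB engines will
  give different per-gene p-values (the m statistic is designed to be
  comparable anyway).
- No out-of-sample PC projection with shrinkage; joint PCA re-fits on the
  merged cohort.
- Case/control-stratified HWE filtering, IBD-based relative removal,
  frequency-based palindromic resolution and genotype imputation are out of
  scope.
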