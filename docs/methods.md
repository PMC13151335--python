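# Methods

This note documents the statistical models implemented in `stratgen`, the
defaults and why they were chosen, what the synthetic cohort does and does
not emulate, and the numerical conventions that matter for reproducing
results.

## Genotype handling and QC

Dosages count copies of the recorded effect allele and live in [0, 2];
missing genotypes are `nan` in stored matrices and are mean-imputed per
variant only inside scoring and regression operations.  Variants are keyed
by (chrom, pos, sorted allele pair), so an allele swap between two files
identifies the same site; rsIDs are labels only.  Coordinates are 1-based
inclusive everywhere (BED is converted on read).  Scope is biallelic SNPs;
indels and multi-allelic records are skipped on read with a count.

Harmonization against a reference set of summary statistics keeps matched
variants, recodes swapped-allele variants as `2 − d` (which leaves every
downstream association statistic unchanged — unit-tested), and removes
strand-ambiguous A/T and C/G pairs, whose orientation cannot be resolved
from allele labels.

Variant QC removes monomorphic sites, sites with > 5% missingness, and
sites with exact Hardy–Weinberg p < 1e-12 computed on hard calls (dosages
rounded at 0.5/1.5; dosage-only data skips the HWE filter with a log
entry).  The exact HWE test uses the standard conditional-distribution
recurrence; it is hand-coded because no installed package exposes it, and
is verified against a direct log-gamma enumeration.  MAF filters use a
strict `>` comparison (a variant at exactly the threshold is excluded)
and cis-window membership is a closed interval; both boundaries are
unit-tested.

## Expression processing

Pseudobulk counts are exact per-individual sums of nucleus-level UMIs for
one cell-type; individuals with zero nuclei of that type are excluded and
flagged.  Expressed genes require TPM > 0.1 (union-exon lengths from the
annotation) and ≥ 6 raw counts in > 20% of individuals; the DE gene
universe additionally keeps only genes within the top 90% of cumulative
total reads, applied after the other two filters (the order is
configurable; applying it first changes the set only marginally at
realistic depth).

TMM scale factors follow the trimmed-mean-of-M-values algorithm: the
reference sample is the one whose upper quartile of nonzero count
fractions is closest to the mean upper quartile; per sample, M-values are
trimmed 30% and A-values 5% on each side, weighted by inverse asymptotic
binomial variances, and factors are rescaled to geometric mean 1.  The
implementation reproduces `edgeR::calcNormFactors(method="TMM")` to ~1e-10
on random count matrices; a frozen 8×4 fixture from that comparison is in
the test suite.  TMM assumes the majority of genes are not differential
between samples — synthetic designs that make most genes sex-differential
will push the module signal into the normalization (this bounded the
demo's module size at 25 of 150 genes).

The inverse-normal transform is `Φ⁻¹((rank − 3/8)/(n + 1/4))` (Blom
offset, configurable), average ranks at ties, missing values preserved,
error on constant vectors.

The number of expression PCs comes from permutation parallel analysis:
each permutation shuffles values within each gene, eigenvalues of the
permuted matrices form the null, and components are retained sequentially
while the add-one permutation p-value `(1 + #{λ_perm ≥ λ_obs})/(B + 1)` is
≤ α (defaults B = 50, α = 0.05).  The add-one p-value rule is used rather
than a raw 95th-percentile cut because it is valid (never
anti-conservative) at any permutation count; with the percentile rule the
per-dataset probability of spuriously retaining a component is exactly α.

## Differential expression

Per gene, log-CPM is regressed on the tested outcome plus covariates
(age, global ancestry, BMI, sex, nucleus count — minus the tested
outcome); continuous outcomes are inverse-normal transformed upstream.
The fit is plain OLS, optionally with precision weights from a lowess
trend of √(residual SD) on mean log-count.  No empirical-Bayes moderation
of the variance is applied: at pseudobulk sample sizes (tens of
individuals) moderation changes little, and the unmoderated t is exactly
checkable against a normal-equations oracle, which the tests do.
Significance is BH-FDR q < 0.1.  Gene-set overlaps use two-sided Fisher
exact tests on the 2×2 cross-classification of a gene universe, with a
Haldane 0.5 correction for the reported odds ratio when a cell is zero.

## cis-eQTL mapping

Expression (INT) is regressed on dosage plus covariates for every
MAF > 0.10 variant within gene body ± 500 kb.  Computation residualizes
expression and dosages against the covariates once and then runs marginal
regressions with degrees of freedom n − (covariates + 2) — exactly the
Frisch–Waugh equivalence with the joint fit, verified to 1e-8 against
statsmodels.  FDR is BH over all tested pairs within a cell-type (pooling
across cell-types is available by flag; within-cell-type is the default
because each cell-type's scan is a separate screen).  Lead pairs per gene
break p ties by larger |t| then smaller position, for determinism.
Sharing classes: `specific` = significant in exactly one cell-type,
`shared` = in all tested, `partial` otherwise.  Replication recomputes
FDR over only discovery-significant pairs present in the replication
scan and requires a concordant sign; eGenes with no overlapping pairs are
`untested`.  An alternate 1-Mb window anchored at the TSS is available
via `windows_from_annotation(anchor="tss")`.

## Colocalization

Wakefield log-ABFs use the quantitative-trait prior W = (0.15·sdY)², with
sdY estimated from each trait's own summary statistics via the
weak-effect identity var(Y) ≈ n·se²·2·eaf(1−eaf), median over variants.
Hypothesis masses are L0 = 1, L1 = p1·ΣABF₁, L2 = p2·ΣABF₂,
L3 = p1·p2(ΣABF₁·ΣABF₂ − Σ(ABF₁ABF₂)), L4 = p12·Σ(ABF₁ABF₂), all in log
space (log-sum-exp), so z-scores in the tens are stable; the L3
cancellation at degenerate single-variant regions is clipped at zero with
a warning.  Variants present in only one trait are dropped at the
intersection.  The region screen requires a significant eQTL (q < 0.1), a
GWAS variant at p < 5e-8, and at least one variant in the > 10%
allele-frequency-difference bin within the cis window.  The GWAS standard
errors are used as supplied (no genomic-control rescaling of ses).

## F_ST

The two-population Weir–Cockerham estimator computes per-locus variance
components a (among populations), b (among individuals within
populations) and c (within individuals) from sample sizes, allele
frequencies and observed heterozygote proportions on hard calls; loci
monomorphic in the pooled sample contribute nothing and are excluded from
the ratio.  The multi-locus estimate is the ratio of sums Σa/Σ(a+b+c) —
not the mean of per-locus ratios, which the tests distinguish explicitly;
a mean-of-ratios variant is exposed for comparison only.  Set enrichment
draws size-matched variant sets without replacement from the background
and uses the add-one permutation p.  An equal-size subsampling helper
(seeded) matches cohort sizes before comparison.

## Partitioned PRS and interactions

Clumping visits GWAS variants in ascending p order and removes variants
within 250 kb at r² > 0.1 with a retained index variant (defaults follow
common clumping practice; ties in p break by input order).  All clumped
set variants are scored with no p-value threshold (set-based scoring);
the set is the clumped variants inside the union of the gene set's cis
windows, counted once.  The enrichment statistic is incremental R² (full
minus covariate-only fit), and the competitive null rebuilds the score
and R² for size-matched random sets from the clumped background of all
expressed genes' windows; permutation draws are without replacement
within a draw and independent across draws from seeded substreams.  Total
cholesterol is divided by 0.8 for individuals on lipid-lowering
medication before normalization.  The targeted genotype×sex scan tests
variants genome-wide significant in exactly one sex stratum inside the
set windows, by OLS of the outcome on dosage + sex + dosage×sex +
covariates (male coded 1), BH-FDR q < 0.1.  The PRS×sex interaction uses
a sex-agnostic-weights score in the same joint fit.  Ties in the
competitive ranking use ≥ with the add-one correction, so p_comp is never
below 1/(n_perm + 1).

## Synthetic cohort: what it emulates, and what it does not

The generator reproduces the *design* of an admixed two-population
study: Balding–Nichols differentiation with a single F (default 0.1,
matching an AMR–European-scale contrast), admixture proportions
q ~ Beta(6.5, 3.5) (mean ≈ 0.65), planted cis-eQTL effects (default
β = 0.8 on a common variant per chosen gene), a female-upregulated
module (default log-fold effects 0.3–1.0, all female-up), and a
phenotype whose cis-region architecture can be male-only, sex-shared, or
null, with GWAS weights estimated in an independent base cohort (default
5,000; target cohort default 500 — the study scale reduced ~17×).
Negative-binomial pseudobulk counts use dispersion 0.3 and library sizes
proportional to Poisson nucleus counts; per-gene/individual log-noise SD
is 0.3.

Two calibration details matter for sex-specific architectures.  The
planted betas of one sex have a random nonzero sum, which shifts that
sex's mean genetic value — a sex main effect, not polygenic variance —
so the noise variance implied by h2 is set from the *within-sex* genetic
variance.  Likewise the sex-combined base GWAS adjusts the phenotype for
sex before the marginal regressions, as lipid GWAS pipelines do; without
it the between-sex mean gap inflates every marginal residual variance
and dilutes the emitted sex-combined weights.

Deliberately not emulated: linkage disequilibrium beyond independent loci
(clumping is exercised on engineered correlated pairs in tests, not in
the generator), realistic recombination maps, three-way admixture,
cell-type mixtures with ambient contamination, and batch structure.
Passing tests therefore demonstrate correctness of the estimators and
calibration of the permutation machinery under the stated generative
model — not robustness to LD leakage, population stratification beyond a
single admixture axis, or expression confounding present in real data.

## Numerical conventions

Degenerate inputs raise rather than warn wherever a silent default would
bias results (constant vectors into INT, empty QC output, single-variant
coloc regions, single-sex interaction cohorts).  Zero-variance scores
report R² = 0 with a warning.  All randomness flows from numpy
`SeedSequence` substreams of one master seed; pipelines and the
demonstration run are byte-deterministic given (config, seed).  Problem
sizes in the test suite (e.g. 500-gene × 20-variant null eQTL scans over
20 seeds, 200-replicate permutation calibrations at 200 permutations) are
chosen so Monte-Carlo error is small relative to the asserted bands while
the whole suite stays in a few minutes.
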