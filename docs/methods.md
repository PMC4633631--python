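# Methods

This note documents the statistical models, numerical choices and known
limitations of the package, in the order the pipeline runs them.

## Synthetic cohorts

The generator draws biallelic SNPs with allele frequencies uniform in a
configurable MAF range (default 0.05–0.5), genotypes binomial(2, f) per
individual, independent across SNPs. Optional LD is block-copying with
re-draw noise (each SNP in a block copies the anchor, individual entries
re-drawn with probability 1 − √r²), which produces a target pairwise r²
without claiming to model human haplotype structure. X-chromosome SNPs
are simulated with male dosages in {0, 2} (a single allele stored on the
diploid scale), i.e. full dosage compensation.

Phenotypes follow a liability-threshold model: causal effects for a pair
of traits are drawn from a bivariate normal with correlation `rg_true`
and per-trait variance h²/n<sub>causal</sub> *on standardized dosages*,
so each causal SNP explains an MAF-independent share of liability
variance — matching the standardization used by the GRM downstream.
Liability is genetic value plus independent N(0, 1 − h²) residual (no
shared-environment term, because the estimators assume additive genetics
plus independent residual); an individual is a case when liability
exceeds the upper-K standard-normal quantile. A designated "extended
MHC" SNP block can carry a configured fraction of the genetic variance.
With `exact_h2=True` the drawn effect vectors are rescaled by a per-trait
scalar so the realized Σβ² equals the h² target exactly instead of only
in expectation; with few causal SNPs the raw chi-square fluctuation has
relative SD √(2/n_causal) (≈ 0.32 at 20 SNPs), large enough to change the
study condition materially between seeds. The rescaling preserves
Corr(β₁, β₂). Recovery and prediction checks use this calibrated mode.

Ascertained studies are simulated in two stages: causal genotypes and
liabilities for a large latent population, then case/control selection,
then the non-causal SNPs drawn only for the selected individuals. Null
SNPs are independent of the phenotype, so deferring them leaves the joint
distribution of (genotypes, phenotype) unchanged while keeping memory at
desk scale even for prevalences of 10⁻².

Comorbid individuals (cases for both traits of a pair) are assigned to
the smaller cohort by post-assignment size, ties to the lexicographically
smaller disease code, computed by fixed-point iteration; controls are
cases for neither trait.

QC artifacts are injected in a fixed order: Balding–Nichols population
structure (subpopulation frequencies Beta-distributed around f with
variance F·f(1−f)), Hardy–Weinberg violations (excess homozygosity,
inbreeding F = 0.5), related individuals (offspring rows appended via
Mendelian transmission from random parent pairs), then uniform and
case-dependent missingness. Structure and HWE injection re-draw
genotypes, so artifact injection is for exercising QC and the structure
stages, not for phenotype analyses.

## Quality control

SNP filters run in a fixed order with per-stage counts logged: call rate
< 0.95; MAF < 0.01; Hardy–Weinberg exact test P < 0.01 computed in
controls only (cases can deviate under true association — standard GWAS
practice), females only on the X; case/control differential missingness
by two-sided Fisher exact test at P < 10⁻³ (the threshold is a
configurable, deliberately conservative default). Samples are removed at
mean call rate < 0.95. The HWE test is the exact conditional test:
conditioning on the allele counts, it sums the probabilities of all
heterozygote counts no more probable than the one observed.

## Structure

LD pruning follows the windowed greedy scheme of `--indep-pairwise 50 10
0.2`: within each 50-SNP window the pair with the highest composite-LD r²
(computed on dosages, missing entries dropped pairwise) loses its
lower-MAF member (tie: the later position) until no pair exceeds 0.2,
then the window slides by 10. If more than a target count (default
100,000) survive, a deterministic every-kth thinning is applied. PCA is
an eigendecomposition of the standardized-genotype covariance over the
pruned SNPs (missing entries mean-imputed), with a deterministic sign
convention (largest-magnitude score positive). Ancestry outliers are
samples beyond 6 SD on any of the top 10 PCs; a single pass by default,
with an optional iteration count for EIGENSTRAT-style repeated removal
(the production tools differ on iteration counts; one pass is the
conservative choice and the count is exposed).

Relatedness pruning removes, greedily, the individual involved in the
most GRM entries above threshold (ties: lower call rate, then identifier)
until none remain, which retains the maximum cohort for chains like
parent–offspring–grandchild. The production threshold of 0.05 assumes a
GRM from hundreds of thousands of SNPs (off-diagonal sampling noise SD
1/√m ≈ 0.0015); desk-scale runs at m ≈ 10³ must raise it (we use 0.2–0.3)
or the noise alone flags unrelated pairs. The threshold is interpreted on
the GRM scale throughout.

## Association and genomic control

Per-SNP additive logistic regression (dosage oriented to the cohort minor
allele; covariates conventionally sex plus 10 PCs) by Newton/IRLS with
step-halving, reporting Wald effect, SE, χ² and p. Non-convergent,
separated (|β| > 15 or non-finite SE) or constant SNPs are flagged with
missing p rather than failing the scan. λ_GC = median χ² / 0.4549 (the
χ²₁ median, stored at full precision via the quantile function). Note
that a truly polygenic trait inflates λ_GC above 1 even without
confounding; the null band [0.95, 1.05] applies to no-signal scans.

## GRM construction

A_jk averages (x_ij − 2f_i)(x_ik − 2f_i) / (2 f_i (1 − f_i)) over SNPs
non-missing in both individuals, with per-pair SNP counts recorded and
monomorphic SNPs skipped. Allele frequencies come from the full analysis
cohort (cases + controls) after QC. The diagonal uses the same
cross-product formula as the off-diagonals (not the inbreeding-adjusted
variant some tools use), which keeps the matrix identical to the
brute-force double-loop oracle used in tests. GRMs over disjoint SNP
subsets recombine exactly by per-pair-count weighting, a tested identity.
The extended MHC is chr6:26,500,000–34,000,000 (1-based, both boundaries
inside). On the X, females are standardized as on the autosomes and
males are scored √2·(a − f)/√(f(1−f)) on their allele count a ∈ {0, 1}
(full dosage compensation; an all-female cohort reduces exactly to the
autosomal formula). The ChrX variance contributions of interest here are
near zero, so the choice of compensation model is low-impact but made
explicit.

## REML

V(θ) = Σ θ_i M_i is maximized in the restricted likelihood
−½[log|V| + log|X'V⁻¹X| + y'Py] by average-information updates,
AI_ij = ½(M_i Py)'P(M_j Py), with step-halving on likelihood decreases or
non-PD proposals and an EM fallback when Newton fails outright. Variance
components are floored at 10⁻⁶·Var(y); convergence is |ΔlogL| < 10⁻⁶
with a 100-iteration cap (typical fits converge in 4–10). Standard
errors come from the inverse AI matrix, with the delta method for ratios
(h², component shares, rG). Each iteration performs exactly one Cholesky
factorization plus one in-place triangular inverse; traces tr(V⁻¹M) are
taken against precomputed strict-lower-triangle copies of each component
so the inverse is never symmetrized, and all other products with V⁻¹ go
through triangular solves. The univariate LRT against σ²_g = 0 uses the
boundary mixture ½χ²₀ + ½χ²₁ (the null is on the parameter-space
boundary); fixed-value interior tests use χ²₁.

The liability transform multiplies both the h²_obs estimate and its SE by
K²(1−K)²/(P(1−P)z²), treating K and P as fixed (the full case-control
ascertainment correction). At K = P = 0.5 the multiplier is exactly π/2,
a closed-form identity the tests pin to 10⁻¹². Estimates transformed
above 1 are reported unclamped with a flag, since clamping would mask
estimator behaviour. %MHC = 100·(h²_auto − h²_exMHC)/h²_auto, undefined
when the autosomal estimate is non-positive.

In the bivariate model two disjoint cohorts (cases of each disease plus
an evenly split shared control pool, larger half to side 1, split
seeded) are stacked; the genetic covariance enters through the
cross-cohort GRM block and the residual covariance is structurally zero
because no individual appears on both sides. Samples are sorted so each
cohort occupies a contiguous block, letting every component live in a
matrix block and only the lower triangle of V be maintained. The
covariance component is kept inside the PD cone by clamping |σ_g12| ≤
0.999·√(σ²_g1σ²_g2); a Haseman–Elston moment estimate on the cross block
initializes it. With the covariance fixed at zero the model decouples
exactly, so the LRT null likelihood is the sum of two univariate fits
computed with the same three-term expression; the test is interior, χ²₁.
rG is invariant under linear rescaling of either phenotype (a tested
property), which is why the observed-scale rG doubles as the
liability-scale rG. If either genetic variance sits at the zero floor,
rG is reported missing with the reason.

## Genome-wide pairwise sharing (GPS)

P-values convert to two-sided magnitude Z-scores Φ⁻¹(1 − p/2), clipped at
the p = 10⁻³⁰⁰ quantile; the direction of association is discarded
because the max–min construction does not use it. γ = max_j min(X_j,
Y_j). Under the exchangeable-pairing null the p-value is exactly
1 − C(n−a, b)/C(n, b) with non-strict exceedance counts a = #{X ≥ γ},
b = #{Y ≥ γ} (non-strict makes a, b ≥ 1 automatic and matches exhaustive
enumeration in the presence of ties); it is evaluated in log space. The
identity to the full n!-permutation distribution is tested exhaustively
for n ≤ 7 and by Monte-Carlo at n = 500. LD among SNPs violates the
independence behind the analytic null, inflating apparent sharing; the
all-pairs driver therefore removes extended-MHC SNPs by default and
pruned input is recommended. All-pairs output is Bonferroni-adjusted by
the number of pairs (45 for 10 cohorts).

## SVM prediction

Stratified ten-fold cross-validation; per fold a GWAS on the training
samples only, SNP selection at each threshold of a decreasing sweep
(default 10⁻⁵…10⁻⁹), features mean-imputed and standardized with
training-fold statistics, a linear SVM (C = 1, inverse-frequency class
weights — control:case imbalance would otherwise collapse the decision
function), scored on the held-out fold by rank-statistic AUC (ties ½).
Selection, imputation and scaling never see the evaluation fold. Cells
where a threshold selects no SNPs are missing, not errors; AUC_mean and
AUC_max summarize over all non-missing (threshold, fold) cells. Null
sanity checks use permissive thresholds (e.g. 0.5/0.1/0.02) because at
genome-wide thresholds a null scan selects nothing, leaving no cells to
evaluate.

`liability_auc_bound(h2, K)` gives the closed-form ceiling of any
genotype-based predictor: the best score is the true genetic liability g,
whose case/control means and variances follow from truncated-normal
moments of the liability at t = Φ⁻¹(1 − K). At h² = 0.3, K = 0.1 the
ceiling is 0.796, and the strong-signal check (20 causal SNPs at 1.5%
liability variance each, n = 4000 ascertained to half cases) demands
AUC_mean > 0.75, a margin the ceiling supports; at 1% per SNP (h² = 0.2)
the ceiling would be 0.744 and no predictor could reach 0.75, which is
why the strong-signal preset uses 1.5%.

## Problem sizes, calibration and known limitations

Simulation sizes used by the test and acceptance runs were chosen so
estimator standard errors, not compute, dominate: univariate recovery at
n = 2000, m = 5000 (SE(h²_obs) ≈ √(2m)/n ≈ 0.05 per replicate, 25
replicates); bivariate recovery at n = 2000 per side with m = 2000 (the
off-diagonal GRM variance 1/m drives the information, so moderate m
keeps SE(rG) ≈ 0.06–0.10 while bounding the O(n³) REML cost); null
calibration at 200 replicates of n = 500, m = 1000; GPS calibration at
500 replicates of n = 500 SNPs.

Two deliberate simplifications matter when reading test results as
statements about real data. First, the generator's SNPs are independent
(no LD beyond the optional block model), so GRM-based estimates are free
of the LD-weighting sensitivity that real panels show, and the GPS
analytic null is exactly valid; on real data both require pruning or
LD-aware corrections. Second, and most important: **REML on strongly
ascertained case-control samples is biased downward even after the
liability transform.** With 10× case oversampling (K = 0.05 sampled to
P = 0.5) at true liability h² = 0.6, the mean estimate across replicates
here is ≈ 0.52 — a ~13% relative attenuation that neither 20 PC
covariates nor more replicates remove, consistent with the analysis of
Golan, Lander & Rosset (PNAS 2014). The estimator is unbiased on
unascertained or quantitative phenotypes (verified in the unit suite).
The acceptance check for ascertained recovery is asserted at the nominal
condition and documents this attenuation when it fails; PCGC-style
regression, the published remedy, is a different estimator and out of
scope here. Genetic correlations are much less affected because the
attenuation acts similarly on variances and covariance, and the
bivariate recovery check passes at its stated tolerance.

Other limitations: no haplotype/imputation support, no rare variants
(MAF < 0.01 is excluded by design), no batch/plate-effect QC, no
mixed-model association, and the pipeline driver orchestrates one
disease pair per run (the GPS and prediction stages accept any number of
cohorts at the library level).
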