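# Methods

This note documents the models implemented in `pqtl`, the defaults and why
they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical choices a maintainer would want to know.

## Synthetic cohorts

**Genotypes.** Dosages are sums of two Bernoulli haplotypes. Within an LD
block, haplotype alleles follow an AR(1) Gaussian copula whose latent
correlation is calibrated per adjacent pair (by Brent root-finding on the
bivariate-normal orthant probability) so that the *allele* — hence dosage —
correlation of adjacent variants equals the requested `r_adj`. Across blocks
variants are independent. With unequal MAFs the attainable correlation of two
binary variables is bounded above (e.g. MAF 0.06 vs 0.5 caps near 0.36); the
calibration then saturates at the bound. MAFs are drawn uniformly from the
requested range and rounded to 4 decimals so the copula solves are cached; a
separate `structure_seed` lets two cohorts share one variant structure (same
MAFs and LD) while holding different individuals, which is what two-sample
MR scenarios need.

**Proteome.** A protein is `β_cis·x_cis + β_trans·x_trans + polygenic +
N(0, σ²_e)`, the polygenic term summing standardized background-SNP effects
drawn N(0, h²_poly/M_bg) (additive infinitesimal model, matching the LD-score
regression assumption). Variance shares are validated to sum ≤ 1, and σ²_e
defaults to the complement so proteins have unit variance. A configurable
fraction of specimens is measured twice; replicate runs share the biological
value plus independent technical noise. Missingness is a
missing-not-at-random censor of the lowest-abundance quantile per feature
plus uniform dropout — the mechanism of real DIA data is not published for
this kind of cohort, so the NMAR+uniform mixture is an explicit assumption;
it is what justifies half-minimum imputation downstream. No spectrum- or
peptide-level signal is simulated: features are abundance columns only, so
passing tests say nothing about search-engine or quantification artifacts.

**Mediation cohort.** BMI is a genetic score over designated instrument SNPs
plus noise; the protein is α·BMI (+ optional cis effect) plus noise; disease
is a liability threshold with a *standard-logistic* residual, thresholded at
the stated prevalence. The logistic residual makes the conditional disease
model exactly logistic with slope β per protein unit, so a per-SNP logistic
GWAS estimates effects on the scale the ground truth is written in. Marginal
(per-SNP) logistic effects are still mildly attenuated by non-collapsibility
(~2–8% here); the mediation recovery tolerance absorbs this, and it is a
real feature of logistic summary statistics, not an artifact.

**Summary-statistic scenarios.** `simulate_cis_summary_pair` builds exposure
and outcome cohorts (default n = 20,000 each) over one 30-SNP cis block
(adjacent-r 0.85), with the exposure's causal variant explaining a strong
cis-pQTL-sized share (allelic effect 0.3 on a unit-variance protein). The
outcome either shares that causal variant (colocalization) or has its own
(linkage). `simulate_mr_summary_pair` gives 10 independent instruments with
allelic effect 0.15 and optional pleiotropic direct effects on the outcome.

## Proteome QC

Thresholds are strict: a sample is removed when its identification count is
*below* 80% of the median; a feature when its missingness is *over* 80%.
Replicate pairs are merged only when Pearson r on jointly observed features
exceeds 0.8; pairs with fewer than 3 shared features (correlation undefined
or degenerate) and pairs failing the gate are excluded and logged. RINT uses
the Blom offset c = 3/8 — the most common convention in molecular-trait GWAS
— with average ranks for ties; it errors on constant input.

## Mixed-model association

The model is y = Xb + g + e with g ~ N(0, σ²_g·A). REML is computed by one
eigendecomposition of the GRM followed by Brent search on the restricted
likelihood profiled over the variance ratio — exact for a two-component
model and more robust than iterative EM/AI updates; tolerance 1e-6 on the
ratio, boundary estimates (σ²_g = 0) allowed. The null-model fit is reused
for all SNPs (the strategy of the standard MLM tools), the candidate SNP
stays in the GRM (no leave-one-chromosome-out; slight proximal contamination
accepted), and the per-SNP statistic is GLS under the fitted V, with
p = χ²₁((b/se)²). With σ²_g = 0 the scan collapses to OLS exactly (tested to
1e-8). HWE uses the exact test (mid-p off) on hard calls obtained by
rounding dosages.

The pipeline skips relatedness pruning when the GRM is built from too few
SNPs to resolve the 0.05 threshold (an entry's sampling sd is ≈ 1/√M;
pruning below that resolution would remove samples on noise). At desk-scale
simulation sizes this guard usually fires; at real-data scale (10⁵ pruned
SNPs) it never does. Age/sex covariates are fitted per sub-cohort when
supplied; synthetic cohorts use genetic PCs only.

## Meta-analysis and significance

DerSimonian–Laird: fixed weights w = 1/se², Q = Σw(b−b_F)²,
τ² = max(0, (Q−(k−1))/(Σw − Σw²/Σw)), then random-effects weights
1/(se²+τ²). Genome-wide significance is the conjunction of (i) meta
p < 5×10⁻⁸/n features, (ii) p < 0.05 in each sub-cohort, (iii) consistent
effect direction. Criteria (ii) and (iii) are evaluated over the cohorts
actually contributing finite statistics to that variant's meta-analysis
(a variant monomorphic in one batch is judged on the rest); a variant with
no contributing cohort is never significant. Lead-SNP ties are broken by
larger |b| then lexicographic variant id.

## Conditional/joint analysis (COJO)

Forward stepwise with a backward check. X'X is reconstructed from the LD
reference's observed centered genotype products scaled to the GWAS sample
size — under HWE this equals the usual 2f(1−f)N·r form, and using observed
products makes the joint estimates *exactly* equal individual-level multiple
regression when the reference is the analysis sample (verified to 1e-6 over
50 loci). The phenotype sum of squares is recovered per SNP as
Sxx·(b² + se²·(N−2)) — the simple-OLS-with-intercept identity — and the
median across SNPs is used. SNP pairs farther apart than 10 Mb (or on
different chromosomes) are treated as uncorrelated; candidates with
r² ≥ 0.9 to a selected SNP or |freq − freq_ref| > 0.2 are never added.

## Heritability and power

q² = 2β²·MAF(1−MAF) assumes a unit-variance (RINT) phenotype; joint signals
contribute q_j² = 2β·β_j·MAF(1−MAF), retained even when negative (flagged) —
a sum can legitimately shrink. LD scores are windowed sums of bias-adjusted
r² (r² − (1−r²)/(n−2), floored at 0, self included). The polygenic fit
regresses χ² on N·ℓ/M with a free intercept; one heteroskedasticity
reweighting pass with weights 1/(1+N h²ℓ/M)² follows an unweighted first
fit. Everything within ±10 Mb of a lead pQTL is excluded first, because a
major locus inflates its LD neighbourhood and would be double-counted; with
fewer than 50 SNPs left the fit refuses (unstable). The single-draw sampling
noise of the slope at the simulation sizes used here (M ≈ 900, n = 3000) is
roughly ±0.09, so calibration checks average several phenotype draws.

Power: NCP = 2f(1−f)b²N / (1 − 2f(1−f)b²) — the denominator is the residual
variance when the phenotype has unit total variance — with the rejection
region from the central χ²₁ quantile and the noncentral tail from scipy's
`ncx2` (series evaluation well below 1e-12). At b = 0 the power equals the
significance threshold exactly.

## SMR, HEIDI and multi-SNP SMR

T_SMR = z_x²z_y²/(z_x²+z_y²) against χ²₁. HEIDI takes the top cis SNP,
selects companions with pQTL p < 1.57e-3 and r² to the top SNP in
[0.05, 0.9] (cap 20, most significant kept — the cited tool's defaults, the
source names only the test), forms d_i = b_xy(i) − b_xy(top), and propagates
first-order delta-method covariance through the LD matrix (exposure and
outcome cohorts independent). The sum Σ(d_i/sd_i)² of correlated 1-df terms
is referred to a Satterthwaite two-moment match (scale = var/2·mean,
df = 2·mean²/var); the same matching with eigenvalue weights of the
instruments' LD matrix gives the multi-SNP SMR p. Satterthwaite rather than
exact weighted-χ² inversion keeps the implementation dependency-free; in
calibration simulations the null rejection at 0.05 sits near 4–6% and the
two-causal-variant linkage scenario rejects in ≈95%+ of replicates at
n = 20,000. Colocalization requires p_SMR below the Bonferroni grid
(α divided by the exposures×outcomes dimensions of the tested grid, computed
at run time) *and* p_HEIDI > 0.05. The MHC region chr6:28,477,797–33,448,354
(inclusive) is excluded before testing. Note the "pass" convention:
acceptance requires p_HEIDI *greater* than 0.05 (no detectable
heterogeneity); text stating the opposite inequality appears in some
published results sections and is treated here as a typo.

## GSMR and mediation

Instruments are greedily clumped (most significant first, removing r² ≥ 0.05
neighbours) at p < 5×10⁻⁸. Per-instrument Wald ratios are pooled by GLS with
covariance built from LD r and *first-order* delta variances
(se_zy²/b_zx²): weights that include the estimated outcome effect would be
anticorrelated with the ratio and bias the pooled estimate toward zero. The
reported standard error propagates the *full* delta covariance (exposure
error included) through those weights and applies a multiplicative
overdispersion floor √max(1, Q/(m−1)) — the classical random-effects IVW
inflation, never deflating. In calibration (10 instruments, n = 20,000,
b_xy = 0.2 over 1600 replicates) the 2·se interval covers the truth 95.7% of
the time. HEIDI-outlier removal iterates: the instrument whose ratio
deviates most from the current pooled estimate with two-sided normal
p < 0.01 is dropped and the model refit; a single instrument reduces to the
Wald ratio (the minimum instrument count is 1, because lead trans-variants
are legitimately used as single instruments). Disease outcomes are on the
log-odds scale; `CausalEstimate.odds_ratio` is exp(b_xy).

Mediation: indirect = α·β with
σ_αβ = √(α²σ_β² + β²σ_α² − σ_α²σ_β²) (Goodman). The radicand is negative
when both effects are small relative to their errors; the first-order form
√(α²σ_β² + β²σ_α²) is then used and flagged. SD-unit conversion divides an
effect per 1-SD exposure (and its se) by the population SD, matching the SD
of the population whose GWAS supplied the leg.

## Pipeline and I/O

Coordinates are 1-based inclusive throughout. Summary statistics travel in
the GCTA ".ma" layout (SNP A1 A2 freq b se p N); genotypes as VCF with GT:DS
or PLINK bed/bim/fam (both writers/readers round-trip, tested); configs as
YAML that round-trips through `PipelineConfig`. Every multiple-testing
denominator is computed from the dimensions of the tables analysed at run
time. Allele harmonization resolves swaps and strand flips against a
reference and can drop ambiguous A/T and C/G pairs (always done for
replication testing).

## Problem sizes in tests

Test and acceptance runs use desk-scale cohorts chosen to keep each
statistical property measurable: discovery pipelines at n ≈ 1200 samples /
80 SNPs / 4 batches; MLM calibration 500 null scans at n = 1000 × 200 SNPs;
HEIDI calibration 500 replicates per scenario at n = 20,000 per cohort;
GSMR coverage 1000 replicates; LDSC panels of 900 SNPs × 3000 samples
averaged over 8 phenotype draws. These sizes trade genome-wide realism for
exhaustive ground-truth checks; the statistical machinery is
scale-independent.

## Known limitations

- No X-chromosome analysis or sex-mismatch checks.
- No batch-effect correction beyond per-batch GWAS with meta-analysis.
- The Satterthwaite weighted-χ² tail is approximate in the far tail; HEIDI
  p-values below ~1e-6 should be read as "very small" rather than exact.
- The LD reference must be ancestry-matched; no reference-panel error model.
- Logistic-scale effects from binary-outcome GWAS carry non-collapsibility
  attenuation into Wald ratios; mediation estimates on such outcomes are
  conservative.
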