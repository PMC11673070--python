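# Methods

This note documents the models, estimators and numerical choices behind
`lipidprs`, and what the synthetic study conditions do and do not establish
about real cohort data.

## Synthetic cohort model

**Genotypes.** The panel is organised in independent LD blocks. Each
haplotype allele arises from a Gaussian copula: latent variables within a
block are equicorrelated at `within_block_r`, and the allele is carried when
the latent falls below the allele-frequency quantile. Diploid dosages are
sums of two independent haplotypes, so dosage LD rises monotonically with the
latent correlation while cross-block LD is zero in expectation. Allele
frequencies are uniform on `maf_range` (default 0.05–0.5); ref/alt pairs
cycle through non-ambiguous combinations; positions place blocks 1 Mb apart.
Missing calls are injected completely at random at a configurable rate
(default 0) to exercise the call-rate filter and imputation paths. This
deliberately omits realistic demography, recombination maps and imputation
structure: tests passing here show the *pipeline arithmetic* is right, not
that the methods are robust to real human LD.

**Base GWAS.** Standardized marginal effects are the LD convolution `R @ β`
of sparse causal effects plus N(0, 1/n_gwas) noise; per-allele effects divide
by `sqrt(2f(1−f))`, with Wald p-values and the panel frequencies attached.
`R` here is the reference panel's empirical correlation banded to a physical
window (default 500 kb). The banding matters: a real GWAS measures LD on its
own large sample, so at truly uncorrelated pairs its marginal effects carry
noise at the `1/sqrt(n_gwas)` scale — convolving through the *unbanded*
correlation of a 2000-sample reference would instead inject reference noise
(sd ≈ 1/sqrt(n_ref) per entry, summed over causals) an order of magnitude
larger, which no summary-statistic model could fit.

**Lipid phenotypes.** phenotype = mean + scale·(g + e) + covariates, where g
is the standardized-genotype score rescaled so its realized variance is
exactly h² of the genetic+residual variance, and e is Gaussian. Triglycerides
are generated on the natural-log scale and exponentiated; the log-scale
column is what the analysis models. Covariates: age uniform on [25, 67] y;
male sex Bernoulli(0.4); BMI N(27.5, 4.5) kg/m² truncated to [16, 50];
smoking never/ex/current at 0.60/0.20/0.20; statin intake Bernoulli(0.05).
Default trait settings put heritability at 0.35–0.4 (the moderate-to-high
range reported for lipids), with conventional covariate effects (e.g. statin
−0.9 mmol/L on LDL-C); no published estimates pin these, so they are
conventions, not estimates.

**Ultrasound block.** Twelve parameters (six per territory): intima-media
thickness right/left (lognormal, median 0.72/0.62 mm carotid/femoral),
plaque number (negative binomial; carotid mean 1.51, SD 1.56), maximum and
total stenosis (zero-inflated scaled beta on [0, 100] %), plaque score
(zero-inflated gamma, mm). Each is a monotone quantile transform of a latent
Gaussian correlated with the standardized genetic liability at
`2·sin(π·ρ/6)` — the inverse of the Spearman–Pearson relation for bivariate
normals — so the realized rank correlation hits the target ρ up to the tie
attenuation of the discrete/zero-inflated marginals (a few percent at
ρ ≤ 0.15, inside the generator's ±0.05 contract at n ≥ 1000).

## Cohort QC

**Relatedness.** IBD state probabilities come from the PLINK-style
method-of-moments: per-pair IBS0/IBS1/IBS2 counts are equated to their
Hardy-Weinberg expectations given allele frequencies, solved sequentially for
P(IBD=0,1,2), truncated to [0,1] and renormalized; PI_HAT = P(IBD=2) +
P(IBD=1)/2. The large-sample expectation formulas are used (no finite-count
bias correction); with the few hundred variants of desk-scale panels PI_HAT
is noisy, which the defaults acknowledge by thresholding high (0.33).
Pruning removes the younger member of each pair above threshold, processing
pairs in decreasing-PI_HAT order (ties by id) so the outcome is independent
of input order; age ties remove the lexicographically larger id.

**Ancestry outliers.** Dosages are mean-imputed, standardized and projected
on the top k = 10 principal components; Ward-linkage agglomerative
clustering on the scores is cut into at most 10 clusters and clusters holding
fewer than `cut` (default 1%) of the cohort are flagged. Linkage, k, cluster
count and cut are all exposed in config — no single convention is canonical
for this step.

## C+T tuning

Clumping is the standard greedy scheme (smallest p first; ties by position).
LD is computed panel-wide from training genotypes, since desk-scale panels
are sparse; a window option bands it for dense inputs. The published-style
threshold range [1e-100, 1e-4] is realised as a log10-uniform ladder
(default 49 points): an arithmetic step of 5e-50 over that range would place
every representable threshold at the top of the range and is not a usable
grid. Selection maximizes training incremental R² (ties: fewer variants,
then smaller r²); validation incremental R² is computed with the
training-fitted normalization and reported separately, never used for
selection.

Two facts about this selection are worth stating because the test suite
encodes them. First, grid selection inflates the training estimate (the
chosen cell's R̂² is biased up by the maximum over cells), which the
pure-noise unit test checks directly. Second, whether the *train-minus-
validation difference* is positive is a competition between that selection
bias, of order (1−ρ²)·2ln(K_eff)/n_train with K_eff the effective number of
distinct cells, and the small-sample inflation of the validation estimate,
(1−ρ²)/n_valid — at a 4:1 split these are the same order, so a single split
on pure noise shows no reliable direction. The direction becomes real when
splits are repeated and averaged and when grid cells differ in true quality
(a weak, noisy base GWAS), which is how the split-experiment regimes are
constructed: the small regime uses n = 800 with a weak GWAS
(n_gwas = 2000, h² = 0.1, 300 variants), the large regime n = 2000 with a
strong one (n_gwas = 5e4, h² = 0.4). The paired t-test is used exactly as
the conventional summary even though repeats share samples, so its
independence assumption is approximate; this caveat is inherent to the
design being emulated and is documented rather than "fixed".

## Spike-and-slab Gibbs shrinkage

Inputs are moved to the standardized scale through the Wald statistic,
β̂_std = z/√n, making the sampler invariant to the units of β and SE (the
output is rescaled by `SE·√n`, restoring per-allele units and exact scale
equivariance). The model is β̂ = Rβ + e, e ~ N(0, R/n), with prior
β_j ~ (1−p)δ₀ + p·N(0, h²/(M·p)). Each sweep resamples every effect from its
conditional (a Bernoulli inclusion with closed-form slab posterior, using the
LD-residualized marginal effect), then updates p from its conjugate
Beta(1+k, 1+M−k) posterior given the k nonzero effects and sets
h² = β'Rβ, the current genetic variance (clipped to [1e-4, 1]). Both
hyperparameters can be fixed instead, which the tests use to check the
one-variant quadrature oracle and the ridge limit (p = 1, diagonal LD gives
β·(1+M/(n·h²))⁻¹).

Numerics: h² is initialised from an LD-score-style moment estimator
(M(mean χ²−1)/(n·mean ℓ), clipped to [0.01, 0.9]), p at 0.1; the LD matrix
is regularized by shrinking off-diagonals by 1/(1+0.01); the reference LD is
banded to 500 kb by default for the same reference-noise reason as in the
GWAS generator — with unbanded desk-scale LD the spurious long-range
correlations inflate residuals and the causal-fraction chain escapes to 1.
Defaults are 500 burn-in + 500 kept sweeps; chains for h² and p are emitted
for trace inspection. A non-finite state aborts with advice to increase the
diagonal loading. Per-variant GWAS sample sizes and effect-allele
frequencies are required; input without frequencies is refused.

## Evaluation statistics

Incremental R² is computed from nested OLS fits (statsmodels), ΔR² =
R²_full − R²_cov, with the nested-model F-test p-value; the internal fast
path used by the tuner and the screens computes the identical quantity via
the partial-correlation identity ΔR² = r²_partial·(1−R²_cov) after QR
residualization, and the two routes are asserted equal in the tests.
Covariates enter as sex, age, BMI, statin and smoking coded as two indicator
contrasts against "never smoked"; collinear designs raise an error naming
the offending columns; missing values are removed listwise with counts kept.
Bootstrap CIs are percentile intervals over case resampling (default 1000
replicates; degenerate resamples redrawn and counted). Spearman ρ uses
midranks, a t-approximation p, and bootstrap percentile CIs. The ultrasound
screen flags pairs at the Bonferroni-adjusted threshold α/m per parameter
family (m defaults to the number of scores; α/28 ≈ 1.78e-3 for the reference
family) and reports ρ alongside with its nominal p.

The family-wise error of that screen is strictly below α
(1−(1−α/28)²⁸ ≈ 0.0488), a margin of ~0.001 — far below Monte Carlo
resolution at a few hundred null simulations. The acceptance test therefore
checks the control claim the only statistically meaningful way: the null
FWER estimate (200 seeds × 12 families) must not exceed 0.05 by more than a
one-sided binomial test at α = 0.01 can attribute to chance, the same
convention the suite uses for the Kolmogorov-Smirnov uniformity check of the
null ANOVA p-values.

## Pipeline scales and sizes

A *scale* is one (cohort, source, method, phenotype) combination; sources
without complete summary statistics are eligible for classical scoring only,
so the reference configuration — three sources, two with full statistics,
four lipid phenotypes — yields 28 scales per cohort. The 4:1 split puts
round(n/5) samples (half up) in validation: 1673 → 1338/335, 817 → 654/163.
All stage seeds derive deterministically from the single config seed, and a
rerun with the same config is byte-identical.

Problem sizes used in the test and acceptance runs (2000 samples × 2000
variants for the heritability-recovery study; 200-repeat split experiments
at n = 800 and 2000; 200-seed null screens at n = 500) were chosen as the
smallest at which the checked effects are comfortably resolved by their own
Monte Carlo error.

## Known limitations

Copula LD has no long-range structure, so window/banding choices are not
stress-tested against real recombination landscapes. The IBD estimator omits
PLINK's small-sample bias corrections. The sampler is a single chain without
formal convergence diagnostics beyond the emitted traces. Ultrasound
marginals are parametric stand-ins matched to summary moments, not fitted
distributions. None of the synthetic defaults should be read as estimates of
real cohort quantities.
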