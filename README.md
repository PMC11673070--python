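# lipidprs

Polygenic risk scores (PRS) for blood lipids — construction, tuning and
evaluation against lipid and subclinical-atherosclerosis phenotypes.

Individual-level genotype data for population lipid cohorts are rarely
shareable, which makes PRS analysis pipelines hard to test and compare.
`lipidprs` implements the complete desk-scale pipeline — cohort QC, three PRS
construction methods, and the association-evaluation layer — together with a
first-class synthetic-data generator that emulates the statistical structure
of such cohorts (block-LD genotypes, base-GWAS summary statistics, heritable
lipid phenotypes with covariates, and carotid/femoral ultrasound outcomes
weakly coupled to lipid genetic liability). Every stage is therefore testable
end to end without access to protected data. It is aimed at statistical
geneticists and methods developers who want a transparent, re-implementable
reference for the standard lipid-PRS workflow.

## What it computes

**Scoring.** The classical PRS of individual *i* is the weighted allele count

&nbsp;&nbsp;&nbsp;&nbsp;PRS_i = Σ_j w_j · G_ij,

with G_ij ∈ {0, 1, 2} the effect-allele dosage and w_j the per-allele effect
estimate from an external study (alleles harmonized to the target panel;
missing dosages imputed as 2·f̂_j). Scores are Z-normalized within the cohort.

**Clumping + thresholding (C+T).** Greedy LD clumping keeps the most
significant variant per LD group at a squared-correlation cutoff r², then
variants with GWAS p ≤ p_T are scored. The (r², p_T) grid — r² ∈
{0, 0.1, …, 0.5}, p_T log-uniform over [1e-100, 1e-4] by default — is tuned
on a 4:1 train/validation split by training incremental R², with validation
R² reported separately. Repeated-split experiments with a paired t-test
quantify the train-vs-validation overfitting of this selection.

**Bayesian shrinkage.** A Gibbs sampler places a spike-and-slab prior on
standardized effects, β_j ~ (1−p)·δ₀ + p·N(0, h²/(M·p)), and samples each
effect conditional on the rest through the LD matrix of a reference panel,
re-estimating the SNP heritability h² and the causal fraction p every sweep
(no tuning cohort needed). Posterior-mean effects become scoring weights.

**Evaluation.** For each score: incremental R² (the gain in variance
explained when the PRS joins a covariate model with sex, age, BMI, smoking
and statin use), nested-model ANOVA p, nonparametric bootstrap CIs, Spearman
ρ with bootstrap CIs, and per-1-SD effects. A Bonferroni-corrected screen
(α/28 = 1.78e-3 for the reference 28-score family) scans all scores against
the twelve ultrasound parameters. Cohort QC covers method-of-moments IBD
relatedness pruning (remove the younger of each pair with PI_HAT > 0.33) and
PCA + Ward-clustering ancestry-outlier removal.

## Worked example

```python
import numpy as np
import lipidprs as lp
from lipidprs.evaluate import covariate_design

# synthetic cohort: 1500 samples, 600 variants in LD blocks
spec = lp.LDBlockSpec(n_blocks=200, variants_per_block=3, within_block_r=0.6)
genotypes = lp.simulate_genotypes(1500, spec, seed=42)

# an external base GWAS (n = 100k) for an LDL-like trait (h² = 0.4)
effects = lp.draw_effect_sizes(genotypes.n_variants, causal_fraction=0.05, h2=0.4, seed=43)
sumstats = lp.simulate_base_gwas(genotypes, effects, n_gwas=100_000, seed=44)
phenos = lp.simulate_lipid_phenotypes(
    genotypes, lp.default_lipid_traits()["ldl"], seed=45, effects=effects, name="ldl")
covariates = covariate_design(phenos)
y = phenos["ldl"].to_numpy()

# classical PRS from the 100 lead variants
lead = lp.SummaryStats(sumstats.table.nsmallest(100, "pval").reset_index(drop=True))
weights, report = lp.harmonize(lead, genotypes)
prs = lp.compute_prs(genotypes, weights)
res = lp.incremental_r2(y, covariates, prs.z, "LDL-C", "classical")
lo, hi = lp.bootstrap_ci_r2(y, covariates, prs.z, reps=1000, seed=46)
```

Running the full script (`C+T` tuning and Gibbs shrinkage included) prints:

```
classical: 100 variants, dR2 = 34.33% [95% CI 30.56-37.83], ANOVA p = 8.86e-147
C+T: best r2=0.1, p<=1.0e-52, 24 variants; train dR2 = 37.32%, validation dR2 = 43.60%
shrinkage: posterior h2 = 0.339, p_causal = 0.053, dR2 = 40.11%
screen: 12/12 ultrasound parameters pass p <= 1.79e-03; carotid max stenosis rho = 0.141
```

Reading the numbers: the classical score explains 34% of LDL variance beyond
the covariates (synthetic effects are noiseless relative to real lead-variant
panels, so this is far above the few percent seen in real cohorts); C+T
selects 24 variants at r² = 0.1 and a stringent threshold; the shrinkage
sampler recovers a posterior SNP heritability (0.34) near the generative 0.4
and a causal fraction near the generative 0.05; and all twelve simulated
ultrasound parameters associate with the LDL score at the Bonferroni
threshold, with rank correlations around the generative target 0.13.

The same pipeline is scriptable from the shell — `lipidprs simulate`, `qc`,
`score`, `tune-ct`, `fit-shrinkage`, `evaluate`, `screen`,
`split-experiment`, `run-all` — driven by one YAML config with a mandatory
seed.

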