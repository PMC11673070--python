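"""Synthetic cohort generator: genotypes with block LD, base-GWAS summary
statistics, lipid phenotypes with covariates, and atherosclerosis-ultrasound
outcomes.

The generator exists so the whole scoring/tuning/evaluation pipeline can be
exercised end to end without individual-level cohort data. It emulates the
statistical features the downstream methods rely on:

* genotypes organised in LD blocks, induced by a Gaussian copula on haplotypes
  with tunable within-block latent correlation;
* marginal GWAS effects that are the LD-convolution of sparse causal effects
  plus sampling noise scaled by the GWAS sample size;
* lipid phenotypes (mmol/L) decomposing into a genetic part with a set
  heritability, additive covariate contributions (age, sex, BMI, smoking,
  statin use) and Gaussian residual, with triglycerides generated on the log
  scale;
* twelve ultrasound parameters (six per arterial territory) of mixed type --
  continuous intima-media thickness, count-valued plaque number, zero-inflated
  bounded stenosis percentages and a nonnegative plaque score -- weakly rank-
  correlated with the lipid genetic liability.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import GenotypeMatrix, SummaryStats

# non-ambiguous ref/alt pairs cycled over variants (A/T and C/G pairs would be
# strand-ambiguous and are deliberately avoided in the default panel)
_ALLELE_CYCLE = (("A", "G"), ("T", "C"), ("G", "A"), ("C", "T"))


@dataclass
class LDBlockSpec:
    """Layout of the simulated variant panel.

    ``within_block_r`` is the pairwise correlation of the latent Gaussians used
    to induce LD inside a block (per haplotype); dosage r² rises monotonically
    with it. Blocks are mutually independent.
    """

    n_blocks: int = 200
    variants_per_block: int = 10
    within_block_r: float = 0.5
    maf_range: tuple[float, float] = (0.05, 0.5)
    missing_rate: float = 0.0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if self.n_blocks < 1 or self.variants_per_block < 1:
            raise ValueError("n_blocks and variants_per_block must be >= 1")
        if not 0.0 <= self.within_block_r < 1.0:
            raise ValueError("within_block_r must lie in [0, 1)")
        if not 0.0 < lo <= hi <= 0.5:
            raise ValueError("maf_range must satisfy 0 < low <= high <= 0.5")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")

    @property
    def n_variants(self) -> int:
        return self.n_blocks * self.variants_per_block


@dataclass
class TraitSpec:
    """Generative description of one lipid trait.

    ``h2`` is the narrow-sense heritability of the (log-scale, for TG) trait;
    ``causal_fraction`` the proportion of panel variants with nonzero effect;
    ``covariate_effects`` maps covariate column names (``age``, ``sex``,
    ``bmi``, ``statin``, ``smoking_ex``, ``smoking_current``) to additive
    effects in trait units; ``mean`` and ``scale_sd`` set the trait location
    and the standard deviation of the genetic+residual part, in mmol/L
    (log mmol/L when ``log_scale``).
    """

    h2: float = 0.4
    causal_fraction: float = 0.05
    covariate_effects: dict[str, float] = field(default_factory=dict)
    log_scale: bool = False
    mean: float = 0.0
    scale_sd: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.h2 <= 1.0:
            raise ValueError("h2 must lie in [0, 1]")
        if not 0.0 < self.causal_fraction <= 1.0:
            raise ValueError("causal_fraction must lie in (0, 1]")
        if self.scale_sd <= 0:
            raise ValueError("scale_sd must be positive")


@dataclass
class UltrasoundSpec:
    """Target rank correlation and marginal shape of the ultrasound block.

    ``plaque_mean``/``plaque_sd`` parameterise the negative-binomial plaque
    number marginal (defaults match the carotid territory of the emulated
    cohort: mean 1.51, SD 1.56).
    """

    target_rho: float = 0.1
    plaque_mean: float = 1.51
    plaque_sd: float = 1.56

    def __post_init__(self) -> None:
        if abs(self.target_rho) > 0.3:
            raise ValueError("target_rho must satisfy |rho| <= 0.3")
        if self.plaque_mean <= 0 or self.plaque_sd <= 0:
            raise ValueError("plaque moments must be positive")


def simulate_genotypes(n_samples: int, spec: LDBlockSpec, seed: int) -> GenotypeMatrix:
    """Draw a diploid dosage matrix with block-structured LD.

    Each haplotype's alleles arise from equicorrelated latent Gaussians
    thresholded at the allele-frequency quantile (a Gaussian copula), so
    within-block dosage correlation increases with ``spec.within_block_r``
    while across-block correlation is zero in expectation.
    """
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    rng = np.random.default_rng(seed)
    m = spec.n_variants
    freq = rng.uniform(spec.maf_range[0], spec.maf_range[1], size=m)
    thresholds = stats.norm.ppf(freq)
    r = spec.within_block_r

    dosages = np.zeros((n_samples, m))
    for _hap in range(2):
        shared = rng.standard_normal((n_samples, spec.n_blocks))
        shared = np.repeat(shared, spec.variants_per_block, axis=1)
        latent = np.sqrt(r) * shared + np.sqrt(1.0 - r) * rng.standard_normal((n_samples, m))
        dosages += (latent < thresholds).astype(float)

    if spec.missing_rate > 0:
        mask = rng.random((n_samples, m)) < spec.missing_rate
        dosages[mask] = np.nan

    block = np.repeat(np.arange(spec.n_blocks), spec.variants_per_block)
    within = np.tile(np.arange(spec.variants_per_block), spec.n_blocks)
    alleles = [_ALLELE_CYCLE[j % len(_ALLELE_CYCLE)] for j in range(m)]
    variants = pd.DataFrame(
        {
            "chrom": "1",
            "pos": (block * 1_000_000 + within * 1_000 + 1).astype(int),
            "id": [f"snp_{b}_{v}" for b, v in zip(block, within)],
            "ref": [a[0] for a in alleles],
            "alt": [a[1] for a in alleles],
            "block": block,
        }
    )
    samples = [f"S{i:05d}" for i in range(n_samples)]
    return GenotypeMatrix(samples, variants, dosages)


def draw_effect_sizes(
    n_variants: int, causal_fraction: float, h2: float, seed: int
) -> np.ndarray:
    """Sparse per-variant effects on the standardized-dosage scale.

    A fraction ``causal_fraction`` of variants receives a Gaussian effect with
    variance ``h2 / n_causal``, so the standardized genetic variance is ``h2``
    in expectation (ignoring LD convolution, which downstream scaling absorbs).
    """
    rng = np.random.default_rng(seed)
    n_causal = max(1, int(round(causal_fraction * n_variants)))
    effects = np.zeros(n_variants)
    idx = rng.choice(n_variants, size=n_causal, replace=False)
    effects[idx] = rng.normal(0.0, np.sqrt(h2 / n_causal), size=n_causal)
    return effects


def _standardize_dosages(dosages: np.ndarray) -> np.ndarray:
    x = dosages.copy()
    mean = np.nanmean(x, axis=0)
    sd = np.nanstd(x, axis=0)
    sd[sd == 0] = 1.0
    inds = ~np.isfinite(x)
    if inds.any():
        x[inds] = np.broadcast_to(mean, x.shape)[inds]
    return (x - mean) / sd


def simulate_base_gwas(
    genotypes_ref: GenotypeMatrix,
    true_effects: np.ndarray,
    n_gwas: int,
    seed: int,
    ld_window_bp: int | None = 500_000,
) -> SummaryStats:
    """Marginal GWAS summary statistics implied by a reference panel.

    The marginal standardized effect of each variant is the LD convolution
    ``R @ beta`` of the true standardized effects plus Gaussian noise with
    standard deviation ``1/sqrt(n_gwas)``; effects are reported per allele
    (divided by ``sqrt(2 f (1-f))``) with Wald p-values. Monomorphic variants
    are excluded with a warning.

    ``R`` is the reference panel's empirical dosage correlation banded to
    ``ld_window_bp``: a real GWAS measures LD on its own (large) sample, so
    convolving through the unbanded correlation of a much smaller reference
    would inject reference sampling noise far above the ``1/sqrt(n_gwas)``
    scale at distant, truly uncorrelated pairs.
    """
    if n_gwas < 1000:
        raise ValueError("n_gwas must be >= 1000")
    true_effects = np.asarray(true_effects, dtype=float)
    if true_effects.shape != (genotypes_ref.n_variants,):
        raise ValueError("true_effects must have one entry per variant")
    rng = np.random.default_rng(seed)

    freq = genotypes_ref.allele_freq()
    poly = (freq > 0) & (freq < 1)
    if not poly.all():
        warnings.warn(
            f"excluding {int((~poly).sum())} monomorphic variant(s) from the simulated GWAS",
            stacklevel=2,
        )
    from .ct import LDMatrix  # local import to avoid a module cycle

    sub = genotypes_ref.subset_variants(np.flatnonzero(poly))
    corr = LDMatrix.from_genotypes(sub, window_bp=ld_window_bp).r

    beta_std = corr @ true_effects[poly] + rng.normal(0.0, 1.0 / np.sqrt(n_gwas), size=poly.sum())
    scale = np.sqrt(2.0 * freq[poly] * (1.0 - freq[poly]))
    beta = beta_std / scale
    se = (1.0 / np.sqrt(n_gwas)) / scale
    wald = (beta / se) ** 2
    pval = np.clip(stats.chi2.sf(wald, df=1), np.nextafter(0, 1), 1.0)

    var = genotypes_ref.variants.loc[poly].reset_index(drop=True)
    table = pd.DataFrame(
        {
            "chrom": var["chrom"],
            "pos": var["pos"],
            "effect_allele": var["alt"],
            "other_allele": var["ref"],
            "beta": beta,
            "se": se,
            "pval": pval,
            "eaf": freq[poly],
            "n": n_gwas,
        }
    )
    return SummaryStats(table)


def simulate_covariates(n_samples: int, seed: int) -> pd.DataFrame:
    """Covariate table emulating a middle-aged population cohort.

    Age uniform on [25, 67] years; sex (male=1) Bernoulli(0.4); BMI normal
    (27.5, 4.5) truncated to [16, 50] kg/m²; smoking trinomial never/ex/current
    (0.60/0.20/0.20); statin intake Bernoulli(0.05).
    """
    rng = np.random.default_rng(seed)
    age = rng.uniform(25.0, 67.0, n_samples)
    sex = rng.binomial(1, 0.4, n_samples)
    a, b = (16.0 - 27.5) / 4.5, (50.0 - 27.5) / 4.5
    bmi = stats.truncnorm.rvs(a, b, loc=27.5, scale=4.5, size=n_samples, random_state=rng)
    smoking = rng.choice(3, size=n_samples, p=[0.60, 0.20, 0.20])
    statin = rng.binomial(1, 0.05, n_samples)
    return pd.DataFrame(
        {"age": age, "sex": sex, "bmi": bmi, "smoking": smoking, "statin": statin}
    )


def _covariate_contribution(covariates: pd.DataFrame, effects: dict[str, float]) -> np.ndarray:
    out = np.zeros(len(covariates))
    for name, coef in effects.items():
        if name == "smoking_ex":
            out += coef * (covariates["smoking"].to_numpy() == 1)
        elif name == "smoking_current":
            out += coef * (covariates["smoking"].to_numpy() == 2)
        elif name in covariates.columns:
            out += coef * covariates[name].to_numpy(dtype=float)
        else:
            raise ValueError(f"unknown covariate in effect map: {name!r}")
    return out


def simulate_lipid_phenotypes(
    genotypes: GenotypeMatrix,
    trait: TraitSpec,
    seed: int,
    effects: np.ndarray | None = None,
    covariates: pd.DataFrame | None = None,
    name: str = "lipid",
) -> pd.DataFrame:
    """Lipid phenotype with a fixed heritable fraction plus covariate effects.

    The genetic component ``Z @ effects`` (standardized dosages) is rescaled so
    its realized variance is exactly ``h2`` of the genetic+residual variance;
    the residual is Gaussian. For ``log_scale`` traits the linear model lives
    on the log scale and the returned phenotype is exponentiated (so the named
    column is in mmol/L and ``log_<name>`` carries the analysis scale).

    Returns a per-sample table with the phenotype, covariates and the true
    ``genetic_liability`` (z-scored), indexed like ``genotypes.samples``.
    """
    rng = np.random.default_rng(seed)
    if effects is None:
        effects = draw_effect_sizes(genotypes.n_variants, trait.causal_fraction, trait.h2, seed)
    effects = np.asarray(effects, dtype=float)
    if covariates is None:
        covariates = simulate_covariates(genotypes.n_samples, seed + 1)

    z = _standardize_dosages(genotypes.dosages)
    g = z @ effects
    g_sd = g.std()
    if trait.h2 > 0 and g_sd > 0:
        g_scaled = g / g_sd * np.sqrt(trait.h2)
    else:
        g_scaled = np.zeros_like(g)
    resid = rng.normal(0.0, np.sqrt(max(1.0 - trait.h2, 0.0)), genotypes.n_samples)
    core = trait.mean + trait.scale_sd * (g_scaled + resid)
    value = core + _covariate_contribution(covariates, trait.covariate_effects)

    out = covariates.copy()
    if trait.log_scale:
        out[f"log_{name}"] = value
        out[name] = np.exp(value)
    else:
        out[name] = value
    liab = g - g.mean()
    out["genetic_liability"] = liab / liab.std() if liab.std() > 0 else liab
    out.index = pd.Index(genotypes.samples, name="sample")
    return out


def default_lipid_traits() -> dict[str, TraitSpec]:
    """Conventional generative settings for the four lipid traits.

    Heritabilities sit in the moderate-to-high range reported for lipids
    (0.2-0.6); covariate effects are conventions chosen to give visible but
    not dominant covariate structure; means/scales approximate population
    medians in mmol/L. TG is generated on the natural-log scale.
    """
    return {
        "hdl": TraitSpec(
            h2=0.4, causal_fraction=0.05, mean=1.4, scale_sd=0.33,
            covariate_effects={"sex": -0.15, "bmi": -0.01, "smoking_current": -0.05},
        ),
        "ldl": TraitSpec(
            h2=0.4, causal_fraction=0.05, mean=3.6, scale_sd=1.1,
            covariate_effects={"age": 0.012, "bmi": 0.02, "statin": -0.9},
        ),
        "tc": TraitSpec(
            h2=0.4, causal_fraction=0.05, mean=5.6, scale_sd=1.2,
            covariate_effects={"age": 0.015, "bmi": 0.02, "statin": -0.9},
        ),
        "tg": TraitSpec(
            h2=0.35, causal_fraction=0.05, mean=0.2, scale_sd=0.5, log_scale=True,
            covariate_effects={"sex": 0.1, "bmi": 0.02, "statin": -0.1},
        ),
    }


# rank-target correction: a bivariate-normal Pearson correlation rho_latent
# yields Spearman (6/pi) asin(rho_latent/2); invert to hit the target rank
# correlation before marginal transforms (which are monotone, hence rank-
# preserving up to ties).
def _latent_corr(target_rho: float) -> float:
    return 2.0 * np.sin(np.pi * target_rho / 6.0)


def _zero_inflated_beta_ppf(
    u: np.ndarray, p_zero: float, a: float, b: float, scale: float
) -> np.ndarray:
    out = np.zeros_like(u)
    nz = u > p_zero
    out[nz] = stats.beta.ppf((u[nz] - p_zero) / (1.0 - p_zero), a, b) * scale
    return out


def _zero_inflated_gamma_ppf(
    u: np.ndarray, p_zero: float, shape: float, scale: float
) -> np.ndarray:
    out = np.zeros_like(u)
    nz = u > p_zero
    out[nz] = stats.gamma.ppf((u[nz] - p_zero) / (1.0 - p_zero), shape, scale=scale)
    return out


def _nbinom_ppf(u: np.ndarray, mean: float, sd: float) -> np.ndarray:
    var = sd**2
    if var <= mean:  # Poisson limit when over-dispersion is absent
        return stats.poisson.ppf(u, mean)
    k = mean**2 / (var - mean)
    p = k / (k + mean)
    return stats.nbinom.ppf(u, k, p)


def simulate_ultrasound(
    liability: np.ndarray, spec: UltrasoundSpec, seed: int
) -> pd.DataFrame:
    """Twelve ultrasound parameters weakly rank-correlated with a liability.

    Per arterial territory (carotid, femoral): right/left intima-media
    thickness (mm, lognormal), plaque number (negative-binomial count),
    maximum and total stenosis (%, zero-inflated scaled beta on [0, 100]) and
    plaque score (mm, zero-inflated gamma). Each parameter is a monotone
    quantile transform of a latent Gaussian correlated with the standardized
    liability at ``2 sin(pi rho / 6)``, targeting Spearman ``target_rho``
    (ties in the zero-inflated/count marginals attenuate it slightly).
    """
    liability = np.asarray(liability, dtype=float)
    if not np.isfinite(liability).all():
        raise ValueError("liability must be finite")
    n = liability.size
    rng = np.random.default_rng(seed)
    liab = (liability - liability.mean()) / liability.std()
    r = _latent_corr(spec.target_rho)

    def latent_uniform() -> np.ndarray:
        z = r * liab + np.sqrt(1.0 - r**2) * rng.standard_normal(n)
        return stats.norm.cdf(z)

    fem_plaque_mean = spec.plaque_mean * 0.6
    fem_plaque_sd = spec.plaque_sd
    cols: dict[str, np.ndarray] = {}
    for territory, imt_med, p0_sten, sten_scale, p0_score, plaque_mu, plaque_sd in (
        ("carotid", 0.72, 0.35, 0.85, 0.30, spec.plaque_mean, spec.plaque_sd),
        ("femoral", 0.62, 0.55, 0.70, 0.45, fem_plaque_mean, fem_plaque_sd),
    ):
        cols[f"{territory}_imt_right"] = stats.lognorm.ppf(
            latent_uniform(), 0.16, scale=imt_med
        )
        cols[f"{territory}_imt_left"] = stats.lognorm.ppf(
            latent_uniform(), 0.16, scale=imt_med
        )
        cols[f"{territory}_plaque_number"] = _nbinom_ppf(
            latent_uniform(), plaque_mu, plaque_sd
        )
        cols[f"{territory}_max_stenosis"] = _zero_inflated_beta_ppf(
            latent_uniform(), p0_sten, 2.0, 4.0, 100.0 * sten_scale
        )
        cols[f"{territory}_total_stenosis"] = _zero_inflated_beta_ppf(
            latent_uniform(), p0_sten, 1.5, 2.5, 100.0
        )
        cols[f"{territory}_plaque_score"] = _zero_inflated_gamma_ppf(
            latent_uniform(), p0_score, 1.3, 3.0
        )
    return pd.DataFrame(cols)


ULTRASOUND_COLUMNS = tuple(
    f"{t}_{p}"
    for t in ("carotid", "femoral")
    for p in (
        "imt_right",
        "imt_left",
        "plaque_number",
        "max_stenosis",
        "total_stenosis",
        "plaque_score",
    )
)
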