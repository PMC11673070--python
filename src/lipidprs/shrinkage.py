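"""Bayesian shrinkage of GWAS summary statistics with a spike-and-slab prior
(LDpred-style Gibbs sampler with automatic hyperparameter estimation).

Marginal effects are moved to the standardized scale ``beta_std = z/sqrt(n)``
(``z`` the Wald statistic), where under the standard summary-statistic model
``beta_hat = R beta + e``, ``e ~ N(0, R/n)``, with ``R`` the LD correlation
matrix of a reference panel. Each variant's effect is resampled conditional on
the others through its LD-residualized marginal effect, under the prior

    beta_j = 0 with probability 1 - p_causal,
    beta_j ~ N(0, h2 / (M * p_causal)) otherwise,

and the hyperparameters are updated every sweep: ``p_causal`` from its
conjugate Beta posterior given the inclusion indicators, ``h2`` as the current
genetic variance ``beta' R beta``. No validation cohort is needed; everything
is estimated from the summary statistics and the LD reference. Posterior-mean
effects are averaged over post-burn-in sweeps and returned on the per-allele
scale of the input betas.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.exceptions import NotFittedError

from .containers import GenotypeMatrix, SummaryStats, WeightTable
from .ct import LDMatrix


class NumericalError(RuntimeError):
    """The sampler became unstable; a stronger LD regularization is advised."""


def build_ld_reference(
    genotypes: GenotypeMatrix,
    mask: pd.Index | None = None,
    window_bp: int | None = 500_000,
) -> LDMatrix:
    """Correlation matrix of standardized dosages over (optionally masked) variants.

    ``mask`` emulates a fixed reference variant list (e.g. a genome-wide panel
    restriction): only variants whose ``chrom:pos`` key is in the mask enter
    the LD reference. By default the matrix is banded to a 500 kb window:
    beyond that distance real LD is negligible and the empirical correlations
    of a desk-scale reference are pure sampling noise, which would otherwise
    destabilise the Gibbs residuals. Monomorphic variants are dropped with a
    warning; a reference below 100 samples triggers a warning.
    """
    if genotypes.n_samples < 100:
        warnings.warn(
            f"LD reference has only {genotypes.n_samples} samples; "
            "correlations will be noisy",
            stacklevel=2,
        )
    keep = np.ones(genotypes.n_variants, dtype=bool)
    if mask is not None:
        keep &= np.asarray(genotypes.keys().isin(mask))
        if not keep.any():
            raise ValueError("reference mask excludes every panel variant")
    freq = genotypes.allele_freq()
    poly = (freq > 0) & (freq < 1)
    if (keep & ~poly).any():
        warnings.warn(
            f"dropping {int((keep & ~poly).sum())} monomorphic variant(s) from the LD reference",
            stacklevel=2,
        )
    keep &= poly
    return LDMatrix.from_genotypes(
        genotypes.subset_variants(np.flatnonzero(keep)), window_bp=window_bp
    )


@dataclass
class ShrinkagePosterior:
    """Posterior-mean weights plus hyperparameter chains from one Gibbs run."""

    weights: WeightTable
    posterior_mean_std: np.ndarray
    h2_chain: np.ndarray
    p_causal_chain: np.ndarray
    iterations: int
    burn_in: int
    seed: int

    @property
    def h2_estimate(self) -> float:
        return float(np.mean(self.h2_chain[self.burn_in:]))

    @property
    def p_causal_estimate(self) -> float:
        return float(np.mean(self.p_causal_chain[self.burn_in:]))

    def trace_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sweep": np.arange(len(self.h2_chain)),
                "h2": self.h2_chain,
                "p_causal": self.p_causal_chain,
                "kept": np.arange(len(self.h2_chain)) >= self.burn_in,
            }
        )


def _ld_score_h2(z: np.ndarray, ld_scores: np.ndarray, n: np.ndarray) -> float:
    """Regression-style SNP-heritability initialiser from summary statistics.

    Uses the expectation E[chi²] = 1 + n h2 l_j / M of LD-score regression,
    solved at the mean: h2 ≈ M (mean chi² - 1) / (mean n * mean l).
    """
    m = z.size
    chi2 = z**2
    h2 = m * (chi2.mean() - 1.0) / (n.mean() * ld_scores.mean())
    return float(np.clip(h2, 0.01, 0.9))


class ShrinkagePRS(BaseEstimator):
    """Spike-and-slab Gibbs shrinkage of summary statistics.

    Parameters
    ----------
    iterations : kept sweeps after burn-in.
    burn_in : discarded initial sweeps.
    seed : RNG seed for the chain.
    diag_loading : LD regularization; off-diagonals are shrunk by
        ``1/(1 + diag_loading)`` (diagonal stays 1).
    h2, p_causal : optional fixed hyperparameter values; when None (default)
        they are estimated automatically each sweep.

    Fitted attributes: ``posterior_`` (:class:`ShrinkagePosterior`),
    ``weights_``, ``h2_estimate_``, ``p_causal_estimate_``.
    """

    def __init__(
        self,
        iterations: int = 500,
        burn_in: int = 500,
        seed: int = 0,
        diag_loading: float = 0.01,
        h2: float | None = None,
        p_causal: float | None = None,
    ):
        self.iterations = iterations
        self.burn_in = burn_in
        self.seed = seed
        self.diag_loading = diag_loading
        self.h2 = h2
        self.p_causal = p_causal

    def fit(self, stats: SummaryStats, ld: LDMatrix) -> "ShrinkagePRS":
        if not stats.has_frequencies:
            raise ValueError(
                "summary statistics without effect-allele frequencies cannot be shrunk"
            )
        if "n" not in stats.table.columns:
            raise ValueError("per-variant GWAS sample size 'n' is required")
        skeys = stats.keys()
        if len(skeys) != len(ld.keys) or set(skeys) != set(ld.keys):
            raise ValueError("summary statistics and LD reference must cover the same variants")
        order = ld.keys.get_indexer(skeys)
        r_full = ld.r[np.ix_(order, order)] if not np.array_equal(order, np.arange(len(order))) else ld.r

        t = stats.table
        beta = t["beta"].to_numpy()
        se = t["se"].to_numpy()
        n = t["n"].to_numpy(dtype=float)
        z = beta / se
        beta_hat = z / np.sqrt(n)
        m = beta_hat.size

        shrink = 1.0 / (1.0 + self.diag_loading)
        r_work = r_full * shrink
        np.fill_diagonal(r_work, 1.0)
        ld_scores = (r_full**2).sum(axis=1)

        rng = np.random.default_rng(self.seed)
        auto_h2 = self.h2 is None
        auto_p = self.p_causal is None
        h2_cur = _ld_score_h2(z, ld_scores, n) if auto_h2 else float(self.h2)
        p_cur = 0.1 if auto_p else float(self.p_causal)

        cur = np.zeros(m)
        s = np.zeros(m)  # r_work @ cur, maintained incrementally
        total = self.burn_in + self.iterations
        post_sum = np.zeros(m)
        h2_chain = np.empty(total)
        p_chain = np.empty(total)

        for sweep in range(total):
            sigma2 = h2_cur / (m * p_cur)
            u = rng.random(m)
            eps = rng.standard_normal(m)
            log_prior_odds = np.log(p_cur) - np.log1p(-p_cur) if p_cur < 1.0 else np.inf
            for j in range(m):
                old = cur[j]
                resid = beta_hat[j] - (s[j] - old)
                tau = 1.0 / n[j]
                denom = sigma2 + tau
                post_var = sigma2 * tau / denom
                post_mean = resid * sigma2 / denom
                if np.isinf(log_prior_odds):
                    include = True
                else:
                    log_odds = (
                        log_prior_odds
                        + 0.5 * np.log(tau / denom)
                        + 0.5 * resid**2 * sigma2 / (tau * denom)
                    )
                    include = u[j] < 1.0 / (1.0 + np.exp(-log_odds))
                new = post_mean + np.sqrt(post_var) * eps[j] if include else 0.0
                if new != old:
                    s += r_work[j] * (new - old)
                    cur[j] = new
            if not np.isfinite(s).all():
                raise NumericalError(
                    "Gibbs chain diverged; increase diag_loading to regularize the LD matrix"
                )
            k = int(np.count_nonzero(cur))
            if auto_p:
                p_cur = float(np.clip(rng.beta(1 + k, 1 + m - k), 1.0 / m, 1.0))
            if auto_h2:
                h2_cur = float(np.clip(cur @ s, 1e-4, 1.0))
            h2_chain[sweep] = h2_cur
            p_chain[sweep] = p_cur
            if sweep >= self.burn_in:
                post_sum += cur

        post_std = post_sum / self.iterations
        # back to the per-allele scale of the input betas: beta = beta_std * se * sqrt(n)
        post_allele = post_std * se * np.sqrt(n)
        self.weights_ = WeightTable(
            pd.DataFrame(
                {
                    "chrom": t["chrom"].to_numpy(),
                    "pos": t["pos"].to_numpy(),
                    "effect_allele": t["effect_allele"].to_numpy(),
                    "weight": post_allele,
                }
            ),
            provenance="shrinkage",
        )
        self.posterior_ = ShrinkagePosterior(
            weights=self.weights_,
            posterior_mean_std=post_std,
            h2_chain=h2_chain,
            p_causal_chain=p_chain,
            iterations=self.iterations,
            burn_in=self.burn_in,
            seed=self.seed,
        )
        self.h2_estimate_ = self.posterior_.h2_estimate
        self.p_causal_estimate_ = self.posterior_.p_causal_estimate
        return self

    def predict_weights(self) -> WeightTable:
        if not hasattr(self, "weights_"):
            raise NotFittedError("ShrinkagePRS is not fitted")
        return self.weights_


def gibbs_fit(
    stats: SummaryStats,
    ld: LDMatrix,
    iterations: int = 500,
    burn_in: int = 500,
    seed: int = 0,
    **kwargs,
) -> ShrinkagePosterior:
    """Run the shrinkage sampler and return its posterior summary."""
    model = ShrinkagePRS(iterations=iterations, burn_in=burn_in, seed=seed, **kwargs)
    return model.fit(stats, ld).posterior_
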