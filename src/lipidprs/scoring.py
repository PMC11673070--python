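"""Classical polygenic risk scoring: dosage-weighted sums, Z-score
normalization and strata summaries.

The raw score of sample *i* is ``sum_j w_j * dosage_ij`` over the harmonized
weight table, with missing dosages imputed as twice the cohort effect-allele
frequency. Scores are Z-normalized (mean 0, SD 1) within the cohort the
calculator was fitted on, so a calculator fitted on a training split applies
the training normalization to validation samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.exceptions import NotFittedError

from .containers import GenotypeMatrix, WeightTable, variant_keys


@dataclass
class PRSVector:
    """Per-sample raw and Z-normalized polygenic scores with provenance."""

    samples: list[str]
    raw: np.ndarray
    z: np.ndarray
    provenance: str = "classical"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"sample": self.samples, "raw": self.raw, "z": self.z, "provenance": self.provenance}
        )


class PRSCalculator(TransformerMixin, BaseEstimator):
    """Fixed-weight PRS scorer with cohort-fitted normalization.

    ``fit`` aligns the weight table to the genotype panel, learns the
    imputation allele frequencies and the raw-score mean/SD of the fitting
    cohort; ``transform`` returns Z-scores for (possibly different) samples of
    the same panel. Weight effect alleles must refer to the panel alt allele
    (the harmonization output); weights reported on the ref allele are folded
    by sign flip.
    """

    def __init__(self, weights: WeightTable | None = None):
        self.weights = weights

    def fit(self, genotypes: GenotypeMatrix, y=None) -> "PRSCalculator":
        if self.weights is None or self.weights.n_variants == 0:
            raise ValueError("a non-empty weight table is required")
        panel = genotypes.variants.set_index(variant_keys(genotypes.variants))
        cols, w = [], []
        positions = {k: i for i, k in enumerate(panel.index)}
        for row in self.weights.table.itertuples(index=False):
            key = f"{row.chrom}:{int(row.pos)}"
            if key not in positions:
                raise KeyError(f"weight variant {key} absent from the genotype panel")
            j = positions[key]
            allele = str(row.effect_allele)
            if allele == str(panel.iloc[j]["alt"]):
                w.append(float(row.weight))
            elif allele == str(panel.iloc[j]["ref"]):
                w.append(-float(row.weight))
            else:
                raise ValueError(f"effect allele {allele} matches neither allele at {key}")
            cols.append(j)
        self.columns_ = np.asarray(cols)
        self.w_ = np.asarray(w)
        self.impute_freq_ = genotypes.allele_freq()[self.columns_]
        raw = self._raw(genotypes)
        self.mean_ = float(raw.mean())
        self.sd_ = float(raw.std())
        return self

    def _raw(self, genotypes: GenotypeMatrix) -> np.ndarray:
        d = genotypes.dosages[:, self.columns_].copy()
        missing = ~np.isfinite(d)
        if missing.any():
            fill = np.broadcast_to(2.0 * self.impute_freq_, d.shape)
            d[missing] = fill[missing]
        return d @ self.w_

    def transform(self, genotypes: GenotypeMatrix) -> np.ndarray:
        """Z-normalized scores under the fitted cohort normalization."""
        if not hasattr(self, "w_"):
            raise NotFittedError("PRSCalculator is not fitted")
        if self.sd_ == 0:
            raise ValueError("constant PRS in the fitting cohort; cannot Z-normalize")
        return (self._raw(genotypes) - self.mean_) / self.sd_

    def score_vector(self, genotypes: GenotypeMatrix) -> PRSVector:
        raw = self._raw(genotypes)
        # a constant score (e.g. all-zero weights) has no Z-normalization
        z = self.transform(genotypes) if self.sd_ != 0 else np.full(raw.shape, np.nan)
        return PRSVector(
            samples=list(genotypes.samples),
            raw=raw,
            z=z,
            provenance=self.weights.provenance,
        )


def compute_prs(genotypes: GenotypeMatrix, weights: WeightTable) -> PRSVector:
    """Score a cohort with a harmonized weight table (cohort-level normalization)."""
    return PRSCalculator(weights).fit(genotypes).score_vector(genotypes)


def stratify(prs: PRSVector, phenotype: np.ndarray, n_strata: int = 5) -> pd.DataFrame:
    """Equal-count score strata with per-stratum mean phenotype and 95% CI.

    Samples are ranked by Z-score (stable order on ties) and split into
    ``n_strata`` contiguous groups of near-equal size; each row reports the
    stratum's score range, size and mean phenotype with a normal-approximation
    confidence interval.
    """
    phenotype = np.asarray(phenotype, dtype=float)
    n = len(prs.z)
    if n_strata < 2:
        raise ValueError("n_strata must be >= 2")
    if n < 2 * n_strata:
        raise ValueError("cohort too small for the requested number of strata")
    if np.ptp(prs.z) == 0:
        raise ValueError("constant PRS cannot be stratified")
    order = np.argsort(prs.z, kind="stable")
    rows = []
    for s, idx in enumerate(np.array_split(order, n_strata)):
        vals = phenotype[idx]
        se = vals.std(ddof=1) / np.sqrt(len(idx)) if len(idx) > 1 else np.nan
        half = stats.norm.ppf(0.975) * se
        rows.append(
            {
                "stratum": s + 1,
                "n": len(idx),
                "score_min": float(prs.z[idx].min()),
                "score_max": float(prs.z[idx].max()),
                "mean_phenotype": float(vals.mean()),
                "ci_lo": float(vals.mean() - half),
                "ci_hi": float(vals.mean() + half),
            }
        )
    return pd.DataFrame(rows)
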