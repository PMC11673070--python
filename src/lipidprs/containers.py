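"""In-memory containers for genotype, summary-statistic, weight and phenotype data.

The package works with four kinds of tabular data:

* :class:`GenotypeMatrix` -- per-sample effect-allele dosages plus variant metadata,
  as parsed from a VCF.
* :class:`SummaryStats` -- per-variant GWAS summary statistics (effect size, standard
  error, p-value, effect-allele frequency, GWAS sample size).
* :class:`WeightTable` -- harmonized scoring weights, ready for dosage-weighted summation.
* Phenotype/covariate tables are plain :class:`pandas.DataFrame` objects indexed by
  sample id; no wrapper is needed.

Variants are identified by the key ``(chrom, pos, ref, alt)`` (1-based positions, as
in VCF). Dosages count copies of the alt allele and live in ``{0, 1, 2}`` with ``NaN``
for missing genotypes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Columns every summary-statistics table must provide.
SUMSTAT_COLUMNS = ("chrom", "pos", "effect_allele", "other_allele", "beta", "se", "pval")
#: Optional summary-statistic columns used by the shrinkage model.
SUMSTAT_OPTIONAL = ("eaf", "n")
#: Columns every weight table must provide.
WEIGHT_COLUMNS = ("chrom", "pos", "effect_allele", "weight")


class SchemaError(ValueError):
    """A table is missing a required column or violates a domain bound."""


def variant_keys(frame: pd.DataFrame) -> pd.Index:
    """Composite ``chrom:pos`` keys for a variant table (position-based matching)."""
    return pd.Index(frame["chrom"].astype(str) + ":" + frame["pos"].astype(int).astype(str))


@dataclass
class GenotypeMatrix:
    """Effect-allele dosage matrix with variant and sample metadata.

    Parameters
    ----------
    samples : list of sample ids (unique).
    variants : DataFrame with columns ``chrom, pos, id, ref, alt`` (one row per
        variant, unique on (chrom, pos, ref, alt)).
    dosages : float array of shape (n_samples, n_variants); values in {0, 1, 2}
        or NaN for missing calls.
    """

    samples: list[str]
    variants: pd.DataFrame
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.samples), len(self.variants)):
            raise ValueError(
                f"dosage matrix shape {self.dosages.shape} does not match "
                f"{len(self.samples)} samples x {len(self.variants)} variants"
            )
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("sample ids are not unique")
        finite = self.dosages[np.isfinite(self.dosages)]
        if finite.size and not np.isin(finite, (0.0, 1.0, 2.0)).all():
            raise ValueError("dosages must be 0, 1, 2 or missing (NaN)")
        keys = list(
            zip(self.variants["chrom"], self.variants["pos"], self.variants["ref"], self.variants["alt"])
        )
        if len(set(keys)) != len(keys):
            raise ValueError("variant keys (chrom, pos, ref, alt) are not unique")
        self.variants = self.variants.reset_index(drop=True)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def call_rate(self) -> np.ndarray:
        """Per-variant fraction of non-missing genotypes."""
        return np.isfinite(self.dosages).mean(axis=0)

    def allele_freq(self) -> np.ndarray:
        """Per-variant empirical alt-allele frequency over non-missing calls."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosages, axis=0) / 2.0

    def imputed_dosages(self) -> np.ndarray:
        """Dosages with missing entries replaced by ``2 x`` cohort alt-allele frequency."""
        filled = self.dosages.copy()
        freq = self.allele_freq()
        missing = ~np.isfinite(filled)
        if missing.any():
            fill = np.broadcast_to(2.0 * freq, filled.shape)
            filled[missing] = fill[missing]
        return filled

    def keys(self) -> pd.Index:
        return variant_keys(self.variants)

    def subset_samples(self, sample_ids: list[str]) -> "GenotypeMatrix":
        index = {s: i for i, s in enumerate(self.samples)}
        rows = [index[s] for s in sample_ids]
        return GenotypeMatrix(list(sample_ids), self.variants.copy(), self.dosages[rows])

    def subset_variants(self, positions: np.ndarray) -> "GenotypeMatrix":
        positions = np.asarray(positions)
        return GenotypeMatrix(
            list(self.samples), self.variants.iloc[positions].copy(), self.dosages[:, positions]
        )


@dataclass
class SummaryStats:
    """GWAS summary statistics, one row per variant.

    ``table`` must contain :data:`SUMSTAT_COLUMNS`; ``eaf`` (effect-allele
    frequency) and ``n`` (GWAS sample size) are optional but required by the
    shrinkage model. Validation enforces p in (0, 1], SE > 0 and non-identical
    alleles.
    """

    table: pd.DataFrame
    has_frequencies: bool = field(init=False)

    def __post_init__(self) -> None:
        missing = [c for c in SUMSTAT_COLUMNS if c not in self.table.columns]
        if missing:
            raise SchemaError(f"summary statistics missing required column(s): {', '.join(missing)}")
        t = self.table.reset_index(drop=True).copy()
        t["pos"] = t["pos"].astype(int)
        t["chrom"] = t["chrom"].astype(str)
        for col in ("beta", "se", "pval"):
            t[col] = t[col].astype(float)
        if ((t["pval"] <= 0) | (t["pval"] > 1)).any():
            raise SchemaError("p-values must lie in (0, 1]")
        if (t["se"] <= 0).any():
            raise SchemaError("standard errors must be positive")
        if (t["effect_allele"] == t["other_allele"]).any():
            raise SchemaError("effect and other allele must differ")
        self.has_frequencies = "eaf" in t.columns and t["eaf"].notna().all()
        if self.has_frequencies:
            t["eaf"] = t["eaf"].astype(float)
            if ((t["eaf"] <= 0) | (t["eaf"] >= 1)).any():
                raise SchemaError("effect-allele frequencies must lie in (0, 1)")
        self.table = t

    @property
    def n_variants(self) -> int:
        return len(self.table)

    def keys(self) -> pd.Index:
        return variant_keys(self.table)


@dataclass
class WeightTable:
    """Harmonized per-variant scoring weights.

    The ``provenance`` tag records how the weights were produced
    (``"classical"``, ``"ct"`` or ``"shrinkage"``).
    """

    table: pd.DataFrame
    provenance: str = "classical"

    def __post_init__(self) -> None:
        missing = [c for c in WEIGHT_COLUMNS if c not in self.table.columns]
        if missing:
            raise SchemaError(f"weight table missing required column(s): {', '.join(missing)}")
        t = self.table.reset_index(drop=True).copy()
        t["pos"] = t["pos"].astype(int)
        t["chrom"] = t["chrom"].astype(str)
        t["weight"] = t["weight"].astype(float)
        if variant_keys(t).duplicated().any():
            raise SchemaError("duplicate variant keys in weight table")
        self.table = t

    @property
    def n_variants(self) -> int:
        return len(self.table)

    def keys(self) -> pd.Index:
        return variant_keys(self.table)
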