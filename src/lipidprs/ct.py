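"""Clumping + thresholding (C+T) PRS construction with grid-search tuning.

Clumping greedily keeps the most significant variant of each LD group: the
smallest-p unclaimed variant becomes an index variant and discards every
unclaimed variant correlated with it above the r² threshold. Thresholding then
retains clumped variants with GWAS p at or below a p-value threshold. The
tuner scores every (r², p-threshold) grid cell on a training split, selects
the cell with the highest training incremental R² (ties: fewer variants, then
smaller r²), and reports the validation incremental R² separately.

The p-threshold grid is log10-uniform between its bounds (default 1e-100 to
1e-4, 49 points); an arithmetic grid over that range would be degenerate, as
every representable step collapses onto the largest thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.exceptions import NotFittedError

from ._stats import PartialR2
from .containers import GenotypeMatrix, SummaryStats, WeightTable
from .scoring import PRSCalculator

DEFAULT_R2_THRESHOLDS = (0.0, 0.1, 0.2, 0.3, 0.4, 0.5)


def default_p_thresholds(low: float = 1e-100, high: float = 1e-4, n: int = 49) -> np.ndarray:
    """Log10-uniform p-value threshold grid spanning [low, high]."""
    return np.logspace(np.log10(low), np.log10(high), n)


@dataclass
class LDMatrix:
    """Pairwise dosage correlation of a variant panel in a reference sample."""

    keys: pd.Index
    r: np.ndarray  # signed Pearson correlation; r**2 is the clumping metric

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        if self.r.shape != (len(self.keys), len(self.keys)):
            raise ValueError("LD matrix shape does not match key count")

    @property
    def r2(self) -> np.ndarray:
        return self.r**2

    @classmethod
    def from_genotypes(
        cls, genotypes: GenotypeMatrix, window_bp: int | None = None
    ) -> "LDMatrix":
        """Empirical dosage correlation, optionally banded to a physical window.

        With ``window_bp`` set, correlations between variants farther apart
        than the window (or on different chromosomes) are zeroed: distant
        pairs have no real LD, and the sampling noise of their empirical
        correlations would otherwise swamp genuine signal in downstream
        summary-statistic models.
        """
        d = genotypes.imputed_dosages()
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.atleast_2d(np.corrcoef(d, rowvar=False))
        # monomorphic columns carry no LD information: correlation 0, self 1
        np.nan_to_num(r, copy=False)
        np.fill_diagonal(r, 1.0)
        if window_bp is not None:
            pos = genotypes.variants["pos"].to_numpy(dtype=float)
            chrom = genotypes.variants["chrom"].to_numpy()
            near = np.abs(pos[:, None] - pos[None, :]) <= window_bp
            near &= chrom[:, None] == chrom[None, :]
            r = np.where(near, r, 0.0)
        return cls(genotypes.keys(), r)


@dataclass
class CTGrid:
    """The (clumping r², p-threshold) search grid."""

    r2_thresholds: tuple[float, ...] = DEFAULT_R2_THRESHOLDS
    p_thresholds: np.ndarray = field(default_factory=default_p_thresholds)

    def __post_init__(self) -> None:
        r2 = tuple(sorted(self.r2_thresholds))
        if len(set(r2)) != len(r2) or any(not 0.0 <= v <= 1.0 for v in r2):
            raise ValueError("r2 thresholds must be unique values in [0, 1]")
        p = np.sort(np.asarray(self.p_thresholds, dtype=float))
        if len(np.unique(p)) != len(p) or ((p <= 0) | (p >= 1)).any():
            raise ValueError("p thresholds must be unique values in (0, 1)")
        self.r2_thresholds = r2
        self.p_thresholds = p


def clump(stats: SummaryStats, ld: LDMatrix, r2_threshold: float) -> np.ndarray:
    """Greedy LD clumping; returns row positions of index variants in ``stats``.

    Repeatedly takes the smallest-p unclaimed variant (ties broken by
    (chrom, pos)) as an index variant and discards all unclaimed variants with
    r² above the threshold to it.
    """
    if stats.n_variants == 0:
        raise ValueError("empty summary statistics")
    skeys = stats.keys()
    pos_in_ld = ld.keys.get_indexer(skeys)
    if (pos_in_ld < 0).any():
        raise KeyError("summary-statistic variants must all be present in the LD matrix")
    r2 = ld.r2[np.ix_(pos_in_ld, pos_in_ld)]

    t = stats.table
    order = np.lexsort((t["pos"].to_numpy(), t["chrom"].to_numpy(), t["pval"].to_numpy()))
    claimed = np.zeros(len(t), dtype=bool)
    index_set = []
    for i in order:
        if claimed[i]:
            continue
        index_set.append(i)
        claimed[r2[i] > r2_threshold] = True
        claimed[i] = True
    return np.sort(np.asarray(index_set))


def split_4to1(sample_ids: list[str], seed: int) -> tuple[list[str], list[str]]:
    """Random 4:1 partition into training and validation ids.

    Validation size is ``n/5`` rounded half up; the split is a seeded shuffle,
    disjoint and exhaustive.
    """
    n = len(sample_ids)
    if n < 5:
        raise ValueError("need at least 5 samples for a 4:1 split")
    n_valid = int(np.floor(n / 5.0 + 0.5))
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    valid = [sample_ids[i] for i in sorted(perm[:n_valid])]
    train = [sample_ids[i] for i in sorted(perm[n_valid:])]
    return train, valid


class ClumpThresholdPRS(BaseEstimator):
    """C+T PRS tuner over a (clumping r², p-threshold) grid.

    Fitted attributes: ``results_`` (long-format per-cell table),
    ``best_r2_threshold_``, ``best_p_threshold_``, ``n_variants_``,
    ``weights_`` (the selected weight table), ``train_delta_r2_`` and, after
    :meth:`validate`, ``validation_delta_r2_``.
    """

    def __init__(self, grid: CTGrid | None = None):
        self.grid = grid

    def fit(
        self,
        genotypes: GenotypeMatrix,
        phenotype: np.ndarray,
        stats: SummaryStats,
        covariates: np.ndarray | None = None,
    ) -> "ClumpThresholdPRS":
        grid = self.grid if self.grid is not None else CTGrid()
        phenotype = np.asarray(phenotype, dtype=float)
        if phenotype.shape[0] != genotypes.n_samples:
            raise ValueError("phenotype length must match the training cohort")

        panel_keys = genotypes.keys()
        in_panel = stats.keys().isin(panel_keys)
        if not in_panel.any():
            raise ValueError("no summary-statistic variant is present in the training panel")
        stats = SummaryStats(stats.table.loc[in_panel].reset_index(drop=True))

        ld = LDMatrix.from_genotypes(genotypes)
        col_of = {k: j for j, k in enumerate(panel_keys)}
        stat_cols = np.asarray([col_of[k] for k in stats.keys()])
        dosages = genotypes.imputed_dosages()
        betas = stats.table["beta"].to_numpy()
        pvals = stats.table["pval"].to_numpy()

        partial = PartialR2(phenotype, covariates)
        rows = []
        best = None
        for r2_thr in grid.r2_thresholds:
            clumped = clump(stats, ld, r2_thr)
            p_clumped = pvals[clumped]
            for p_thr in grid.p_thresholds:
                sel = clumped[p_clumped <= p_thr]
                if sel.size == 0:
                    rows.append(
                        {"r2": r2_thr, "p_thr": p_thr, "n_variants": 0,
                         "r2_train": np.nan, "p_anova": np.nan}
                    )
                    continue
                score = dosages[:, stat_cols[sel]] @ betas[sel]
                d_r2, _, p_anova = partial.delta_r2(score)
                rows.append(
                    {"r2": r2_thr, "p_thr": p_thr, "n_variants": int(sel.size),
                     "r2_train": d_r2, "p_anova": p_anova}
                )
                cand = (d_r2, -int(sel.size), -r2_thr)
                if best is None or cand > best[0]:
                    best = (cand, r2_thr, p_thr, sel)
        if best is None:
            raise ValueError("every grid cell is empty of variants; cannot tune")

        _, r2_thr, p_thr, sel = best
        self.results_ = pd.DataFrame(rows)
        self.best_r2_threshold_ = float(r2_thr)
        self.best_p_threshold_ = float(p_thr)
        self.n_variants_ = int(sel.size)
        chosen = stats.table.iloc[sel]
        self.weights_ = WeightTable(
            pd.DataFrame(
                {
                    "chrom": chosen["chrom"].to_numpy(),
                    "pos": chosen["pos"].to_numpy(),
                    "effect_allele": chosen["effect_allele"].to_numpy(),
                    "weight": chosen["beta"].to_numpy(),
                }
            ),
            provenance="ct",
        )
        self.scorer_ = PRSCalculator(self.weights_).fit(genotypes)
        self.train_delta_r2_ = float(self.results_.loc[
            (self.results_["r2"] == r2_thr)
            & (self.results_["p_thr"] == p_thr), "r2_train"
        ].iloc[0])
        return self

    def predict(self, genotypes: GenotypeMatrix) -> np.ndarray:
        """Z-scores of the tuned PRS under the training normalization."""
        if not hasattr(self, "scorer_"):
            raise NotFittedError("ClumpThresholdPRS is not fitted")
        return self.scorer_.transform(genotypes)

    def validate(
        self,
        genotypes: GenotypeMatrix,
        phenotype: np.ndarray,
        covariates: np.ndarray | None = None,
    ) -> float:
        """Incremental R² of the tuned score on held-out samples."""
        score = self.predict(genotypes)
        d_r2, _, _ = PartialR2(np.asarray(phenotype, dtype=float), covariates).delta_r2(score)
        self.validation_delta_r2_ = float(d_r2)
        return self.validation_delta_r2_


def tune(
    stats: SummaryStats,
    genotypes_train: GenotypeMatrix,
    phenotype_train: np.ndarray,
    covariates: np.ndarray | None = None,
    grid: CTGrid | None = None,
) -> ClumpThresholdPRS:
    """Grid-search C+T tuning on a training split (spec-level convenience wrapper)."""
    return ClumpThresholdPRS(grid=grid).fit(genotypes_train, phenotype_train, stats, covariates)
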