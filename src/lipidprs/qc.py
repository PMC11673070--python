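"""Cohort quality control: relatedness pruning by identity-by-descent and
ancestry-outlier removal by PCA plus hierarchical clustering.

Relatedness uses a method-of-moments estimator of the IBD state probabilities
from pairwise identity-by-state counts given allele frequencies (the PLINK
``--genome`` construction, re-derived). The summary statistic is
``PI_HAT = P(IBD=2) + P(IBD=1)/2``; above a threshold (default 0.33, i.e.
closer than second degree) the younger member of each pair is removed.

Outliers are flagged by Ward-linkage agglomerative clustering of the top
principal-component scores: samples falling in clusters smaller than a set
fraction of the cohort are treated as ancestry outliers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.decomposition import PCA

from .containers import GenotypeMatrix

PI_HAT_THRESHOLD = 0.33


class QCError(ValueError):
    """Quality-control stage could not run on the given inputs."""


def estimate_ibd(genotypes: GenotypeMatrix, min_maf: float = 0.01) -> pd.DataFrame:
    """Method-of-moments IBD estimates for all sample pairs.

    Returns a table with one row per unordered pair: ``sample_a``,
    ``sample_b``, ``p_ibd0``, ``p_ibd1``, ``p_ibd2`` (truncated to [0, 1] and
    renormalized) and ``pi_hat``. Only variants with minor-allele frequency
    above ``min_maf`` contribute; missing genotypes are excluded pairwise.
    """
    if genotypes.n_samples < 2:
        raise QCError("IBD estimation needs at least two samples")
    freq = genotypes.allele_freq()
    maf = np.minimum(freq, 1.0 - freq)
    keep = maf > min_maf
    if not keep.any():
        raise QCError("all variants are (near-)monomorphic; cannot estimate IBD")
    if keep.sum() < 50:
        raise QCError(f"only {int(keep.sum())} variants with maf > {min_maf}; need >= 50")

    d = genotypes.dosages[:, keep]
    p = freq[keep]
    q = 1.0 - p

    # P(IBS | IBD) under Hardy-Weinberg, per variant
    e_ibs0_ibd0 = 2.0 * p**2 * q**2
    e_ibs1_ibd0 = 4.0 * p**3 * q + 4.0 * p * q**3
    e_ibs2_ibd0 = p**4 + q**4 + 4.0 * p**2 * q**2
    e_ibs1_ibd1 = 2.0 * p**2 * q + 2.0 * p * q**2
    e_ibs2_ibd1 = p**3 + q**3 + p**2 * q + p * q**2

    finite = np.isfinite(d)
    a0 = np.where(finite, d == 0, False).astype(float)
    a1 = np.where(finite, d == 1, False).astype(float)
    a2 = np.where(finite, d == 2, False).astype(float)
    fin = finite.astype(float)

    ibs0 = a0 @ a2.T + a2 @ a0.T
    ibs2 = a0 @ a0.T + a1 @ a1.T + a2 @ a2.T
    total = fin @ fin.T
    ibs1 = total - ibs0 - ibs2

    def pair_expect(e: np.ndarray) -> np.ndarray:
        return (fin * e) @ fin.T

    s00, s10, s20 = pair_expect(e_ibs0_ibd0), pair_expect(e_ibs1_ibd0), pair_expect(e_ibs2_ibd0)
    s11, s21 = pair_expect(e_ibs1_ibd1), pair_expect(e_ibs2_ibd1)

    n = genotypes.n_samples
    ia, ib = np.triu_indices(n, k=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        p0 = ibs0[ia, ib] / s00[ia, ib]
        p1 = (ibs1[ia, ib] - p0 * s10[ia, ib]) / s11[ia, ib]
        p2 = (ibs2[ia, ib] - p0 * s20[ia, ib] - p1 * s21[ia, ib]) / total[ia, ib]
    probs = np.clip(np.column_stack([p0, p1, p2]), 0.0, 1.0)
    probs /= probs.sum(axis=1, keepdims=True)

    samples = np.asarray(genotypes.samples)
    return pd.DataFrame(
        {
            "sample_a": samples[ia],
            "sample_b": samples[ib],
            "p_ibd0": probs[:, 0],
            "p_ibd1": probs[:, 1],
            "p_ibd2": probs[:, 2],
            "pi_hat": probs[:, 2] + probs[:, 1] / 2.0,
        }
    )


def prune_relatives(
    pairs: pd.DataFrame,
    ages: pd.Series | dict,
    threshold: float = PI_HAT_THRESHOLD,
) -> list[str]:
    """Samples to remove so that no retained pair has PI_HAT above ``threshold``.

    The younger member of each flagged pair is removed (age tie: the
    lexicographically larger id). Pairs are processed in decreasing PI_HAT
    order (id order on ties), so the result is independent of input ordering.
    """
    ages = dict(ages)
    flagged = pairs[pairs["pi_hat"] > threshold]
    for col in ("sample_a", "sample_b"):
        missing = [s for s in flagged[col] if s not in ages or pd.isna(ages.get(s))]
        if missing:
            raise QCError(f"age missing for flagged sample(s): {sorted(set(missing))}")

    order = flagged.sort_values(
        by=["pi_hat", "sample_a", "sample_b"], ascending=[False, True, True]
    )
    removed: list[str] = []
    gone: set[str] = set()
    for row in order.itertuples(index=False):
        a, b = row.sample_a, row.sample_b
        if a in gone or b in gone:
            continue
        if ages[a] < ages[b]:
            victim = a
        elif ages[b] < ages[a]:
            victim = b
        else:
            victim = max(a, b)
        removed.append(victim)
        gone.add(victim)
    return removed


@dataclass
class PCAResult:
    """PCA scores, explained-variance fractions, cluster labels and outlier flags."""

    samples: list[str]
    scores: np.ndarray
    variance_fractions: np.ndarray
    cluster_labels: np.ndarray
    outlier: np.ndarray

    def outlier_ids(self) -> list[str]:
        return [s for s, o in zip(self.samples, self.outlier) if o]


def pca_outliers(
    genotypes: GenotypeMatrix,
    k: int = 10,
    cut: float = 0.01,
    max_clusters: int = 10,
) -> PCAResult:
    """Flag ancestry outliers via PCA and Ward-linkage clustering.

    Dosages are mean-imputed and standardized, projected on the first ``k``
    principal components; samples are clustered (Ward linkage, Euclidean,
    dendrogram cut into at most ``max_clusters`` groups) and any cluster
    holding fewer than ``cut`` of the cohort is flagged as outlying.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    if k >= min(genotypes.n_samples, genotypes.n_variants):
        raise ValueError("k must be smaller than both sample and variant counts")
    if not 0.0 < cut < 1.0:
        raise ValueError("cut must lie in (0, 1)")

    d = genotypes.imputed_dosages()
    sd = d.std(axis=0)
    sd[sd == 0] = 1.0
    z = (d - d.mean(axis=0)) / sd
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(z)

    tree = linkage(scores, method="ward")
    labels = fcluster(tree, t=max_clusters, criterion="maxclust")
    sizes = pd.Series(labels).value_counts()
    small = set(sizes[sizes < cut * genotypes.n_samples].index)
    outlier = np.array([lab in small for lab in labels])
    return PCAResult(
        samples=list(genotypes.samples),
        scores=scores,
        variance_fractions=pca.explained_variance_ratio_,
        cluster_labels=labels,
        outlier=outlier,
    )


def qc_accounting(initial_n: int, removals: dict[str, int]) -> pd.DataFrame:
    """Stage-by-stage sample accounting for a QC run.

    Returns a table with one row per stage (removal count and remaining n)
    plus a ``final`` row; raises if any stage removes more samples than remain.
    """
    rows = []
    n = initial_n
    for stage, removed in removals.items():
        if removed < 0 or removed > n:
            raise QCError(f"stage {stage!r} removes {removed} of {n} samples")
        n -= removed
        rows.append({"stage": stage, "removed": removed, "remaining": n})
    rows.append({"stage": "final", "removed": 0, "remaining": n})
    return pd.DataFrame(rows)
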