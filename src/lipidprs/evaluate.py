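"""Association statistics for PRS evaluation: covariate-adjusted incremental
R² with nested-model ANOVA p-values and bootstrap CIs, Spearman rank
correlation with bootstrap CIs, per-SD effects, and the Bonferroni-screened
PRS × ultrasound association scan.

Incremental R² is the increase in the linear model's coefficient of
determination when a Z-normalized PRS is added to a covariate-only model
(sex, age, BMI, smoking as two indicator contrasts against "never smoked",
and statin intake); its p-value comes from the nested-model F test. Complete
cases only (listwise deletion).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from ._stats import PartialR2

#: Default covariate columns, in the encoding produced by :func:`covariate_design`.
COVARIATE_COLUMNS = ("age", "sex", "bmi", "smoking", "statin")


class RankDeficiencyError(ValueError):
    """The covariate design is collinear; names the offending columns."""


def covariate_design(
    table: pd.DataFrame, columns: tuple[str, ...] = COVARIATE_COLUMNS
) -> pd.DataFrame:
    """Numeric covariate design; 3-level smoking becomes two dummy contrasts."""
    out = {}
    for col in columns:
        if col not in table.columns:
            raise KeyError(f"covariate column {col!r} not found")
        if col == "smoking":
            smoking = table[col].to_numpy()
            out["smoking_ex"] = (smoking == 1).astype(float)
            out["smoking_current"] = (smoking == 2).astype(float)
        else:
            out[col] = table[col].to_numpy(dtype=float)
    return pd.DataFrame(out, index=table.index)


@dataclass
class AssociationResult:
    """One PRS-phenotype association, on the reporting scale of the results tables."""

    phenotype: str
    prs_id: str
    n: int
    delta_r2_pct: float
    r2_ci_lo: float
    r2_ci_hi: float
    p_anova: float
    beta_per_sd: float
    beta_ci_lo: float
    beta_ci_hi: float
    rho: float = np.nan
    rho_ci_lo: float = np.nan
    rho_ci_hi: float = np.nan
    rho_p: float = np.nan
    significant_bonferroni: bool | None = None


def _complete_cases(*arrays: np.ndarray) -> np.ndarray:
    ok = np.ones(arrays[0].shape[0], dtype=bool)
    for a in arrays:
        if a is None:
            continue
        a = np.asarray(a, dtype=float)
        ok &= np.isfinite(a if a.ndim == 1 else a).all(axis=1) if a.ndim > 1 else np.isfinite(a)
    return ok


def _check_rank(design: pd.DataFrame) -> None:
    x = design.to_numpy(dtype=float)
    x = np.column_stack([np.ones(len(x)), x])
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        q, r = np.linalg.qr(x)
        diag = np.abs(np.diag(r))
        bad = diag < diag.max() * 1e-10
        names = [design.columns[i - 1] for i in np.flatnonzero(bad) if i > 0]
        raise RankDeficiencyError(f"collinear covariate column(s): {', '.join(names)}")


def incremental_r2(
    phenotype: np.ndarray,
    covariates: pd.DataFrame | None,
    prs: np.ndarray,
    phenotype_id: str = "phenotype",
    prs_id: str = "prs",
) -> AssociationResult:
    """Incremental R² of a PRS over the covariate model, via nested OLS fits.

    Returns the result with ΔR² in percent, the ANOVA (F-test) p-value of the
    nested-model comparison, and the PRS coefficient per 1 SD with its
    normal-theory 95% CI. Bootstrap CIs for ΔR² are added separately by
    :func:`bootstrap_ci_r2`.
    """
    y = np.asarray(phenotype, dtype=float)
    x = np.asarray(prs, dtype=float)
    cov = covariates.reset_index(drop=True) if covariates is not None else None
    keep = _complete_cases(y, x, cov.to_numpy(dtype=float) if cov is not None else None)
    y, x = y[keep], x[keep]
    cov = cov.loc[keep] if cov is not None else None
    if cov is not None:
        _check_rank(cov)
        base = sm.add_constant(cov.to_numpy(dtype=float))
    else:
        base = np.ones((y.size, 1))

    fit_cov = sm.OLS(y, base).fit()
    fit_full = sm.OLS(y, np.column_stack([base, x])).fit()
    f_stat, p_anova, _ = fit_full.compare_f_test(fit_cov)
    delta = fit_full.rsquared - fit_cov.rsquared
    coef = fit_full.params[-1]
    ci_lo, ci_hi = fit_full.conf_int()[-1]
    return AssociationResult(
        phenotype=phenotype_id,
        prs_id=prs_id,
        n=int(y.size),
        delta_r2_pct=100.0 * float(delta),
        r2_ci_lo=np.nan,
        r2_ci_hi=np.nan,
        p_anova=float(p_anova),
        beta_per_sd=float(coef),
        beta_ci_lo=float(ci_lo),
        beta_ci_hi=float(ci_hi),
    )


def bootstrap_ci_r2(
    phenotype: np.ndarray,
    covariates: pd.DataFrame | None,
    prs: np.ndarray,
    reps: int = 1000,
    seed: int = 0,
    level: float = 0.95,
) -> tuple[float, float]:
    """Percentile bootstrap CI (percent scale) for the incremental R².

    Case resampling; a degenerate resample (constant PRS or phenotype) is
    redrawn and counted.
    """
    if reps < 100:
        raise ValueError("reps must be >= 100")
    y = np.asarray(phenotype, dtype=float)
    x = np.asarray(prs, dtype=float)
    cov = covariates.to_numpy(dtype=float) if covariates is not None else None
    keep = _complete_cases(y, x, cov)
    y, x = y[keep], x[keep]
    cov = cov[keep] if cov is not None else None
    n = y.size
    rng = np.random.default_rng(seed)

    vals = np.empty(reps)
    redrawn = 0
    i = 0
    while i < reps:
        idx = rng.integers(0, n, n)
        if np.ptp(x[idx]) == 0 or np.ptp(y[idx]) == 0:
            redrawn += 1
            if redrawn > 100 * reps:
                raise RuntimeError("bootstrap resampling keeps degenerating")
            continue
        partial = PartialR2(y[idx], cov[idx] if cov is not None else None)
        vals[i], _, _ = partial.delta_r2(x[idx])
        i += 1
    alpha = 1.0 - level
    lo, hi = np.quantile(100.0 * vals, [alpha / 2, 1 - alpha / 2])
    return float(lo), float(hi)


def spearman_ci(
    x: np.ndarray,
    y: np.ndarray,
    reps: int = 1000,
    seed: int = 0,
    level: float = 0.95,
) -> tuple[float, tuple[float, float], float]:
    """Spearman ρ (midranks for ties), bootstrap percentile CI, and t-approximation p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = _complete_cases(x, y)
    x, y = x[keep], y[keep]
    if x.size < 10:
        raise ValueError("need at least 10 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Spearman correlation undefined for constant input")
    rho, p = stats.spearmanr(x, y)
    rng = np.random.default_rng(seed)
    boots = np.empty(reps)
    i = 0
    while i < reps:
        idx = rng.integers(0, x.size, x.size)
        if np.ptp(x[idx]) == 0 or np.ptp(y[idx]) == 0:
            continue
        boots[i] = stats.spearmanr(x[idx], y[idx]).statistic
        i += 1
    alpha = 1.0 - level
    lo, hi = np.quantile(boots, [alpha / 2, 1 - alpha / 2])
    return float(rho), (float(lo), float(hi)), float(p)


def bonferroni_threshold(alpha: float, m_tests: int) -> float:
    """Family-wise adjusted significance threshold ``alpha / m_tests``."""
    if m_tests <= 0:
        raise ValueError("m_tests must be positive")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    return alpha / m_tests


def association_screen(
    prs_set: pd.DataFrame,
    ultrasound: pd.DataFrame,
    covariates: pd.DataFrame | None,
    alpha: float = 0.05,
    m_tests: int | None = None,
    spearman_reps: int = 0,
    seed: int = 0,
) -> pd.DataFrame:
    """Screen every PRS against every ultrasound parameter.

    ``m_tests`` is the size of the per-parameter test family (defaults to the
    number of PRS columns); a pair is flagged significant when its
    nested-model ANOVA p-value is at or below ``alpha / m_tests``. Spearman ρ
    is reported alongside with its own nominal p (bootstrap CIs when
    ``spearman_reps`` > 0). Listwise deletion per parameter; results are
    independent of PRS column order.
    """
    if m_tests is None:
        m_tests = prs_set.shape[1]
    threshold = bonferroni_threshold(alpha, m_tests)

    rows = []
    for param in ultrasound.columns:
        y = ultrasound[param].to_numpy(dtype=float)
        keep = _complete_cases(
            y,
            prs_set.to_numpy(dtype=float),
            covariates.to_numpy(dtype=float) if covariates is not None else None,
        )
        yk = y[keep]
        covk = covariates.loc[keep].to_numpy(dtype=float) if covariates is not None else None
        partial = PartialR2(yk, covk)
        for prs_id in prs_set.columns:
            x = prs_set[prs_id].to_numpy(dtype=float)[keep]
            d_r2, _, p_anova = partial.delta_r2(x)
            rho, p_rho = stats.spearmanr(x, yk)
            row = {
                "phenotype": param,
                "prs_id": prs_id,
                "n": int(yk.size),
                "delta_r2_pct": 100.0 * d_r2,
                "p_anova": p_anova,
                "rho": float(rho),
                "rho_p": float(p_rho),
                "threshold": threshold,
                "significant_bonferroni": bool(p_anova <= threshold),
            }
            if spearman_reps > 0:
                _, (lo, hi), _ = spearman_ci(x, yk, reps=spearman_reps, seed=seed)
                row["rho_ci_lo"], row["rho_ci_hi"] = lo, hi
            rows.append(row)
    return pd.DataFrame(rows)
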