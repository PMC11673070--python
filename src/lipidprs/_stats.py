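"""Fast incremental-R² primitives shared by the tuner, the split experiment and
the association screen.

The incremental R² of a single added predictor equals the squared partial
correlation of outcome and predictor given the covariates, times
``1 - R²_cov``; residualizing both against the covariate design once makes
each additional predictor an O(n) dot product. The public statistics module
fits the same quantity through statsmodels; the two routes are checked against
each other in the test suite.
"""

from __future__ import annotations

import numpy as np
from scipy import stats


class PartialR2:
    """Incremental R², F statistic and p-value of one predictor over covariates.

    Parameters
    ----------
    y : outcome vector, complete cases only.
    covariates : (n, p) design without intercept, or None for intercept-only.
    """

    def __init__(self, y: np.ndarray, covariates: np.ndarray | None = None):
        y = np.asarray(y, dtype=float)
        n = y.size
        if covariates is None:
            design = np.ones((n, 1))
        else:
            covariates = np.asarray(covariates, dtype=float)
            design = np.column_stack([np.ones(n), covariates])
        q, r = np.linalg.qr(design)
        rank = int(np.sum(np.abs(np.diag(r)) > np.abs(r).max() * 1e-12)) if r.size else 0
        self.q = q[:, :rank] if rank < design.shape[1] else q
        self.n = n
        self.p_cov = self.q.shape[1]  # parameters in the covariate model (incl. intercept)
        self.resid_y = y - self.q @ (self.q.T @ y)
        ss_tot = np.sum((y - y.mean()) ** 2)
        ss_res = np.sum(self.resid_y**2)
        self.r2_cov = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
        self._ss_res_cov = ss_res

    def delta_r2(self, x: np.ndarray) -> tuple[float, float, float]:
        """Return (incremental R² fraction, F statistic, nested-model p-value)."""
        x = np.asarray(x, dtype=float)
        rx = x - self.q @ (self.q.T @ x)
        denom = np.sqrt(np.sum(rx**2) * np.sum(self.resid_y**2))
        if denom == 0:
            return 0.0, 0.0, 1.0
        r_partial = float(np.dot(rx, self.resid_y) / denom)
        r_partial = min(1.0, max(-1.0, r_partial))
        d_r2 = (1.0 - self.r2_cov) * r_partial**2
        df_resid = self.n - self.p_cov - 1
        if df_resid <= 0 or r_partial**2 >= 1.0:
            return d_r2, np.inf, 0.0
        f_stat = r_partial**2 / (1.0 - r_partial**2) * df_resid
        p = float(stats.f.sf(f_stat, 1, df_resid))
        return d_r2, f_stat, p
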