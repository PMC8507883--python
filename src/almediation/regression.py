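"""Lean ordinary-least-squares engine used by the scan and the mediation paths.

Implemented directly on numpy's least-squares solver (rank-revealing SVD) with
classical t-based inference, because the bootstrap refits on the order of 10^6
small models and per-fit overhead dominates.  Tests cross-check coefficients,
standard errors and p-values against an independent normal-equations solver
and against statsmodels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .types import EstimationError


@dataclass
class OLSFit:
    """Coefficients and t-based inference for one OLS model."""

    beta: np.ndarray
    se: np.ndarray
    tstat: np.ndarray
    pvalues: np.ndarray
    df_resid: int
    nobs: int
    names: tuple[str, ...]

    def coef(self, name: str) -> float:
        return float(self.beta[self.names.index(name)])

    def se_of(self, name: str) -> float:
        return float(self.se[self.names.index(name)])

    def pvalue(self, name: str) -> float:
        return float(self.pvalues[self.names.index(name)])


def fit_ols(X: np.ndarray, y: np.ndarray, names=None, model_label: str = "model") -> OLSFit:
    """Fit y = X b by OLS with intercept already in X.

    Raises :class:`EstimationError` on rank deficiency or too few rows; an
    exact fit (zero residual) yields zero SEs and p-values of 0 for nonzero
    coefficients.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    n, p = X.shape
    if n <= p:
        raise EstimationError(
            f"{model_label}: {n} observations cannot identify {p} coefficients"
        )
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < p:
        raise EstimationError(f"{model_label}: singular design (rank {rank} < {p})")
    resid = y - X @ beta
    df = n - p
    sigma2 = float(resid @ resid) / df
    xtx_inv = np.linalg.inv(X.T @ X)
    se = np.sqrt(np.clip(np.diag(xtx_inv), 0.0, None) * sigma2)
    t = np.divide(beta, se, out=np.zeros_like(beta), where=se > 0)
    # exact fit: se == 0 with a nonzero coefficient -> infinite t, p = 0
    t[(se == 0) & (beta != 0)] = np.inf * np.sign(beta[(se == 0) & (beta != 0)])
    pvals = 2.0 * stats.t.sf(np.abs(t), df)
    if names is None:
        names = tuple(f"x{i}" for i in range(p))
    return OLSFit(
        beta=beta,
        se=se,
        tstat=np.asarray(t, dtype=float),
        pvalues=np.asarray(pvals, dtype=float),
        df_resid=df,
        nobs=n,
        names=tuple(names),
    )


def design_with_intercept(*columns: np.ndarray) -> np.ndarray:
    """Stack an intercept column with the given predictor columns."""
    cols = [np.asarray(c, dtype=np.float64).reshape(len(c)) for c in columns]
    n = len(cols[0]) if cols else 0
    return np.column_stack([np.ones(n)] + cols) if cols else np.ones((0, 1))
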