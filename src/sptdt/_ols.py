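"""Shared least-squares machinery for residual z-scores and per-gene fits."""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = ["residual_z", "batch_ols_t"]


def residual_z(y: np.ndarray, X: pd.DataFrame) -> np.ndarray:
    """OLS-with-intercept residuals standardized by their sample s.d. (ddof=1).

    The returned z column has mean 0 and unit s.d. over the fitted rows,
    and is invariant to row order.
    """
    y = np.asarray(y, dtype=float)
    design = sm.add_constant(X.astype(float), has_constant="add")
    fit = sm.OLS(y, design).fit()
    resid = np.asarray(fit.resid)
    sd = resid.std(ddof=1)
    scale = max(1.0, float(np.abs(y).max()))
    if sd <= 1e-12 * scale:
        if np.allclose(resid, 0.0, atol=1e-9 * scale):
            return np.zeros_like(resid)  # exact fit: every partition on the line
        raise ValueError("residuals are constant; z-scores undefined")
    return resid / sd


def batch_ols_t(X: np.ndarray, Y: np.ndarray, coef: int = 1) -> tuple[np.ndarray, np.ndarray]:
    """OLS of many responses on one design; returns (beta, t) for ``coef``.

    ``X`` is (n, p) including the intercept column; ``Y`` is (n, m).  Used
    in the per-gene association and its permutation loop, where a
    per-response model-fitting call would dominate run time.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    n, p = X.shape
    if n <= p:
        raise ValueError("need more observations than design columns")
    if np.linalg.matrix_rank(X) < p:
        raise np.linalg.LinAlgError("design matrix is rank deficient")
    xtx_inv = np.linalg.inv(X.T @ X)
    betas = xtx_inv @ (X.T @ Y)          # (p, m)
    resid = Y - X @ betas
    sigma2 = (resid**2).sum(axis=0) / (n - p)
    se = np.sqrt(sigma2 * xtx_inv[coef, coef])
    with np.errstate(divide="ignore", invalid="ignore"):
        t = betas[coef] / se
    return betas[coef], t
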