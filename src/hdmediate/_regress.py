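"""Vectorised least-squares helpers shared by the three estimators.

Everything here is plain OLS; the tricks are (a) fitting many response
columns against one common design in a single solve and (b) the
Frisch-Waugh-Lovell residualisation that turns "outcome ~ feature_j +
covariates, for every j" into one pass of vector algebra.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

__all__ = [
    "design_matrix",
    "ols_many_responses",
    "marginal_outcome_slopes",
    "ols_inference",
]


def design_matrix(*blocks: np.ndarray | None) -> np.ndarray:
    """Column-stack an intercept with the given blocks (None skipped)."""
    cols = [np.ones((next(b.shape[0] for b in blocks if b is not None), 1))]
    for b in blocks:
        if b is None:
            continue
        b = np.asarray(b, dtype=float)
        cols.append(b[:, None] if b.ndim == 1 else b)
    return np.hstack(cols)


def _check_full_rank(X: np.ndarray) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name the first column that is linearly dependent on its predecessors
        for j in range(1, X.shape[1]):
            if np.linalg.matrix_rank(X[:, : j + 1]) < j + 1:
                raise np.linalg.LinAlgError(
                    f"design is rank deficient: column {j} is collinear"
                )


def _t_pvalues(coef: np.ndarray, se: np.ndarray, dof: int) -> np.ndarray:
    """Two-sided t p-values; exact-fit columns (se == 0) get p = 0 for a
    nonzero coefficient and p = 1 for a zero one."""
    coef = np.atleast_1d(coef)
    se = np.atleast_1d(se)
    p = np.empty_like(coef, dtype=float)
    ok = se > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        p[ok] = 2.0 * stats.t.sf(np.abs(coef[ok] / se[ok]), dof)
    p[~ok] = np.where(coef[~ok] == 0.0, 1.0, 0.0)
    return p


def ols_many_responses(
    X: np.ndarray, Y: np.ndarray, coef_col: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Regress every column of Y on the common design X.

    Returns (coefficient, standard error, two-sided p-value) of column
    ``coef_col`` of X, one entry per response column.  Raises
    LinAlgError naming the offending column when X is rank deficient.
    """
    X = np.asarray(X, float)
    Y = np.asarray(Y, float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n, k = X.shape
    if n <= k:
        raise np.linalg.LinAlgError("need more rows than design columns")
    _check_full_rank(X)
    Q, R = np.linalg.qr(X)
    B = np.linalg.solve(R, Q.T @ Y)
    resid = Y - X @ B
    dof = n - k
    sigma2 = (resid**2).sum(axis=0) / dof
    Rinv = np.linalg.solve(R, np.eye(k))
    var_scale = (Rinv**2).sum(axis=1)[coef_col]  # (X'X)^-1 diagonal entry
    se = np.sqrt(sigma2 * var_scale)
    coef = B[coef_col]
    return coef, se, _t_pvalues(coef, se, dof)


def marginal_outcome_slopes(
    y: np.ndarray, M: np.ndarray, covariates: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Slope of feature j in ``y ~ feature_j + covariates`` for every j.

    Frisch-Waugh-Lovell: residualise y and every feature on the
    covariate block (which must include the intercept), then the simple
    slopes between residuals equal the full-model coefficients, with the
    degrees of freedom of the full model.
    """
    y = np.asarray(y, float)
    M = np.asarray(M, float)
    X0 = np.asarray(covariates, float)
    n, k0 = X0.shape
    _check_full_rank(X0)
    Q, _ = np.linalg.qr(X0)
    ry = y - Q @ (Q.T @ y)
    rM = M - Q @ (Q.T @ M)
    ss = (rM**2).sum(axis=0)
    bad = ss <= n * 1e-14
    if np.any(bad):
        raise np.linalg.LinAlgError(
            f"design is rank deficient: feature column {int(np.argmax(bad))} "
            "is collinear with the covariates"
        )
    coef = (rM.T @ ry) / ss
    dof = n - k0 - 1
    rss = ry @ ry - coef**2 * ss
    rss = np.clip(rss, 0.0, None)
    sigma2 = rss / dof
    se = np.sqrt(sigma2 / ss)
    return coef, se, _t_pvalues(coef, se, dof)


def ols_inference(
    X: np.ndarray, y: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Full-model OLS coefficients, standard errors and t p-values."""
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    n, k = X.shape
    _check_full_rank(X)
    Q, R = np.linalg.qr(X)
    coef = np.linalg.solve(R, Q.T @ y)
    resid = y - X @ coef
    dof = n - k
    sigma2 = (resid @ resid) / dof if dof > 0 else 0.0
    Rinv = np.linalg.solve(R, np.eye(k))
    se = np.sqrt(sigma2 * (Rinv**2).sum(axis=1))
    return coef, se, _t_pvalues(coef, se, dof)
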