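"""HDMA-style high-dimensional mediation with a debiased Lasso.

Pipeline: (1) sure independence screening with ``d = n / log(n)``;
(2) a cross-validated Lasso of the outcome on all screened mediators
jointly (exposure and confounders are unpenalised — they are partialled
out exactly, which for the Lasso is equivalent to leaving them in the
model without penalty); (3) the desparsified-Lasso correction, built
from node-wise Lasso regressions of each design column on the others,
which restores asymptotically normal per-coefficient inference;
(4) joint-significance testing at the Bonferroni level ``alpha / d``,
with the component indirect effect the product of the exposure-path OLS
coefficient and the debiased outcome-path coefficient.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._regress import design_matrix, ols_many_responses
from ._solvers import cd_path_gram, cv_error_path, make_folds, nodewise_coefficients
from .hima import ScreenResult, sis_screen
from .results import MediationResults

__all__ = [
    "DebiasedFit",
    "hdma_screen",
    "lasso_fit",
    "debias_lasso",
    "Hdma",
    "hdma_mediate",
]


def hdma_screen(M: np.ndarray, O: np.ndarray, n: int | None = None,
                log_base: float = np.e) -> ScreenResult:
    """SIS with the size rule d = floor(n / log(n)).

    Natural log by default (the SIS literature's convention); pass
    ``log_base=10`` for the base-10 reading.
    """
    M = np.asarray(M, float)
    if n is None:
        n = M.shape[0]
    if n < 8:
        raise ValueError("need n >= 8 for the n/log(n) screening rule")
    d = int(np.floor(n / (np.log(n) / np.log(log_base))))
    return sis_screen(M, O, d)


def lasso_fit(
    X: np.ndarray,
    y: np.ndarray,
    lam: float | str = "cv",
    cv: int = 10,
    seed: int = 0,
    n_alphas: int = 50,
    alpha_ratio: float = 1e-3,
    penalty: np.ndarray | None = None,
    tol: float = 1e-7,
    max_iter: int = 10_000,
) -> np.ndarray:
    """Coordinate-descent Lasso; lambda by seeded K-fold CV when requested.

    The penalty is ``lam * sum|b_j|`` against the mean squared error
    ``||y - Xb||^2 / (2n)``; columns are expected standardized by the
    caller.  Returns the coefficient vector.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    n, d = X.shape
    G = X.T @ X / n
    c = X.T @ y / n
    if isinstance(lam, str):
        if lam != "cv":
            raise ValueError("lam must be a number or 'cv'")
        lam_max = max(float(np.max(np.abs(c))), 1e-12)
        alphas = np.geomspace(lam_max, lam_max * alpha_ratio, n_alphas)
        folds = make_folds(n, cv, seed)
        errs = cv_error_path(X, y, alphas, folds, penalty=penalty,
                             tol=tol, max_iter=max_iter)
        lam = float(alphas[int(np.argmin(errs))])
        path = alphas[alphas >= lam]
    else:
        lam = float(lam)
        lam_max = max(float(np.max(np.abs(c))), lam, 1e-12)
        path = np.geomspace(lam_max, lam, 10) if lam > 0 else np.array([lam])
        path[-1] = lam
    B = cd_path_gram(G, c, path, gamma=-1.0, penalty=penalty,
                     tol=tol, max_iter=max_iter)
    return B[-1]


@dataclass(frozen=True)
class DebiasedFit:
    """Desparsified-Lasso estimates with per-coefficient inference."""

    lasso_coefficients: np.ndarray
    debiased_coefficients: np.ndarray
    standard_errors: np.ndarray
    p_values: np.ndarray
    noise_level: float

    def __post_init__(self) -> None:
        k = len(self.lasso_coefficients)
        if not (len(self.debiased_coefficients) == len(self.standard_errors)
                == len(self.p_values) == k):
            raise ValueError("all coefficient vectors must share one length")


def debias_lasso(
    X: np.ndarray,
    y: np.ndarray,
    lasso_coef: np.ndarray,
    cv: int = 5,
    seed: int = 0,
    n_alphas: int = 50,
    alpha_ratio: float = 0.01,
) -> DebiasedFit:
    """Desparsified-Lasso correction of an initial Lasso fit.

    A relaxed inverse of the sample covariance is built from node-wise
    Lasso regressions (one per column, CV-tuned with a shared fold
    seed); the debiased estimate adds the projected residual correlation
    ``Theta X'(y - X b)/n`` to the Lasso coefficients.  Standard errors
    use the sandwich form ``sigma * sqrt((Theta G Theta')_jj / n)`` with
    the residual scale estimated from the Lasso fit; p-values are
    two-sided normal.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    lasso_coef = np.asarray(lasso_coef, float)
    n, d = X.shape
    folds = make_folds(n, cv, seed)
    Gamma, tau2, _ = nodewise_coefficients(X, folds, n_alphas=n_alphas,
                                           alpha_ratio=alpha_ratio)
    # Theta row j: (e_j - gamma_j) / tau2_j
    Theta = (np.eye(d) - Gamma) / tau2[:, None]
    G = X.T @ X / n
    resid = y - X @ lasso_coef
    debiased = lasso_coef + Theta @ (X.T @ resid) / n
    df = int(np.count_nonzero(lasso_coef))
    dof = max(n - df, 1)
    sigma = float(np.sqrt(resid @ resid / dof))
    omega_diag = np.einsum("ij,jk,ik->i", Theta, G, Theta)
    se = sigma * np.sqrt(omega_diag / n)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, debiased / np.where(se > 0, se, 1.0), np.inf)
    p = 2 * stats.norm.sf(np.abs(z))
    return DebiasedFit(lasso_coef, debiased, se, p, sigma)


class Hdma:
    """HDMA-style model bound to one dataset (see module docstring)."""

    method = "HDMA"

    def __init__(self, outcome, mediators, exposure, confounders=None) -> None:
        self.outcome = np.asarray(outcome, float)
        self.mediators = np.asarray(mediators, float)
        self.exposure = np.asarray(exposure, float)
        self.confounders = None if confounders is None else np.asarray(confounders, float)
        if self.mediators.shape[0] != len(self.outcome):
            raise ValueError("inconsistent sample sizes across inputs")

    @classmethod
    def from_dataset(cls, dataset) -> "Hdma":
        return cls(dataset.O, dataset.M, dataset.E, dataset.C)

    def fit(
        self,
        alpha: float = 0.05,
        cv: int = 5,
        seed: int = 0,
        n_alphas: int = 50,
        log_base: float = np.e,
    ) -> MediationResults:
        if not 0 < alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        n, p = self.mediators.shape
        screen = hdma_screen(self.mediators, self.outcome, n, log_base=log_base)
        d = min(screen.d, p)
        kept = np.sort(screen.kept)

        # partial out intercept, exposure, confounders (unpenalised block)
        X0 = design_matrix(self.exposure, self.confounders)
        Q, _ = np.linalg.qr(X0)
        rO = self.outcome - Q @ (Q.T @ self.outcome)
        rM = self.mediators[:, kept] - Q @ (Q.T @ self.mediators[:, kept])
        sd = rM.std(axis=0)
        sd = np.where(sd > 0, sd, 1.0)
        Z = rM / sd

        b_lasso = lasso_fit(Z, rO, "cv", cv=cv, seed=seed, n_alphas=n_alphas)
        deb = debias_lasso(Z, rO, b_lasso, cv=cv, seed=seed, n_alphas=n_alphas)
        b_coef = deb.debiased_coefficients / sd  # back to the original scale
        b_p = deb.p_values

        # a-path: mediator ~ E + C for every screened mediator
        a_coef, _, a_p = ols_many_responses(X0, self.mediators[:, kept], 1)

        joint = np.maximum(a_p, b_p)
        declared_mask = joint < alpha / d
        declared = kept[declared_mask]
        cie = a_coef[declared_mask] * b_coef[declared_mask]

        pvalues = np.full(p, np.nan)
        pvalues[kept] = joint
        details = pd.DataFrame(
            {
                "feature": np.arange(p),
                "screened": np.isin(np.arange(p), kept),
                "lasso_coef": 0.0,
                "a_coef": np.nan,
                "a_p": np.nan,
                "b_coef": np.nan,
                "b_p": np.nan,
                "joint_p": np.nan,
                "declared": False,
                "cie": np.nan,
            }
        )
        details.loc[kept, "lasso_coef"] = deb.lasso_coefficients / sd
        details.loc[kept, "a_coef"] = a_coef
        details.loc[kept, "a_p"] = a_p
        details.loc[kept, "b_coef"] = b_coef
        details.loc[kept, "b_p"] = b_p
        details.loc[kept, "joint_p"] = joint
        details.loc[declared, "declared"] = True
        details.loc[declared, "cie"] = cie
        return MediationResults(
            self.method, declared, cie, float(cie.sum()),
            pvalues, details, alpha,
            extras={"screen": screen, "debias": deb, "d": d},
        )


def hdma_mediate(dataset, alpha: float = 0.05, cv: int = 5, seed: int = 0,
                 n_alphas: int = 50) -> MediationResults:
    return Hdma.from_dataset(dataset).fit(alpha=alpha, cv=cv, seed=seed,
                                          n_alphas=n_alphas)
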