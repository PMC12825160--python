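"""HIMA-style high-dimensional mediation.

Three steps: (1) sure independence screening (SIS) of the mediator ->
outcome model down to ``d`` candidates, (2) minimax concave penalty (MCP)
selection of mediators in the joint outcome model (exposure and
confounders enter unpenalised), and (3) joint-significance testing: each
surviving mediator's p-value is the maximum of its exposure-path and
outcome-path p-values, declared at the Bonferroni level ``alpha / d``.

The outcome-path p-value comes from a post-selection least-squares refit
on the MCP support; the refit coefficient is also the one used in the
component indirect effect, keeping the estimate and its test consistent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._regress import design_matrix, ols_inference, ols_many_responses
from ._solvers import cd_path_gram
from .results import MediationResults

__all__ = [
    "ScreenResult",
    "McpFit",
    "sis_screen",
    "mcp_threshold",
    "mcp_fit",
    "default_screen_size",
    "Hima",
    "hima_mediate",
]


@dataclass(frozen=True)
class ScreenResult:
    """Ranking of mediator columns by screening statistic."""

    ranking: np.ndarray  # all columns, descending |statistic|
    kept: np.ndarray  # top-d subset, in ranking order
    d: int
    statistic: np.ndarray  # per-column |marginal correlation with outcome|

    def __post_init__(self) -> None:
        if len(self.kept) != min(self.d, len(self.ranking)):
            raise ValueError("kept must hold the top min(d, p) columns")


def sis_screen(M: np.ndarray, O: np.ndarray, d: int) -> ScreenResult:
    """Rank columns by absolute marginal correlation with the outcome.

    Columns are standardized first, so the statistic is scale free.
    Zero-variance columns get statistic 0 and rank last; ties break by
    ascending column index.
    """
    if d < 1:
        raise ValueError("d must be >= 1")
    M = np.asarray(M, float)
    O = np.asarray(O, float)
    p = M.shape[1]
    sd_o = O.std()
    Mc = M - M.mean(axis=0)
    sd = Mc.std(axis=0)
    ok = sd > 0
    stat = np.zeros(p)
    if sd_o > 0 and ok.any():
        Oc = O - O.mean()
        stat[ok] = np.abs(Mc[:, ok].T @ Oc) / (len(O) * sd[ok] * sd_o)
    ranking = np.lexsort((np.arange(p), -stat))
    kept = ranking[: min(d, p)]
    return ScreenResult(ranking=ranking, kept=kept, d=d, statistic=stat)


def mcp_threshold(z: float, lam: float, gamma: float) -> float:
    """Univariate MCP solution for an orthonormal coordinate update.

    ``sign(z) * max(|z| - lam, 0) / (1 - 1/gamma)`` inside
    ``|z| <= gamma * lam``; the unpenalised ``z`` beyond (the MCP is flat
    there).  Requires ``gamma > 1``.
    """
    if gamma <= 1:
        raise ValueError("gamma must be > 1 for a convex coordinate update")
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    az = abs(z)
    if lam == 0:
        return float(z)
    if az <= gamma * lam:
        return float(np.sign(z) * max(az - lam, 0.0) / (1.0 - 1.0 / gamma))
    return float(z)


@dataclass(frozen=True)
class McpFit:
    """MCP regression chosen by BIC along a lambda path."""

    coefficients: np.ndarray
    support: np.ndarray  # indices with nonzero coefficient
    lambda_: float
    gamma: float
    objective: float  # penalized objective at the solution
    bic_path: np.ndarray
    lambda_grid: np.ndarray


def _mcp_penalty_value(b: np.ndarray, lam: float, gamma: float,
                       penalty: np.ndarray) -> float:
    ab = np.abs(b)
    lamj = lam * penalty
    inner = ab <= gamma * lamj
    val = np.where(inner, lamj * ab - ab**2 / (2 * gamma), gamma * lamj**2 / 2)
    return float(val.sum())


def mcp_fit(
    X: np.ndarray,
    y: np.ndarray,
    lambda_grid: np.ndarray | None = None,
    gamma: float = 3.0,
    penalty: np.ndarray | None = None,
    n_lambda: int = 100,
    lambda_min_ratio: float = 1e-3,
    tol: float = 1e-7,
    max_iter: int = 10_000,
) -> McpFit:
    """MCP coordinate descent along a decreasing lambda path, BIC-chosen.

    Columns of X are expected centered (and penalized ones standardized);
    ``penalty`` is a 0/1 vector marking which columns are penalized
    (default: all).  Warm starts run from the null model down; the final
    lambda minimises ``n log(RSS/n) + log(n) * df``.
    """
    if gamma <= 1:
        raise ValueError("gamma must be > 1")
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    n, d = X.shape
    if penalty is None:
        penalty = np.ones(d)
    penalty = np.asarray(penalty, float)
    G = X.T @ X / n
    c = X.T @ y / n

    if lambda_grid is None:
        pen = penalty > 0
        if pen.all():
            resid_corr = c
        else:
            # residualise on the unpenalised block to find lambda_max
            Xu = X[:, ~pen]
            bu = np.linalg.lstsq(Xu, y, rcond=None)[0]
            resid_corr = X[:, pen].T @ (y - Xu @ bu) / n
        lam_max = np.max(np.abs(resid_corr)) if pen.any() else 1.0
        lam_max = max(lam_max, 1e-12)
        lambda_grid = np.geomspace(lam_max, lam_max * lambda_min_ratio, n_lambda)
    lambda_grid = np.asarray(lambda_grid, float)
    if np.any(np.diff(lambda_grid) >= 0):
        raise ValueError("lambda_grid must be strictly decreasing")

    B = cd_path_gram(G, c, lambda_grid, gamma=gamma, penalty=penalty,
                     tol=tol, max_iter=max_iter)
    yy = float(y @ y / n)
    rss = n * np.maximum(yy - 2 * B @ c + np.einsum("kj,ji,ki->k", B, G, B), 1e-300)
    df = (B != 0).sum(axis=1)
    bic = n * np.log(rss / n) + np.log(n) * df
    k = int(np.argmin(bic))
    b = B[k]
    obj = rss[k] / (2 * n) + _mcp_penalty_value(
        b, lambda_grid[k], gamma, penalty
    )
    return McpFit(
        coefficients=b,
        support=np.flatnonzero(b),
        lambda_=float(lambda_grid[k]),
        gamma=gamma,
        objective=obj,
        bic_path=bic,
        lambda_grid=lambda_grid,
    )


def default_screen_size(n: int, p: int, n_confounders: int = 2) -> int:
    """HIMA's conventional screening size floor(2n/ln n), capped so the
    post-screening model stays estimable: min(d, p, n - q - 2)."""
    d = int(np.floor(2 * n / np.log(n)))
    return max(1, min(d, p, n - n_confounders - 2))


class Hima:
    """HIMA-style model bound to one dataset (see module docstring)."""

    method = "HIMA"

    def __init__(self, outcome, mediators, exposure, confounders=None) -> None:
        self.outcome = np.asarray(outcome, float)
        self.mediators = np.asarray(mediators, float)
        self.exposure = np.asarray(exposure, float)
        self.confounders = None if confounders is None else np.asarray(confounders, float)
        if self.mediators.shape[0] != len(self.outcome):
            raise ValueError("inconsistent sample sizes across inputs")

    @classmethod
    def from_dataset(cls, dataset) -> "Hima":
        return cls(dataset.O, dataset.M, dataset.E, dataset.C)

    def fit(
        self,
        d: int | None = None,
        alpha: float = 0.05,
        gamma: float = 3.0,
        n_lambda: int = 100,
    ) -> MediationResults:
        if not 0 < alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        n, p = self.mediators.shape
        q = 0 if self.confounders is None else self.confounders.shape[1]
        if d is None:
            d = default_screen_size(n, p, q)
        if d >= n:
            raise ValueError("screening size d must be < n")

        screen = sis_screen(self.mediators, self.outcome, d)
        kept = np.sort(screen.kept)

        # outcome model: O ~ screened mediators (penalised, standardised)
        #                + E + C (unpenalised, centered)
        Mk = self.mediators[:, kept]
        mu, sd = Mk.mean(axis=0), Mk.std(axis=0)
        sd = np.where(sd > 0, sd, 1.0)
        Mk_std = (Mk - mu) / sd
        blocks = [Mk_std, (self.exposure - self.exposure.mean())[:, None]]
        if self.confounders is not None:
            blocks.append(self.confounders - self.confounders.mean(axis=0))
        X = np.hstack(blocks)
        y = self.outcome - self.outcome.mean()
        penalty = np.zeros(X.shape[1])
        penalty[: len(kept)] = 1.0
        fit = mcp_fit(X, y, gamma=gamma, penalty=penalty, n_lambda=n_lambda)
        support_local = fit.support[fit.support < len(kept)]
        support = kept[support_local]

        pvalues = np.full(p, np.nan)
        details = pd.DataFrame(
            {
                "feature": np.arange(p),
                "screened": np.isin(np.arange(p), kept),
                "mcp_coef": 0.0,
                "a_coef": np.nan,
                "a_p": np.nan,
                "b_coef": np.nan,
                "b_p": np.nan,
                "joint_p": np.nan,
                "declared": False,
                "cie": np.nan,
            }
        )
        details.loc[kept, "mcp_coef"] = fit.coefficients[: len(kept)] / sd

        if len(support) == 0:
            return MediationResults(
                self.method, np.array([], int), np.array([]), 0.0,
                pvalues, details, alpha,
                extras={"screen": screen, "mcp": fit, "d": d},
            )

        # a-path: mediator ~ E + C, per supported mediator
        Xa = design_matrix(self.exposure, self.confounders)
        a_coef, _, a_p = ols_many_responses(Xa, self.mediators[:, support], 1)
        # b-path: post-selection OLS refit of O on [support, E, C]
        Xb = design_matrix(self.mediators[:, support], self.exposure, self.confounders)
        b_all, _, pb_all = ols_inference(Xb, self.outcome)
        b_coef = b_all[1 : 1 + len(support)]
        b_p = pb_all[1 : 1 + len(support)]

        joint = np.maximum(a_p, b_p)
        declared_mask = joint < alpha / d
        declared = support[declared_mask]
        cie = a_coef[declared_mask] * b_coef[declared_mask]
        pvalues[support] = joint

        details.loc[support, "a_coef"] = a_coef
        details.loc[support, "a_p"] = a_p
        details.loc[support, "b_coef"] = b_coef
        details.loc[support, "b_p"] = b_p
        details.loc[support, "joint_p"] = joint
        details.loc[declared, "declared"] = True
        details.loc[declared, "cie"] = cie
        return MediationResults(
            self.method, declared, cie, float(cie.sum()),
            pvalues, details, alpha,
            extras={"screen": screen, "mcp": fit, "d": d, "support": support},
        )


def hima_mediate(
    dataset, d: int | None = None, alpha: float = 0.05,
    gamma: float = 3.0, n_lambda: int = 100,
) -> MediationResults:
    return Hima.from_dataset(dataset).fit(d=d, alpha=alpha, gamma=gamma,
                                          n_lambda=n_lambda)
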