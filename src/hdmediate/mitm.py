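"""Meet-in-the-middle (MITM) mediation.

Two marginal metabolome-wide association passes — exposure -> feature,
and feature -> outcome controlling for the exposure — followed by overlap
selection: a feature is called a mediator when it is significant in both
passes.  Each selected feature's component indirect effect (CIE) is the
product of its two path coefficients and the total indirect effect (TIE)
is the sum of the selected CIEs.

Confounder adjustment defaults to on in both passes (the generating DAG
confounds exposure with both mediators and outcome); it can be switched
off for sensitivity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._regress import design_matrix, marginal_outcome_slopes, ols_many_responses
from .results import MediationResults

__all__ = [
    "MwasResult",
    "MeetInTheMiddle",
    "mwas_exposure",
    "mwas_outcome",
    "mitm_mediate",
]

_CORRECTIONS = ("none", "bonferroni", "bh")


@dataclass(frozen=True)
class MwasResult:
    """Per-feature coefficients from one marginal regression pass."""

    coef: np.ndarray
    se: np.ndarray
    pvalue: np.ndarray
    pass_label: str

    def __post_init__(self) -> None:
        if not (len(self.coef) == len(self.se) == len(self.pvalue)):
            raise ValueError("coef, se and pvalue must have equal length")


def _bh_reject(pvalues: np.ndarray, alpha: float) -> np.ndarray:
    """Benjamini-Hochberg step-up rejection mask."""
    m = len(pvalues)
    order = np.argsort(pvalues, kind="stable")
    thresh = alpha * (np.arange(1, m + 1)) / m
    below = pvalues[order] <= thresh
    reject = np.zeros(m, dtype=bool)
    if below.any():
        kmax = np.max(np.nonzero(below)[0])
        reject[order[: kmax + 1]] = True
    return reject


class MeetInTheMiddle:
    """MITM model bound to one (outcome, mediators, exposure, confounders).

    Parameters are plain arrays; use :meth:`from_dataset` for a simulated
    replicate or :meth:`from_frame` for the package's tabular export
    format (columns ``C_*``, ``E``, ``M_*``, ``O``).
    """

    method = "MITM"

    def __init__(
        self,
        outcome: np.ndarray,
        mediators: np.ndarray,
        exposure: np.ndarray,
        confounders: np.ndarray | None = None,
    ) -> None:
        self.outcome = np.asarray(outcome, float)
        self.mediators = np.asarray(mediators, float)
        self.exposure = np.asarray(exposure, float)
        self.confounders = None if confounders is None else np.asarray(confounders, float)
        n = len(self.outcome)
        if self.mediators.shape[0] != n or len(self.exposure) != n:
            raise ValueError("inconsistent sample sizes across inputs")

    @classmethod
    def from_dataset(cls, dataset) -> "MeetInTheMiddle":
        return cls(dataset.O, dataset.M, dataset.E, dataset.C)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "MeetInTheMiddle":
        c_cols = [c for c in frame.columns if c.startswith("C_")]
        m_cols = [c for c in frame.columns if c.startswith("M_")]
        return cls(
            frame["O"].to_numpy(float),
            frame[m_cols].to_numpy(float),
            frame["E"].to_numpy(float),
            frame[c_cols].to_numpy(float) if c_cols else None,
        )

    # -- the two MWAS passes ------------------------------------------------

    def mwas_exposure(self, adjust_confounders: bool = True) -> MwasResult:
        """feature_j ~ exposure (+ confounders), coefficient on exposure."""
        conf = self.confounders if adjust_confounders else None
        X = design_matrix(self.exposure, conf)
        coef, se, p = ols_many_responses(X, self.mediators, coef_col=1)
        return MwasResult(coef, se, p, "exposure->feature")

    def mwas_outcome(self, adjust_confounders: bool = True) -> MwasResult:
        """outcome ~ feature_j + exposure (+ confounders), coefficient on
        the feature."""
        conf = self.confounders if adjust_confounders else None
        X0 = design_matrix(self.exposure, conf)
        coef, se, p = marginal_outcome_slopes(self.outcome, self.mediators, X0)
        return MwasResult(coef, se, p, "feature->outcome")

    # -- overlap selection --------------------------------------------------

    def fit(
        self,
        alpha: float = 0.05,
        correction: str = "none",
        adjust_confounders: bool = True,
    ) -> MediationResults:
        """Run both passes and select the overlap.

        ``correction`` applies per pass: ``"none"`` keeps the unadjusted
        p < alpha rule of prior MITM applications, ``"bonferroni"``
        divides alpha by p, ``"bh"`` controls FDR per pass.
        """
        if not 0 < alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if correction not in _CORRECTIONS:
            raise ValueError(f"correction must be one of {_CORRECTIONS}")
        a = self.mwas_exposure(adjust_confounders)
        b = self.mwas_outcome(adjust_confounders)
        p = self.mediators.shape[1]
        if correction == "bh":
            sig_a = _bh_reject(a.pvalue, alpha)
            sig_b = _bh_reject(b.pvalue, alpha)
        else:
            level = alpha / p if correction == "bonferroni" else alpha
            sig_a = a.pvalue < level
            sig_b = b.pvalue < level
        selected = np.flatnonzero(sig_a & sig_b)
        cie_all = a.coef * b.coef
        joint_p = np.maximum(a.pvalue, b.pvalue)
        details = pd.DataFrame(
            {
                "feature": np.arange(p),
                "a_coef": a.coef,
                "a_p": a.pvalue,
                "b_coef": b.coef,
                "b_p": b.pvalue,
                "selected": sig_a & sig_b,
                "cie": np.where(sig_a & sig_b, cie_all, np.nan),
            }
        )
        return MediationResults(
            method=self.method,
            selected=selected,
            cie=cie_all[selected],
            tie=float(cie_all[selected].sum()),
            pvalues=joint_p,
            details=details,
            alpha=alpha,
            extras={"correction": correction},
        )


# -- functional surface -----------------------------------------------------

def mwas_exposure(dataset, adjust_confounders: bool = True) -> MwasResult:
    return MeetInTheMiddle.from_dataset(dataset).mwas_exposure(adjust_confounders)


def mwas_outcome(dataset, adjust_confounders: bool = True) -> MwasResult:
    return MeetInTheMiddle.from_dataset(dataset).mwas_outcome(adjust_confounders)


def mitm_mediate(
    dataset,
    alpha: float = 0.05,
    correction: str = "none",
    adjust_confounders: bool = True,
) -> MediationResults:
    return MeetInTheMiddle.from_dataset(dataset).fit(alpha, correction, adjust_confounders)
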