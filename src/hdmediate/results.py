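"""Results container shared by the three mediation estimators."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["MediationResults"]


@dataclass
class MediationResults:
    """Output of one mediation method on one dataset.

    Attributes
    ----------
    method
        One of ``"MITM"``, ``"HIMA"``, ``"HDMA"``.
    selected
        Indices (0-based, into the mediator matrix) the method declares
        as mediators.
    cie
        Component indirect effect per selected mediator, aligned with
        ``selected``; the product of the exposure->mediator and
        mediator->outcome coefficients.
    tie
        Total indirect effect, the sum of the selected CIEs.
    pvalues
        Per-candidate joint p-values (max of the two path p-values) on
        the full mediator axis; NaN where the method never tested the
        candidate (e.g. screened out).
    details
        Tidy per-feature table with the method's intermediate
        quantities (path coefficients, p-values, selection flags).
    alpha
        Significance level the selection used.
    """

    method: str
    selected: np.ndarray
    cie: np.ndarray
    tie: float
    pvalues: np.ndarray
    details: pd.DataFrame
    alpha: float
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.selected = np.asarray(self.selected, dtype=int)
        self.cie = np.asarray(self.cie, dtype=float)
        if len(self.cie) != len(self.selected):
            raise ValueError("cie must align with selected")
        if len(self.cie) and not np.isclose(self.tie, self.cie.sum()):
            raise ValueError("tie must equal sum(cie)")

    @property
    def n_selected(self) -> int:
        return len(self.selected)

    def summary(self) -> str:
        lines = [
            f"{self.method} mediation results",
            "=" * 34,
            f"selected mediators : {self.n_selected}",
            f"total indirect effect (TIE) : {self.tie:.6g}",
            f"selection level alpha : {self.alpha:g}",
            "",
        ]
        if self.n_selected:
            tab = pd.DataFrame(
                {
                    "mediator": self.selected,
                    "cie": self.cie,
                    "joint_p": self.pvalues[self.selected],
                }
            )
            lines.append(tab.to_string(index=False, float_format="%.4g"))
        else:
            lines.append("(no mediators selected)")
        return "\n".join(lines)

    def __repr__(self) -> str:  # short, informative
        return (
            f"<MediationResults {self.method}: {self.n_selected} selected, "
            f"TIE={self.tie:.4g}>"
        )
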