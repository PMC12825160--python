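"""Synthetic metabolomics data with a known mediation structure.

The generating model is a linear DAG.  Confounders C are iid standard
normal; the exposure is ``E = E0 + 0.2 * sum(C)``; metabolites are either
iid standard normal or rows of a zero-mean multivariate normal under a
positive-definite correlation matrix; a chosen subset of metabolite
columns is made into true mediators by the mean shift ``M_j += beta * E``;
and the outcome is ``O = O0 + 0.8*E + 0.01*sum(C) + beta * sum(M_true)``.

Under this DAG the mediated (indirect) effect of a one-unit exposure
contrast has closed form: each true mediator transmits beta**2 and the
total indirect effect is ``n_true * beta**2``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ScenarioConfig",
    "CorrelationModel",
    "SimulatedDataset",
    "make_correlation_matrix",
    "simulate_dataset",
    "true_effects",
]

#: exposure <- confounder coefficient
CONFOUNDER_TO_EXPOSURE = 0.2
#: outcome <- exposure (direct effect) coefficient
DIRECT_EFFECT = 0.8
#: outcome <- confounder coefficient
CONFOUNDER_TO_OUTCOME = 0.01

_PROP_LEVELS = (0.02, 0.05, 0.10)


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


@dataclass(frozen=True)
class ScenarioConfig:
    """One cell of the simulation design.

    Parameters
    ----------
    scenario_id
        Label in 1..36; ids 1-18 are the correlated settings, 19-36 the
        independent ones.
    n, p
        Sample size and mediator-set size.
    prop_true
        Fraction of metabolites that are true mediators.
    beta
        Shared path coefficient for exposure->mediator and
        mediator->outcome.
    correlated
        Whether metabolites are drawn under a correlation matrix.
    n_confounders
        Number of standard-normal confounders (q).
    base_seed
        Seed at the scenario level; replicate streams are derived from it.
    """

    scenario_id: int
    n: int
    p: int
    prop_true: float
    beta: float
    correlated: bool
    n_confounders: int = 2
    base_seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 10:
            raise ValueError(f"n must be >= 10, got {self.n}")
        if self.beta < 0:
            raise ValueError(f"beta must be >= 0, got {self.beta}")
        if not 0 < self.prop_true < 1:
            raise ValueError(f"prop_true must be in (0, 1), got {self.prop_true}")
        if self.n_confounders < 0:
            raise ValueError("n_confounders must be >= 0")
        n_true = self.n_true
        if n_true < 1:
            raise ValueError(
                f"round(prop_true * p) = {n_true}; at least one true mediator required"
            )
        if n_true >= self.p:
            raise ValueError("n_true must be < p")
        if 1 <= self.scenario_id <= 36:
            expect_corr = self.scenario_id <= 18
            if self.correlated != expect_corr:
                raise ValueError(
                    f"scenario_id {self.scenario_id} implies correlated={expect_corr}"
                )

    @property
    def n_true(self) -> int:
        """Number of true mediators, round-half-up of prop_true * p."""
        return _round_half_up(self.prop_true * self.p)


@dataclass(frozen=True)
class CorrelationModel:
    """A validated positive-definite metabolite correlation matrix."""

    matrix: np.ndarray
    seed: int

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("correlation matrix must be square")
        if not np.allclose(m, m.T, atol=1e-10):
            raise ValueError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(m), 1.0, atol=1e-10):
            raise ValueError("correlation matrix must have unit diagonal")
        if np.any(np.abs(m) > 1 + 1e-12):
            raise ValueError("correlations must lie in [-1, 1]")
        if np.linalg.eigvalsh(m)[0] <= 0:
            raise ValueError("correlation matrix must be positive definite")
        object.__setattr__(self, "matrix", m)

    @property
    def p(self) -> int:
        return self.matrix.shape[0]

    def cholesky(self) -> np.ndarray:
        return np.linalg.cholesky(self.matrix)


def make_correlation_matrix(
    p: int,
    seed: int,
    target_range: tuple[float, float] = (-0.42, 0.45),
    n_factors: int = 8,
    signal: float = 0.5,
    eig_floor: float = 1e-4,
) -> CorrelationModel:
    """Random positive-definite correlation matrix with a controlled range.

    Correlations arise from ``n_factors`` shared latent factors: each
    metabolite loads on the factors with a communality of ``signal``, and
    the loading matrix's Gram (diagonal filled to 1 by uniqueness) gives a
    positive-definite correlation matrix whose off-diagonals are bell
    shaped around zero.  Off-diagonals are then rescaled so their realized
    minimum/maximum sit at the edges of ``target_range`` (shrinking toward
    the identity preserves positive definiteness; inflating is followed by
    an eigenvalue-floor repair with re-standardization and box clipping).

    Realized extremes match the target to within ~0.05 for p >= 20; very
    small p have too few metabolite pairs to span both tails.

    Deterministic given ``(p, seed)`` and the tuning arguments.
    """
    if p < 1:
        raise ValueError(f"p must be >= 1, got {p}")
    lo, hi = target_range
    if not (-1 < lo < hi < 1):
        raise ValueError("target_range must satisfy -1 < lo < hi < 1")
    if p == 1:
        return CorrelationModel(np.ones((1, 1)), seed)

    rng = np.random.default_rng(seed)
    loadings = rng.standard_normal((p, n_factors))
    loadings *= np.sqrt(signal) / np.linalg.norm(loadings, axis=1, keepdims=True)
    mat = loadings @ loadings.T
    np.fill_diagonal(mat, 1.0)

    iu = np.triu_indices(p, 1)
    off = mat[iu]
    # rescale so realized extremes just touch the target box
    ratios = [off.max() / hi if off.max() > 0 else 0.0,
              off.min() / lo if off.min() < 0 else 0.0]
    s = max(ratios)
    if s > 0:
        c = 1.0 / s
        if c <= 1.0:
            mat = c * mat + (1.0 - c) * np.eye(p)
        else:
            mat = mat * c
            np.fill_diagonal(mat, 1.0)

    # repair: eigenvalue floor -> unit diagonal -> clip to the box
    for _ in range(100):
        w, v = np.linalg.eigh(mat)
        in_box = (mat[iu].min() >= lo - 1e-12) and (mat[iu].max() <= hi + 1e-12)
        if w[0] >= eig_floor and in_box:
            break
        w = np.clip(w, eig_floor, None)
        mat = (v * w) @ v.T
        d = np.sqrt(np.diag(mat))
        mat = mat / np.outer(d, d)
        off = np.clip(mat[iu], lo, hi)
        mat = np.zeros((p, p))
        mat[iu] = off
        mat = mat + mat.T
        np.fill_diagonal(mat, 1.0)
    else:
        raise RuntimeError(
            "could not reach positive definiteness within the box constraints"
        )
    return CorrelationModel(mat, seed)


@dataclass(frozen=True)
class SimulatedDataset:
    """One simulated replicate plus its ground truth."""

    C: np.ndarray  # n x q confounders
    E: np.ndarray  # n exposure
    M: np.ndarray  # n x p metabolites
    O: np.ndarray  # n outcome
    true_idx: np.ndarray  # indices of true mediator columns
    beta: float
    config: ScenarioConfig | None = None

    @property
    def n(self) -> int:
        return self.M.shape[0]

    @property
    def p(self) -> int:
        return self.M.shape[1]

    @property
    def n_true(self) -> int:
        return len(self.true_idx)

    @property
    def true_cie(self) -> np.ndarray:
        """Per-true-mediator component indirect effect (beta**2 each)."""
        return np.full(self.n_true, self.beta**2)

    @property
    def true_tie(self) -> float:
        """Total indirect effect: n_true * beta**2."""
        return self.n_true * self.beta**2

    def to_frame(self) -> pd.DataFrame:
        """Samples x columns table: confounders, E, M_1..M_p, O."""
        cols = {f"C_{i + 1}": self.C[:, i] for i in range(self.C.shape[1])}
        cols["E"] = self.E
        for j in range(self.p):
            cols[f"M_{j + 1}"] = self.M[:, j]
        cols["O"] = self.O
        return pd.DataFrame(cols)

    @classmethod
    def from_frame(
        cls,
        frame: pd.DataFrame,
        true_idx: np.ndarray | None = None,
        beta: float = np.nan,
    ) -> "SimulatedDataset":
        c_cols = [c for c in frame.columns if c.startswith("C_")]
        m_cols = [c for c in frame.columns if c.startswith("M_")]
        return cls(
            C=frame[c_cols].to_numpy(float),
            E=frame["E"].to_numpy(float),
            M=frame[m_cols].to_numpy(float),
            O=frame["O"].to_numpy(float),
            true_idx=np.asarray([] if true_idx is None else true_idx, dtype=int),
            beta=beta,
        )


def replicate_rng(config: ScenarioConfig, replicate: int) -> np.random.Generator:
    """Non-overlapping stream for one replicate of one scenario.

    Counter-based derivation via SeedSequence spawn keys, so streams are
    independent across (scenario, replicate) without seed arithmetic.
    """
    ss = np.random.SeedSequence(
        entropy=config.base_seed, spawn_key=(config.scenario_id, replicate)
    )
    return np.random.default_rng(ss)


def simulate_dataset(
    config: ScenarioConfig,
    corr: CorrelationModel | None = None,
    replicate_seed: int = 0,
    random_placement: bool = False,
) -> SimulatedDataset:
    """Draw one replicate from the generating DAG.

    ``corr`` must be given exactly when ``config.correlated``; its
    Cholesky factor colours the metabolite draw.  ``replicate_seed``
    indexes the replicate within the scenario's seed stream.
    """
    if config.correlated and corr is None:
        raise ValueError("correlated config requires a CorrelationModel")
    if not config.correlated and corr is not None:
        raise ValueError("independent config must not pass a CorrelationModel")
    if corr is not None and corr.p != config.p:
        raise ValueError(
            f"correlation matrix is {corr.p}x{corr.p} but config.p = {config.p}"
        )

    rng = replicate_rng(config, replicate_seed)
    n, p, q = config.n, config.p, config.n_confounders

    C = rng.standard_normal((n, q))
    c_sum = C.sum(axis=1)
    E = rng.standard_normal(n) + CONFOUNDER_TO_EXPOSURE * c_sum

    M = rng.standard_normal((n, p))
    if corr is not None:
        M = M @ corr.cholesky().T

    if random_placement:
        true_idx = np.sort(rng.choice(p, size=config.n_true, replace=False))
    else:
        true_idx = np.arange(config.n_true)
    M[:, true_idx] += config.beta * E[:, None]

    O = (
        rng.standard_normal(n)
        + DIRECT_EFFECT * E
        + CONFOUNDER_TO_OUTCOME * c_sum
        + config.beta * M[:, true_idx].sum(axis=1)
    )
    return SimulatedDataset(
        C=C, E=E, M=M, O=O, true_idx=true_idx, beta=config.beta, config=config
    )


def true_effects(config: ScenarioConfig) -> tuple[float, np.ndarray]:
    """Closed-form estimands of the linear DAG for a unit exposure contrast.

    Every true mediator transmits ``beta**2``; the total indirect effect
    is their sum, ``n_true * beta**2``.  Mediator-mediator correlation
    does not change these values because mediator means are linear in E
    with the same coefficient either way.
    """
    cie = np.full(config.n_true, config.beta**2)
    return float(cie.sum()), cie
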