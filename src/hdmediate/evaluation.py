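"""Estimands, metrics and the Monte Carlo driver of the simulation study.

The design crosses {correlated, independent} mediators x three sample
sizes x three true-mediator proportions x two effect sizes into 36
scenarios per mediator-set size.  Scenarios 1-18 are the correlated
settings, 19-36 the independent ones; within each block of 18 the first
9 use beta = 0.1 and the rest beta = 0.3, ordered by the proportion of
true mediators and then by sample size (so scenarios 25 and 34 are the
n=250, 10%-true cells, high-dimensional whenever p > 250).

Component-indirect-effect (CIE) bias is only defined in the independent
scenarios: when mediators are causally dependent the single-mediator
contrast has no identifiable interpretation (the "recanting witness"
problem), so correlated scenarios carry no CIE column at all.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from .dgp import CorrelationModel, ScenarioConfig, make_correlation_matrix, simulate_dataset
from .hdma import hdma_mediate
from .hima import hima_mediate
from .mitm import mitm_mediate
from .results import MediationResults

__all__ = [
    "ScenarioGrid",
    "sensitivity",
    "specificity",
    "bias",
    "build_scenario_grid",
    "run_monte_carlo",
    "summarize",
    "METHODS",
]

N_LEVELS = (250, 500, 1000)
PROP_LEVELS = (0.02, 0.05, 0.10)
BETA_LEVELS = (0.1, 0.3)

METHODS = {
    "MITM": lambda ds, alpha: mitm_mediate(ds, alpha=alpha),
    "HIMA": lambda ds, alpha: hima_mediate(ds, alpha=alpha),
    "HDMA": lambda ds, alpha: hdma_mediate(ds, alpha=alpha),
}

METRIC_COLUMNS = [
    "scenario_id", "method", "replicate", "tie_est", "tie_true",
    "cie_bias", "cie_bias_all", "sensitivity", "specificity",
    "n_selected", "failed",
]


def sensitivity(selected, true_idx) -> float:
    """Correctly identified mediators / total true mediators."""
    true_idx = {int(i) for i in true_idx}
    if not true_idx:
        raise ValueError("true_idx must be nonempty")
    selected = {int(i) for i in selected}
    return len(selected & true_idx) / len(true_idx)


def specificity(selected, true_idx, p: int) -> float:
    """Correctly rejected non-mediators / total non-mediators."""
    true_idx = {int(i) for i in true_idx}
    if len(true_idx) >= p:
        raise ValueError("need at least one non-mediator (|true_idx| < p)")
    selected = {int(i) for i in selected}
    false_pos = len(selected - true_idx)
    n_neg = p - len(true_idx)
    return (n_neg - false_pos) / n_neg


def bias(estimates, truth: float) -> float:
    """Mean estimate across replicates minus the true effect."""
    estimates = np.asarray(estimates, float)
    if estimates.size == 0:
        raise ValueError("estimates must be nonempty")
    return float(estimates.mean() - truth)


@dataclass(frozen=True)
class ScenarioGrid:
    """The 36-scenario design at one mediator-set size."""

    p_level: int
    scenarios: tuple[ScenarioConfig, ...]

    def __post_init__(self) -> None:
        if len(self.scenarios) != 36:
            raise ValueError("a scenario grid has exactly 36 entries")

    def __iter__(self):
        return iter(self.scenarios)

    def __getitem__(self, scenario_id: int) -> ScenarioConfig:
        """Look up by 1-based scenario id."""
        cfg = self.scenarios[scenario_id - 1]
        assert cfg.scenario_id == scenario_id
        return cfg

    def subset(self, ids) -> "list[ScenarioConfig]":
        return [self[i] for i in ids]


def build_scenario_grid(
    p_level: int,
    base_seed: int = 0,
    n_levels=N_LEVELS,
    prop_levels=PROP_LEVELS,
    beta_levels=BETA_LEVELS,
    n_confounders: int = 2,
) -> ScenarioGrid:
    """The full 36-scenario cross in the study's id ordering."""
    if p_level < 2:
        raise ValueError("p_level must be >= 2")
    scenarios = []
    sid = 1
    for correlated in (True, False):
        for beta in beta_levels:
            for prop in prop_levels:
                for n in n_levels:
                    scenarios.append(
                        ScenarioConfig(
                            scenario_id=sid, n=n, p=p_level, prop_true=prop,
                            beta=beta, correlated=correlated,
                            n_confounders=n_confounders, base_seed=base_seed,
                        )
                    )
                    sid += 1
    return ScenarioGrid(p_level=p_level, scenarios=tuple(scenarios))


def _replicate_rows(
    config: ScenarioConfig,
    corr: CorrelationModel | None,
    replicate: int,
    methods,
    alpha: float,
) -> list[dict]:
    ds = simulate_dataset(config, corr, replicate)
    rows = []
    for name in methods:
        row = {
            "scenario_id": config.scenario_id, "method": name,
            "replicate": replicate, "tie_true": ds.true_tie,
            "tie_est": np.nan, "cie_bias": np.nan, "cie_bias_all": np.nan,
            "sensitivity": np.nan, "specificity": np.nan,
            "n_selected": -1, "failed": False,
        }
        try:
            res: MediationResults = METHODS[name](ds, alpha)
        except Exception:  # noqa: BLE001 - recorded, never silently dropped
            row["failed"] = True
            rows.append(row)
            continue
        row["tie_est"] = res.tie
        row["n_selected"] = res.n_selected
        row["sensitivity"] = sensitivity(res.selected, ds.true_idx)
        row["specificity"] = specificity(res.selected, ds.true_idx, ds.p)
        if not config.correlated:
            # selection-conditional convention: average over selected true
            # mediators only (replicates selecting none contribute nothing)
            in_true = np.isin(res.selected, ds.true_idx)
            if in_true.any():
                row["cie_bias"] = float(
                    (res.cie[in_true] - config.beta**2).mean()
                )
            # mediator-set convention: every true mediator counts, with
            # estimate 0 when not selected
            est = np.zeros(ds.n_true)
            pos = {j: i for i, j in enumerate(ds.true_idx)}
            for j, c in zip(res.selected, res.cie):
                if j in pos:
                    est[pos[j]] = c
            row["cie_bias_all"] = float(est.mean() - config.beta**2)
        rows.append(row)
    return rows


_corr_cache: dict[tuple[int, int], CorrelationModel] = {}


def _shared_correlation(p: int, seed: int) -> CorrelationModel:
    """One fixed matrix per (p, seed), reused across scenarios/replicates."""
    key = (p, seed)
    if key not in _corr_cache:
        _corr_cache[key] = make_correlation_matrix(p, seed)
    return _corr_cache[key]


def _scenario_rows(config, corr_seed, n_reps, methods, alpha):
    corr = (
        _shared_correlation(config.p, corr_seed)
        if config.correlated else None
    )
    rows = []
    for rep in range(n_reps):
        rows.extend(_replicate_rows(config, corr, rep, methods, alpha))
    return rows


def run_monte_carlo(
    grid: ScenarioGrid | list[ScenarioConfig],
    n_reps: int = 1000,
    methods=("MITM", "HIMA", "HDMA"),
    base_seed: int | None = None,
    alpha: float = 0.05,
    n_jobs: int = 1,
) -> pd.DataFrame:
    """Apply each method to every replicate of every scenario.

    Every method sees the identical replicate dataset.  One correlation
    matrix per (p, seed) is shared by all replicates of a correlated
    scenario.  Failures are recorded as missing rows (``failed=True``),
    never dropped.  Fully reproducible from the configs' seeds and
    invariant to ``n_jobs`` (parallelism is over scenarios, each with
    its own derived stream).
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    unknown = set(methods) - set(METHODS)
    if unknown:
        raise ValueError(f"unknown methods: {sorted(unknown)}")
    configs = list(grid)
    if base_seed is not None:
        from dataclasses import replace
        configs = [replace(c, base_seed=base_seed) for c in configs]
    corr_seed = configs[0].base_seed if configs else 0

    if n_jobs == 1:
        chunks = [
            _scenario_rows(c, corr_seed, n_reps, methods, alpha) for c in configs
        ]
    else:
        chunks = Parallel(n_jobs=n_jobs)(
            delayed(_scenario_rows)(c, corr_seed, n_reps, methods, alpha)
            for c in configs
        )
    rows = [r for chunk in chunks for r in chunk]
    return pd.DataFrame(rows, columns=METRIC_COLUMNS)


def summarize(rows: pd.DataFrame) -> pd.DataFrame:
    """Per-(scenario, method) means and sample SDs of every metric.

    TIE bias is the mean estimate minus the true value; CIE bias
    averages only over replicates where it is defined (independent
    scenarios with at least one true mediator selected).  Failed
    replicates are excluded from all means and counted.
    """
    if len(rows) == 0:
        raise ValueError("no metric rows to summarize")
    out = []
    for (sid, method), g in rows.groupby(["scenario_id", "method"], sort=True):
        ok = g[~g["failed"]]
        tie_true = g["tie_true"].iloc[0]
        rec = {
            "scenario_id": sid,
            "method": method,
            "n_reps": len(g),
            "n_failed": int(g["failed"].sum()),
            "tie_true": tie_true,
            "tie_est_mean": ok["tie_est"].mean(),
            "tie_est_sd": ok["tie_est"].std(ddof=1),
            "tie_bias": ok["tie_est"].mean() - tie_true,
            "cie_bias_mean": ok["cie_bias"].mean(),
            "cie_bias_sd": ok["cie_bias"].std(ddof=1),
            "cie_bias_all_mean": ok["cie_bias_all"].mean(),
            "sensitivity_mean": ok["sensitivity"].mean(),
            "sensitivity_sd": ok["sensitivity"].std(ddof=1),
            "specificity_mean": ok["specificity"].mean(),
            "specificity_sd": ok["specificity"].std(ddof=1),
        }
        out.append(rec)
    return pd.DataFrame(out)
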