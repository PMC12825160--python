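"""Run configuration, seed ledger, manifests and fixture generation.

A run is described by a small YAML key-value file; :func:`load_config`
validates it against the scenario invariants and fills defaults.  A
:class:`RunManifest` snapshots everything needed to reproduce a run
bitwise: the config, package version, base seed and per-scenario seeds,
plus the output paths.
"""

from __future__ import annotations

import datetime as _dt
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .dgp import ScenarioConfig, SimulatedDataset, make_correlation_matrix, simulate_dataset
from .evaluation import (
    BETA_LEVELS,
    N_LEVELS,
    PROP_LEVELS,
    build_scenario_grid,
    run_monte_carlo,
    summarize,
)

__all__ = ["RunConfig", "RunManifest", "load_config", "make_fixture", "run_from_config"]

_KNOWN_KEYS = {
    "p_levels", "n_levels", "prop_levels", "beta_levels", "n_reps",
    "methods", "alpha", "n_confounders", "base_seed", "n_jobs", "out_dir",
}


@dataclass(frozen=True)
class RunConfig:
    """Validated configuration for a full or partial study run."""

    p_levels: tuple[int, ...] = (200,)
    n_levels: tuple[int, ...] = N_LEVELS
    prop_levels: tuple[float, ...] = PROP_LEVELS
    beta_levels: tuple[float, ...] = BETA_LEVELS
    n_reps: int = 1000
    methods: tuple[str, ...] = ("MITM", "HIMA", "HDMA")
    alpha: float = 0.05
    n_confounders: int = 2
    base_seed: int = 0
    n_jobs: int = 1
    out_dir: str = "results"

    def grids(self):
        return [
            build_scenario_grid(
                p, base_seed=self.base_seed, n_levels=self.n_levels,
                prop_levels=self.prop_levels, beta_levels=self.beta_levels,
                n_confounders=self.n_confounders,
            )
            for p in self.p_levels
        ]


def load_config(path: str | Path) -> RunConfig:
    """Parse and validate a YAML run configuration.

    Unknown keys are rejected; every scenario parameter is checked
    against the ScenarioConfig invariants by building the grids once.
    """
    path = Path(path)
    raw = yaml.safe_load(path.read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping")
    unknown = set(raw) - _KNOWN_KEYS
    if unknown:
        raise ValueError(f"{path}: unknown keys {sorted(unknown)}")
    kwargs = {}
    for key in ("p_levels", "n_levels", "prop_levels", "beta_levels", "methods"):
        if key in raw:
            val = raw[key]
            if not isinstance(val, (list, tuple)):
                raise ValueError(f"{path}: {key} must be a list")
            kwargs[key] = tuple(val)
    for key in ("n_reps", "n_confounders", "base_seed", "n_jobs"):
        if key in raw:
            if not isinstance(raw[key], int):
                raise ValueError(f"{path}: {key} must be an integer")
            kwargs[key] = raw[key]
    if "alpha" in raw:
        alpha = float(raw["alpha"])
        if not 0 < alpha < 1:
            raise ValueError(f"{path}: alpha must be in (0, 1)")
        kwargs["alpha"] = alpha
    if "out_dir" in raw:
        kwargs["out_dir"] = str(raw["out_dir"])
    config = RunConfig(**kwargs)
    if config.n_reps < 1:
        raise ValueError(f"{path}: n_reps must be >= 1")
    for prop in config.prop_levels:
        if not 0 < prop < 1:
            raise ValueError(f"{path}: prop_true level {prop} outside (0, 1)")
    config.grids()  # raises with the offending field on any bad scenario
    return config


@dataclass
class RunManifest:
    """Everything needed to reproduce one run bitwise."""

    config: dict
    package_version: str
    base_seed: int
    scenario_seeds: dict = field(default_factory=dict)
    outputs: list = field(default_factory=list)
    started: str = ""
    finished: str = ""

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "RunManifest":
        return cls(**json.loads(Path(path).read_text()))


def run_from_config(config: RunConfig, out_dir: str | Path | None = None):
    """Execute the configured study: metrics.csv, summary.csv, manifest.

    Returns (metrics frame, summary frame, manifest).  Re-running from
    the saved manifest's config reproduces metrics.csv bitwise.
    """
    out = Path(out_dir if out_dir is not None else config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config=asdict(config),
        package_version=__version__,
        base_seed=config.base_seed,
        started=_dt.datetime.now(_dt.timezone.utc).isoformat(),
    )
    frames = []
    for grid in config.grids():
        rows = run_monte_carlo(
            grid, n_reps=config.n_reps, methods=config.methods,
            alpha=config.alpha, n_jobs=config.n_jobs,
        )
        rows.insert(0, "p_level", grid.p_level)
        frames.append(rows)
        manifest.scenario_seeds.update({
            f"p{grid.p_level}_s{c.scenario_id}": c.base_seed for c in grid
        })
    metrics = frames[0] if len(frames) == 1 else _concat(frames)
    summary = (
        metrics.groupby("p_level", group_keys=False)
        .apply(lambda g: summarize(g).assign(p_level=g.name), include_groups=False)
        .reset_index(drop=True)
    )
    metrics_path = out / "metrics.csv"
    summary_path = out / "summary.csv"
    metrics.to_csv(metrics_path, index=False)
    summary.to_csv(summary_path, index=False)
    manifest.outputs = [str(metrics_path), str(summary_path)]
    manifest.finished = _dt.datetime.now(_dt.timezone.utc).isoformat()
    manifest.save(out / "manifest.json")
    return metrics, summary, manifest


def _concat(frames):
    import pandas as pd

    return pd.concat(frames, ignore_index=True)


_FIXTURE_KINDS = ("tiny_independent", "tiny_correlated", "null")


def make_fixture(kind: str, seed: int = 0, out_dir: str | Path | None = None
                 ) -> SimulatedDataset:
    """Small deterministic datasets (n=200, p=20) for fast unit tests.

    ``null`` has beta = 0 (no mediation); the other kinds use beta = 0.3
    with two true mediators.  When ``out_dir`` is given, writes
    ``<kind>.csv`` (samples x columns) and ``<kind>.json`` (ground
    truth); bytes are identical across runs for a fixed seed.
    """
    if kind not in _FIXTURE_KINDS:
        raise ValueError(f"kind must be one of {_FIXTURE_KINDS}")
    correlated = kind == "tiny_correlated"
    config = ScenarioConfig(
        scenario_id=0, n=200, p=20, prop_true=0.10,
        beta=0.0 if kind == "null" else 0.3,
        correlated=correlated, base_seed=seed,
    )
    corr = make_correlation_matrix(20, seed) if correlated else None
    ds = simulate_dataset(config, corr, replicate_seed=0)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        ds.to_frame().to_csv(out / f"{kind}.csv", index=False, float_format="%.12g")
        truth = {
            "kind": kind, "seed": seed, "beta": ds.beta,
            "true_idx": np.asarray(ds.true_idx).tolist(),
            "true_tie": ds.true_tie,
        }
        (out / f"{kind}.json").write_text(json.dumps(truth, indent=2, sort_keys=True))
    return ds
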