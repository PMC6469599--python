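"""End-to-end experiment drivers: slowdown sweep and completeness sweep.

``run_slowdown_experiment`` reproduces the core protocol: for each synapse
count N, build the square (K = N) ensemble, start from the unequal mix of
two selective fixed points ``w(0) = (1-eps) w1* + eps w2*``, simulate the
permuted-schedule dynamics, measure the angle to ``w1*``, fit the simulation
time constant and compare it with the spectral prediction.

``run_completeness_experiment`` varies the stimulus count (K = N/2, N, or
2N equi-spaced profiles).  For K != N no closed-form fixed point exists
(the circulant theory does not extend), so runs start from a seeded random
non-negative weight vector and convergence is measured post hoc against the
weight vector at the final recorded step; the winning stimulus (largest
final response) is reported alongside.

Step budgets scale with the predicted timescale and are capped by the
config; per-run seeds are derived deterministically from (config seed, N, K)
so a K = N completeness run reproduces the slowdown trajectory exactly.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd
import yaml

from .convergence import (
    ConvergenceTrace,
    FitFailureError,
    fit_time_constant,
    steps_to_convergence,
    trace_convergence,
    trace_to_csv,
)
from .core import BCMParams, SimulationDivergedError, simulate
from .fixed_points import mixed_initial_condition, selective_fixed_point
from .spectral import critical_timescale, eigen_spectrum
from .stimuli import build_ensemble

__all__ = [
    "ExperimentConfig",
    "ExperimentResult",
    "run_slowdown_experiment",
    "run_completeness_experiment",
    "export_results",
]

logger = logging.getLogger("bcmring.experiments")

_K_FACTORS = {"half": 0.5, "equal": 1.0, "double": 2.0}


@dataclass(frozen=True)
class ExperimentConfig:
    """All knobs of an experiment sweep; a results file is a pure function
    of (config, seed)."""

    profile_kind: str = "von_mises"
    omega: float = 0.5
    n_values: tuple[int, ...] = (8, 10, 12)
    k_ratio: str = "equal"
    tau_w: float = 1000.0
    threshold_mode: str = "averaged"
    epsilon: float = 0.1
    seed: int = 0
    max_steps: int = 200_000_000
    record_every: int | None = None
    fit_window: tuple[float, float] = (0.5, 0.05)
    steps_per_tau: float = 20.0
    conv_threshold: float = 0.05
    mixed_pair: tuple[int, int] = (0, 1)
    output_dir: str | None = None

    def __post_init__(self) -> None:
        for n in self.n_values:
            if n < 4 or n % 2 != 0:
                raise ValueError(f"n_values must be even integers >= 4 (got {n})")
        if self.k_ratio not in _K_FACTORS:
            raise ValueError(f"k_ratio must be one of {sorted(_K_FACTORS)}")
        if self.max_steps < max(self.n_values) * 2:
            raise ValueError("max_steps must allow at least one epoch for the largest N")
        if self.steps_per_tau <= 0:
            raise ValueError("steps_per_tau must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "ExperimentConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update(overrides)
        for key in ("n_values", "fit_window", "mixed_pair"):
            if key in data and data[key] is not None:
                data[key] = tuple(data[key])
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


class ExperimentResult(NamedTuple):
    table: pd.DataFrame
    traces: dict[str, ConvergenceTrace]
    trajectories: dict[str, "object"]


def _run_seed(config: ExperimentConfig, n: int, k: int) -> int:
    """Deterministic per-run seed; independent of which experiment calls it."""
    return int(np.random.SeedSequence((config.seed, n, k)).generate_state(1)[0] % 2**31)


def _k_for(config: ExperimentConfig, n: int) -> int:
    k = int(round(_K_FACTORS[config.k_ratio] * n))
    if config.k_ratio == "half" and n % 4 != 0 and k * 2 != n:
        k = n // 2
    return k


def _step_budget(config: ExperimentConfig, n: int, k: int, tau_steps: float | None) -> int:
    """Presentation budget: steps_per_tau predicted timescales, capped.

    For K = N/2 convergence does not slow with N, so a flat budget is used;
    for K = 2N the slowdown persists at roughly twice the square-case scale.
    """
    if k < n:
        return int(min(config.max_steps, 4_000_000))
    if tau_steps is None or not math.isfinite(tau_steps):
        return config.max_steps
    factor = 2.0 if k > n else 1.0
    return int(min(config.max_steps, math.ceil(factor * config.steps_per_tau * tau_steps)))


def _record_every(config: ExperimentConfig, n_steps: int) -> int:
    if config.record_every is not None:
        return config.record_every
    return max(1, n_steps // 2000)


def run_slowdown_experiment(config: ExperimentConfig) -> ExperimentResult:
    """Timescale-vs-N sweep at K = N; one row per synapse count.

    Columns: N, kind, tau_sim (presentation steps), tau_theory (sweeps),
    tau_theory_steps (= K * tau_theory), r_squared, lambda_crit, crit_mode,
    lambda_half_mode, n_steps, seed, status.
    """
    if config.k_ratio != "equal":
        raise ValueError("the slowdown experiment requires k_ratio='equal'")
    rows = []
    traces: dict[str, ConvergenceTrace] = {}
    trajectories: dict[str, object] = {}
    for n in config.n_values:
        ensemble = build_ensemble(config.profile_kind, n, n, config.omega)
        spec = eigen_spectrum(ensemble.profile, config.tau_w)
        row = {
            "N": n,
            "kind": config.profile_kind,
            "K": n,
            "lambda_crit": spec.lambda_crit,
            "crit_mode": spec.crit_mode,
            "lambda_half_mode": spec.lambda_half_mode,
            "tau_sim": np.nan,
            "r_squared": np.nan,
            "tau_theory": np.nan,
            "tau_theory_steps": np.nan,
            "n_steps": 0,
            "seed": _run_seed(config, n, n),
            "status": "ok",
        }
        if ensemble.is_singular:
            row["status"] = "singular"
            rows.append(row)
            logger.warning("N=%d ensemble singular; skipping simulation", n)
            continue
        tau_theory = critical_timescale(ensemble.profile, config.tau_w)
        tau_steps = n * tau_theory
        row["tau_theory"] = tau_theory
        row["tau_theory_steps"] = tau_steps
        n_steps = _step_budget(config, n, n, tau_steps)
        row["n_steps"] = n_steps
        ka, kb = config.mixed_pair
        fp1 = selective_fixed_point(ensemble, ka)
        fp2 = selective_fixed_point(ensemble, kb)
        w0 = mixed_initial_condition(fp1, fp2, config.epsilon)
        params = BCMParams(
            tau_w=config.tau_w,
            threshold_mode=config.threshold_mode,
            epsilon=config.epsilon,
            seed=row["seed"],
            max_steps=n_steps,
        )
        logger.info("slowdown N=%d: %d steps (theory %.3g steps), seed %d",
                    n, n_steps, tau_steps, row["seed"])
        try:
            traj = simulate(ensemble, params, w0, record_every=_record_every(config, n_steps))
            trajectories[f"slowdown_{config.profile_kind}_N{n}"] = traj
            trace = trace_convergence(traj, fp1, normalize=True)
            traces[f"slowdown_{config.profile_kind}_N{n}"] = trace
            fit = fit_time_constant(trace, config.fit_window)
            row["tau_sim"] = fit.tau_sim
            row["r_squared"] = fit.r_squared
        except (FitFailureError, SimulationDivergedError) as exc:
            row["status"] = f"failed: {exc.__class__.__name__}"
            logger.warning("N=%d run failed: %s", n, exc)
        rows.append(row)
    return ExperimentResult(pd.DataFrame(rows), traces, trajectories)


def run_completeness_experiment(config: ExperimentConfig) -> ExperimentResult:
    """Convergence-vs-N sweep at K = N/2, N, or 2N (set by ``k_ratio``).

    Columns: N, K, k_ratio, init, conv_steps (first recorded step from which
    the angle to the final state stays below ``conv_threshold`` radians),
    winner (stimulus with the largest final response), final_theta, n_steps,
    seed, status.
    """
    rows = []
    traces: dict[str, ConvergenceTrace] = {}
    trajectories: dict[str, object] = {}
    for n in config.n_values:
        k = _k_for(config, n)
        ensemble = build_ensemble(config.profile_kind, n, k, config.omega)
        seed = _run_seed(config, n, k)
        tau_steps = None
        if not (ensemble.is_square and ensemble.is_singular):
            try:
                tau_steps = k * critical_timescale(
                    build_ensemble(config.profile_kind, n, n, config.omega).profile,
                    config.tau_w,
                )
            except ValueError:
                tau_steps = None
        n_steps = _step_budget(config, n, k, tau_steps)
        row = {
            "N": n, "K": k, "k_ratio": config.k_ratio,
            "init": "mixed" if k == n else "random",
            "conv_steps": np.nan, "winner": -1, "final_theta": np.nan,
            "n_steps": n_steps, "seed": seed, "status": "ok",
        }
        if ensemble.is_square and ensemble.is_singular:
            row["status"] = "singular"
            rows.append(row)
            continue
        if k == n:
            ka, kb = config.mixed_pair
            fp1 = selective_fixed_point(ensemble, ka)
            fp2 = selective_fixed_point(ensemble, kb)
            w0 = mixed_initial_condition(fp1, fp2, config.epsilon)
        else:
            w0 = np.random.default_rng(seed).uniform(0.0, 1.0, n)
        params = BCMParams(
            tau_w=config.tau_w,
            threshold_mode=config.threshold_mode,
            epsilon=config.epsilon,
            seed=seed,
            max_steps=n_steps,
        )
        logger.info("completeness N=%d K=%d: %d steps, seed %d", n, k, n_steps, seed)
        try:
            traj = simulate(ensemble, params, w0, record_every=_record_every(config, n_steps))
            trajectories[f"completeness_{config.k_ratio}_N{n}"] = traj
            # post-hoc target: the state at the final recorded step
            trace = trace_convergence(traj, traj.final_weights, normalize=False)
            traces[f"completeness_{config.k_ratio}_N{n}"] = trace
            row["conv_steps"] = steps_to_convergence(trace, config.conv_threshold)
            responses = ensemble.matrix.T @ traj.final_weights
            row["winner"] = int(np.argmax(responses))
            row["final_theta"] = float(np.mean(responses**2))
        except SimulationDivergedError as exc:
            row["status"] = f"failed: {exc.__class__.__name__}"
            logger.warning("N=%d K=%d run failed: %s", n, k, exc)
        rows.append(row)
    return ExperimentResult(pd.DataFrame(rows), traces, trajectories)


def export_results(
    tables: dict[str, pd.DataFrame],
    traces: dict[str, ConvergenceTrace],
    config: ExperimentConfig,
    output_dir: str | Path | None = None,
    plots: bool = False,
) -> list[Path]:
    """Write result tables, per-run traces, and a reproducibility manifest.

    Empty tables produce a manifest-only output.  Every file is reproducible
    from the manifest's config + seed.  With ``plots`` a log-time PNG per
    trace set is written as well.
    """
    out = Path(output_dir or config.output_dir or ".")
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    manifest = {
        "config": _jsonable(config.to_dict()),
        "tables": sorted(k for k, t in tables.items() if len(t)),
        "traces": sorted(traces),
    }
    for name, table in tables.items():
        if len(table) == 0:
            continue
        path = out / f"{name}.csv"
        table.to_csv(path, index=False)
        written.append(path)
    for name, trace in traces.items():
        path = out / f"trace_{name}.csv"
        trace_to_csv(trace, path)
        written.append(path)
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    written.append(manifest_path)
    if plots and traces:
        written.append(_plot_traces(traces, out / "traces.png"))
    return written


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def _plot_traces(traces: dict[str, ConvergenceTrace], path: Path) -> Path:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for name, trace in sorted(traces.items()):
        mask = trace.times > 0
        ax.plot(trace.times[mask], trace.angles[mask], label=name, lw=1)
    ax.set_xscale("log")
    ax.set_yscale("log")
    ax.set_xlabel("presentation step")
    ax.set_ylabel("angle to target")
    ax.legend(fontsize=6)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
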