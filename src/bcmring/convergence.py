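"""Convergence metrics: angle to the target state and time-constant fits.

The convergence measure is the angle between the instantaneous weight
vector and the steady-state weight vector — invariant to the overall weight
scale, which the BCM rule does not pin down along the way.  Near a stable
fixed point only the slowest Jacobian mode survives, so the angle decays as
a single exponential and an ordinary least-squares fit of log(angle) against
time recovers the simulation time constant.  The fit is restricted to a
window of normalised angle (default: from 0.5 down to 0.05 of the initial
angle) to exclude both the early multi-mode transient and the late-time
noise floor.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import scipy.stats

from .core import BCMTrajectory
from .fixed_points import FixedPoint

__all__ = [
    "ConvergenceTrace",
    "FitResult",
    "FitFailureError",
    "angle_to_target",
    "trace_convergence",
    "fit_time_constant",
    "steps_to_convergence",
]


class FitFailureError(RuntimeError):
    """The time-constant fit is ill-posed on this trace."""


@dataclass
class ConvergenceTrace:
    """Angle-to-target time series.

    ``angles`` are radians in [0, pi]; if ``normalized`` the series was
    divided by its first value (so it starts at 1, dimensionless).
    ``raw_angles`` always keeps the unnormalised radians.
    """

    times: np.ndarray
    angles: np.ndarray
    normalized: bool
    target_ref: str = ""
    raw_angles: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.angles = np.asarray(self.angles, dtype=float)
        if self.raw_angles is None:
            self.raw_angles = self.angles if not self.normalized else None


@dataclass(frozen=True)
class FitResult:
    tau_sim: float
    r_squared: float
    window_used: tuple[float, float]
    n_points: int


def angle_to_target(weights: np.ndarray, target: np.ndarray) -> float:
    """Angle in radians between two weight vectors (scale-invariant)."""
    w = np.asarray(weights, dtype=float)
    t = np.asarray(target, dtype=float)
    if w.shape != t.shape:
        raise ValueError(f"dimension mismatch: {w.shape} vs {t.shape}")
    nw = np.linalg.norm(w)
    nt = np.linalg.norm(t)
    if nw == 0 or nt == 0:
        raise ValueError("angle to a zero vector is undefined")
    cosine = np.clip(float(w @ t) / (nw * nt), -1.0, 1.0)
    return float(np.arccos(cosine))


def trace_convergence(
    trajectory: BCMTrajectory,
    target: FixedPoint | np.ndarray,
    normalize: bool = True,
) -> ConvergenceTrace:
    """Angle to ``target`` at every recorded time of a trajectory.

    With ``normalize`` the series is divided by the angle at the first
    recorded time (which must be non-zero).
    """
    tvec = target.weights if isinstance(target, FixedPoint) else np.asarray(target, float)
    raw = np.empty(trajectory.times.size)
    for i, w in enumerate(trajectory.weight_history):
        if not np.any(w):
            raise ValueError(f"zero weight vector recorded at step {trajectory.times[i]}")
        raw[i] = angle_to_target(w, tvec)
    if normalize:
        if raw[0] == 0.0:
            raise ValueError("cannot normalize: initial angle is zero")
        angles = raw / raw[0]
    else:
        angles = raw
    ref = "fixed_point" if isinstance(target, FixedPoint) else "vector"
    return ConvergenceTrace(
        times=trajectory.times.astype(float),
        angles=angles,
        normalized=normalize,
        target_ref=ref,
        raw_angles=raw,
    )


def fit_time_constant(
    trace: ConvergenceTrace,
    fit_window: tuple[float, float] = (0.5, 0.05),
) -> FitResult:
    """Exponential time constant from OLS of log(angle) against time.

    The fit uses records whose *normalised* angle lies in
    ``[fit_window[1], fit_window[0]]``; at least 10 such records with
    strictly positive angles are required, and a non-decaying fit (slope
    >= 0, i.e. infinite or negative tau) is rejected rather than silently
    extrapolated.
    """
    upper, lower = fit_window
    if not 0 < lower < upper:
        raise ValueError("fit_window must be (upper, lower) with 0 < lower < upper")
    angles = trace.angles if trace.normalized else trace.angles / trace.angles[0]
    raw = trace.raw_angles if trace.raw_angles is not None else trace.angles
    mask = (angles <= upper) & (angles >= lower)
    n_pts = int(mask.sum())
    if n_pts < 10:
        raise FitFailureError(
            f"only {n_pts} records fall in the fit window {fit_window}; "
            "need >= 10 (trace too short or not yet converged)"
        )
    if np.any(raw[mask] <= 0):
        raise FitFailureError("non-positive angles inside the fit window")
    res = scipy.stats.linregress(trace.times[mask], np.log(raw[mask]))
    if res.slope >= 0:
        raise FitFailureError(
            f"non-decaying fit (slope {res.slope:.3g} >= 0); "
            "infinite time constant rejected"
        )
    return FitResult(
        tau_sim=-1.0 / res.slope,
        r_squared=float(res.rvalue**2),
        window_used=(float(upper), float(lower)),
        n_points=n_pts,
    )


def steps_to_convergence(trace: ConvergenceTrace, threshold: float = 0.05) -> float:
    """First recorded time from which the raw angle stays below ``threshold``.

    ``threshold`` is in radians on the unnormalised angle.  Returns NaN when
    the trace never settles below the threshold.
    """
    raw = trace.raw_angles if trace.raw_angles is not None else trace.angles
    below = raw <= threshold
    if not below[-1]:
        return float("nan")
    # walk back to the start of the final below-threshold run
    idx = raw.size - 1
    while idx > 0 and below[idx - 1]:
        idx -= 1
    return float(trace.times[idx])


def trace_to_csv(trace: ConvergenceTrace, path: str | Path) -> None:
    """Write ``step, angle, normalized_angle`` columns."""
    raw = trace.raw_angles if trace.raw_angles is not None else trace.angles
    norm = raw / raw[0] if raw[0] != 0 else raw
    lines = ["step,angle,normalized_angle"]
    for t, a, na in zip(trace.times, raw, norm):
        lines.append(f"{t!r},{a!r},{na!r}")
    Path(path).write_text("\n".join(lines) + "\n")
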