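"""BCM weight and threshold dynamics for a single linear neuron.

The neuron's output is ``y = sum_i w_i x_i``.  Each presentation of a
stimulus ``x`` moves the weights by

    dw_i = (1/tau_w) * x_i * y * (y - theta)

where the sliding threshold ``theta`` tracks the average squared output.
Two threshold conventions are provided:

* ``averaged`` (default) — ``theta = (1/K) sum_k (y^k)^2`` is recomputed from
  all K stimuli before every update.  This is the quasi-static limit in which
  the threshold equilibrates much faster than the weights and reduces the
  system to N dimensions; the spectral analysis is built on it.
* ``online`` — ``theta`` is a state variable integrated as
  ``d(theta)/dt = (-theta + y^2)/tau_theta`` using the current stimulus only,
  which keeps the full (N+1)-dimensional system.  With ``tau_theta << tau_w``
  the two conventions agree.

Time is discretised so one stimulus presentation is one unit step (forward
Euler with dt = 1); ``tau_w`` is therefore counted in presentation steps.
Weights are unconstrained in sign and magnitude — the selective fixed points
``w* = N X^{-1} e_k`` generally have negative entries, and any clipping or
normalisation would destroy them.

For analysis there is also the deterministic drift field summed over the
stimulus set, ``F_i(w) = sum_k x_i^k y^k (y^k - theta)``, whose zeros are the
equilibria and whose Jacobian at a selective fixed point is ``-N X X``.  One
application of ``F`` corresponds to one full sweep of K presentations, so a
time constant of the drift flow equals K presentation steps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels
from .stimuli import StimulusEnsemble

__all__ = [
    "BCMParams",
    "BCMState",
    "BCMTrajectory",
    "SimulationDivergedError",
    "response",
    "batch_threshold",
    "averaged_drift",
    "bcm_step",
    "simulate",
    "integrate_drift",
]

#: simulate aborts when ||w|| exceeds this multiple of max(||w(0)||, 1)
DIVERGENCE_FACTOR = 1e6


class SimulationDivergedError(RuntimeError):
    """Raised when the weight norm explodes; carries the offending step."""

    def __init__(self, step: int):
        self.step = int(step)
        super().__init__(
            f"weight norm exceeded {DIVERGENCE_FACTOR:.0e} x its initial value "
            f"at presentation step {step}; the learning rate (1/tau_w) is "
            "likely too large for this ensemble"
        )


@dataclass(frozen=True)
class BCMParams:
    """Dynamics constants.

    tau_w : weight time constant, in presentation steps.
    tau_theta : threshold time constant (online mode only); defaults to
        ``tau_w / 20`` and must be smaller than ``tau_w`` — the analysis
        assumes the threshold equilibrates fast.
    threshold_mode : ``"averaged"`` or ``"online"``.
    epsilon : mixing weight for the two-fixed-point initial condition.
    seed : PRNG seed for the permuted presentation schedule.
    max_steps : presentation budget for :func:`simulate`.
    """

    tau_w: float = 1000.0
    tau_theta: float | None = None
    threshold_mode: str = "averaged"
    epsilon: float = 0.1
    seed: int = 0
    max_steps: int = 100_000

    def __post_init__(self) -> None:
        if self.tau_w <= 0:
            raise ValueError("tau_w must be positive")
        if self.threshold_mode not in ("averaged", "online"):
            raise ValueError(f"unknown threshold_mode {self.threshold_mode!r}")
        if self.threshold_mode == "online":
            tt = self.tau_theta if self.tau_theta is not None else self.tau_w / 20.0
            if tt <= 0 or tt >= self.tau_w:
                raise ValueError(
                    "online mode requires 0 < tau_theta < tau_w (threshold "
                    "must equilibrate faster than the weights)"
                )
        if not 0 <= self.epsilon < 1:
            raise ValueError("epsilon must lie in [0, 1)")
        if self.max_steps < 1:
            raise ValueError("max_steps must be >= 1")

    @property
    def effective_tau_theta(self) -> float:
        return self.tau_theta if self.tau_theta is not None else self.tau_w / 20.0


@dataclass
class BCMState:
    weights: np.ndarray
    theta: float = 0.0
    step: int = 0

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)


@dataclass
class BCMTrajectory:
    """Recorded time series of a simulation run."""

    times: np.ndarray
    weight_history: np.ndarray
    theta_history: np.ndarray
    ensemble_ref: str = ""
    params_ref: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("recorded times must be strictly increasing")
        if self.weight_history.shape[0] != self.times.size:
            raise ValueError("one weight record per recorded time required")

    @property
    def final_weights(self) -> np.ndarray:
        return self.weight_history[-1]


def response(weights: np.ndarray, stimulus: np.ndarray) -> float:
    """Linear output ``y = sum_i w_i x_i``."""
    weights = np.asarray(weights, dtype=float)
    stimulus = np.asarray(stimulus, dtype=float)
    if weights.shape != stimulus.shape:
        raise ValueError(
            f"weight/stimulus length mismatch: {weights.shape} vs {stimulus.shape}"
        )
    return float(weights @ stimulus)


def _check_weights(weights: np.ndarray, ensemble: StimulusEnsemble) -> np.ndarray:
    weights = np.asarray(weights, dtype=float)
    if weights.shape != (ensemble.n_synapses,):
        raise ValueError(
            f"weight vector of length {weights.shape} does not match "
            f"ensemble with N={ensemble.n_synapses}"
        )
    return weights


def batch_threshold(weights: np.ndarray, ensemble: StimulusEnsemble) -> float:
    """Stimulus-averaged threshold ``theta = (1/K) sum_k (y^k)^2``."""
    weights = _check_weights(weights, ensemble)
    y = ensemble.matrix.T @ weights
    return float(np.mean(y * y))


def averaged_drift(weights: np.ndarray, ensemble: StimulusEnsemble) -> np.ndarray:
    """Drift field ``F_i = sum_k x_i^k y^k (y^k - theta)`` (sum over stimuli).

    Vanishes exactly at every equilibrium of the averaged dynamics.  Note the
    sum (not mean) over stimuli: this is the convention under which the
    Jacobian at a selective fixed point is ``-N X X``.
    """
    weights = _check_weights(weights, ensemble)
    x = ensemble.matrix
    y = x.T @ weights
    theta = float(np.mean(y * y))
    return x @ (y * (y - theta))


def bcm_step(
    state: BCMState,
    stimulus: np.ndarray,
    params: BCMParams,
    ensemble: StimulusEnsemble,
) -> BCMState:
    """One presentation: update ``theta`` per the threshold mode, then ``w``.

    In averaged mode the threshold is recomputed from all K stimuli using the
    pre-update weights; in online mode the threshold state is advanced by
    ``(-theta + y^2)/tau_theta`` with the current stimulus response before
    the weight update.
    """
    w = _check_weights(state.weights, ensemble)
    stimulus = np.asarray(stimulus, dtype=float)
    if stimulus.shape != (ensemble.n_synapses,):
        raise ValueError("stimulus length does not match ensemble N")
    y = float(w @ stimulus)
    if params.threshold_mode == "averaged":
        theta = batch_threshold(w, ensemble)
    else:
        theta = state.theta + (-state.theta + y * y) / params.effective_tau_theta
    w_new = w + (y * (y - theta) / params.tau_w) * stimulus
    return BCMState(weights=w_new, theta=theta, step=state.step + 1)


def simulate(
    ensemble: StimulusEnsemble,
    params: BCMParams,
    init_weights: np.ndarray,
    record_every: int = 1,
    schedule: np.ndarray | None = None,
) -> BCMTrajectory:
    """Run ``params.max_steps`` presentations in randomly permuted order.

    Within each epoch of K presentations every stimulus appears exactly once;
    the order is drawn from a Generator seeded with ``params.seed``, so the
    run is fully deterministic given (seed, params, init_weights, ensemble).
    The state is recorded at step 0, every ``record_every`` steps, and at the
    final step.  An explicit ``schedule`` (array of stimulus indices)
    overrides the permuted order, e.g. for cross-checks against
    :func:`bcm_step`.

    Raises :class:`SimulationDivergedError` if the weight norm explodes.
    """
    w0 = _check_weights(init_weights, ensemble)
    if record_every < 1:
        raise ValueError("record_every must be >= 1")
    x = ensemble.matrix
    k = ensemble.n_stimuli
    gram = x.T @ x
    w = w0.copy()
    r = x.T @ w
    mode = _kernels.MODE_AVERAGED if params.threshold_mode == "averaged" else _kernels.MODE_ONLINE
    # online runs start the threshold at its quasi-static value
    theta = batch_threshold(w, ensemble) if mode == _kernels.MODE_ONLINE else 0.0
    n_steps = int(params.max_steps)
    diverge_norm2 = (DIVERGENCE_FACTOR * max(float(np.linalg.norm(w0)), 1.0)) ** 2

    n_rec = n_steps // record_every + 2
    rec_t = np.zeros(n_rec, dtype=np.int64)
    rec_w = np.zeros((n_rec, ensemble.n_synapses))
    rec_th = np.zeros(n_rec)
    rec_t[0] = 0
    rec_w[0] = w
    rec_th[0] = batch_threshold(w, ensemble) if mode == _kernels.MODE_AVERAGED else theta
    ri = 1

    if schedule is not None:
        chunks = [np.ascontiguousarray(schedule, dtype=np.int64)]
        if len(chunks[0]) != n_steps:
            n_steps = len(chunks[0])
    else:
        rng = np.random.default_rng(params.seed)
        chunks = _kernels.schedule_chunks(rng, k, n_steps)

    offset = 0
    for sched in chunks:
        ri, status, bad_step, theta = _kernels.run_schedule(
            x, gram, w, r, params.tau_w, sched, mode, theta,
            params.effective_tau_theta, record_every, offset,
            rec_t, rec_w, rec_th, ri, diverge_norm2,
        )
        if status == _kernels.DIVERGED:
            raise SimulationDivergedError(bad_step)
        offset += len(sched)

    if rec_t[ri - 1] != n_steps:
        rec_t[ri] = n_steps
        rec_w[ri] = w
        rec_th[ri] = batch_threshold(w, ensemble) if mode == _kernels.MODE_AVERAGED else theta
        ri += 1
    return BCMTrajectory(
        times=rec_t[:ri].copy(),
        weight_history=rec_w[:ri].copy(),
        theta_history=rec_th[:ri].copy(),
        ensemble_ref=f"{ensemble.profile.kind}(N={ensemble.n_synapses},K={k})",
        params_ref=f"seed={params.seed},mode={params.threshold_mode}",
    )


def integrate_drift(
    ensemble: StimulusEnsemble,
    init_weights: np.ndarray,
    tau_w: float = 1000.0,
    n_steps: int = 10_000,
    record_every: int = 1,
) -> BCMTrajectory:
    """Deterministic forward-Euler flow of the summed drift field.

    ``w <- w + (1/tau_w) F(w)`` with unit time step; one step corresponds to
    one full sweep of the K stimuli, so time constants measured here are in
    sweep units (multiply by K for presentation steps).  Used to compare the
    relaxation rate with the analytic eigenvalues without schedule noise.
    """
    w = _check_weights(init_weights, ensemble).copy()
    if tau_w <= 0:
        raise ValueError("tau_w must be positive")
    times = [0]
    ws = [w.copy()]
    ths = [batch_threshold(w, ensemble)]
    x = ensemble.matrix
    for t in range(1, n_steps + 1):
        y = x.T @ w
        theta = float(np.mean(y * y))
        w += (x @ (y * (y - theta))) / tau_w
        if not np.all(np.isfinite(w)):
            raise SimulationDivergedError(t)
        if t % record_every == 0 or t == n_steps:
            times.append(t)
            ws.append(w.copy())
            ths.append(batch_threshold(w, ensemble))
    return BCMTrajectory(
        times=np.array(times),
        weight_history=np.array(ws),
        theta_history=np.array(ths),
        ensemble_ref=f"{ensemble.profile.kind}(N={ensemble.n_synapses},K={ensemble.n_stimuli})",
        params_ref=f"drift,tau_w={tau_w}",
    )
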