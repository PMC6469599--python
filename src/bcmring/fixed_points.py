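"""Equilibria of the averaged BCM dynamics and their stability.

With a complete stimulus basis (det X != 0) every equilibrium is determined
by its *active set* S — the stimuli to which the neuron responds.  The
threshold constraint theta = (1/K) sum_k (y^k)^2 with y^k in {0, theta}
forces theta = K/|S|, so the equilibrium weights solve the linear system
``X^T w = y*`` with ``y*_k = K/|S|`` on S and 0 elsewhere.  The selective
equilibria (|S| = 1) are the columns of the inverse stimulus matrix scaled
by N, ``w* = N X^{-1} e_k``, and are the only stable ones; equilibria active
for several stimuli, or for none, are unstable (or marginal for the empty
set, whose linearisation vanishes identically).

Stability is classified numerically from a central-finite-difference
Jacobian of the summed drift field, which includes the threshold's
dependence on the weights.  Linear solves use an LU factorisation of X
rather than an explicit inverse, and the condition number of X is reported:
X becomes ill-conditioned exactly in the slow-learning regime (a_{N/2} -> 0),
so the conditioning is itself diagnostic.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import scipy.linalg

from .core import averaged_drift
from .stimuli import SINGULARITY_TOL, StimulusEnsemble

__all__ = [
    "FixedPoint",
    "selective_fixed_point",
    "general_fixed_point",
    "classify_stability",
    "mixed_initial_condition",
    "enumerate_fixed_points",
    "fixed_point_report",
]

#: finite-difference step scale for the stability Jacobian
FD_STEP = 1e-5

#: eigenvalue real parts within +/- STABILITY_TOL * N count as marginal
STABILITY_TOL = 1e-7


@dataclass
class FixedPoint:
    """An equilibrium weight vector with its active-stimulus set.

    ``responses[k]`` is within solver tolerance of ``theta_star`` for k in
    the active set and of 0 otherwise; ``theta_star = K/|S|`` (0 for the
    empty set).  ``stability`` is None until :func:`classify_stability` is
    called.
    """

    weights: np.ndarray
    active_set: frozenset[int]
    responses: np.ndarray
    theta_star: float
    stability: str | None = None
    condition_number: float = np.nan


def _require_invertible(ensemble: StimulusEnsemble) -> np.ndarray:
    if not ensemble.is_square:
        raise ValueError(
            "fixed points in closed form require a square ensemble (K = N); "
            f"got N={ensemble.n_synapses}, K={ensemble.n_stimuli}"
        )
    if ensemble.is_singular:
        raise ValueError(
            "ensemble matrix is singular (sigma_min/sigma_max below "
            f"{SINGULARITY_TOL:g}, i.e. det(X) = 0 numerically); the stimuli "
            "do not span a complete basis, so X^{-1} does not exist"
        )
    return ensemble.matrix


def general_fixed_point(ensemble: StimulusEnsemble, active_set) -> FixedPoint:
    """Equilibrium with responses ``K/|S|`` on the active set, 0 elsewhere.

    Solves ``X^T w = y*`` via LU factorisation.  The empty set gives the
    trivial equilibrium w = 0.
    """
    x = _require_invertible(ensemble)
    k = ensemble.n_stimuli
    active = frozenset(int(i) for i in active_set)
    if active and (min(active) < 0 or max(active) >= k):
        raise ValueError(f"active set {sorted(active)} out of range 0..{k - 1}")
    y_target = np.zeros(k)
    theta_star = 0.0
    if active:
        theta_star = k / len(active)
        y_target[sorted(active)] = theta_star
    lu, piv = scipy.linalg.lu_factor(x.T)
    w = scipy.linalg.lu_solve((lu, piv), y_target)
    return FixedPoint(
        weights=w,
        active_set=active,
        responses=x.T @ w,
        theta_star=theta_star,
        condition_number=float(np.linalg.cond(x)),
    )


def selective_fixed_point(ensemble: StimulusEnsemble, k: int) -> FixedPoint:
    """Selective equilibrium ``w* = N X^{-1} e_k`` (responds only to stimulus k)."""
    return general_fixed_point(ensemble, {k})


def finite_difference_jacobian(weights: np.ndarray, ensemble: StimulusEnsemble) -> np.ndarray:
    """Central-difference Jacobian of the summed drift, theta dependence included."""
    weights = np.asarray(weights, dtype=float)
    n = weights.size
    jac = np.empty((n, n))
    for i in range(n):
        h = FD_STEP * (1.0 + abs(weights[i]))
        e = np.zeros(n)
        e[i] = h
        jac[:, i] = (averaged_drift(weights + e, ensemble) - averaged_drift(weights - e, ensemble)) / (2 * h)
    return jac


def classify_stability(fp: FixedPoint, ensemble: StimulusEnsemble) -> str:
    """Label ``fp`` stable / unstable / marginal from the numerical Jacobian.

    Stable iff every eigenvalue real part is below ``-tol``, unstable iff any
    exceeds ``+tol``, marginal otherwise, with ``tol = 1e-7 * N`` (scaling
    with the Jacobian's natural magnitude).  The label is also stored on the
    fixed point.
    """
    jac = finite_difference_jacobian(fp.weights, ensemble)
    real_parts = np.linalg.eigvals(jac).real
    tol = STABILITY_TOL * ensemble.n_synapses
    if np.all(real_parts < -tol):
        label = "stable"
    elif np.any(real_parts > tol):
        label = "unstable"
    else:
        label = "marginal"
    fp.stability = label
    return label


def mixed_initial_condition(fp1: FixedPoint, fp2: FixedPoint, epsilon: float) -> np.ndarray:
    """Unequal mix ``(1 - eps) w1* + eps w2*`` of two fixed points.

    With a small eps the dynamics is prone to converge to fp1.  eps may
    range from 0 (fp1 exactly) to 0.5 (midpoint).
    """
    if not 0 <= epsilon <= 0.5:
        raise ValueError(f"epsilon must lie in [0, 0.5] (got {epsilon})")
    w1 = np.asarray(fp1.weights, dtype=float)
    w2 = np.asarray(fp2.weights, dtype=float)
    if w1.shape != w2.shape:
        raise ValueError("fixed points live in different weight spaces")
    return (1.0 - epsilon) * w1 + epsilon * w2


def enumerate_fixed_points(ensemble: StimulusEnsemble, classify: bool = True) -> list[FixedPoint]:
    """All 2^K equilibria of a small square ensemble, optionally classified.

    Brute-force lattice enumeration; intended for K <= ~12.
    """
    k = ensemble.n_stimuli
    if k > 16:
        raise ValueError(f"refusing to enumerate 2^{k} fixed points")
    fps = []
    for r in range(k + 1):
        for subset in combinations(range(k), r):
            fp = general_fixed_point(ensemble, subset)
            if classify:
                classify_stability(fp, ensemble)
            fps.append(fp)
    return fps


def fixed_point_report(fp: FixedPoint) -> dict:
    """JSON-ready summary of a fixed point."""
    return {
        "active_set": sorted(fp.active_set),
        "theta_star": float(fp.theta_star),
        "stability": fp.stability,
        "response_vector": [float(v) for v in fp.responses],
        "condition_number": float(fp.condition_number),
    }
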