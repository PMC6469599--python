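"""Circulant spectrum of the linearised BCM dynamics.

Near a selective fixed point the averaged dynamics linearise to
``tau_w dw/dt = J (w - w*)`` with ``J = -N X X``.  Because ``X`` is a
symmetric circulant matrix, its eigenvalues are the real cosine Fourier
coefficients of the profile row,

    a_m = sum_j f_j cos(2 pi j m / N),   m = -N/2+1 .. N/2,

and the Jacobian eigenvalues follow as ``lambda_m = -N a_m**2``.  The
eigenvalue of smallest magnitude (the critical eigenvalue) sets the slowest
relaxation time constant ``tau_crit = tau_w / |lambda_crit|``.

For smooth profiles the highest mode ``m = N/2`` dominates: its coefficient
is the alternating sum ``f_0 - 2 f_1 + 2 f_2 - ...`` — equivalently half the
sum of discrete second differences at odd offsets — which shrinks rapidly as
the profile is sampled more finely, producing the exponential slowdown.  For
non-smooth (triangular) profiles ``a_{N/2}`` does not decay with N and the
critical mode need not be ``N/2`` at all, so both ``lambda_crit`` and the
``m = N/2`` eigenvalue are reported separately.

The spectrum is computed from cosine sums of the profile, which is exact for
circulant matrices; dense diagonalisation of ``-N X X`` is used only as an
independent oracle in the tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .stimuli import StimulusEnsemble, StimulusProfile

__all__ = [
    "SpectralResult",
    "DegenerateModeError",
    "fourier_coefficients",
    "analytic_jacobian",
    "eigen_spectrum",
    "critical_timescale",
    "alternating_sum_check",
    "spectrum_to_csv",
]

#: |a_m| below this multiple of max_m |a_m| counts as a degenerate (zero) mode
DEGENERACY_TOL = 1e-12


class DegenerateModeError(ValueError):
    """The critical eigenvalue is numerically zero (singular ensemble)."""

    def __init__(self, mode: int):
        self.mode = mode
        super().__init__(
            f"Fourier mode m={mode} has a vanishing coefficient, so the "
            "critical eigenvalue is zero and no finite relaxation time "
            "exists (det X = 0)"
        )


@dataclass(frozen=True)
class SpectralResult:
    """Fourier coefficients, Jacobian eigenvalues, and the predicted timescale.

    ``eigenvalues[m] = -N a_m**2`` are in units of inverse sweeps scaled by
    ``tau_w`` (one sweep = K presentations).  ``lambda_half_mode`` is kept
    separately from ``lambda_crit`` because for non-smooth profiles the
    slowest mode need not be the highest one.
    """

    fourier_coeffs: dict[int, float]
    eigenvalues: dict[int, float]
    lambda_crit: float
    crit_mode: int
    lambda_half_mode: float
    tau_crit: float
    tau_w: float


def _check_profile(profile: StimulusProfile) -> np.ndarray:
    f = np.asarray(profile.values, dtype=float)
    n = f.size
    scale = max(1.0, float(np.max(np.abs(f))))
    if np.max(np.abs(f[1:] - f[::-1][:-1])) > 1e-12 * scale:
        raise ValueError(
            "profile is not symmetric (f_{N-j} != f_j); its Fourier "
            "coefficients would have imaginary parts"
        )
    if n % 2 != 0:
        raise ValueError("profile length N must be even")
    return f


def fourier_coefficients(profile: StimulusProfile) -> dict[int, float]:
    """Real cosine coefficients ``a_m`` for ``m = -N/2+1 .. N/2``.

    These are exactly the eigenvalues of the square circulant ensemble built
    from the profile; symmetry guarantees ``a_{-m} = a_m``.
    """
    f = _check_profile(profile)
    n = f.size
    j = np.arange(n)
    coeffs: dict[int, float] = {}
    for m in range(0, n // 2 + 1):
        a = float(np.sum(f * np.cos(2.0 * np.pi * j * m / n)))
        coeffs[m] = a
        if 0 < m < n // 2:
            coeffs[-m] = a
    return dict(sorted(coeffs.items()))


def analytic_jacobian(ensemble: StimulusEnsemble) -> np.ndarray:
    """Jacobian ``J = -N X X`` of the summed drift at a selective fixed point."""
    if not ensemble.is_square:
        raise ValueError(
            "the analytic Jacobian -N X X is defined for square (K = N) "
            f"ensembles only; got N={ensemble.n_synapses}, K={ensemble.n_stimuli}"
        )
    x = ensemble.matrix
    return -ensemble.n_synapses * (x @ x)


def eigen_spectrum(profile: StimulusProfile, tau_w: float = 1000.0) -> SpectralResult:
    """Full eigenvalue spectrum ``lambda_m = -N a_m**2`` and the critical mode.

    ``crit_mode`` is the mode of smallest ``|lambda_m|``; ties are broken
    toward the smallest non-negative m.
    """
    coeffs = fourier_coefficients(profile)
    n = profile.n_synapses
    eigs = {m: -n * a * a for m, a in coeffs.items()}
    crit_mode = 0
    best = abs(eigs[0])
    for m in range(1, n // 2 + 1):
        if abs(eigs[m]) < best:
            best = abs(eigs[m])
            crit_mode = m
    lambda_crit = eigs[crit_mode]
    lambda_half = eigs[n // 2]
    a_scale = max(abs(a) for a in coeffs.values())
    if abs(coeffs[crit_mode]) < DEGENERACY_TOL * max(a_scale, 1.0):
        tau_crit = np.inf
    else:
        tau_crit = tau_w / abs(lambda_crit)
    return SpectralResult(
        fourier_coeffs=coeffs,
        eigenvalues=eigs,
        lambda_crit=lambda_crit,
        crit_mode=crit_mode,
        lambda_half_mode=lambda_half,
        tau_crit=tau_crit,
        tau_w=tau_w,
    )


def critical_timescale(profile: StimulusProfile, tau_w: float = 1000.0) -> float:
    """Slowest relaxation time constant ``tau_crit = tau_w / |lambda_crit|``.

    Units: sweeps of the full stimulus set; multiply by K for presentation
    steps.  Raises :class:`DegenerateModeError` when the critical coefficient
    is numerically zero.
    """
    if tau_w <= 0:
        raise ValueError("tau_w must be positive")
    spec = eigen_spectrum(profile, tau_w)
    if not np.isfinite(spec.tau_crit):
        raise DegenerateModeError(spec.crit_mode)
    return spec.tau_crit


def alternating_sum_check(profile: StimulusProfile) -> dict[str, float]:
    """Compute ``a_{N/2}`` three equivalent ways.

    * ``a_half_direct`` — the cosine sum at m = N/2, i.e. sum_j (-1)^j f_j;
    * ``a_half_alternating`` — the explicit alternating sum
      ``f_0 - 2f_1 + 2f_2 - ... (+/-) 2f_{N/2-1} (-/+) f_{N/2}``;
    * ``odd_second_derivative_sum`` — half the sum of discrete second
      differences ``f''_i = f_{i-1} - 2f_i + f_{i+1}`` over odd offsets
      (indices mod N).

    The identities are algebraic; the smaller this quantity, the slower the
    highest mode relaxes.
    """
    f = _check_profile(profile)
    n = f.size
    half = n // 2
    j = np.arange(n)
    direct = float(np.sum(f * np.cos(np.pi * j)))

    alt = f[0] + (-1.0) ** half * f[half]
    for jj in range(1, half):
        alt += 2.0 * (-1.0) ** jj * f[jj]

    second = f[np.roll(j, 1)] - 2.0 * f + f[np.roll(j, -1)]
    odd_sum = 0.5 * float(np.sum(second[1::2]))
    return {
        "a_half_direct": direct,
        "a_half_alternating": float(alt),
        "odd_second_derivative_sum": odd_sum,
    }


def spectrum_to_csv(result: SpectralResult, path: str | Path) -> None:
    """Write ``m, a_m, lambda_m`` rows; summary JSON is the caller's concern."""
    path = Path(path)
    lines = ["m,a_m,lambda_m"]
    for m in sorted(result.fourier_coeffs):
        lines.append(f"{m},{result.fourier_coeffs[m]!r},{result.eigenvalues[m]!r}")
    path.write_text("\n".join(lines) + "\n")


def summary_dict(result: SpectralResult) -> dict[str, float | int]:
    """JSON-ready summary of the critical quantities."""
    return {
        "lambda_crit": result.lambda_crit,
        "crit_mode": result.crit_mode,
        "lambda_half_mode": result.lambda_half_mode,
        "tau_crit": result.tau_crit,
        "tau_w": result.tau_w,
    }
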