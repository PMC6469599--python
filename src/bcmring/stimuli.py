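"""Circulant stimulus ensembles on a ring of synapses.

A single model neuron receives input through ``N`` synapses arranged on a
ring.  Every stimulus is the same symmetric bump profile ``f`` centred at one
of ``K`` equi-spaced positions, so the full stimulus set is summarised by an
``N x K`` matrix ``X`` with entries ``X[i, k] = f(offset(i, c_k))``.  When
``K == N`` and the centres sit on the synapses, ``X`` is symmetric and
circulant — each row is the previous row rotated by one position — which is
what makes the learning dynamics analytically tractable (see
:mod:`bcmring.spectral`).

Two profile families are provided: a von Mises bump (smooth, the circular
analogue of a Gaussian) and a triangular bump (non-smooth).  The contrast
between them is the whole point of the analysis: smooth profiles have
vanishing high-frequency Fourier content, which stalls learning as ``N``
grows, while the triangular profile does not.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "StimulusProfile",
    "StimulusEnsemble",
    "EnsembleDiagnostics",
    "von_mises_profile",
    "triangular_profile",
    "delta_profile",
    "constant_profile",
    "build_ensemble",
    "ensemble_from_profile",
    "validate_ensemble",
    "save_ensemble",
    "load_ensemble",
]

#: sigma_min/sigma_max below this marks a square ensemble singular.  A
#: determinant-based measure would misfire here: det X is the product of all
#: Fourier coefficients and shrinks exponentially with N for smooth profiles
#: even while X stays comfortably invertible.
SINGULARITY_TOL = 1e-12

_SYMMETRY_TOL = 1e-12


def _check_even_n(n: int) -> None:
    if n < 4 or n % 2 != 0:
        raise ValueError(
            f"N must be an even integer >= 4 (got N={n}); the analysis "
            "requires the m = N/2 Fourier mode, which is undefined for odd N"
        )


def circular_distance(offsets: np.ndarray | float, n: int) -> np.ndarray:
    """Shortest distance on a ring of circumference ``n`` (real-valued)."""
    d = np.abs(np.asarray(offsets, dtype=float)) % n
    return np.minimum(d, n - d)


def _von_mises_values(offsets, n: int, omega: float) -> np.ndarray:
    # evaluate at the circular distance rather than the raw offset: cos makes
    # the two equivalent, but this way f_j == f_{N-j} holds bit-exactly and a
    # square ensemble equals the rolled profile vector exactly
    d = circular_distance(offsets, n)
    return np.exp((np.cos(2.0 * np.pi * d / n) - 1.0) / omega)


def _triangular_values(offsets, n: int, omega: float) -> np.ndarray:
    return np.maximum(1.0 - circular_distance(offsets, n) / (omega * n), 0.0)


def _delta_values(offsets, n: int, omega: float) -> np.ndarray:
    return (circular_distance(offsets, n) < 0.5 - 1e-9).astype(float)


def _constant_values(offsets, n: int, omega: float) -> np.ndarray:
    return np.ones_like(np.asarray(offsets, dtype=float))


_EVALUATORS = {
    "von_mises": _von_mises_values,
    "triangular": _triangular_values,
    "delta": _delta_values,
    "constant": _constant_values,
}


@dataclass(eq=False)
class StimulusProfile:
    """A symmetric activation profile sampled at the ``N`` integer offsets.

    ``values[j]`` is the input strength at circular offset ``j`` from the
    stimulus centre; symmetry ``values[N-j] == values[j]`` is required so the
    circulant stimulus matrix is symmetric and has a real cosine spectrum.
    """

    values: np.ndarray
    kind: str
    width: float
    n_synapses: int = field(init=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("profile values must be a 1-D vector")
        n = self.values.size
        _check_even_n(n)
        self.n_synapses = n
        if np.any(self.values < 0):
            raise ValueError("profile values must be non-negative")
        f0 = self.values[0]
        if f0 <= 0:
            raise ValueError("peak value f_0 must be positive")
        if f0 < self.values.max() - _SYMMETRY_TOL * max(1.0, self.values.max()):
            raise ValueError("profile must peak at zero offset (f_0 = max)")
        mirrored = self.values[::-1]
        scale = max(1.0, float(self.values.max()))
        if np.max(np.abs(self.values[1:] - mirrored[:-1])) > _SYMMETRY_TOL * scale:
            raise ValueError("profile must satisfy f_{N-j} = f_j (ring symmetry)")

    @property
    def n(self) -> int:
        return self.n_synapses


def von_mises_profile(n: int, omega: float) -> StimulusProfile:
    """Smooth periodic bump ``f_j = exp{[cos(2*pi*j/N) - 1]/omega}``.

    Parameters
    ----------
    n : even int >= 4
        Number of synapses on the ring.
    omega : float > 0
        Width parameter; larger ``omega`` gives a broader bump.
    """
    _check_even_n(n)
    if omega <= 0:
        raise ValueError(f"omega must be positive (got {omega})")
    return StimulusProfile(_von_mises_values(np.arange(n), n, omega), "von_mises", omega)


def triangular_profile(n: int, omega: float) -> StimulusProfile:
    """Triangular bump ``f_j = max(1 - d(j)/(omega*N), 0)`` on the ring.

    ``d(j) = min(j, N-j)`` is the circular offset distance, so the sampled
    vector is symmetric under ``j <-> N-j``.  Requires ``omega < 0.5`` so the
    support radius ``omega*N`` fits within half the ring without wrapping
    onto itself.
    """
    _check_even_n(n)
    if not 0 < omega < 0.5:
        raise ValueError(
            f"triangular width must satisfy 0 < omega < 0.5 (got {omega}); "
            "omega >= 0.5 would wrap the support onto itself"
        )
    return StimulusProfile(_triangular_values(np.arange(n), n, omega), "triangular", omega)


def delta_profile(n: int) -> StimulusProfile:
    """Unit pulse at zero offset; its circulant ensemble is the identity."""
    _check_even_n(n)
    return StimulusProfile(_delta_values(np.arange(n), n, 0.0), "delta", 0.0)


def constant_profile(n: int, level: float = 1.0) -> StimulusProfile:
    """Flat profile; its square ensemble is rank one (deliberately singular)."""
    _check_even_n(n)
    if level <= 0:
        raise ValueError("level must be positive")
    return StimulusProfile(np.full(n, float(level)), "constant", 0.0)


@dataclass(eq=False)
class StimulusEnsemble:
    """The ``N x K`` stimulus matrix ``X`` plus its generating profile.

    Column ``k`` is the profile centred at ``centers[k]``; centres are real
    positions on the ring ``[0, N)`` so over-complete ensembles (``K = 2N``)
    with half-integer centres are representable.  ``is_singular`` is set for
    square ensembles whose smallest singular value is negligible relative to
    the largest (numerically vanishing determinant).
    """

    matrix: np.ndarray
    profile: StimulusProfile
    centers: np.ndarray
    is_singular: bool | None = None

    def __post_init__(self) -> None:
        self.matrix = np.ascontiguousarray(self.matrix, dtype=float)
        self.centers = np.asarray(self.centers, dtype=float)
        if self.matrix.ndim != 2:
            raise ValueError("ensemble matrix must be 2-D")
        if self.centers.size != self.matrix.shape[1]:
            raise ValueError("one centre per stimulus column required")
        if self.is_singular is None and self.is_square:
            self.is_singular = _inverse_condition(self.matrix) < SINGULARITY_TOL

    @property
    def n_synapses(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_stimuli(self) -> int:
        return self.matrix.shape[1]

    @property
    def is_square(self) -> bool:
        return self.matrix.shape[0] == self.matrix.shape[1]


def _inverse_condition(x: np.ndarray) -> float:
    """sigma_min / sigma_max — a scale-free invertibility measure."""
    s = np.linalg.svd(x, compute_uv=False)
    if s[0] == 0.0:
        return 0.0
    return float(s[-1] / s[0])


def build_ensemble(profile_kind: str, n: int, k: int, omega: float) -> StimulusEnsemble:
    """Build the ``N x K`` ensemble of equi-spaced shifted profiles.

    Centres are ``c_k = k * N/K`` for ``k = 0 .. K-1``; for ``K = N`` and the
    delta/von Mises/triangular kinds this reproduces the symmetric circulant
    matrix exactly.  For ``K != N`` the profile formula is evaluated at real
    offsets (e.g. half-integer centres when ``K = 2N``).
    """
    _check_even_n(n)
    if k < 2:
        raise ValueError(f"need at least 2 stimuli (got K={k})")
    if profile_kind not in _EVALUATORS:
        raise ValueError(f"unknown profile kind {profile_kind!r}; choose from {sorted(_EVALUATORS)}")
    if profile_kind == "von_mises":
        profile = von_mises_profile(n, omega)
    elif profile_kind == "triangular":
        profile = triangular_profile(n, omega)
    elif profile_kind == "delta":
        profile = delta_profile(n)
    else:
        profile = constant_profile(n)
    evaluator = _EVALUATORS[profile_kind]
    centers = np.arange(k) * (n / k)
    offsets = np.arange(n)[:, None] - centers[None, :]
    matrix = evaluator(offsets, n, omega)
    return StimulusEnsemble(matrix, profile, centers)


def ensemble_from_profile(profile: StimulusProfile) -> StimulusEnsemble:
    """Square circulant ensemble obtained by rolling the sampled profile."""
    n = profile.n_synapses
    matrix = np.column_stack([np.roll(profile.values, shift) for shift in range(n)])
    return StimulusEnsemble(matrix, profile, np.arange(n, dtype=float))


@dataclass(frozen=True)
class EnsembleDiagnostics:
    """Pure-inspection report on an ensemble; never mutates its input."""

    is_symmetric: bool | None
    is_circulant: bool | None
    rank: int
    determinant: float | None
    inverse_condition: float | None
    condition_number: float
    column_norm_ratio: float
    is_singular: bool | None


def validate_ensemble(ensemble: StimulusEnsemble) -> EnsembleDiagnostics:
    """Check symmetry, circulant structure, rank and conditioning of ``X``."""
    x = ensemble.matrix
    norms = np.linalg.norm(x, axis=0)
    norm_ratio = float(norms.max() / norms.min()) if norms.min() > 0 else np.inf
    rank = int(np.linalg.matrix_rank(x))
    cond = float(np.linalg.cond(x))
    if ensemble.is_square:
        sym = bool(np.allclose(x, x.T, rtol=0, atol=1e-12 * max(1.0, x.max())))
        circ = all(
            np.allclose(x[:, j], np.roll(x[:, 0], j), rtol=0, atol=1e-12 * max(1.0, x.max()))
            for j in range(1, x.shape[1])
        )
        det = float(np.linalg.det(x))
        rel_det = _inverse_condition(x)
        singular = rel_det < SINGULARITY_TOL
    else:
        sym = circ = None
        det = rel_det = None
        singular = None
    return EnsembleDiagnostics(
        is_symmetric=sym,
        is_circulant=circ,
        rank=rank,
        determinant=det,
        inverse_condition=rel_det,
        condition_number=cond,
        column_norm_ratio=norm_ratio,
        is_singular=singular,
    )


def save_ensemble(ensemble: StimulusEnsemble, csv_path: str | Path) -> Path:
    """Write ``X`` as CSV (header row = centre positions) plus a JSON sidecar."""
    csv_path = Path(csv_path)
    header = ",".join(repr(float(c)) for c in ensemble.centers)
    np.savetxt(csv_path, ensemble.matrix, delimiter=",", header=header, comments="")
    sidecar = csv_path.with_suffix(".json")
    meta = {
        "kind": ensemble.profile.kind,
        "N": int(ensemble.n_synapses),
        "K": int(ensemble.n_stimuli),
        "omega": float(ensemble.profile.width),
    }
    sidecar.write_text(json.dumps(meta, indent=2))
    return sidecar


def load_ensemble(csv_path: str | Path) -> StimulusEnsemble:
    """Rebuild an ensemble from :func:`save_ensemble` output."""
    csv_path = Path(csv_path)
    meta = json.loads(csv_path.with_suffix(".json").read_text())
    with open(csv_path) as fh:
        centers = np.array([float(tok) for tok in fh.readline().split(",")])
    matrix = np.loadtxt(csv_path, delimiter=",", skiprows=1)
    if meta["kind"] in ("delta", "constant"):
        profile = delta_profile(meta["N"]) if meta["kind"] == "delta" else constant_profile(meta["N"])
    elif meta["kind"] == "von_mises":
        profile = von_mises_profile(meta["N"], meta["omega"])
    else:
        profile = triangular_profile(meta["N"], meta["omega"])
    return StimulusEnsemble(matrix, profile, centers)
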