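"""Effective-medium homogenization of crystallites in a non-absorbing matrix.

Given the (generally anisotropic, complex) permittivity tensor eps_i(nu) of
the crystal, the scalar matrix permittivity eps_e, the inclusion shape L and
the volume fraction f, three mixing rules produce an isotropic effective
permittivity per frequency:

Maxwell-Garnett
    eps_mg = eps_e + n <alpha> / (1 - n <alpha L> / eps_e)

    with the inclusion polarizability (volume V, number density n = f/V)

    alpha = V eps_e (eps_i - eps_e 1)(eps_e 1 + L (eps_i - eps_e 1))^-1

    and exact uniform-orientation averages <alpha> = tr(alpha)/3,
    <alpha L> = tr(alpha L)/3.

Bruggeman
    Both phases are polarized against the effective medium itself; the
    orientation-averaged self-consistency condition

    sum_i f_i < (eps_i - eps_br 1)(eps_br 1 + L (eps_i - eps_br 1))^-1 > = 0

    is solved per frequency by fixed-point iteration, seeded with the
    Maxwell-Garnett value at the first grid point and with the previous
    frequency's solution thereafter.  Both phases share one depolarization
    tensor, a known approximation of the symmetric rule.

Averaged permittivity (AP)
    eps_ap = f tr(eps_i)/3 + (1 - f) eps_e -- no shape effects; its peaks
    sit at the TO frequencies and serve as the internal-field-free baseline.

Bruggeman solutions can be unphysical (negative absorption) in regimes of
strong contrast; such frequencies are flagged, never silently returned.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .shape_geometry import DepolarizationTensor

_I3 = np.eye(3)

#: Relative-change convergence tolerance of the Bruggeman iteration.
BRUGGEMAN_TOL = 1.0e-8
#: Iteration cap per frequency.
BRUGGEMAN_MAX_ITER = 1000
#: Tolerated negative imaginary part before a frequency is flagged.
PASSIVITY_TOL = 1.0e-10

METHODS = ("maxwell", "bruggeman", "ap")


class SingularMixtureError(ZeroDivisionError):
    """A lossless resonance made a mixing denominator exactly singular."""


@dataclass
class MixingScenario:
    """One homogenization request.

    method              : 'maxwell', 'bruggeman' or 'ap'
    volume_fraction     : f in (0, 1)
    matrix_permittivity : real scalar eps_e >= 1, constant over the grid
    shape               : depolarization tensor of the inclusions
    crystal_volume      : unit-cell volume V of the crystal, A^3
    """

    method: str
    volume_fraction: float
    matrix_permittivity: float
    shape: DepolarizationTensor
    crystal_volume: float

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"unknown mixing method {self.method!r}")
        if not 0.0 < self.volume_fraction < 1.0:
            raise ValueError("volume fraction must lie in (0, 1)")
        if self.matrix_permittivity < 1.0:
            raise ValueError("matrix permittivity must be >= 1")
        if self.crystal_volume <= 0:
            raise ValueError("crystal volume must be positive")

    @property
    def number_density(self) -> float:
        """Inclusion number density n = f / V, A^-3."""
        return self.volume_fraction / self.crystal_volume


@dataclass
class EffectivePermittivity:
    """Per-frequency scalar effective permittivity with diagnostics."""

    values: np.ndarray
    converged: np.ndarray = field(default=None)
    passive: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=complex)
        if self.converged is None:
            self.converged = np.ones(self.values.shape, dtype=bool)
        if self.passive is None:
            self.passive = self.values.imag >= -PASSIVITY_TOL


def polarizability(eps_i: np.ndarray, eps_e: float, L: np.ndarray, volume: float) -> np.ndarray:
    """Polarizability tensor of one ellipsoidal inclusion (crystal frame)."""
    contrast = np.asarray(eps_i, dtype=complex) - eps_e * _I3
    denom = eps_e * _I3 + L @ contrast
    try:
        inv = np.linalg.inv(denom)
    except np.linalg.LinAlgError as exc:
        raise SingularMixtureError(
            "singular shape denominator (lossless resonance); use sigma > 0"
        ) from exc
    return volume * eps_e * contrast @ inv


def orientational_average(alpha: np.ndarray, L: np.ndarray) -> tuple[complex, complex]:
    """Exact uniform-rotation averages <alpha> and <alpha L> (scalars).

    For tensors that co-rotate with the particle, the isotropic average of
    R T R^T over the rotation group is tr(T)/3 times the identity; applied
    to alpha and to the product alpha L.
    """
    return (
        complex(np.trace(alpha)) / 3.0,
        complex(np.trace(alpha @ L)) / 3.0,
    )


def maxwell_garnett(scenario: MixingScenario, eps_i_grid: np.ndarray) -> EffectivePermittivity:
    """Maxwell-Garnett effective permittivity over a frequency grid."""
    eps_e = scenario.matrix_permittivity
    L = scenario.shape.tensor
    n = scenario.number_density
    v = scenario.crystal_volume
    out = np.empty(len(eps_i_grid), dtype=complex)
    for j, eps_i in enumerate(eps_i_grid):
        alpha = polarizability(eps_i, eps_e, L, v)
        a_mean, al_mean = orientational_average(alpha, L)
        denom = 1.0 - n * al_mean / eps_e
        if denom == 0:
            raise SingularMixtureError(
                "Maxwell-Garnett denominator vanished; use sigma > 0"
            )
        out[j] = eps_e + n * a_mean / denom
    return EffectivePermittivity(values=out)


def _bruggeman_step(eps_br: complex, phases, L: np.ndarray) -> complex:
    """One fixed-point update of the symmetric rule."""
    num = 0.0 + 0.0j
    den = 0.0 + 0.0j
    for eps, frac in phases:
        m = np.linalg.inv(eps_br * _I3 + L @ (eps - eps_br * _I3))
        num += frac * np.trace(eps @ m) / 3.0
        den += frac * np.trace(m) / 3.0
    return num / den


def _iterate_bruggeman(seed: complex, phases, L: np.ndarray) -> tuple[complex, bool]:
    eps = seed
    for _ in range(BRUGGEMAN_MAX_ITER):
        new = _bruggeman_step(eps, phases, L)
        if abs(new - eps) <= BRUGGEMAN_TOL * max(abs(new), 1.0e-300):
            return new, True
        eps = new
    return eps, False


def bruggeman(scenario: MixingScenario, eps_i_grid: np.ndarray) -> EffectivePermittivity:
    """Bruggeman effective permittivity over a frequency grid.

    Non-convergence and passivity violations are recorded per frequency in
    the returned flags.  A frequency that converges to a negative-absorption
    root is retried from the Maxwell-Garnett seed before being flagged.
    """
    eps_e = scenario.matrix_permittivity
    f = scenario.volume_fraction
    L = scenario.shape.tensor
    mg = maxwell_garnett(scenario, eps_i_grid)
    out = np.empty(len(eps_i_grid), dtype=complex)
    converged = np.ones(len(eps_i_grid), dtype=bool)
    prev = mg.values[0]
    for j, eps_i in enumerate(eps_i_grid):
        phases = (
            (np.asarray(eps_i, dtype=complex), f),
            ((eps_e + 0.0j) * _I3, 1.0 - f),
        )
        value, ok = _iterate_bruggeman(prev, phases, L)
        if value.imag < -PASSIVITY_TOL:
            value, ok = _iterate_bruggeman(mg.values[j], phases, L)
        out[j] = value
        converged[j] = ok
        prev = value
    return EffectivePermittivity(values=out, converged=converged)


def averaged_permittivity(scenario: MixingScenario, eps_i_grid: np.ndarray) -> EffectivePermittivity:
    """Shape-free volume-weighted average of the permittivities."""
    f = scenario.volume_fraction
    traces = np.trace(np.asarray(eps_i_grid, dtype=complex), axis1=1, axis2=2) / 3.0
    return EffectivePermittivity(
        values=f * traces + (1.0 - f) * scenario.matrix_permittivity
    )


_DISPATCH = {
    "maxwell": maxwell_garnett,
    "bruggeman": bruggeman,
    "ap": averaged_permittivity,
}


def effective_permittivity(scenario: MixingScenario, eps_i_grid: np.ndarray) -> EffectivePermittivity:
    """Dispatch on ``scenario.method``."""
    return _DISPATCH[scenario.method](scenario, eps_i_grid)
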