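"""Lorentz-oscillator dielectric model built from Born charges and phonons.

The complex permittivity tensor of an insulating crystal is written as a sum
over damped Lorentz oscillators centred at the transverse-optic (TO) phonon
frequencies:

    eps(nu) = eps_inf + (gamma / V) * sum_k S_k / (nu_k^2 - nu^2 - i sigma_k nu)

where S_k is the 3x3 oscillator-strength tensor of mode k in (D/A)^2/amu,
V the cell volume in A^3, frequencies in cm^-1 and gamma the unit bridge of
:mod:`powderspec.units`.  The strength tensor is the outer product of the
mode charge vector

    Zbar_k = sum_a Z_a . U_ka / sqrt(m_a)

with itself; the 1/sqrt(m_a) undoes the mass weighting of the eigenvector so
that Zbar_k is the dipole derivative with respect to the mode coordinate, and
keeps the convention consistent with the longitudinal-optic (LO) correction
below.  The trace of S_k is the mode's infrared intensity.

LO frequencies follow from the long-wavelength non-analytic correction to
the mass-weighted dynamical matrix for an approach direction q:

    D_LO[s a, t b] = D[s a, t b]
        + (gamma' / V) (q^T Z_s)_a (q^T Z_t)_b / (sqrt(M_s M_t) q^T eps_inf q)

with gamma' = gamma * e^2->(D/A)^2 so that the same unit system pins both
the permittivity and the LO shift.  The denominator uses the optical
permittivity, which is what reduces the single-oscillator isotropic limit to
the Lyddane-Sachs-Teller relation nu_LO = nu_TO sqrt(eps_static/eps_inf).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .phonon_data import PhononData, reconstruct_dynamical_matrix
from .units import E2_TO_DA2, PERMITTIVITY_FACTOR

#: Modes below this |frequency| (cm^-1) are treated as translational noise
#: and excluded from the dielectric sum.
LOW_FREQUENCY_CUTOFF = 5.0

#: Default damping (FWHM-like) parameter, cm^-1.
DEFAULT_SIGMA = 5.0


class SingularityError(ZeroDivisionError):
    """Undamped oscillator evaluated exactly at resonance."""


@dataclass
class Oscillator:
    """A single Lorentz oscillator.

    frequency : TO wavenumber, cm^-1 (negative marks an imaginary mode)
    strength  : 3x3 symmetric PSD tensor, (D/A)^2/amu
    sigma     : damping, cm^-1
    degeneracy: multiplicity used for molecular-route intensities
    active    : whether the oscillator enters the dielectric sum
    """

    frequency: float
    strength: np.ndarray
    sigma: float = DEFAULT_SIGMA
    degeneracy: int = 1
    active: bool = True

    def __post_init__(self) -> None:
        self.strength = np.asarray(self.strength, dtype=float)

    @property
    def intensity(self) -> float:
        """IR intensity = trace of the strength tensor, (D/A)^2/amu."""
        return float(np.trace(self.strength))


@dataclass
class DielectricModel:
    """Optical permittivity plus oscillators: the machine yielding eps(nu)."""

    epsilon_inf: np.ndarray
    oscillators: list[Oscillator]
    cell_volume: float
    name: str = ""

    def __post_init__(self) -> None:
        self.epsilon_inf = np.asarray(self.epsilon_inf, dtype=float)
        if self.cell_volume <= 0:
            raise ValueError("cell_volume must be positive")

    def active_oscillators(self) -> list[Oscillator]:
        return [o for o in self.oscillators if o.active]


def oscillator_strengths(
    data: PhononData, sigma: float = DEFAULT_SIGMA
) -> list[Oscillator]:
    """One oscillator per phonon mode, from Born charges and eigenvectors.

    Modes with |nu| < 5 cm^-1 (translations, numerical zeros) are returned
    flagged inactive rather than dropped, so 1-based mode numbering is
    stable against the file contents.
    """
    inv_sqrt_m = 1.0 / np.sqrt(data.masses)
    born = np.array([a.born_charge for a in data.atoms])  # (N, 3, 3)
    oscillators = []
    for k, nu in enumerate(data.frequencies):
        disp = data.eigenvectors[k].reshape(-1, 3) * inv_sqrt_m[:, np.newaxis]
        z_k = np.einsum("aij,aj->i", born, disp)  # e / sqrt(amu)
        strength = np.outer(z_k, z_k) * E2_TO_DA2
        oscillators.append(
            Oscillator(
                frequency=float(nu),
                strength=strength,
                sigma=sigma,
                active=abs(nu) >= LOW_FREQUENCY_CUTOFF,
            )
        )
    return oscillators


def dielectric_model_from_phonons(
    data: PhononData, sigma: float = DEFAULT_SIGMA, name: str = ""
) -> DielectricModel:
    """Convenience wrapper: PhononData -> DielectricModel."""
    return DielectricModel(
        epsilon_inf=data.optical_permittivity,
        oscillators=oscillator_strengths(data, sigma=sigma),
        cell_volume=data.cell.volume,
        name=name,
    )


def permittivity(model: DielectricModel, grid) -> np.ndarray:
    """Complex permittivity tensor eps(nu) on a wavenumber grid.

    Returns an array of shape (len(grid), 3, 3).  Raises
    :class:`SingularityError` when an undamped oscillator coincides with a
    grid point (the damping sigma must be positive for a finite response).
    """
    grid = np.asarray(grid, dtype=float)
    eps = np.broadcast_to(
        model.epsilon_inf.astype(complex), (grid.size, 3, 3)
    ).copy()
    scale = PERMITTIVITY_FACTOR / model.cell_volume
    for osc in model.active_oscillators():
        denom = osc.frequency**2 - grid**2 - 1j * osc.sigma * grid
        if np.any(denom == 0):
            raise SingularityError(
                f"grid hits undamped resonance at {osc.frequency} cm^-1; "
                "use sigma > 0"
            )
        eps += scale * osc.strength[np.newaxis, :, :] / denom[:, np.newaxis, np.newaxis]
    return eps


def lo_frequencies(data: PhononData, q_direction) -> np.ndarray:
    """Mode frequencies after the non-analytic LO correction along (h k l).

    The direction is a wave-vector: it is resolved through the reciprocal
    lattice.  Returns all 3N corrected frequencies sorted ascending, with
    negative values marking imaginary modes.
    """
    hkl = np.asarray(q_direction, dtype=float)
    if np.allclose(hkl, 0):
        raise ValueError("q direction must be non-zero")
    q = hkl @ data.cell.reciprocal_vectors
    q_hat = q / np.linalg.norm(q)

    eps_inf = data.optical_permittivity
    screening = float(q_hat @ eps_inf @ q_hat)
    born = np.array([a.born_charge for a in data.atoms])
    # (q^T Z_a): charge component along q per Cartesian displacement, in e.
    qz = np.einsum("i,aij->aj", q_hat, born)  # (N, 3)
    weighted = qz / np.sqrt(data.masses)[:, np.newaxis]
    vec = weighted.reshape(-1)  # (3N,)
    correction = (
        PERMITTIVITY_FACTOR
        * E2_TO_DA2
        / (data.cell.volume * screening)
        * np.outer(vec, vec)
    )
    d_lo = reconstruct_dynamical_matrix(data) + correction
    lam = np.linalg.eigvalsh(d_lo)
    return np.sort(np.sign(lam) * np.sqrt(np.abs(lam)))


def apply_mode_controls(
    oscillators: list[Oscillator],
    ignore=(),
    only=None,
    sigma: float | None = None,
    mode_sigma: dict[int, float] | None = None,
) -> list[Oscillator]:
    """Apply user mode selections and damping overrides (1-based indices).

    ``sigma`` sets a global damping first; ``mode_sigma`` then overrides
    individual modes.  ``only`` restricts the active set to the listed modes;
    ``ignore`` deactivates modes.  Automatic deactivation of near-zero modes
    is preserved regardless of selection.
    """
    n = len(oscillators)

    def check(indices):
        for k in indices:
            if not 1 <= k <= n:
                raise IndexError(f"mode index {k} outside 1..{n}")

    check(ignore)
    if only is not None:
        check(only)
    if mode_sigma:
        check(mode_sigma.keys())

    result = []
    for i, osc in enumerate(oscillators, start=1):
        new = replace(osc, strength=osc.strength.copy())
        if sigma is not None:
            new.sigma = sigma
        if mode_sigma and i in mode_sigma:
            new.sigma = mode_sigma[i]
        if abs(new.frequency) < LOW_FREQUENCY_CUTOFF:
            new.active = False
        elif only is not None:
            new.active = i in only and i not in ignore
        elif i in ignore:
            new.active = False
        result.append(new)
    return result


def static_permittivity(model: DielectricModel) -> np.ndarray:
    """Zero-frequency (static) permittivity tensor, real part."""
    return permittivity(model, np.array([0.0]))[0].real
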