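"""From permittivities to absorption spectra (solid-state and molecular routes).

Solid-state route: the scalar effective permittivity gives the complex
refractive index N = n + i kappa with N^2 = eps and the branch kappa >= 0;
the decadic absorption coefficient is alpha = 4 pi nu kappa log10(e) (cm^-1)
and the molar absorption coefficient a = alpha / C, where the concentration
of unit cells C = f * 1000 / (V * 1e-24 * N_A) mol/L includes the volume
fraction f of crystallites.

Molecular route: each transition of intensity I_k carries an integrated
molar absorption coefficient A_k = 4225.6 g_k I_k (L mol^-1 cm^-2 with I in
(D/A)^2/amu, constant derived in :mod:`powderspec.units`); a Lorentzian of
FWHM sigma_k normalized to integrate to A_k gives the band profile with peak
height 2 A_k / (pi sigma_k).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .effective_medium import MixingScenario, effective_permittivity
from .oscillator_model import DielectricModel, permittivity
from .units import AVOGADRO, LOG10_E, MOLAR_ABSORPTION_FACTOR


@dataclass
class SpectralGrid:
    """Inclusive wavenumber grid [v_min, v_max] with a fixed increment."""

    v_min: float = 0.0
    v_max: float = 300.0
    increment: float = 0.2

    def __post_init__(self) -> None:
        if self.v_min > self.v_max:
            raise ValueError("v_min must not exceed v_max")
        if self.increment <= 0:
            raise ValueError("increment must be positive")

    @property
    def values(self) -> np.ndarray:
        # Endpoint included when it falls within half a step of v_max.
        count = int(np.floor((self.v_max - self.v_min) / self.increment + 0.5)) + 1
        return self.v_min + self.increment * np.arange(count)


@dataclass
class MolecularBand:
    """One molecular transition as a normalized Lorentzian band."""

    a_integrated: float  # A_k, L mol^-1 cm^-2
    frequency: float  # cm^-1
    sigma: float  # FWHM, cm^-1
    degeneracy: int = 1

    def __post_init__(self) -> None:
        if self.a_integrated < 0:
            raise ValueError("integrated absorption must be non-negative")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")

    def profile(self, grid: np.ndarray) -> np.ndarray:
        """a_k(nu): Lorentzian integrating to A_k, peak 2A_k/(pi sigma)."""
        return (
            2.0
            * self.a_integrated
            / np.pi
            * self.sigma
            / (4.0 * (grid - self.frequency) ** 2 + self.sigma**2)
        )


@dataclass
class SpectrumTable:
    """Per-frequency results of one homogenization scenario."""

    frequencies: np.ndarray
    eps_eff: np.ndarray
    absorption: np.ndarray  # alpha, cm^-1
    molar_absorption: np.ndarray  # a, L mol^-1 cm^-1
    concentration: float  # C, mol/L
    description: str = ""
    converged: np.ndarray = field(default=None)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "frequency_cm-1": self.frequencies,
                "eps_real": self.eps_eff.real,
                "eps_imag": self.eps_eff.imag,
                "absorption_cm-1": self.absorption,
                "molar_absorption_L_mol-1_cm-1": self.molar_absorption,
            }
        )


def refractive_index(eps_eff) -> np.ndarray:
    """Complex refractive index N = sqrt(eps) on the kappa >= 0 branch."""
    n = np.sqrt(np.asarray(eps_eff, dtype=complex))
    return np.where(n.imag < 0, -n, n)


def absorption_coefficient(nu, kappa) -> np.ndarray:
    """Decadic absorption coefficient alpha = 4 pi nu kappa log10(e), cm^-1."""
    return 4.0 * np.pi * np.asarray(nu) * np.asarray(kappa) * LOG10_E


def concentration(volume_fraction: float, cell_volume: float) -> float:
    """Moles of unit cells per litre: C = f * 1000 / (V * 1e-24 * N_A)."""
    if not 0.0 < volume_fraction <= 1.0:
        raise ValueError("volume fraction must lie in (0, 1]")
    if cell_volume <= 0:
        raise ValueError("cell volume must be positive")
    return volume_fraction * 1000.0 / (cell_volume * 1.0e-24 * AVOGADRO)


def integrated_molar_absorption(intensity: float, degeneracy: int = 1) -> float:
    """A_k (L mol^-1 cm^-2) from an intensity in (D/A)^2/amu."""
    if intensity < 0:
        raise ValueError("intensity must be non-negative")
    return MOLAR_ABSORPTION_FACTOR * degeneracy * intensity


def molecular_spectrum(
    bands: list[MolecularBand], grid: SpectralGrid, conc: float
) -> tuple[np.ndarray, np.ndarray]:
    """Total molar absorption a(nu) and absorption alpha(nu) = C a(nu)."""
    values = grid.values
    a = np.zeros_like(values)
    for band in bands:
        a += band.profile(values)
    return a, conc * a


def powder_spectrum(
    model: DielectricModel, scenario: MixingScenario, grid: SpectralGrid
) -> SpectrumTable:
    """Full pipeline: oscillators -> eps_eff -> refractive index -> spectra."""
    values = grid.values
    eps_i = permittivity(model, values)
    eff = effective_permittivity(scenario, eps_i)
    n_complex = refractive_index(eff.values)
    alpha = absorption_coefficient(values, n_complex.imag)
    conc = concentration(scenario.volume_fraction, scenario.crystal_volume)
    return SpectrumTable(
        frequencies=values,
        eps_eff=eff.values,
        absorption=alpha,
        molar_absorption=alpha / conc,
        concentration=conc,
        description=scenario.method,
        converged=eff.converged,
    )


def peak_position(x: np.ndarray, y: np.ndarray) -> float:
    """Location of the global maximum, refined by quadratic interpolation."""
    i = int(np.argmax(y))
    if i == 0 or i == len(y) - 1:
        return float(x[i])
    denom = y[i - 1] - 2.0 * y[i] + y[i + 1]
    if denom == 0:
        return float(x[i])
    shift = 0.5 * (y[i - 1] - y[i + 1]) / denom
    return float(x[i] + shift * (x[i + 1] - x[i]))


def peak_positions(x: np.ndarray, y: np.ndarray, min_fraction: float = 0.01) -> list[float]:
    """All local maxima above min_fraction of the global maximum, refined."""
    from scipy.signal import find_peaks

    idx, _ = find_peaks(y, height=min_fraction * float(np.max(y)))
    peaks = []
    for i in idx:
        lo = max(i - 1, 0)
        hi = min(i + 2, len(y))
        window = slice(lo, hi)
        peaks.append(peak_position(x[window], y[window]))
    return peaks
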