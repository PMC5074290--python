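"""Unit conventions and derived conversion constants.

Spectroscopic units are used throughout the package: mode frequencies are
wavenumbers in cm^-1, unit-cell volumes are in Angstrom^3, mode intensities
(traces of oscillator-strength tensors) are in (D/A)^2/amu and Born effective
charges are in units of the elementary charge e.

Two bridge constants tie these units together:

``PERMITTIVITY_FACTOR`` (gamma)
    The dimensionless permittivity contributed by a Lorentz oscillator of
    intensity I [(D/A)^2/amu] in a cell of volume V [A^3] at wavenumber
    offset nu [cm^-1] is gamma * I / (V * nu^2).  It is the "4 pi / V" of the
    Gaussian-units oscillator sum once the spectroscopic units above are
    adopted.

``E_TO_DEBYE_PER_ANGSTROM``
    The elementary charge expressed in Debye per Angstrom; its square
    converts an intensity in e^2/amu (natural when built from Born charges)
    to (D/A)^2/amu.

``MOLAR_ABSORPTION_FACTOR``
    Integrated molar absorption coefficient, in L mol^-1 cm^-2, of a
    non-degenerate transition of unit intensity (1 (D/A)^2/amu); equivalently
    42.256 km/mol per unit intensity.

All values are derived from CODATA constants at import time, never typed in
as literals.
"""

from __future__ import annotations

import math

from scipy import constants as _codata

#: Speed of light in cm/s (CGS value used by the oscillator algebra).
SPEED_OF_LIGHT_CM: float = _codata.c * 1.0e2

#: Avogadro's number, mol^-1.
AVOGADRO: float = _codata.N_A

#: Atomic mass unit in grams.
ATOMIC_MASS_G: float = _codata.atomic_mass * 1.0e3

# 1 Debye = 1e-18 esu cm, so 1 D/A = 1e-10 esu; (D/A)^2 = 1e-20 esu^2.
_DEBYE_PER_ANGSTROM_ESU = 1.0e-10

#: Elementary charge in D/A (e in esu divided by 1e-10 esu).
E_TO_DEBYE_PER_ANGSTROM: float = (_codata.e * _codata.c * 10.0) / _DEBYE_PER_ANGSTROM_ESU

#: e^2 -> (D/A)^2 conversion for intensities per amu.
E2_TO_DA2: float = E_TO_DEBYE_PER_ANGSTROM**2

#: gamma: permittivity per unit [intensity / (volume * wavenumber^2)].
PERMITTIVITY_FACTOR: float = (
    4.0
    * math.pi
    * (_DEBYE_PER_ANGSTROM_ESU**2 / ATOMIC_MASS_G)
    / ((2.0 * math.pi * SPEED_OF_LIGHT_CM) ** 2 * 1.0e-24)
)

#: A_k per unit intensity and degeneracy, L mol^-1 cm^-2.
MOLAR_ABSORPTION_FACTOR: float = (
    AVOGADRO
    * math.pi
    / (3000.0 * SPEED_OF_LIGHT_CM**2)
    * (_DEBYE_PER_ANGSTROM_ESU**2 / ATOMIC_MASS_G)
)

#: log10(e): decadic Beer-Lambert conversion.
LOG10_E: float = math.log10(math.e)
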