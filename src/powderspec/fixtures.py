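"""Synthetic crystals and tabulated oscillator models.

Two kinds of inputs make every stage of the pipeline testable without any
external lattice-dynamics calculation:

* :func:`make_toy_crystal` builds a random but physically valid
  :class:`~powderspec.phonon_data.PhononData`: orthonormal mass-weighted
  eigenvectors, three exact translational (zero-frequency) modes, Born
  charges obeying the acoustic sum rule (they sum to the zero tensor, so the
  translations carry no oscillator strength) and an optionally anisotropic
  optical permittivity.  Deterministic under its seed.

* :class:`OscillatorTableModel` captures the reduced description that
  published work tabulates for benchmark materials -- cell parameters, the
  diagonal optical permittivity, and per-band TO frequency / intensity /
  symmetry label -- and :func:`from_oscillator_table` rebuilds a diagonal
  :class:`~powderspec.oscillator_model.DielectricModel` from it.
  :func:`reference_models` transcribes published tables for MgO, ZnO,
  calcite, fluoroapatite and L-aspartic acid (the last two are partial:
  only selected transitions were published).

Degenerate-band convention: an E (doubly degenerate) band contributes its
printed intensity on *each* of the two axes perpendicular to the unique
axis, one oscillator per partner; a T (triply degenerate) band likewise on
all three axes.  The alternative reading (printed intensity shared across
partners) is available via ``shared_degenerate=True`` for sensitivity
checks, but the per-partner convention is the one that reproduces the
published static permittivities and powder peak shifts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .oscillator_model import DEFAULT_SIGMA, DielectricModel, Oscillator
from .phonon_data import Atom, CrystalCell, PhononData, write_phonon_data
from .units import E2_TO_DA2


def _orthonormal_with_translations(masses: np.ndarray, rng) -> np.ndarray:
    """Orthonormal (3N, 3N) basis whose first three rows are translations."""
    n = len(masses)
    sqrt_m = np.sqrt(masses)
    trans = np.zeros((3, 3 * n))
    for axis in range(3):
        trans[axis, axis::3] = sqrt_m
        trans[axis] /= np.linalg.norm(trans[axis])
    random = rng.standard_normal((3 * n, 3 * n))
    # Project translations out, then orthonormalize the remainder.
    proj = random - random @ trans.T @ trans
    q, _ = np.linalg.qr(proj.T)
    optic = q.T[: 3 * n - 3]
    return np.vstack([trans, optic])


def make_toy_crystal(
    n_atoms: int = 2,
    seed: int = 0,
    permittivity_kind: str = "isotropic",
    degenerate_pair: bool = False,
    path=None,
) -> PhononData:
    """Random valid phonon data for an n_atoms crystal.

    permittivity_kind: 'isotropic', 'uniaxial' or 'monoclinic' (symmetric
    with an xz off-diagonal element).  If ``path`` is given the canonical
    file is also written there.
    """
    if n_atoms < 2:
        raise ValueError("need at least two atoms")
    rng = np.random.default_rng(seed)

    a = 4.0 + 2.0 * rng.random()
    if permittivity_kind == "monoclinic":
        cell = CrystalCell.from_parameters(a, 1.1 * a, 0.9 * a, 90.0, 105.0, 90.0)
    else:
        cell = CrystalCell(np.diag([a, a, 1.2 * a]))

    masses = rng.uniform(1.0, 50.0, size=n_atoms)
    born = rng.normal(0.0, 1.5, size=(n_atoms, 3, 3))
    born -= born.mean(axis=0)  # acoustic sum rule
    atoms = [
        Atom(label=f"X{i + 1}", mass=float(masses[i]), born_charge=born[i])
        for i in range(n_atoms)
    ]

    eigenvectors = _orthonormal_with_translations(masses, rng)
    optic = np.sort(rng.uniform(50.0, 1200.0, size=3 * n_atoms - 3))
    if degenerate_pair and len(optic) >= 2:
        optic[1] = optic[0]
    frequencies = np.concatenate([np.zeros(3), optic])

    if permittivity_kind == "isotropic":
        eps_inf = (1.5 + rng.random()) * np.eye(3)
    elif permittivity_kind == "uniaxial":
        p, q = 1.5 + rng.random(), 2.0 + rng.random()
        eps_inf = np.diag([p, p, q])
    elif permittivity_kind == "monoclinic":
        d = 1.5 + rng.random(3)
        eps_inf = np.diag(d)
        off = 0.2 * rng.random()
        eps_inf[0, 2] = eps_inf[2, 0] = off
    else:
        raise ValueError(f"unknown permittivity_kind {permittivity_kind!r}")

    data = PhononData(
        cell=cell,
        atoms=atoms,
        frequencies=frequencies,
        eigenvectors=eigenvectors,
        optical_permittivity=eps_inf,
    )
    if path is not None:
        write_phonon_data(data, path)
    return data


def diatomic_ionic_crystal(
    nu_to: float,
    intensity: float,
    eps_inf: float,
    cell: CrystalCell,
    masses: tuple[float, float],
    labels: tuple[str, str] = ("A", "B"),
) -> PhononData:
    """Two-atom cubic ionic crystal with a triply degenerate TO mode.

    The Born charge +/- Z_B is chosen so each of the three optic modes has
    the requested intensity ((D/A)^2/amu): Z_B = sqrt(I_e2 * mu) with mu the
    reduced mass and I_e2 the intensity in e^2/amu.  Useful for building a
    synthetic crystal that matches a published single-oscillator model and
    for Lyddane-Sachs-Teller checks.
    """
    m1, m2 = masses
    mu = m1 * m2 / (m1 + m2)
    z_b = np.sqrt(intensity / E2_TO_DA2 * mu)
    total = m1 + m2
    atoms = [
        Atom(label=labels[0], mass=m1, born_charge=z_b * np.eye(3)),
        Atom(label=labels[1], mass=m2, born_charge=-z_b * np.eye(3)),
    ]
    eigenvectors = np.zeros((6, 6))
    for axis in range(3):
        # translation
        eigenvectors[axis, axis] = np.sqrt(m1 / total)
        eigenvectors[axis, 3 + axis] = np.sqrt(m2 / total)
        # optic partner
        eigenvectors[3 + axis, axis] = np.sqrt(m2 / total)
        eigenvectors[3 + axis, 3 + axis] = -np.sqrt(m1 / total)
    frequencies = np.array([0.0, 0.0, 0.0, nu_to, nu_to, nu_to])
    return PhononData(
        cell=cell,
        atoms=atoms,
        frequencies=frequencies,
        eigenvectors=eigenvectors,
        optical_permittivity=eps_inf * np.eye(3),
    )


@dataclass
class OscillatorTableModel:
    """Published reduced description of a crystal's IR response.

    bands: list of (symmetry label, TO frequency cm^-1, intensity
    (D/A)^2/amu).  Labels: 'A' non-degenerate along the unique (z) axis,
    'E' doubly degenerate in the perpendicular (xy) plane, 'T' triply
    degenerate, 'I' no directional information (spread isotropically).
    """

    name: str
    lengths: tuple[float, float, float]
    angles: tuple[float, float, float]
    epsilon_inf: tuple[float, float, float]
    bands: list[tuple[str, float, float]]
    partial: bool = False
    notes: str = ""

    @property
    def cell(self) -> CrystalCell:
        return CrystalCell.from_parameters(*self.lengths, *self.angles)


_BAND_AXES = {
    "A": ((0, 0, 1),),
    "E": ((1, 0, 0), (0, 1, 0)),
    "T": ((1, 0, 0), (0, 1, 0), (0, 0, 1)),
}


def from_oscillator_table(
    model: OscillatorTableModel,
    sigma: float = DEFAULT_SIGMA,
    shared_degenerate: bool = False,
) -> DielectricModel:
    """Rebuild a diagonal dielectric model from a published band table.

    The crystal frame has z along the unique axis.  Each degenerate partner
    carries the printed intensity (see module docstring); with
    ``shared_degenerate=True`` the printed intensity is split equally over
    the partners instead.
    """
    oscillators = []
    for label, nu, intensity in model.bands:
        if intensity < 0:
            raise ValueError(f"{model.name}: negative intensity for band at {nu}")
        if label == "I":
            strength = (intensity / 3.0) * np.eye(3)
            oscillators.append(Oscillator(frequency=nu, strength=strength, sigma=sigma))
            continue
        axes = _BAND_AXES[label]
        per_partner = intensity / len(axes) if shared_degenerate else intensity
        for axis in axes:
            strength = per_partner * np.outer(axis, axis).astype(float)
            oscillators.append(Oscillator(frequency=nu, strength=strength, sigma=sigma))
    return DielectricModel(
        epsilon_inf=np.diag(model.epsilon_inf),
        oscillators=oscillators,
        cell_volume=model.cell.volume,
        name=model.name,
    )


def reference_models() -> dict[str, OscillatorTableModel]:
    """Published oscillator tables for the five benchmark materials.

    Cell settings are chosen so the metric tensor reproduces the published
    primitive-cell volume: MgO is the primitive rhombohedral setting of the
    face-centred cubic cell (conventional edge 2 x 2.1234 A, so the
    primitive lengths are 2.1234*sqrt(2) with 60 degree angles); ZnO and
    fluoroapatite are hexagonal; calcite is rhombohedral; aspartic acid is
    monoclinic.  Fluoroapatite and aspartic acid are partial transcriptions
    (only selected transitions were published), good for qualitative and
    smoke tests only.
    """
    a_mgo = 2.1234 * np.sqrt(2.0)
    return {
        "mgo": OscillatorTableModel(
            name="MgO",
            lengths=(a_mgo, a_mgo, a_mgo),
            angles=(60.0, 60.0, 60.0),
            epsilon_inf=(3.14, 3.14, 3.14),
            bands=[("T", 388.3, 9.29)],
            notes="cubic Fm-3m, primitive fcc setting",
        ),
        "zno": OscillatorTableModel(
            name="ZnO",
            lengths=(3.295, 3.295, 5.285),
            angles=(90.0, 90.0, 120.0),
            epsilon_inf=(5.09, 5.09, 6.0),
            bands=[("A", 350.0, 17.1), ("E", 372.1, 16.4)],
            notes="wurtzite P6_3mc, unique axis c",
        ),
        "calcite": OscillatorTableModel(
            name="calcite",
            lengths=(6.376, 6.376, 6.376),
            angles=(46.0, 46.0, 46.0),
            epsilon_inf=(1.91, 1.91, 2.0),
            bands=[
                ("E", 114.8, 2.39),
                ("A", 127.4, 3.36),
                ("A", 249.3, 1.23),
                ("E", 320.7, 5.82),
                ("A", 338.1, 4.14),
                ("E", 620.1, 3.38),
                ("A", 732.0, 26.89),
                ("E", 1463.6, 16.97),
            ],
            notes="R-3c primitive rhombohedral cell; unique axis = 3-fold axis",
        ),
        "fluoroapatite": OscillatorTableModel(
            name="fluoroapatite",
            lengths=(9.447, 9.447, 6.926),
            angles=(90.0, 90.0, 120.0),
            epsilon_inf=(2.891, 2.891, 2.894),
            bands=[
                ("A", 981.8, 112.6),
                ("E", 986.3, 101.0),
                ("E", 1038.1, 7.92),
            ],
            partial=True,
            notes="P6_3/m; only the three highest-frequency bands tabulated",
        ),
        "aspartic_acid": OscillatorTableModel(
            name="L-aspartic acid",
            lengths=(7.597, 7.028, 5.113),
            angles=(90.0, 98.77, 90.0),
            epsilon_inf=(2.68, 2.20, 2.56),
            bands=[
                ("I", 84.5, 0.120),
                ("I", 104.7, 0.202),
                ("I", 106.0, 0.243),
                ("I", 115.3, 0.474),
                ("I", 137.3, 0.617),
                ("I", 1290.0, 55.0),
                ("I", 2945.9, 102.8),
                ("I", 2947.3, 48.2),
                ("I", 3053.7, 44.1),
            ],
            partial=True,
            notes=(
                "P2_1 monoclinic; published bands carry no directional "
                "information, so intensities are spread isotropically -- "
                "smoke tests only"
            ),
        ),
    }


def mgo_crystal() -> PhononData:
    """Synthetic two-atom crystal equivalent to the MgO oscillator table.

    Primitive fcc cell of the conventional cube (edge 4.2468 A), masses of
    Mg and O, isotropic Born charges fitted to the published TO intensity.
    """
    a = 2.0 * 2.1234
    lattice = 0.5 * a * np.array([[0.0, 1.0, 1.0], [1.0, 0.0, 1.0], [1.0, 1.0, 0.0]])
    return diatomic_ionic_crystal(
        nu_to=388.3,
        intensity=9.29,
        eps_inf=3.14,
        cell=CrystalCell(lattice),
        masses=(24.305, 15.999),
        labels=("Mg", "O"),
    )
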