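"""Canonical phonon-data model: crystal cell, atoms, modes, and file I/O.

The package consumes a single text format (YAML-based, versioned header
``powderspec-phonon v1``) holding everything a gamma-point lattice-dynamics
calculation provides: lattice vectors, atomic masses, Born effective charge
tensors, mode frequencies, mass-weighted eigenvectors and the optical
(high-frequency) permittivity tensor.  Code-specific output dialects are
deliberately not parsed; converters can target this schema instead.

Conventions
-----------
* Lattice vectors are rows of a 3x3 matrix, in Angstrom.
* Frequencies are in cm^-1; imaginary (unstable) modes are encoded as
  negative numbers and carried through.
* Eigenvectors are those of the mass-weighted dynamical matrix: dimensionless
  and orthonormal.  The physical displacement of atom a in mode k is
  proportional to U_ka / sqrt(m_a).  Files holding Cartesian-displacement
  eigenvectors declare ``eigenvector_convention: cartesian`` and are
  converted (and re-normalized) at read time.
* Reciprocal vectors use the 2*pi convention; only their directions are
  observable downstream (plane normals), so the convention is neutral.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

FORMAT_HEADER = "powderspec-phonon v1"

#: Tolerance for eigenvector orthonormality validation.
ORTHONORMALITY_TOL = 1.0e-6


class PhononFileError(ValueError):
    """Raised when a phonon file cannot be parsed or violates the schema."""


class PhononValidationError(ValueError):
    """Raised when numeric content violates a physical invariant."""


@dataclass
class CrystalCell:
    """Unit cell defined by its lattice vectors (rows, Angstrom)."""

    lattice_vectors: np.ndarray

    def __post_init__(self) -> None:
        self.lattice_vectors = np.asarray(self.lattice_vectors, dtype=float)
        if self.lattice_vectors.shape != (3, 3):
            raise PhononValidationError("lattice_vectors must be 3x3")
        if self.volume <= 0:
            raise PhononValidationError("cell volume must be positive")

    @classmethod
    def from_parameters(
        cls, a: float, b: float, c: float, alpha: float, beta: float, gamma: float
    ) -> "CrystalCell":
        """Build a cell from lengths (Angstrom) and angles (degrees).

        Standard orientation: a1 along x, a2 in the xy plane.
        """
        ca, cb, cg = (np.cos(np.radians(x)) for x in (alpha, beta, gamma))
        sg = np.sin(np.radians(gamma))
        vterm = 1.0 - ca * ca - cb * cb - cg * cg + 2.0 * ca * cb * cg
        if vterm <= 0:
            raise PhononValidationError("cell angles do not define a valid cell")
        vec = np.array(
            [
                [a, 0.0, 0.0],
                [b * cg, b * sg, 0.0],
                [c * cb, c * (ca - cb * cg) / sg, c * np.sqrt(vterm) / sg],
            ]
        )
        return cls(vec)

    @property
    def volume(self) -> float:
        """Cell volume |a1 . (a2 x a3)| in Angstrom^3."""
        return abs(float(np.linalg.det(self.lattice_vectors)))

    @property
    def reciprocal_vectors(self) -> np.ndarray:
        """Reciprocal lattice vectors (rows, 2*pi convention, A^-1)."""
        return 2.0 * np.pi * np.linalg.inv(self.lattice_vectors).T


@dataclass
class Atom:
    """An atom: label, mass (amu) and 3x3 Born effective charge tensor (e)."""

    label: str
    mass: float
    born_charge: np.ndarray

    def __post_init__(self) -> None:
        self.born_charge = np.asarray(self.born_charge, dtype=float)
        if self.mass <= 0:
            raise PhononValidationError(f"atom {self.label}: mass must be positive")
        if self.born_charge.shape != (3, 3):
            raise PhononValidationError(f"atom {self.label}: born_charge must be 3x3")


@dataclass
class PhononData:
    """Full gamma-point phonon description of one crystal.

    ``eigenvectors`` is a (3N, 3N) array whose k-th row is the mass-weighted
    eigenvector of mode k; components are grouped per atom (x, y, z).
    """

    cell: CrystalCell
    atoms: list[Atom]
    frequencies: np.ndarray
    eigenvectors: np.ndarray
    optical_permittivity: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.eigenvectors = np.asarray(self.eigenvectors, dtype=float)
        self.optical_permittivity = np.asarray(self.optical_permittivity, dtype=float)
        self.validate()

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def masses(self) -> np.ndarray:
        return np.array([a.mass for a in self.atoms])

    def validate(self) -> None:
        n3 = 3 * self.n_atoms
        if self.frequencies.shape != (n3,):
            raise PhononFileError(
                f"expected {n3} frequencies for {self.n_atoms} atoms, "
                f"got {self.frequencies.shape}"
            )
        if self.eigenvectors.shape != (n3, n3):
            raise PhononFileError(
                f"expected eigenvectors of shape ({n3}, {n3}), "
                f"got {self.eigenvectors.shape}"
            )
        for name, arr in (
            ("frequencies", self.frequencies),
            ("eigenvectors", self.eigenvectors),
            ("optical_permittivity", self.optical_permittivity),
        ):
            if not np.all(np.isfinite(arr)):
                raise PhononValidationError(f"{name} contains non-finite values")
        gram = self.eigenvectors @ self.eigenvectors.T
        if not np.allclose(gram, np.eye(n3), atol=ORTHONORMALITY_TOL):
            dev = float(np.max(np.abs(gram - np.eye(n3))))
            raise PhononValidationError(
                f"eigenvectors not orthonormal (max deviation {dev:.2e})"
            )
        eps = self.optical_permittivity
        if eps.shape != (3, 3):
            raise PhononValidationError("optical_permittivity must be 3x3")
        if not np.allclose(eps, eps.T, atol=1.0e-8):
            raise PhononValidationError("optical_permittivity must be symmetric")
        if np.any(np.diag(eps) < 1.0):
            raise PhononValidationError(
                "optical_permittivity diagonal must be >= 1 (electronic screening)"
            )


def read_phonon_data(path) -> PhononData:
    """Read and validate a canonical phonon file.

    The format is YAML (comments and blank lines are therefore free), with
    a mandatory ``format: powderspec-phonon v1`` key.
    """
    with open(path) as handle:
        try:
            doc = yaml.safe_load(handle)
        except yaml.YAMLError as exc:
            raise PhononFileError(f"{path}: cannot parse: {exc}") from exc
    if not isinstance(doc, dict):
        raise PhononFileError(f"{path}: top level must be a mapping")
    header = doc.get("format")
    if header != FORMAT_HEADER:
        raise PhononFileError(
            f"{path}: missing or unsupported format header {header!r} "
            f"(expected {FORMAT_HEADER!r})"
        )
    for key in ("lattice_vectors", "atoms", "frequencies", "eigenvectors",
                "optical_permittivity"):
        if key not in doc:
            raise PhononFileError(f"{path}: missing required field '{key}'")

    cell = CrystalCell(np.array(doc["lattice_vectors"], dtype=float))
    atoms = []
    for i, entry in enumerate(doc["atoms"]):
        try:
            atoms.append(
                Atom(
                    label=str(entry["label"]),
                    mass=float(entry["mass"]),
                    born_charge=np.array(entry["born_charge"], dtype=float),
                )
            )
        except (KeyError, TypeError) as exc:
            raise PhononFileError(f"{path}: atoms[{i}]: {exc}") from exc

    eigenvectors = np.array(doc["eigenvectors"], dtype=float)
    convention = doc.get("eigenvector_convention", "mass_weighted")
    if convention == "cartesian":
        # Cartesian displacement rows: re-weight by sqrt(mass) and normalize.
        weights = np.repeat(np.sqrt([a.mass for a in atoms]), 3)
        eigenvectors = eigenvectors * weights[np.newaxis, :]
        norms = np.linalg.norm(eigenvectors, axis=1)
        if np.any(norms == 0):
            raise PhononFileError(f"{path}: zero eigenvector after mass weighting")
        eigenvectors = eigenvectors / norms[:, np.newaxis]
    elif convention != "mass_weighted":
        raise PhononFileError(
            f"{path}: unknown eigenvector_convention {convention!r}"
        )

    return PhononData(
        cell=cell,
        atoms=atoms,
        frequencies=np.array(doc["frequencies"], dtype=float),
        eigenvectors=eigenvectors,
        optical_permittivity=np.array(doc["optical_permittivity"], dtype=float),
        meta={k: v for k, v in doc.items() if k.startswith("x_")},
    )


def write_phonon_data(data: PhononData, path) -> None:
    """Write a validated :class:`PhononData` to the canonical format.

    Numbers are emitted at full double precision so that a read/write round
    trip is an identity to 1e-12 (in practice bit-exact).
    """
    data.validate()
    doc = {
        "format": FORMAT_HEADER,
        "eigenvector_convention": "mass_weighted",
        "lattice_vectors": data.cell.lattice_vectors.tolist(),
        "atoms": [
            {
                "label": a.label,
                "mass": float(a.mass),
                "born_charge": a.born_charge.tolist(),
            }
            for a in data.atoms
        ],
        "optical_permittivity": data.optical_permittivity.tolist(),
        "frequencies": data.frequencies.tolist(),
        "eigenvectors": data.eigenvectors.tolist(),
    }
    doc.update(data.meta)
    with open(path, "w") as handle:
        yaml.safe_dump(doc, handle, sort_keys=False, default_flow_style=None)


def reconstruct_dynamical_matrix(data: PhononData) -> np.ndarray:
    """Rebuild the mass-weighted dynamical matrix D = U^T diag(L) U (cm^-2).

    Eigenvalues are signed squared frequencies: a mode stored with a negative
    (imaginary) frequency contributes a negative eigenvalue, so instabilities
    survive the round trip.
    """
    nu = data.frequencies
    lam = np.sign(nu) * nu**2
    u = data.eigenvectors  # rows are eigenvectors
    return u.T @ (lam[:, np.newaxis] * u)
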