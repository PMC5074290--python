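"""Particle morphology: unique axes and depolarization tensors.

A small inclusion interacts with the radiation field through its shape,
encoded in the symmetric, unit-trace depolarization tensor L.  Supported
morphologies are the spheroids used in powder work:

    sphere     L = 1/3 (V1 V1^T + V2 V2^T + V3 V3^T)
    plate/slab L = V1 V1^T
    needle     L = 1/2 (V2 V2^T + V3 V3^T)
    ellipsoid  L = a V1 V1^T + b V2 V2^T + b V3 V3^T

V1 is the unique direction; for needles and ellipsoids it is the direct
lattice direction [hkl], for plates the normal to the (hkl) plane, i.e. the
reciprocal-lattice vector h b1 + k b2 + l b3 (for non-orthogonal cells these
differ).  The ellipsoid is a spheroid with aspect ratio z = unique-axis
length / perpendicular-axis length; z > 1 is prolate, z < 1 oblate, z = 1 a
sphere.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .phonon_data import CrystalCell

KINDS = ("sphere", "plate", "needle", "ellipsoid")


@dataclass
class ShapeSpec:
    """Morphology request: kind, crystallographic axis, aspect ratio."""

    kind: str
    hkl: tuple[int, int, int] = (0, 0, 1)
    z_ratio: float = 1.0

    def __post_init__(self) -> None:
        if self.kind == "slab":  # synonym used in the field
            self.kind = "plate"
        if self.kind not in KINDS:
            raise ValueError(f"unknown shape kind {self.kind!r}")
        if self.kind != "sphere" and all(h == 0 for h in self.hkl):
            raise ValueError("hkl must be non-zero for oriented shapes")
        if self.z_ratio <= 0:
            raise ValueError("z_ratio must be positive")

    def describe(self) -> str:
        if self.kind == "sphere":
            return "sphere"
        s = f"{self.kind} {self.hkl[0]} {self.hkl[1]} {self.hkl[2]}"
        if self.kind == "ellipsoid":
            s += f" z={self.z_ratio:g}"
        return s


@dataclass
class DepolarizationTensor:
    """Depolarization tensor with the axes it was built in."""

    tensor: np.ndarray
    axes: np.ndarray  # rows V1, V2, V3

    def __post_init__(self) -> None:
        self.tensor = np.asarray(self.tensor, dtype=float)
        self.axes = np.asarray(self.axes, dtype=float)


def _complete_axes(v1: np.ndarray) -> np.ndarray:
    """Deterministic orthonormal completion of a unit vector.

    Pivot on the smallest-magnitude component of v1 so the result is
    reproducible; downstream observables are provably independent of the
    choice.
    """
    pivot = int(np.argmin(np.abs(v1)))
    e = np.zeros(3)
    e[pivot] = 1.0
    v2 = e - (e @ v1) * v1
    v2 /= np.linalg.norm(v2)
    v3 = np.cross(v1, v2)
    return np.vstack([v1, v2, v3])


def unique_axis(cell: CrystalCell, spec: ShapeSpec) -> np.ndarray:
    """Cartesian orthonormal axes (rows) with V1 the unique direction.

    Needle and ellipsoid axes are direct-lattice directions [hkl]; the plate
    axis is the (hkl) plane normal from the reciprocal lattice.
    """
    h = np.asarray(spec.hkl, dtype=float)
    if spec.kind == "sphere":
        return np.eye(3)
    if spec.kind == "plate":
        v1 = h @ cell.reciprocal_vectors
    else:
        v1 = h @ cell.lattice_vectors
    norm = np.linalg.norm(v1)
    if norm == 0:
        raise ValueError(f"direction {spec.hkl} maps to the zero vector")
    return _complete_axes(v1 / norm)


def ellipsoid_depolarization_factors(z: float) -> tuple[float, float]:
    """Depolarization factors (a, b, b) of a spheroid with aspect ratio z.

    Continuous through z = 1 (sphere, a = b = 1/3).
    """
    if z <= 0:
        raise ValueError("aspect ratio must be positive")
    if abs(z - 1.0) < 1.0e-8:
        return 1.0 / 3.0, 1.0 / 3.0
    if z > 1.0:  # prolate
        e = np.sqrt(1.0 - z**-2)
        a = ((1.0 - e**2) / (2.0 * e**3)) * (np.log((1.0 + e) / (1.0 - e)) - 2.0 * e)
    else:  # oblate
        e = np.sqrt(z**-2 - 1.0)
        a = ((1.0 + e**2) / e**3) * (e - np.arctan(e))
    return a, 0.5 * (1.0 - a)


def depolarization(spec: ShapeSpec, axes: np.ndarray | None = None) -> DepolarizationTensor:
    """Build the depolarization tensor for a shape in the given axes.

    ``axes`` defaults to the laboratory frame (rows of the identity); use
    :func:`unique_axis` to orient a shape crystallographically.
    """
    if axes is None:
        axes = np.eye(3)
    axes = np.asarray(axes, dtype=float)
    v1, v2, v3 = axes
    p1, p2, p3 = (np.outer(v, v) for v in (v1, v2, v3))
    if spec.kind == "sphere":
        tensor = (p1 + p2 + p3) / 3.0
    elif spec.kind == "plate":
        tensor = p1
    elif spec.kind == "needle":
        tensor = 0.5 * (p2 + p3)
    else:
        a, b = ellipsoid_depolarization_factors(spec.z_ratio)
        tensor = a * p1 + b * (p2 + p3)
    return DepolarizationTensor(tensor=tensor, axes=axes)
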