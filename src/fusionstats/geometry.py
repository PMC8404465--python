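"""Spherical egg geometry.

The mouse egg is modelled as a sphere (radius ~36.6 µm) whose maternal
chromosomes sit a fixed depth (~5 µm) beneath the plasma membrane, on the
"chromosome axis" through the egg center. Every downstream statistic is a
function of the axis angle θ — the angle, measured at the egg center,
between the chromosome direction and a point on the egg surface — or of the
3D chord distance from the chromosome point to that surface point.

All lengths are in µm and all angles in degrees unless stated otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "EggModel",
    "AngularBinning",
    "DistanceBinning",
    "DegenerateGeometryError",
    "angle_to_chromosome_axis",
    "chord_distance_to_chromosomes",
    "arc_distance_to_chromosomes",
    "angle_from_chord_distance",
    "band_area_fraction",
    "project_to_sphere",
]

#: strict relative radial tolerance for simulated points
SIM_RADIAL_TOL = 1e-6
#: loose relative radial tolerance for measured (tracked) points
MEASURED_RADIAL_TOL = 0.10


class DegenerateGeometryError(ValueError):
    """Raised when a point coincides with the egg center or the geometry
    is otherwise undefined."""


@dataclass(frozen=True, eq=False)
class EggModel:
    """Spherical egg with maternal chromosomes beneath the surface.

    Parameters
    ----------
    radius : float
        Egg radius R in µm (default 36.6).
    chromosome_depth : float
        Depth d of maternal chromosomes beneath the plasma membrane in µm
        (default 5.0). The chromosome point is at distance R - d from the
        center along ``chromosome_direction``.
    center : array-like of shape (3,)
        Egg center in µm.
    chromosome_direction : array-like of shape (3,)
        Unit vector from the center toward the maternal chromosomes.
    """

    radius: float = 36.6
    chromosome_depth: float = 5.0
    center: np.ndarray = field(default_factory=lambda: np.zeros(3))
    chromosome_direction: np.ndarray = field(
        default_factory=lambda: np.array([0.0, 0.0, 1.0])
    )

    def __post_init__(self) -> None:
        object.__setattr__(self, "center", np.asarray(self.center, dtype=float))
        d = np.asarray(self.chromosome_direction, dtype=float)
        norm = np.linalg.norm(d)
        if not np.isfinite(norm) or abs(norm - 1.0) > 1e-6:
            if norm <= 0 or not np.isfinite(norm):
                raise ValueError("chromosome_direction must be a nonzero vector")
            d = d / norm
        object.__setattr__(self, "chromosome_direction", d)
        if not self.radius > 0:
            raise ValueError(f"radius must be positive, got {self.radius}")
        if not 0 < self.chromosome_depth < self.radius:
            raise ValueError(
                "chromosome_depth must lie strictly between 0 and the radius"
            )

    def __eq__(self, other) -> bool:
        if not isinstance(other, EggModel):
            return NotImplemented
        return (
            self.radius == other.radius
            and self.chromosome_depth == other.chromosome_depth
            and np.array_equal(self.center, other.center)
            and np.array_equal(self.chromosome_direction, other.chromosome_direction)
        )

    __hash__ = None

    @property
    def chromosome_point(self) -> np.ndarray:
        """Position of the maternal chromosomes (strictly inside the egg)."""
        return self.center + (self.radius - self.chromosome_depth) * self.chromosome_direction

    def surface_point(self, theta_deg: float, phi_deg: float = 0.0) -> np.ndarray:
        """Surface point at axis angle ``theta_deg`` and azimuth ``phi_deg``.

        The azimuth is measured about the chromosome axis; any orthonormal
        completion of the axis is valid because every statistic here is
        rotationally symmetric about it.
        """
        theta = np.deg2rad(theta_deg)
        phi = np.deg2rad(phi_deg)
        e1, e2 = _orthonormal_complement(self.chromosome_direction)
        u = (
            np.cos(theta) * self.chromosome_direction
            + np.sin(theta) * (np.cos(phi) * e1 + np.sin(phi) * e2)
        )
        return self.center + self.radius * u

    def to_dict(self) -> dict:
        return {
            "center": self.center.tolist(),
            "radius_um": self.radius,
            "chromosome_depth_um": self.chromosome_depth,
            "chromosome_direction": self.chromosome_direction.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EggModel":
        return cls(
            radius=float(d["radius_um"]),
            chromosome_depth=float(d["chromosome_depth_um"]),
            center=np.asarray(d.get("center", [0.0, 0.0, 0.0]), dtype=float),
            chromosome_direction=np.asarray(
                d.get("chromosome_direction", [0.0, 0.0, 1.0]), dtype=float
            ),
        )


def _orthonormal_complement(axis: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two unit vectors orthogonal to ``axis`` and to each other."""
    helper = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(helper, axis)) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(axis, helper)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(axis, e1)
    return e1, e2


def project_to_sphere(
    position: np.ndarray, egg: EggModel, rel_tol: float = MEASURED_RADIAL_TOL
) -> np.ndarray:
    """Radially project a measured point onto the egg sphere.

    Measured fusion sites sit only approximately on the membrane; points
    within ``rel_tol`` relative radial error are snapped onto the sphere,
    anything further off is rejected.

    Raises
    ------
    DegenerateGeometryError
        If the point coincides with the egg center.
    ValueError
        If the radial error exceeds ``rel_tol``.
    """
    v = np.asarray(position, dtype=float) - egg.center
    r = np.linalg.norm(v)
    if r == 0:
        raise DegenerateGeometryError("point coincides with the egg center")
    if abs(r - egg.radius) / egg.radius > rel_tol:
        raise ValueError(
            f"point at radius {r:.3f} µm deviates more than {rel_tol:.0%} "
            f"from the egg radius {egg.radius} µm"
        )
    return egg.center + egg.radius * v / r


def angle_to_chromosome_axis(position: np.ndarray, egg: EggModel) -> float:
    """Axis angle θ in degrees, in [0, 180].

    The angle at the egg center between the chromosome direction and the
    direction to ``position``. Rotationally symmetric about the axis.
    """
    v = np.asarray(position, dtype=float) - egg.center
    r = np.linalg.norm(v)
    if r == 0:
        raise DegenerateGeometryError("point coincides with the egg center")
    c = np.clip(np.dot(v, egg.chromosome_direction) / r, -1.0, 1.0)
    return float(np.degrees(np.arccos(c)))


def angles_to_chromosome_axis(positions: np.ndarray, egg: EggModel) -> np.ndarray:
    """Vectorized :func:`angle_to_chromosome_axis` over an (n, 3) array."""
    v = np.asarray(positions, dtype=float) - egg.center
    r = np.linalg.norm(v, axis=1)
    if np.any(r == 0):
        raise DegenerateGeometryError("a point coincides with the egg center")
    c = np.clip(v @ egg.chromosome_direction / r, -1.0, 1.0)
    return np.degrees(np.arccos(c))


def chord_distance_to_chromosomes(theta_deg, egg: EggModel):
    """3D (chord) distance from the chromosome point to the surface point
    at axis angle θ, by the law of cosines: sqrt(R² + r² − 2Rr cosθ) with
    r = R − d. Strictly monotone increasing in θ for d < R."""
    theta_deg = np.asarray(theta_deg, dtype=float)
    if np.any(theta_deg < 0) or np.any(theta_deg > 180):
        raise ValueError("axis angle must lie in [0, 180] degrees")
    R = egg.radius
    r = R - egg.chromosome_depth
    theta = np.deg2rad(theta_deg)
    out = np.sqrt(R**2 + r**2 - 2 * R * r * np.cos(theta))
    return float(out) if out.ndim == 0 else out


def arc_distance_to_chromosomes(theta_deg, egg: EggModel):
    """Great-circle arc length R·θ from the surface pole above the
    chromosomes to the surface point at axis angle θ. Provided as the
    alternative distance convention; chord distance is the default."""
    theta_deg = np.asarray(theta_deg, dtype=float)
    if np.any(theta_deg < 0) or np.any(theta_deg > 180):
        raise ValueError("axis angle must lie in [0, 180] degrees")
    out = egg.radius * np.deg2rad(theta_deg)
    return float(out) if out.ndim == 0 else out


def angle_from_chord_distance(distance, egg: EggModel):
    """Inverse of :func:`chord_distance_to_chromosomes` (degrees)."""
    distance = np.asarray(distance, dtype=float)
    R = egg.radius
    r = R - egg.chromosome_depth
    c = (R**2 + r**2 - distance**2) / (2 * R * r)
    if np.any(c < -1 - 1e-12) or np.any(c > 1 + 1e-12):
        raise ValueError("distance outside the geometric range [d, 2R-d]")
    out = np.degrees(np.arccos(np.clip(c, -1.0, 1.0)))
    return float(out) if out.ndim == 0 else out


def band_area_fraction(theta1_deg: float, theta2_deg: float) -> float:
    """Fraction of the sphere's surface between axis angles θ1 and θ2.

    Equal to (cos θ1 − cos θ2)/2; fractions over a partition of [0, 180]
    sum to 1 exactly.
    """
    if not (0 <= theta1_deg < theta2_deg <= 180):
        raise ValueError("require 0 <= theta1 < theta2 <= 180")
    return float(
        (np.cos(np.deg2rad(theta1_deg)) - np.cos(np.deg2rad(theta2_deg))) / 2.0
    )


@dataclass(frozen=True)
class _Binning:
    edges: np.ndarray

    def __post_init__(self) -> None:
        e = np.asarray(self.edges, dtype=float)
        if e.ndim != 1 or len(e) < 2:
            raise ValueError("need at least two bin edges")
        if np.any(np.diff(e) <= 0):
            raise ValueError("bin edges must be strictly increasing")
        object.__setattr__(self, "edges", e)

    @property
    def n_bins(self) -> int:
        return len(self.edges) - 1

    @property
    def labels(self) -> list[str]:
        return [
            f"{lo:g}-{hi:g}" for lo, hi in zip(self.edges[:-1], self.edges[1:])
        ]

    def assign(self, values) -> np.ndarray:
        """Bin index per value. Bins are half-open [lo, hi) with the final
        bin closed, so the domain endpoint is never dropped."""
        values = np.asarray(values, dtype=float)
        if np.any(values < self.edges[0]) or np.any(values > self.edges[-1]):
            raise ValueError("value outside binning domain")
        idx = np.searchsorted(self.edges, values, side="right") - 1
        return np.minimum(idx, self.n_bins - 1)

    def count(self, values) -> np.ndarray:
        return np.bincount(self.assign(values), minlength=self.n_bins)


@dataclass(frozen=True)
class AngularBinning(_Binning):
    """Axis-angle bins in degrees; default 30° bins spanning [0, 180]."""

    edges: np.ndarray = field(
        default_factory=lambda: np.arange(0.0, 181.0, 30.0)
    )

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.edges[0] != 0.0 or self.edges[-1] != 180.0:
            raise ValueError("angular bin edges must span [0, 180] degrees")

    def area_fractions(self) -> np.ndarray:
        """Analytic sphere-surface area fraction of each band."""
        return np.array(
            [
                band_area_fraction(lo, hi)
                for lo, hi in zip(self.edges[:-1], self.edges[1:])
            ]
        )


@dataclass(frozen=True)
class DistanceBinning(_Binning):
    """Chord-distance bins in µm; default 10-µm bins covering the full
    geometric range of the default egg (chord distance spans [d, 2R−d])."""

    edges: np.ndarray = field(
        default_factory=lambda: np.arange(0.0, 80.0, 10.0)
    )

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.edges[0] < 0:
            raise ValueError("distance bin edges must be non-negative")
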