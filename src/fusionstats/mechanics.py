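"""Zona pellucida mechanics and porosity analysis.

The microneedle assay applies cycles of compressive force to the zona
pellucida; the force is the force-sensing needle's tip deflection ΔX times
its precalibrated stiffness kf (12.2 nN/µm in the reference setup), and the
local zona stiffness is the linear-regression slope of force on the zona
deformation ΔD. The porosity assay scans dextran fluorescence along the
zona circumference; the scan is normalized by its mean and its variation
reported as a coefficient of variation in percent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "ForceDeformationSeries",
    "StiffnessEstimate",
    "IntensityProfile",
    "PorosityResult",
    "deflection_to_force",
    "estimate_stiffness",
    "porosity_variation",
]

#: precalibrated force-sensing needle stiffness, nN/µm
DEFAULT_NEEDLE_STIFFNESS = 12.2


@dataclass(frozen=True)
class ForceDeformationSeries:
    """Compression cycles at one cardinal point of the zona pellucida.

    ``deflections`` are the needle-tip displacements ΔX (µm) and
    ``deformations`` the zona deformations ΔD (µm), one entry per cycle.
    """

    deflections: np.ndarray
    deformations: np.ndarray
    needle_stiffness: float = DEFAULT_NEEDLE_STIFFNESS
    cardinal_point_deg: int = 0

    def __post_init__(self) -> None:
        dx = np.asarray(self.deflections, dtype=float)
        dd = np.asarray(self.deformations, dtype=float)
        if dx.shape != dd.shape or dx.ndim != 1:
            raise ValueError("deflections and deformations must be 1D and equal length")
        if np.any(dx < 0) or np.any(dd < 0):
            raise ValueError("deflections and deformations must be non-negative")
        if not self.needle_stiffness > 0:
            raise ValueError("needle stiffness must be positive")
        if self.cardinal_point_deg not in (0, 90, 180, 270):
            raise ValueError("cardinal point must be one of 0, 90, 180, 270 degrees")
        object.__setattr__(self, "deflections", dx)
        object.__setattr__(self, "deformations", dd)

    @property
    def forces(self) -> np.ndarray:
        return deflection_to_force(self.deflections, self.needle_stiffness)


def deflection_to_force(delta_x, kf: float = DEFAULT_NEEDLE_STIFFNESS):
    """Force in nN from needle-tip deflection: F = kf · ΔX."""
    delta_x = np.asarray(delta_x, dtype=float)
    if np.any(delta_x < 0):
        raise ValueError("deflection must be non-negative")
    if not kf > 0:
        raise ValueError("needle stiffness must be positive")
    out = kf * delta_x
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class StiffnessEstimate:
    slope_nn_per_um: float
    intercept_nn: float
    r_squared: float
    slope_stderr: float
    n: int


def estimate_stiffness(series: ForceDeformationSeries) -> StiffnessEstimate:
    """Local zona stiffness: least-squares slope of force on deformation.

    An intercept is included (contact offset: deformation at zero force
    need not be zero); the stiffness is the slope only.
    """
    dd = series.deformations
    if len(dd) < 2 or np.ptp(dd) == 0:
        raise ValueError("need at least 2 distinct deformation values")
    res = stats.linregress(dd, series.forces)
    return StiffnessEstimate(
        slope_nn_per_um=float(res.slope),
        intercept_nn=float(res.intercept),
        r_squared=float(res.rvalue**2),
        slope_stderr=float(res.stderr),
        n=len(dd),
    )


@dataclass(frozen=True)
class IntensityProfile:
    """Circumferential fluorescence scan of the zona pellucida.

    Angles in degrees within [0, 360), strictly increasing; intensities in
    arbitrary units (non-negative). ``scan_width_um`` records the scan line
    width of the acquisition.
    """

    angles_deg: np.ndarray
    intensities: np.ndarray
    scan_width_um: float = 1.5

    def __post_init__(self) -> None:
        a = np.asarray(self.angles_deg, dtype=float)
        y = np.asarray(self.intensities, dtype=float)
        if a.shape != y.shape or a.ndim != 1:
            raise ValueError("angles and intensities must be 1D and equal length")
        if np.any(np.diff(a) <= 0):
            raise ValueError("angles must be strictly increasing")
        if np.any(a < 0) or np.any(a >= 360):
            raise ValueError("angles must lie in [0, 360)")
        if np.any(y < 0):
            raise ValueError("intensities must be non-negative")
        object.__setattr__(self, "angles_deg", a)
        object.__setattr__(self, "intensities", y)


@dataclass(frozen=True)
class PorosityResult:
    normalized: np.ndarray
    cv_percent: float
    range_percent: float
    angle_min_deg: float
    angle_max_deg: float


def porosity_variation(profile: IntensityProfile) -> PorosityResult:
    """Mean-normalize the circular scan and report its variation.

    The variation is the coefficient of variation of the normalized
    intensities in percent (invariant to any positive rescaling of the
    raw intensities). The peak-to-peak range of the normalized profile is
    reported alongside, as are the angles of the intensity minimum and
    maximum.
    """
    y = profile.intensities
    if len(y) < 8:
        raise ValueError("need at least 8 samples around the circumference")
    mean = y.mean()
    if mean == 0:
        raise ValueError("zero mean intensity")
    norm = y / mean
    cv = float(norm.std(ddof=1) * 100.0)
    return PorosityResult(
        normalized=norm,
        cv_percent=cv,
        range_percent=float((norm.max() - norm.min()) * 100.0),
        angle_min_deg=float(profile.angles_deg[np.argmin(y)]),
        angle_max_deg=float(profile.angles_deg[np.argmax(y)]),
    )
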