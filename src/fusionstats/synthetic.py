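"""Synthetic-data generators with known ground truth.

No tracking data accompany the study this pipeline reproduces, so every
input the analysis consumes can be generated here with known parameters:
fusion sites on a spherical egg (uniform, exclusion-cone or axially biased
relative to the maternal-chromosome axis), paternal/maternal chromosome
tracks whose angular velocity toward the maternal chromosomes follows the
angle x time interaction model, force-deformation cycles for the zona
stiffness assay, and circumferential intensity profiles for the porosity
scan. Each generator is a pure function of its seed, and generators emit
their ground truth alongside the data so every estimator has an oracle.

Default parameters emulate the study's conditions: egg radius 36.6 µm,
chromosomes 5 µm beneath the membrane, 3-min frames over a ~2 h span, a
40° fusion exclusion cone around the chromosome axis, and velocity
coefficients with a negative angle x time interaction (paternal chromosomes
retreat from the spindle half early and drift back late).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .bias_test import FusionEvent
from .geometry import EggModel, _orthonormal_complement
from .mechanics import (
    DEFAULT_NEEDLE_STIFFNESS,
    ForceDeformationSeries,
    IntensityProfile,
)
from .trajectories import Track

__all__ = [
    "SyntheticConfig",
    "synth_eggs",
    "synth_fusion_events",
    "synth_tracks",
    "synth_velocity_records",
    "synth_force_deformation",
    "synth_intensity_profile",
]

log = logging.getLogger(__name__)

#: default velocity coefficients (β0, β1, β2, β3): deg/min intercept,
#: deg/min per deg, deg/min per min, deg/min per (deg·min). Negative
#: interaction: the early outward push near the spindle fades with time.
DEFAULT_VELOCITY_PARAMS = (-1.6, 0.016, 0.024, -0.00013)


@dataclass(frozen=True)
class SyntheticConfig:
    """Study-condition parameters for all generators."""

    seed: int = 0
    egg: EggModel = field(default_factory=EggModel)
    n_eggs: int = 20
    n_events_per_egg: int = 3
    fusion_model: str = "uniform"  # uniform | exclusion_cone | axial_bias
    theta_ex_deg: float = 40.0
    kappa: float = 2.0
    velocity_params: tuple[float, float, float, float] = DEFAULT_VELOCITY_PARAMS
    noise_sd: float = 1.2  # deg/min
    frame_interval: float = 3.0  # minutes
    duration: float = 120.0  # minutes
    tangential_diffusion: float = 2.0  # deg/sqrt(min)
    maternal_jitter_um: float = 1.0

    def __post_init__(self) -> None:
        if self.fusion_model not in ("uniform", "exclusion_cone", "axial_bias"):
            raise ValueError(f"unknown fusion model {self.fusion_model!r}")
        if not 0 <= self.theta_ex_deg < 180:
            raise ValueError("exclusion-cone angle must lie in [0, 180)")
        if self.kappa < 0:
            raise ValueError("kappa must be non-negative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not self.duration > self.frame_interval:
            raise ValueError("duration must exceed the frame interval")


def synth_eggs(cfg: SyntheticConfig) -> dict[str, EggModel]:
    """One egg model per synthetic egg, sharing the configured geometry but
    each with an independently oriented chromosome axis (so per-egg angle
    computation and pooling are exercised)."""
    rng = np.random.default_rng(_substream(cfg.seed, 1))
    eggs = {}
    for i in range(cfg.n_eggs):
        axis = rng.standard_normal(3)
        axis /= np.linalg.norm(axis)
        eggs[f"egg{i:03d}"] = replace(cfg.egg, chromosome_direction=axis)
    return eggs


def _substream(seed: int, stream: int) -> np.random.SeedSequence:
    return np.random.SeedSequence(entropy=seed, spawn_key=(stream,))


def _sample_cos_theta(rng, n: int, cfg: SyntheticConfig) -> np.ndarray:
    """cos θ draws for the configured fusion model (θ is the axis angle)."""
    if cfg.fusion_model == "uniform":
        return rng.uniform(-1.0, 1.0, size=n)
    if cfg.fusion_model == "exclusion_cone":
        if cfg.theta_ex_deg >= 180:
            raise ValueError("exclusion cone of 180 degrees leaves empty support")
        hi = np.cos(np.deg2rad(cfg.theta_ex_deg))
        return rng.uniform(-1.0, hi, size=n)
    # axial_bias: von Mises-Fisher about the ANTI-axis with concentration
    # kappa, i.e. density ∝ exp(-kappa·cosθ), increasing with θ; the
    # kappa → 0 limit is exactly uniform.
    k = cfg.kappa
    if k == 0:
        return rng.uniform(-1.0, 1.0, size=n)
    u = rng.uniform(size=n)
    # inverse CDF of cos ψ for vMF about the anti-axis, ψ = 180 - θ
    w = 1.0 + np.log(u + (1.0 - u) * np.exp(-2.0 * k)) / k
    return -w


def _theta_phi_to_position(
    theta_deg: np.ndarray, phi_deg: np.ndarray, egg: EggModel, radius: float
) -> np.ndarray:
    theta = np.deg2rad(np.atleast_1d(theta_deg))
    phi = np.deg2rad(np.atleast_1d(phi_deg))
    e1, e2 = _orthonormal_complement(egg.chromosome_direction)
    u = (
        np.cos(theta)[:, None] * egg.chromosome_direction
        + np.sin(theta)[:, None] * (np.cos(phi)[:, None] * e1 + np.sin(phi)[:, None] * e2)
    )
    return egg.center + radius * u


def synth_fusion_events(
    cfg: SyntheticConfig,
) -> tuple[list[FusionEvent], dict[str, EggModel]]:
    """Fusion sites per egg under the configured fusion model.

    uniform reproduces the null exactly; exclusion_cone is uniform
    conditional on θ > theta_ex; axial_bias tilts the density toward large
    θ with a rotationally symmetric exponential kernel.
    """
    eggs = synth_eggs(cfg)
    rng = np.random.default_rng(_substream(cfg.seed, 2))
    events = []
    for egg_id, egg in eggs.items():
        cos_t = _sample_cos_theta(rng, cfg.n_events_per_egg, cfg)
        theta = np.degrees(np.arccos(np.clip(cos_t, -1.0, 1.0)))
        phi = rng.uniform(0.0, 360.0, size=cfg.n_events_per_egg)
        pos = _theta_phi_to_position(theta, phi, egg, egg.radius)
        for j in range(cfg.n_events_per_egg):
            events.append(
                FusionEvent(
                    egg_id=egg_id,
                    position=pos[j],
                    time_min=0.0,
                    monospermic=cfg.n_events_per_egg == 1,
                )
            )
    return events, eggs


def synth_tracks(
    cfg: SyntheticConfig,
) -> tuple[list[Track], pd.DataFrame, dict[str, EggModel]]:
    """Paternal + maternal tracks per egg with the ground-truth ω stream.

    The maternal chromosomes sit near their pole (one static jittered
    offset per egg) at radius R − d; the paternal chromosomes move on the
    same radius with angular velocity toward the maternal chromosomes

        ω = β0 + β1·θ + β2·t + β3·θ·t + N(0, noise_sd²),

    positive ω meaning approach (θ decreases), plus tangential (azimuthal)
    diffusion. Steps that would drive θ outside [0, 180] are reflected at
    the boundary with a logged note. The initial θ is drawn from the
    configured fusion model. Returns (tracks, ground_truth, eggs); the
    ground-truth frame has columns egg_id, theta, t, omega — the exact ω
    realized at each step.
    """
    eggs = synth_eggs(cfg)
    rng = np.random.default_rng(_substream(cfg.seed, 3))
    b0, b1, b2, b3 = cfg.velocity_params
    r_inner = cfg.egg.radius - cfg.egg.chromosome_depth
    times = np.arange(0.0, cfg.duration + 1e-9, cfg.frame_interval)
    dt = cfg.frame_interval
    tracks: list[Track] = []
    truth_rows = []
    n_reflected = 0
    for egg_id, egg in eggs.items():
        # static maternal point near the chromosome pole
        e1, e2 = _orthonormal_complement(egg.chromosome_direction)
        jitter = cfg.maternal_jitter_um * rng.standard_normal(2)
        m_pos = egg.chromosome_point + jitter[0] * e1 + jitter[1] * e2
        m_dir = (m_pos - egg.center) / np.linalg.norm(m_pos - egg.center)
        m_egg = replace(egg, chromosome_direction=m_dir)

        theta = float(
            np.degrees(np.arccos(np.clip(_sample_cos_theta(rng, 1, cfg)[0], -1, 1)))
        )
        phi = float(rng.uniform(0.0, 360.0))
        thetas = np.empty(len(times))
        phis = np.empty(len(times))
        for k, t in enumerate(times):
            thetas[k] = theta
            phis[k] = phi
            if k == len(times) - 1:
                break
            omega = b0 + b1 * theta + b2 * t + b3 * theta * t
            omega += rng.normal(0.0, cfg.noise_sd)
            truth_rows.append((egg_id, theta, t, omega))
            theta = theta - omega * dt
            if theta < 0.0:
                theta = -theta
                n_reflected += 1
            elif theta > 180.0:
                theta = 360.0 - theta
                n_reflected += 1
            phi += cfg.tangential_diffusion * np.sqrt(dt) * rng.standard_normal()
        p_pos = _theta_phi_to_position(thetas, phis, m_egg, r_inner)
        tracks.append(
            Track(
                object_id="paternal",
                times=times,
                positions=p_pos,
                egg_id=egg_id,
                frame_interval=dt,
                fusion_time=0.0,
            )
        )
        tracks.append(
            Track(
                object_id="maternal",
                times=times,
                positions=np.tile(m_pos, (len(times), 1)),
                egg_id=egg_id,
                frame_interval=dt,
                fusion_time=0.0,
            )
        )
    if n_reflected:
        log.info("reflected %d boundary crossings of theta", n_reflected)
    truth = pd.DataFrame(truth_rows, columns=["egg_id", "theta", "t", "omega"])
    return tracks, truth, eggs


def synth_velocity_records(
    cfg: SyntheticConfig, n: int, theta_range: tuple[float, float] = (0.0, 180.0)
) -> pd.DataFrame:
    """i.i.d. angular-displacement records drawn directly from the linear
    model: θ ~ U(theta_range), t ~ U(0, duration), ω = β'x + N(0, σ²).

    The clean-regression counterpart of :func:`synth_tracks`, used for
    coefficient-recovery checks without the window-averaging that lag
    differencing of a simulated track introduces.
    """
    if n < 1:
        raise ValueError("need n >= 1 records")
    rng = np.random.default_rng(_substream(cfg.seed, 4))
    b0, b1, b2, b3 = cfg.velocity_params
    theta = rng.uniform(*theta_range, size=n)
    t = rng.uniform(0.0, cfg.duration, size=n)
    omega = b0 + b1 * theta + b2 * t + b3 * theta * t
    omega = omega + rng.normal(0.0, cfg.noise_sd, size=n)
    return pd.DataFrame({"egg_id": "synthetic", "theta": theta, "t": t, "omega": omega})


def synth_force_deformation(
    true_slope: float,
    intercept: float = 0.0,
    noise_sd: float = 0.0,
    n: int = 20,
    seed: int = 0,
    max_deformation_um: float = 10.0,
    needle_stiffness: float = DEFAULT_NEEDLE_STIFFNESS,
    cardinal_point_deg: int = 0,
) -> ForceDeformationSeries:
    """Linear force-deformation cycles with Gaussian force noise.

    Deformations sit on a grid up to ``max_deformation_um``; forces are
    true_slope·ΔD + intercept + noise and are converted back to needle
    deflections via the needle stiffness (negative draws are clipped at 0,
    which the default scales make vanishingly rare).
    """
    if n < 2:
        raise ValueError("need at least 2 cycles")
    rng = np.random.default_rng(seed)
    dd = np.linspace(0.5, max_deformation_um, n)
    force = true_slope * dd + intercept + rng.normal(0.0, noise_sd, size=n)
    dx = np.clip(force / needle_stiffness, 0.0, None)
    return ForceDeformationSeries(
        deflections=dx,
        deformations=dd,
        needle_stiffness=needle_stiffness,
        cardinal_point_deg=cardinal_point_deg,
    )


def synth_intensity_profile(
    mean: float = 100.0,
    cv_target_percent: float = 8.6,
    n: int = 360,
    seed: int = 0,
) -> IntensityProfile:
    """Circumferential scan whose coefficient of variation is close to the
    target: a random-phase sinusoid carrying ~80% of the variance plus
    Gaussian sample noise carrying the rest."""
    if mean <= 0:
        raise ValueError("mean intensity must be positive")
    if cv_target_percent < 0:
        raise ValueError("cv target must be non-negative")
    rng = np.random.default_rng(seed)
    angles = np.linspace(0.0, 360.0, n, endpoint=False)
    sd = mean * cv_target_percent / 100.0
    phase = rng.uniform(0.0, 2 * np.pi)
    wave = np.sqrt(2.0 * 0.8) * sd * np.sin(np.deg2rad(angles) + phase)
    noise = np.sqrt(0.2) * sd * rng.standard_normal(n)
    y = np.clip(mean + wave + noise, 0.0, None)
    return IntensityProfile(angles_deg=angles, intensities=y)
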