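"""Monte-Carlo null model: sperm fuse uniformly anywhere on the egg surface.

The null hypothesis for the fusion-site bias test is that fusion sites are
uniform on the sphere. A large seeded sample of uniform surface points
(default 40,000) is binned by axis angle and by chord distance to the
maternal chromosomes; the per-bin counts serve as the simulated comparison
sample for the per-bin exact tests, and the per-bin fractions as the
expected assignment probabilities.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .geometry import (
    AngularBinning,
    DistanceBinning,
    EggModel,
    angles_to_chromosome_axis,
    chord_distance_to_chromosomes,
)

__all__ = ["NullDistribution", "sample_uniform_sphere", "build_null_distribution"]


def sample_uniform_sphere(n: int, seed: int, egg: EggModel | None = None) -> np.ndarray:
    """Draw ``n`` points uniformly on the egg surface.

    Uniform directions are obtained by normalizing standard-Gaussian
    triples, which is exactly uniform in law on the sphere. Reproducible
    for a fixed seed.

    Returns an (n, 3) array of positions in µm.
    """
    if n < 1:
        raise ValueError(f"need n >= 1 points, got {n}")
    if egg is None:
        egg = EggModel()
    rng = np.random.default_rng(seed)
    v = rng.standard_normal((n, 3))
    norms = np.linalg.norm(v, axis=1)
    # a zero vector has probability 0 but guard against it anyway
    bad = norms == 0
    while np.any(bad):
        v[bad] = rng.standard_normal((bad.sum(), 3))
        norms = np.linalg.norm(v, axis=1)
        bad = norms == 0
    return egg.center + egg.radius * v / norms[:, None]


@dataclass(frozen=True)
class NullDistribution:
    """Binned uniform-fusion null.

    Counts are the raw occupancy of one seeded Monte-Carlo sample; probs
    are counts/n_points; area_fractions are the analytic band areas of the
    angular binning (exact, not simulated).
    """

    n_points: int
    seed: int
    angle_binning: AngularBinning
    distance_binning: DistanceBinning
    angle_bin_counts: np.ndarray
    distance_bin_counts: np.ndarray
    area_fractions: np.ndarray = field(repr=False, default=None)

    def __post_init__(self) -> None:
        if int(self.angle_bin_counts.sum()) != self.n_points:
            raise ValueError("angle bin counts must sum to n_points")
        if int(self.distance_bin_counts.sum()) != self.n_points:
            raise ValueError("distance bin counts must sum to n_points")
        if self.area_fractions is None:
            object.__setattr__(
                self, "area_fractions", self.angle_binning.area_fractions()
            )

    @property
    def angle_bin_probs(self) -> np.ndarray:
        return self.angle_bin_counts / self.n_points

    @property
    def distance_bin_probs(self) -> np.ndarray:
        return self.distance_bin_counts / self.n_points

    def to_dict(self) -> dict:
        return {
            "n_points": self.n_points,
            "seed": self.seed,
            "angle_bin_edges_deg": self.angle_binning.edges.tolist(),
            "distance_bin_edges_um": self.distance_binning.edges.tolist(),
            "angle_bin_counts": self.angle_bin_counts.tolist(),
            "distance_bin_counts": self.distance_bin_counts.tolist(),
            "angle_bin_probs": self.angle_bin_probs.tolist(),
            "distance_bin_probs": self.distance_bin_probs.tolist(),
            "area_fractions": self.area_fractions.tolist(),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_dict(cls, d: dict) -> "NullDistribution":
        return cls(
            n_points=int(d["n_points"]),
            seed=int(d["seed"]),
            angle_binning=AngularBinning(np.asarray(d["angle_bin_edges_deg"])),
            distance_binning=DistanceBinning(np.asarray(d["distance_bin_edges_um"])),
            angle_bin_counts=np.asarray(d["angle_bin_counts"], dtype=int),
            distance_bin_counts=np.asarray(d["distance_bin_counts"], dtype=int),
        )

    @classmethod
    def from_json(cls, path) -> "NullDistribution":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def build_null_distribution(
    egg: EggModel,
    n: int = 40_000,
    angle_binning: AngularBinning | None = None,
    distance_binning: DistanceBinning | None = None,
    seed: int = 0,
) -> NullDistribution:
    """Simulate the uniform-fusion null and bin it by angle and distance."""
    if angle_binning is None:
        angle_binning = AngularBinning()
    if distance_binning is None:
        distance_binning = DistanceBinning()
    points = sample_uniform_sphere(n, seed=seed, egg=egg)
    thetas = angles_to_chromosome_axis(points, egg)
    distances = chord_distance_to_chromosomes(thetas, egg)
    return NullDistribution(
        n_points=n,
        seed=seed,
        angle_binning=angle_binning,
        distance_binning=distance_binning,
        angle_bin_counts=angle_binning.count(thetas),
        distance_bin_counts=distance_binning.count(distances),
    )
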