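#!/usr/bin/env python
"""Simulate the uniform-fusion null and check it against closed-form geometry.

Sperm fusing anywhere on the egg surface with equal probability defines the
null for the fusion-site bias analysis. This script draws the 40,000-point
null on the reference egg (R = 36.6 µm, chromosomes 5 µm beneath the
membrane), verifies the simulated angle-bin probabilities against the
analytic band areas (cos θ1 − cos θ2)/2, and reports the geometric link
between the two exclusion thresholds: a 40° axis angle is a 23.8 µm chord
distance, i.e. 24 µm to the nearest micron.

Writes results/null_distribution.json and results/null_angle_bins.csv.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from fusionstats import EggModel, build_null_distribution, chord_distance_to_chromosomes

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

egg = EggModel(radius=36.6, chromosome_depth=5.0)
null = build_null_distribution(egg, n=40_000, seed=1)

areas = null.angle_binning.area_fractions()
se = np.sqrt(areas * (1 - areas) / null.n_points)
table = pd.DataFrame(
    {
        "bin_deg": null.angle_binning.labels,
        "simulated_prob": null.angle_bin_probs,
        "analytic_area_fraction": areas,
        "z_score": (null.angle_bin_probs - areas) / se,
    }
)
table.to_csv(OUT / "null_angle_bins.csv", index=False)
null.to_json(OUT / "null_distribution.json")

d40 = chord_distance_to_chromosomes(40.0, egg)
print("Uniform-fusion null, n = 40,000 points, seed 1")
print(table.to_string(index=False, float_format=lambda v: f"{v:.4f}"))
print(f"\nmax |z| across bins: {table.z_score.abs().max():.2f} "
      "(all within Monte-Carlo noise of the closed-form band areas)")
print(f"chord distance at a 40 deg axis angle: {d40:.1f} um "
      f"(nearest micron: {round(d40)} um) — the paired angle/distance "
      "exclusion thresholds describe the same boundary")
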