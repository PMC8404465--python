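#!/usr/bin/env python
"""Zona pellucida stiffness and porosity from synthetic assay data.

Microneedle assay: at each of four cardinal points (0/90/180/270° relative
to the protruding cortex), 30 compression cycles are generated with a true
local stiffness of 2.05 nN/µm (the measured per-point scale of the mouse
zona pellucida) and realistic force noise; the local stiffness is
re-estimated as the linear-regression slope of force (kf·ΔX with
kf = 12.2 nN/µm) on deformation ΔD.

Porosity assay: five circumferential dextran-intensity scans are generated
with ~8.6% target variation; each is mean-normalized and its coefficient of
variation (and peak-to-peak range) reported.

Writes results/zona_stiffness.csv and results/zona_porosity.csv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from fusionstats import (
    estimate_stiffness,
    porosity_variation,
    synth_force_deformation,
    synth_intensity_profile,
)

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

TRUE_SLOPE = 2.05  # nN/µm

rows = []
for i, point in enumerate((0, 90, 180, 270)):
    series = synth_force_deformation(
        true_slope=TRUE_SLOPE, intercept=1.0, noise_sd=0.8, n=30,
        seed=100 + i, cardinal_point_deg=point,
    )
    est = estimate_stiffness(series)
    rows.append(
        {
            "cardinal_point_deg": point,
            "stiffness_nn_per_um": est.slope_nn_per_um,
            "stderr": est.slope_stderr,
            "r_squared": est.r_squared,
            "n_cycles": est.n,
        }
    )
stiff = pd.DataFrame(rows)
stiff.to_csv(OUT / "zona_stiffness.csv", index=False)
print(f"Local zona stiffness (true slope {TRUE_SLOPE} nN/um):")
print(stiff.to_string(index=False, float_format=lambda v: f"{v:.3f}"))
print(f"mean over cardinal points: {stiff.stiffness_nn_per_um.mean():.3f} "
      f"+/- {stiff.stiffness_nn_per_um.std(ddof=1):.3f} nN/um — "
      "no positional dependence built in, none detected")

rows = []
for s in range(5):
    prof = synth_intensity_profile(mean=100.0, cv_target_percent=8.6, seed=200 + s)
    res = porosity_variation(prof)
    rows.append(
        {
            "egg": s,
            "cv_percent": res.cv_percent,
            "range_percent": res.range_percent,
            "angle_min_deg": res.angle_min_deg,
            "angle_max_deg": res.angle_max_deg,
        }
    )
poro = pd.DataFrame(rows)
poro.to_csv(OUT / "zona_porosity.csv", index=False)
print("\nPorosity variation of circumferential scans (target CV 8.6%):")
print(poro.to_string(index=False, float_format=lambda v: f"{v:.2f}"))
print(f"mean CV: {poro.cv_percent.mean():.2f} +/- {poro.cv_percent.std(ddof=1):.2f} % — "
      "extrema angles scatter randomly (random sinusoid phase), "
      "no preferred location")
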