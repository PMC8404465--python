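#!/usr/bin/env python
"""Test fusion-site spatial bias against the uniform null.

Generates two synthetic cohorts of fusion sites on 40 eggs (120 events):
one with a 40° exclusion cone around the maternal-chromosome axis (what the
biased-fusion biology produces) and one uniform control. Each cohort is
binned in 30° axis-angle bins and 10 µm chord-distance bins and compared to
the 40,000-point simulated null with per-bin two-sided Fisher exact tests,
Holm-corrected; angular rates are then corrected by band surface area.

Expected outcome: the exclusion cohort shows a significant deficit in the
0–30° bin (and a deficit below ~24 µm in the distance binning); the uniform
control should reject in at most ~5% of cohorts family-wise.

Writes results/fusion_bias_angle.csv, results/fusion_bias_distance.csv and
results/fusion_bias_control.csv.
"""

from pathlib import Path

import pandas as pd

from fusionstats import (
    SyntheticConfig,
    build_null_distribution,
    run_bias_test,
    synth_fusion_events,
)

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

SEED = 1
cfg_biased = SyntheticConfig(seed=SEED, fusion_model="exclusion_cone",
                             theta_ex_deg=40.0, n_eggs=40, n_events_per_egg=3)
cfg_uniform = SyntheticConfig(seed=SEED, fusion_model="uniform",
                              n_eggs=40, n_events_per_egg=3)

events_b, eggs_b = synth_fusion_events(cfg_biased)
events_u, eggs_u = synth_fusion_events(cfg_uniform)
null = build_null_distribution(next(iter(eggs_b.values())), n=40_000, seed=SEED)


def to_frame(result):
    d = result.to_dict()
    d.pop("bin_edges", None)
    d.pop("alpha", None)
    return pd.DataFrame(d)


res_angle = run_bias_test(events_b, eggs_b, null)
res_dist = run_bias_test(events_b, eggs_b, null, binning=null.distance_binning)
res_ctrl = run_bias_test(events_u, eggs_u, null)

to_frame(res_angle).to_csv(OUT / "fusion_bias_angle.csv", index=False)
to_frame(res_dist).to_csv(OUT / "fusion_bias_distance.csv", index=False)
to_frame(res_ctrl).to_csv(OUT / "fusion_bias_control.csv", index=False)

print(f"Biased cohort ({len(events_b)} events, 40 deg exclusion cone), angle bins:")
print(to_frame(res_angle).to_string(index=False, float_format=lambda v: f"{v:.4g}"))
sig = [lbl for lbl, s in zip(res_angle.binning.labels, res_angle.significant) if s]
print(f"\nHolm-significant angle bins: {sig or 'none'}")
sig_d = [lbl for lbl, s in zip(res_dist.binning.labels, res_dist.significant) if s]
print(f"Holm-significant distance bins (um): {sig_d or 'none'}")
sig_c = [
    (lbl, p)
    for lbl, s, p in zip(res_ctrl.binning.labels, res_ctrl.significant, res_ctrl.holm_p)
    if s
]
if sig_c:
    print("Uniform control Holm-significant bins: "
          + ", ".join(f"{lbl} (Holm p = {p:.3f})" for lbl, p in sig_c)
          + " — marginal rejections like this are expected in ~5% of uniform"
            " cohorts; the family-wise error rate is what the test controls")
else:
    print("Uniform control: no Holm-significant bin")
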