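# fusionstats

Statistical analysis of where sperm fuse on the mouse egg and how paternal
chromosomes move afterwards.

## Scientific problem

In mouse fertilization the egg is arrested in metaphase II with the maternal
chromosomes held on a spindle just beneath the plasma membrane. Live imaging
shows that sperm rarely fuse near that spindle region, and that after fusion
the paternal chromosomes first move *away* from the maternal chromosomes
before converging toward them around anaphase. Two quantitative questions
follow:

1. **Is the spatial distribution of fusion sites biased?** Each fusion site
   can be reduced to an angle θ between the egg-center→fusion-site vector and
   the egg-center→maternal-chromosome axis (or equivalently a straight-line
   chord distance to the chromosomes). Under the null hypothesis that sperm
   fuse uniformly over the egg surface, the probability of landing in an
   angular band [θ₁, θ₂] is the band's area fraction, (cos θ₁ − cos θ₂)/2.
   The package builds a large Monte-Carlo uniform null, bins observed fusion
   sites, and tests each bin with a two-sided Fisher exact test under
   Holm's family-wise correction; rates are then reported per unit surface
   area so that bins of different size are comparable.

2. **What drives the paternal chromosomes' angular motion?** From 3-D tracks
   the angle θ(t) to the maternal chromosomes is extracted and an angular
   velocity ω (positive = approaching) is computed over a two-frame lag.
   Four nested linear models of ω — angle only, time only, additive, and
   angle × time interaction — are fit by ordinary least squares and ranked
   by AIC. The interaction model captures motion that is initially
   away-from-spindle near the spindle and converges everywhere late.

A third, mechanical module estimates zona pellucida stiffness from
microneedle force–deformation cycles (force = needle stiffness × needle
deflection; local stiffness = regression slope of force on deformation) and
quantifies zona porosity as the coefficient of variation of a mean-normalized
circumferential intensity scan.

## Geometry

The egg is modeled as a sphere of radius R = 36.6 µm with the maternal
chromosomes treated as a point d = 5 µm beneath the membrane along a unit
axis. For a surface point at axis angle θ, the chord distance to the
chromosomes is √(R² + r² − 2Rr cos θ) with r = R − d. The two exclusion
descriptions used in the field — "within 40° of the axis" and "within ~24 µm
of the chromosomes" — are the same boundary: the chord at 40° is 23.8 µm.

## Worked example

```python
from fusionstats import (EggModel, SyntheticConfig, build_null_distribution,
                         chord_distance_to_chromosomes, run_bias_test,
                         synth_fusion_events)

egg = EggModel()  # radius 36.6 um, chromosomes 5 um beneath the membrane
print(f"chord distance at a 40 deg axis angle: "
      f"{chord_distance_to_chromosomes(40.0, egg):.1f} um")

# a synthetic cohort in which sperm never fuse within 40 deg of the
# maternal-chromosome axis, tested against a 40,000-point uniform null
cfg = SyntheticConfig(seed=1, fusion_model="exclusion_cone",
                      n_eggs=40, n_events_per_egg=3)
events, eggs = synth_fusion_events(cfg)
null = build_null_distribution(egg, n=40_000, seed=1)
result = run_bias_test(events, eggs, null)

for label, obs, p, rate in zip(result.binning.labels, result.observed,
                               result.holm_p, result.area_corrected_rate):
    flag = " *" if p < result.alpha else ""
    print(f"{label:>8} deg: {obs:3d} events, Holm p = {p:.4f}, "
          f"area-corrected rate = {rate:.2f}{flag}")
```

Output:

```
chord distance at a 40 deg axis angle: 23.8 um
    0-30 deg:   0 events, Holm p = 0.0023, area-corrected rate = 0.00 *
   30-60 deg:  12 events, Holm p = 0.0917, area-corrected rate = 0.55
   60-90 deg:  32 events, Holm p = 1.0000, area-corrected rate = 1.07
  90-120 deg:  42 events, Holm p = 0.0752, area-corrected rate = 1.40
 120-150 deg:  22 events, Holm p = 1.0000, area-corrected rate = 1.00
 150-180 deg:  12 events, Holm p = 0.6016, area-corrected rate = 1.49
```

The only Holm-significant bin is the deficit at 0–30°, exactly where the
exclusion cone removed events; the other bins absorb the displaced mass
without individually crossing the corrected threshold.

The same pipeline is available from the command line:

```bash
fusionstats gen-synthetic --preset paperlike --seed 1 --out data
fusionstats run --events data/events.csv --tracks data/tracks.csv \
                --egg data/eggs.json --out results --seed 1
```

which writes `results/report.json` and a plain-text `results/summary.txt`
covering the bias test, the AIC model ranking and the half-sphere Welch
comparison.

## Analysis scripts

The `analysis/` directory contains numbered driver scripts that exercise the
library end to end on synthetic cohorts and write small tables to
`results/`:

- `01_simulate_null.py` — builds the 40,000-point uniform null and verifies
  the simulated angle-bin probabilities against the closed-form band areas
  (max |z| = 1.60 across bins at seed 1).
- `02_fusion_bias.py` — the biased-vs-uniform cohort comparison shown above,
  in both angle and chord-distance binnings, plus a uniform control.
- `03_trajectory_models.py` — generates 20 eggs of paternal/maternal tracks,
  fits the four velocity models, and recovers the interaction model as
  AIC-best (ΔAIC = 26.3 to the additive model at seed 1) with coefficients
  close to the generator's; Welch's test shows the spindle-half chromosomes
  moving away early (mean ω −0.29 vs +0.39 °/min, p = 1.3 × 10⁻⁴) and
  everything converging late.
- `04_zona_mechanics.py` — recovers a 2.05 nN/µm local zona stiffness at
  four cardinal points (estimated mean 2.047 ± 0.066 nN/µm) and an ~8.6%
  porosity coefficient of variation with randomly located extrema.

## Layout

```
src/fusionstats/   library: geometry, null_model, bias_test, trajectories,
                   mechanics, synthetic, io, cli
analysis/          numbered driver scripts writing tables to results/
scripts/           acceptance.py (headline quantities from scratch)
tests/             pytest suite
docs/methods.md    methods note: model, assumptions, parameters, limitations
```
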