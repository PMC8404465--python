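# Methods

This note documents the model, the statistical procedures, the parameter
choices, and the known limitations of `fusionstats`. Everything stated here
is computed by the package; nothing is an empirical claim about real eggs
beyond the published parameter values adopted as defaults.

## Egg model

The egg is a sphere of radius R centered at an arbitrary point, with the
metaphase-II maternal chromosomes idealized as a single point a depth d
beneath the membrane along a unit axis **u** (the spindle axis, pointing
from the center toward the chromosome-proximal cortex). A fusion site or
chromosome position **x** on the membrane is summarized by:

- the **axis angle** θ = arccos(⟨(**x**−**c**)/R, **u**⟩) ∈ [0°, 180°];
- the **chord distance** to the chromosome point,
  √(R² + r² − 2Rr cos θ) with r = R − d (straight-line, through the
  cytoplasm);
- optionally the **arc distance** R·θ along the surface.

Chord distance is the primary distance measure because the biological
question concerns proximity of the fusion site to the chromosomes in 3-D,
not path length along the membrane. With the defaults (R = 36.6 µm,
d = 5 µm) the chord at a 40° axis angle is 23.794 µm, so the "40° cone" and
"~24 µm ball" descriptions of the exclusion zone coincide; `round()` to the
nearest micron gives 24.

The area fraction of an angular band [θ₁, θ₂] on the sphere is
(cos θ₁ − cos θ₂)/2; these closed-form fractions are used both to validate
the Monte-Carlo null and to area-correct observed bin rates.

## Uniform-fusion null

Uniform points on the sphere are drawn by normalizing i.i.d. standard
Gaussian triples (exactly rotation-invariant, no polar-coordinate area
distortion). The null distribution object stores the bin counts of
n = 40,000 such points in both binnings, with the seed, so it is
serializable and exactly reproducible. 40,000 points give a per-bin
standard error of at most ~0.25 percentage points, negligible next to
cohort-level sampling noise at realistic cohort sizes, while building in
well under a second.

## Fusion-site bias test

1. Each event is assigned θ and chord distance using **its own egg's** axis
   and geometry; events that do not lie on their egg's membrane within a
   10% radial tolerance are rejected and logged.
2. Counts in 30° angle bins (or 10 µm distance bins) are compared to the
   simulated null counts with a per-bin **two-sided Fisher exact test** on
   the 2×2 table [[obs_in, obs_out], [null_in, null_out]]. Using the
   simulated counts (rather than analytic probabilities) keeps the test a
   genuine contingency-table comparison in which the null's Monte-Carlo
   noise is part of the model; an analytic **exact binomial** alternative
   against the closed-form band areas is also provided and agrees at these
   sample sizes.
3. P-values are corrected by **Holm's step-down** procedure across bins,
   controlling the family-wise error rate at α = 0.05 without the
   independence assumptions of Šidák-type corrections.
4. For interpretation, each bin's event share is divided by its area
   fraction (**area-corrected rate**: 1 = uniform); the correction is
   applied after testing and never feeds back into the p-values.

Bins are half-open [lo, hi) with the final bin closed, and θ/distance are
rounded to 10⁻⁶ before binning so that trigonometric round-trip noise
cannot flip a value sitting exactly on a bin edge.

Power at small cohorts is limited by the discreteness of the Fisher test:
with 50 events, even a completely empty 0–30° bin (expected ≈ 3.35) has a
two-sided p of 0.079 before correction, so no 6-bin Holm family can reject.
Roughly 100 events are needed before an empty exclusion bin becomes
family-wise significant (Holm p ≈ 0.012 at 100 events); the bundled
analyses therefore use 120-event cohorts when demonstrating detection, and
50-event cohorts when measuring the false-positive rate.

## Trajectory analysis

From paired paternal/maternal 3-D tracks sampled every Δt minutes, the
angle series θ(t) is computed per egg (the maternal position is carried
forward, with a warning, if its track ends early). The **angular velocity**
uses a two-frame lag,

  ω_n = (θ_n − θ_{n+2}) / (t_{n+2} − t_n),

positive when the paternal chromosomes approach the maternal ones. The
two-frame lag halves frame-to-frame localization noise at the cost of a
one-frame smoothing window.

Pooled (θ, t, ω) records from all eggs are fit by OLS to four nested mean
models:

| model | mean of ω |
|---|---|
| angle_only | β₀ + β₁θ |
| time_only | β₀ + β₂t |
| additive | β₀ + β₁θ + β₂t |
| interaction | β₀ + β₁θ + β₂t + β₃θt |

and ranked by AIC = 2k − 2·loglik with the full Gaussian log-likelihood
−(n/2)(log(2πσ̂²) + 1), where k counts all mean parameters **plus the error
variance** (k = p + 1). RSS is floored at 10⁻¹² to keep the likelihood
finite on degenerate data; rank-deficient design matrices mark a fit
invalid rather than silently pseudo-inverting. Ties in AIC break by smaller
k, then model name. A negative β₃ with positive β₁, β₂ reproduces the
observed kinetics: early outward motion in the spindle half, late
convergence everywhere.

A complementary nonparametric check splits records at θ = 90° (records at
exactly 90° count as the opposite half) within a time window and compares
mean ω between halves with **Welch's unequal-variance t test**.

## Zona mechanics

Microneedle cycles give force F = k_f·ΔX from the calibrated needle
stiffness k_f = 12.2 nN/µm and needle deflection ΔX; the local zona
stiffness is the slope of the OLS regression of F on zona deformation ΔD
(intercept included, so contact-offset errors do not bias the slope).
Porosity variation of a circumferential intensity scan is the coefficient
of variation (sample SD / mean × 100%) of the mean-normalized profile; the
CV is scale-invariant, so illumination differences between eggs cancel.
The peak-to-peak range and the angles of the extrema are reported
alongside, since a CV alone cannot say *where* the zona is most porous.

## Synthetic data

The generator emulates the **geometry and sampling structure** of a
fertilization imaging experiment: multiple eggs with random spindle axes,
fusion events drawn from a uniform, 40°-exclusion-cone, or
von-Mises–Fisher-like axial-bias model, and paternal tracks evolving as
θ_{k+1} = θ_k − ω_k Δt with reflection at 0°/180°, azimuthal diffusion, and
i.i.d. Gaussian measurement noise on ω. Independent seed substreams
(`SeedSequence(seed, spawn_key=(stream,))`) make eggs, events, tracks and
records reproducible separately.

Defaults are study conditions: 20 eggs, 3-minute frames over 120 minutes,
velocity parameters β = (−1.6, 0.016, 0.024, −0.00013) °/min with
σ = 1.2 °/min noise. These were calibrated once, before the test suite was
frozen, so that the generated kinetics produce the qualitative pattern of
interest (early outward motion near the spindle, late convergence) and a
stable AIC ordering interaction < additive < time_only < angle_only
(99/100 seeds).

The generator does **not** emulate: 3-D localization error (noise enters ω
directly, not positions), chromosome congression or spindle migration,
membrane deformation at the fusion cone, polyspermy-dependent dynamics,
variable frame intervals, or track loss. Coefficient-recovery tests use an
i.i.d. record generator rather than tracks, because the two-frame lag
window-averages ω along a track and would bias β estimates relative to the
instantaneous ground truth; this is a property of the estimator, recorded
as a design decision, not a bug.

## Parameters

| parameter | default | units | rationale |
|---|---|---|---|
| egg radius R | 36.6 | µm | published mean mouse-egg radius |
| chromosome depth d | 5 | µm | metaphase-II plate just beneath the cortex |
| angle bins | 30 | deg | 6 bins: resolution vs per-bin counts |
| distance bins | 10 | µm | 7 bins over the 0–70 µm chord range |
| null size n | 40,000 | points | per-bin SE ≤ 0.25 pp, builds in < 1 s |
| α | 0.05 | — | conventional family-wise level |
| velocity lag | 2 | frames | noise suppression vs temporal resolution |
| needle stiffness k_f | 12.2 | nN/µm | calibrated microneedle constant |
| exclusion cone | 40 | deg | geometric twin of the 24 µm chord threshold |
| frame interval | 3 | min | typical light-sheet acquisition cadence |

## Limitations

- The maternal chromosomes are a point; a real metaphase plate is ~10 µm
  wide, so chord distances near the spindle are lower bounds.
- The uniform null assumes a spherical egg; strongly ovoid or deformed eggs
  violate the band-area formula (the per-egg projection tolerance catches
  gross deviations only).
- Per-bin Fisher tests ignore the ordering of bins; a smooth monotone bias
  spread over several bins is detected less efficiently than a
  concentrated one.
- AIC model selection compares only the four specified mean structures with
  homoscedastic Gaussian errors; it cannot validate the error model itself,
  and pooled OLS ignores within-egg correlation (standard errors are
  anti-conservative if eggs differ systematically).
- Stiffness regression assumes quasi-static, elastic deformation; viscous
  or plastic response would bias the slope.
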