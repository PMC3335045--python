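# Methods

This note documents the models, default parameters and numerical choices
behind `divetherm`, and what the synthetic-data tests do and do not show
about real logger data.

## Sensor model

The simulated logger mirrors a small archival tag for diving seabirds:
depth at 0.05 m resolution and temperature at 0.01 °C, both at 1 Hz, and
bi-axial acceleration (surge = longitudinal, heave = dorso-ventral) clipped
to ±30 m s⁻² at 32 Hz. Depth and temperature are quantized by rounding to
the nearest resolution step; acceleration is hard-clipped.

The temperature sensor is modelled as a first-order (single-pole) system.
Its characteristic figure is the 90% step-response time T₀.₉ ≈ 15 s; the exponential time
constant follows from 1 − e^(−t/τ) = 0.9 as τ = T₀.₉/ln 10 ≈ 6.51 s.
Discretely we use the exact zero-order-hold update
y[n+1] = x[n] + (y[n] − x[n])·e^(−Δt/τ), under which a step applied at
sample t₀ reaches 90% of its amplitude exactly at t₀ + T₀.₉.

**Lag inversion.** The analysis inverts this model as
corrected(t) = measured(t) + τ·d(measured)/dt. The derivative is a
centered difference across a 5 s window (samples ±2 s apart, edges
replicated): wide enough that 0.01 °C quantization noise, amplified by τ,
stays well below 0.1 °C, and short enough to track a ~1 m s⁻¹ descent
through 2-m depth bins. On a noise-free descent through a 3 °C
thermocline the forward-model-then-inversion round trip has ≈ 0.04 °C RMS
error away from the series edges; residuals concentrate where the
temperature slope changes abruptly (the window smooths the derivative
there).

## Synthetic trips

The simulator's defaults describe a one-day guard-phase foraging trip:
hundreds of dives (the study scale is roughly 600–1450 dives per trip)
over a 60–80 m water column, reaching at most ~70 m. Dive max depths are
drawn from a mixture of truncated normal modes (default: 85% shallow at
8 ± 3 m, 15% deep at 35 ± 8 m, giving a deep-dive share in the 10–15%
range seen in stratified weeks). Dives are trapezoids on the 1 Hz grid —
constant 1 m s⁻¹ descent and ascent, flat bottom with exponential
duration (mean 8 s), V-dives having zero bottom time — so the phase
ground truth is analytic. Surface intervals are exponential (mean 20 s)
with depth exactly 0; this is the simplest stationary choice and is not
meant to capture real surface-recovery physiology.

Flipper strokes are a sinusoid at 2.5 Hz on the heave axis (half-amplitude
2 m s⁻² over a 9.8 m s⁻² gravity/posture baseline, plus 0.2 m s⁻² white
noise), present during descent and bottom only — little penguins ascend
largely passively. Surge carries a 0.3× in-phase copy. A dive hosts a
prey-pursuit segment with probability `pursuit_probability` provided its
max depth lies in `pursuit_depth_range` (default 12–60 m, keeping
pursuits below the 10 m buoyancy floor of the analysis); during a pursuit
(3–6 s within the bottom phase) the stroke amplitude is multiplied by
`pursuit_amplitude_multiplier` (default 2). The multiplier is a free
simulator parameter — the field data underlying the method give no
quantitative "normal vs elevated" amplitude — so recovery results should
be read as "detectable at a 2× contrast", not as a statement about real
prey-capture signatures.

For the stratified-vs-mixed contrast the scenario can declare prey
aggregated against the thermocline: with `aggregated_pursuit_probability`
set (default scenario conditions 0.7 vs a dispersed 0.3) dives reaching
the layer within 8 m above the thermocline top use the higher probability.
Over a mixed column every dive uses the dispersed value, reproducing
qualitatively the observed pattern of higher hunting efficiency in
stratified weeks.

The water column is warm-constant / linear-ramp / cold-constant (a tanh
transition is available); bin-level temperature noise defaults to
0.05 °C. Real water columns have internal waves, lateral structure and
diurnal heating that the simulator does not emulate, so passing recovery
tests demonstrates correctness of the signal-processing chain, not
robustness to every oceanographic regime.

## Dive analysis

Submergences are samples with depth > 0.1 m (two depth quanta); a dive is
a maximal submergence whose **max depth exceeds 1 m** (strictly). The
1 m rule applies to max depth only; the 0.1 m threshold merely separates
submergences. An optional zero-offset correction removes slow surface
drift by subtracting the interpolated running mode of near-surface
readings (real pressure sensors drift; the simulator can inject drift to
test this).

Vertical rate is the central difference of depth at 1 Hz, by default
without smoothing (quantization contributes only ±0.05 m s⁻¹ of rate
noise, below the 0.25 m s⁻¹ threshold) and as a magnitude — the
rate-below-threshold condition is read symmetrically for descent and
ascent; a signed-rate variant is available. Bottom start/end are the
first/last qualifying samples. One consequence of central differencing:
at the corners of an ideal trapezoid the rate reads half the descent
rate, so the two corner samples are excluded and the detected bottom is
the flat span minus 2 s. If no sample qualifies (a sharp V-dive), the
dive splits at its deepest sample with an empty bottom. Dives shorter
than 3 samples degenerate to descent-only and are flagged.

## Strokes and prey encounters

The heave channel is separated into posture/gravity (low) and dynamic
(high) components with a 4th-order zero-phase Butterworth low-pass
(`filtfilt`; no time shift of stroke peaks); the high component is the
residual, so low + high reconstructs the input exactly. The 1 Hz default
cutoff sits below penguin stroke frequencies (~2–3 Hz) and above postural
dynamics.

A stroke is one oscillation cycle of the high component between
consecutive upward zero crossings. Amplitude is estimated as
2√2 × cycle RMS, which equals the peak-to-trough excursion for a
sinusoid but is far less biased by sample-level noise than a raw
max-minus-min (at amplitude SNR 5 the raw estimator runs ~15% hot, the
RMS estimator ~4%). Cycles below a 1 m s⁻² floor or outside 0.5–10 Hz
are discarded.

"Higher than normal amplitude" is formalized per trip as
median + 3·MAD over all strokes during dives at depths > 10 m — the
median/MAD pair is robust to the pursuit bursts themselves contaminating
the baseline, and the rule co-scales with the channel so the flagged-dive
set is invariant to rescaling the heave axis. A prey-encounter segment is
≥ 3 consecutive elevated strokes (a pursuit is sustained beating; a
single large cycle is noise) whose mean depth exceeds 10 m, the floor
below which buoyancy distorts flipper beating. Depth at stroke times is
sample-and-hold from the 1 Hz channel, keeping it causally consistent
with the logger. This threshold rule is this package's explicit
formalization of a procedure that is qualitative in the field literature.
Hunting efficiency = flagged dives / all dives; it indexes prey
*encounter*, not consumption.

## Thermal profiles and thermocline

For each clock hour (00:00–00:59, …) with at least one dive deeper than
25 m, the deepest such dive contributes an hourly profile: descent and
ascent (depth, lag-corrected temperature) samples pooled — bottom-phase
samples excluded — and averaged in 2-m bins [2k, 2k+2) with centers
2k+1 m. Hourly profiles are then averaged per bird: per bin, mean and SD
across the hourly profiles populating it (SD of a single source is
reported as 0 so downstream tables stay total), unpopulated bins omitted.

Thermocline detection replaces visual identification with an explicit
two-stage rule:

1. **Screening.** The binned profile is smoothed with a 3-bin moving
   average and between-bin cooling gradients computed. Candidate zones
   are contiguous runs of bin pairs cooling at ≥ 0.05 °C m⁻¹ — runs may
   bridge one still-cooling sub-threshold pair, since with 0.05 °C bin
   noise the pairwise gradient noise (~0.035 °C m⁻¹ unsmoothed) is the
   same order as the threshold — with cumulative unsmoothed drop
   ≥ 0.4 °C. The largest-drop run wins. The 0.05 °C m⁻¹ / 0.4 °C
   defaults separate genuine gradient zones from quantization and
   binning jitter; both are config keys. The minimum-drop guard is this
   package's own addition.
2. **Refinement.** Bin noise can push the edge of a gradient run one bin
   out, so the run's bounds are sharpened by least-squares fitting of the
   warm/ramp/cold piecewise-linear model over a 0.25 m breakpoint grid
   around the run (the warm and cold temperatures solve in closed form
   per candidate). The fit is exact on noise-free profiles, so clean
   worked cases are unchanged.

If the winning run reaches the profile's deepest pair, the thermocline
bottom lies below the profiled water and `bottom_undetected` is set
rather than a bottom depth. Profiles with fewer than 3 bins return
"absent, insufficient data". Under the randomized recovery conditions
used in the tests (top 20–50 m, thickness 5–20 m, drop 1–3 °C, 0.05 °C
bin noise) the detector localizes both bounds within one 2-m bin in
≈ 98% of stratified profiles with no false positives on mixed profiles;
residual failures are extreme thick-and-weak bands (≤ 0.06 °C m⁻¹) or
bands abutting the profiled bottom.

## Weekly summaries

Trips are assigned to fixed 7-day weeks from the study start date
(default 13 Nov 2005, 5 weeks): week = 1 + ⌊days since start / 7⌋, dates
outside the window rejected. Weekly tables report mean ± SE (sd/√n,
ddof = 1; SE of a single trip reported as 0). GLMM/post-hoc inference is
deliberately out of scope — the package's value is the signal-processing
chain — so the module exports a tidy long table (one row per trip per
metric, with optional explicit log transforms) shaped for external
mixed-model tooling.

## Problem sizes and known limitations

The test suite runs the full chain on trips of 80–600 dives and on 400
synthetic profiles; these sizes give binomial/recovery margins comfortably
inside the asserted tolerances while keeping the suite fast. Limitations:
no hydrodynamic or buoyancy modelling of the bird, no horizontal movement,
no prey-field dynamics beyond per-dive pursuit probabilities, no
oceanographic mixed-layer criteria beyond the gradient rule, and no
inference layer. The stroke-amplitude threshold and the thermocline
gradient/drop parameters are explicit formalizations of procedures that
were qualitative in the original field setting; conclusions drawn from
them on real data should check sensitivity to those config keys.
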