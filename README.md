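# divetherm

Analysis of animal-borne logger data from diving seabirds — specifically
little penguins (*Eudyptula minor*) carrying depth/temperature/acceleration
loggers on one-day foraging trips — linking foraging performance to the
thermal structure of the water column. The package takes raw 1 Hz
(depth, temperature) and 32 Hz (surge, heave acceleration) channels and
produces:

- **Dive metrics** — dive detection (max depth > 1 m), segmentation into
  descent / bottom / ascent (bottom = first-to-last sample with vertical
  rate |dz/dt| < 0.25 m s⁻¹), and trip-level statistics (dive count, mean
  depth, time underwater, bottom-phase proportion, deep-dive fraction).
- **Hunting efficiency** — flipper strokes extracted from the heave axis
  after low/high frequency separation; runs of strokes with amplitude above
  the bird's normal diving amplitude (median + 3·MAD, at depths > 10 m) are
  a proxy for prey encounter and pursuit. Hunting efficiency is the
  fraction of dives with at least one such period.
- **Thermal profiles and thermoclines** — temperature corrected for the
  sensor's first-order lag (T₀.₉ ≈ 15 s, τ = T₀.₉/ln 10), hourly vertical
  profiles from each clock hour's deepest dive (> 25 m, descent + ascent
  samples), averaged into one per-bird profile (mean ± SD every 2 m), on
  which a thermocline — a zone of rapid temperature decrease — is detected
  and localized.
- **Weekly summaries** — trips grouped into fixed 7-day study weeks with
  mean ± SE tables, plus tidy long-format exports for external mixed-model
  statistics.
- **A synthetic-trip simulator** — trapezoid/V dives, sinusoidal stroke
  bursts with elevated amplitude during pursuits, a stratified or mixed
  water column, and a faithful sensor model (0.05 m depth and 0.01 °C
  temperature quantization at 1 Hz, ±30 m s⁻² clipping at 32 Hz,
  first-order temperature lag). Every embedded event is returned as ground
  truth, so the whole chain is testable without field data.

## Worked example

```python
import divetherm as dt

scn = dt.TripScenario(
    n_dives=600,
    depth_modes=((0.6, 10.0, 3.0), (0.4, 32.0, 6.0)),
    pursuit_probability=0.4,
    seed=1,
    water_column=dt.WaterColumnSpec(surface_temp=17.0, deep_temp=14.0,
                                    thermocline_top=24.0,
                                    thermocline_bottom=40.0),
)
rec, truth = dt.simulate_trip(scn)

t, d = rec.slow["time_s"].to_numpy(), rec.slow["depth_m"].to_numpy()
dives = dt.detect_dives(t, d)
metrics = dt.trip_metrics(dives)

_, high = dt.separate_components(rec.fast["heave_ms2"].to_numpy(),
                                 rate=32.0, cutoff=1.0)
strokes = dt.detect_strokes(rec.fast["time_s"].to_numpy(), high)
segments = dt.flag_prey_encounters(strokes, dives, t, d)
metrics.hunting_efficiency = dt.hunting_efficiency(dives, segments)

corrected = dt.correct_temperature_lag(t, rec.slow["temp_c"].to_numpy(),
                                       rec.sensors)
hourly = dt.extract_hourly_profiles(rec, dives, corrected)
profile = dt.aggregate_bird_profile(hourly, rec.bird_id, rec.date)
tc = dt.detect_thermocline(profile)
```

Output:

```
dives detected        600  (truth 600)
mean dive depth       18.3 m
time underwater       7.24 h
bottom proportion     0.15
deep dives (>25 m)    0.34
hunting efficiency    0.227  (pursuit prob 0.4)
thermocline present   True
thermocline bounds    24.2-40.2 m  (truth 24-40 m)
```

All 600 simulated dives are recovered; the detected thermocline bounds land
within a fraction of a 2-m bin of the simulated 24–40 m band. Hunting
efficiency (0.227) is below the per-dive pursuit probability because only
dives deeper than the 12 m pursuit floor can host a pursuit — it matches
the true fraction of pursuit dives in the ground truth (136/600 = 0.227)
exactly.

The same pipeline is available from the shell:

```bash
divetherm --out-dir out simulate scenario.yaml
divetherm --out-dir out dives     sim_2005-11-13
divetherm --out-dir out strokes   sim_2005-11-13
divetherm --out-dir out profile   sim_2005-11-13 --plot
divetherm --out-dir out summarize out/*_metrics.json --start 2005-11-13
```

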