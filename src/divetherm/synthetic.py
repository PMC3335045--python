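"""Synthetic foraging-trip generator with known ground truth.

Little penguins at guard phase make one-day foraging trips of several
hundred dives over a 60-80 m shelf water column.  An animal-borne logger
samples depth and water temperature at 1 Hz and bi-axial acceleration
(surge = longitudinal, heave = dorso-ventral) at 32 Hz.  This module
simulates such trips: a water column with an optional thermocline, a dive
trajectory per dive (trapezoidal U-dives or V-dives), flipper-stroke
oscillations on the heave axis with elevated amplitude during prey-pursuit
segments, and a faithful sensor model (depth/temperature quantization,
first-order temperature lag, acceleration clipping).  Every embedded event
is recorded in a :class:`GroundTruth` so the analysis chain can be tested
for recovery.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import lfilter

LN10 = float(np.log(10.0))

__all__ = [
    "WaterColumnSpec",
    "WaterColumn",
    "SensorSpec",
    "TripScenario",
    "GroundTruth",
    "TripRecording",
    "make_water_column",
    "apply_sensor_model",
    "simulate_trip",
]


# ---------------------------------------------------------------------------
# specifications
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WaterColumnSpec:
    """Vertical thermal structure of the foraging zone.

    A stratified column is warm (``surface_temp``) above ``thermocline_top``,
    cold (``deep_temp``) below ``thermocline_bottom`` and decreases
    monotonically across the band.  A mixed column is isothermal.
    ``noise_sd`` is the standard deviation (degC) of additive measurement /
    microstructure noise applied when temperatures are sampled.
    """

    surface_temp: float = 17.0
    deep_temp: float = 14.0
    thermocline_top: float | None = 24.0
    thermocline_bottom: float | None = 40.0
    mixed: bool = False
    seabed_depth: float = 70.0
    noise_sd: float = 0.05

    def validate(self) -> None:
        if not (10.0 <= self.seabed_depth <= 200.0):
            raise ValueError(f"implausible seabed depth {self.seabed_depth} m")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.mixed:
            return
        if self.thermocline_top is None or self.thermocline_bottom is None:
            raise ValueError("stratified column requires thermocline bounds")
        if not (0.0 < self.thermocline_top < self.thermocline_bottom <= self.seabed_depth):
            raise ValueError(
                "thermocline band must satisfy 0 < top < bottom <= seabed "
                f"(got {self.thermocline_top}-{self.thermocline_bottom} m)"
            )
        if not self.surface_temp > self.deep_temp:
            raise ValueError("stratified column requires surface_temp > deep_temp")


@dataclass(frozen=True)
class SensorSpec:
    """Logger physics: resolutions, rates, range and thermal response.

    ``t90`` is the time the temperature sensor takes to reach 90% of a step
    change; the equivalent first-order time constant is
    ``tau = t90 / ln(10)`` (about 6.5 s for t90 = 15 s).
    """

    depth_resolution: float = 0.05     # m
    temp_resolution: float = 0.01      # degC
    slow_rate: float = 1.0             # Hz (depth, temperature)
    accel_rate: float = 32.0           # Hz
    accel_min: float = -30.0           # m s^-2
    accel_max: float = 30.0            # m s^-2
    t90: float = 15.0                  # s

    def __post_init__(self) -> None:
        if min(self.depth_resolution, self.temp_resolution) <= 0:
            raise ValueError("resolutions must be > 0")
        if min(self.slow_rate, self.accel_rate) <= 0:
            raise ValueError("sample rates must be > 0")
        if not self.accel_min < self.accel_max:
            raise ValueError("accel_min must be < accel_max")
        if self.t90 < 0:
            raise ValueError("t90 must be >= 0")

    @property
    def tau(self) -> float:
        """First-order time constant (s) of the temperature sensor."""
        return self.t90 / LN10


@dataclass(frozen=True)
class TripScenario:
    """Configuration of one simulated foraging trip.

    Dive max depths are drawn from a mixture of truncated normal modes
    ``depth_modes = ((weight, mean_m, sd_m), ...)`` clipped to
    ``[min_depth, seabed - 1]``.  Each dive descends and ascends at a
    constant rate; U-dives hold a flat bottom whose duration is exponential
    with mean ``bottom_duration_mean``; V-dives have zero bottom time
    (unless a pursuit forces a short bottom to live in).

    A dive hosts a prey-pursuit segment with probability
    ``pursuit_probability`` provided its max depth lies inside
    ``pursuit_depth_range``.  If ``aggregated_pursuit_probability`` is set
    and the column is stratified, dives reaching the layer just above the
    thermocline (within ``prey_layer_thickness`` m of its top) use that
    probability instead — prey aggregating against the thermocline.
    During a pursuit the stroke amplitude is multiplied by
    ``pursuit_amplitude_multiplier``.
    """

    n_dives: int = 600
    depth_modes: tuple[tuple[float, float, float], ...] = (
        (0.85, 8.0, 3.0),
        (0.15, 35.0, 8.0),
    )
    min_depth: float = 2.0
    dive_shape: str = "U"              # "U" or "V"
    bottom_duration_mean: float = 8.0  # s
    descent_rate: float = 1.0          # m s^-1
    ascent_rate: float = 1.0           # m s^-1
    surface_interval_mean: float = 20.0  # s
    stroke_frequency: float = 2.5      # Hz
    baseline_stroke_amplitude: float = 2.0  # m s^-2 (half amplitude)
    accel_noise_sd: float = 0.2        # m s^-2
    pursuit_probability: float = 0.3
    pursuit_amplitude_multiplier: float = 2.0
    pursuit_depth_range: tuple[float, float] = (12.0, 60.0)
    aggregated_pursuit_probability: float | None = None
    prey_layer_thickness: float = 8.0  # m above thermocline top
    water_column: WaterColumnSpec = field(default_factory=WaterColumnSpec)
    sensors: SensorSpec = field(default_factory=SensorSpec)
    start_seconds: int = 6 * 3600      # trip start, seconds after midnight
    bird_id: str = "sim"
    date: _dt.date = _dt.date(2005, 11, 13)
    seed: int = 0

    def validate(self) -> None:
        self.water_column.validate()
        if self.n_dives < 0:
            raise ValueError("n_dives must be >= 0")
        if not 0.0 <= self.pursuit_probability <= 1.0:
            raise ValueError("pursuit_probability must lie in [0, 1]")
        if self.aggregated_pursuit_probability is not None and not (
            0.0 <= self.aggregated_pursuit_probability <= 1.0
        ):
            raise ValueError("aggregated_pursuit_probability must lie in [0, 1]")
        if not self.stroke_frequency < self.sensors.accel_rate / 2:
            raise ValueError("stroke_frequency must be below accelerometer Nyquist")
        if not self.pursuit_amplitude_multiplier > 1.0:
            raise ValueError("pursuit_amplitude_multiplier must be > 1")
        if self.dive_shape not in ("U", "V"):
            raise ValueError(f"unknown dive_shape {self.dive_shape!r}")
        if min(self.descent_rate, self.ascent_rate) <= 0:
            raise ValueError("vertical rates must be > 0")
        w = sum(m[0] for m in self.depth_modes)
        if not w > 0:
            raise ValueError("depth mode weights must sum to > 0")
        deepest = max(m[1] for m in self.depth_modes)
        if deepest > self.water_column.seabed_depth:
            raise ValueError("requested dive depths exceed the seabed")


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class GroundTruth:
    """True events embedded in a simulated trip."""

    dive_intervals: np.ndarray          # (n, 2) start/end times, s
    dive_max_depths: np.ndarray         # (n,) m
    pursuit_segments: list[dict]        # dive_index, start, end, depth
    stroke_times: np.ndarray            # s, time of each stroke-cycle peak
    true_column: "WaterColumn"

    @property
    def n_dives(self) -> int:
        return len(self.dive_max_depths)

    @property
    def pursuit_dive_indices(self) -> set[int]:
        return {int(s["dive_index"]) for s in self.pursuit_segments}


@dataclass
class TripRecording:
    """Logger output for one trip: 1 Hz slow and 32 Hz fast channels.

    ``slow`` has columns ``time_s, depth_m, temp_c``; ``fast`` has
    ``time_s, surge_ms2, heave_ms2``.  Times are seconds from trip start;
    ``start_seconds`` anchors them to the clock for hourly grouping.
    """

    bird_id: str
    date: _dt.date
    slow: pd.DataFrame
    fast: pd.DataFrame
    start_seconds: int = 6 * 3600
    sensors: SensorSpec = field(default_factory=SensorSpec)


# ---------------------------------------------------------------------------
# water column
# ---------------------------------------------------------------------------

class WaterColumn:
    """Temperature-at-depth function built from a :class:`WaterColumnSpec`."""

    def __init__(self, spec: WaterColumnSpec, shape: str = "linear") -> None:
        spec.validate()
        if shape not in ("linear", "tanh"):
            raise ValueError(f"unknown transition shape {shape!r}")
        self.spec = spec
        self.shape = shape

    def temperature(self, depth, rng: np.random.Generator | None = None):
        """True water temperature (degC) at ``depth`` (m, scalar or array).

        With ``rng`` given and ``noise_sd > 0``, adds independent Gaussian
        noise per sample.
        """
        d = np.asarray(depth, dtype=float)
        s = self.spec
        if s.mixed:
            t = np.full_like(d, s.surface_temp)
        elif self.shape == "linear":
            t = np.interp(
                d,
                [0.0, s.thermocline_top, s.thermocline_bottom, s.seabed_depth],
                [s.surface_temp, s.surface_temp, s.deep_temp, s.deep_temp],
            )
        else:  # tanh
            mid = 0.5 * (s.thermocline_top + s.thermocline_bottom)
            width = s.thermocline_bottom - s.thermocline_top
            frac = 0.5 * (1.0 + np.tanh(4.0 * (d - mid) / width))
            t = s.surface_temp + (s.deep_temp - s.surface_temp) * frac
        if rng is not None and s.noise_sd > 0:
            t = t + rng.normal(0.0, s.noise_sd, size=t.shape)
        return t if t.ndim else float(t)

    def table(self, dz: float = 1.0) -> pd.DataFrame:
        """Tabulate the noise-free profile every ``dz`` m down to the seabed."""
        z = np.arange(0.0, self.spec.seabed_depth + dz / 2, dz)
        return pd.DataFrame({"depth_m": z, "temp_c": self.temperature(z)})


def make_water_column(spec: WaterColumnSpec, shape: str = "linear") -> WaterColumn:
    """Build the temperature-at-depth function for a column specification."""
    return WaterColumn(spec, shape=shape)


# ---------------------------------------------------------------------------
# sensor model
# ---------------------------------------------------------------------------

def _quantize(values: np.ndarray, resolution: float) -> np.ndarray:
    return np.round(np.asarray(values, dtype=float) / resolution) * resolution


def first_order_lag(values: np.ndarray, dt: float, tau: float) -> np.ndarray:
    """Exact zero-order-hold discretization of a first-order sensor.

    ``y[n+1] = x[n] + (y[n] - x[n]) * exp(-dt/tau)`` with ``y[0] = x[0]``:
    the input is held over each sampling interval, so a step applied at
    sample time t0 first reaches 90% of its amplitude at ``t0 + t90``.
    """
    x = np.asarray(values, dtype=float)
    if tau <= 0 or x.size == 0:
        return x.copy()
    b = float(np.exp(-dt / tau))
    # y[n] = (1-b) x[n-1] + b y[n-1]
    y, _ = lfilter([0.0, 1.0 - b], [1.0, -b], x, zi=np.array([x[0]]))
    return y


def _decimate_hold(time: np.ndarray, values: np.ndarray, rate_out: float):
    """Subsample a series to ``rate_out`` by instantaneous pick-off."""
    t = np.asarray(time, dtype=float)
    if t.size < 2:
        return t.copy(), np.asarray(values, dtype=float).copy()
    dt_in = float(np.median(np.diff(t)))
    step = max(1, int(round(1.0 / (rate_out * dt_in))))
    return t[::step], np.asarray(values, dtype=float)[::step]


def apply_sensor_model(time, values, channel: str, sensors: SensorSpec):
    """Pass a true physical series through the logger's sensor physics.

    Parameters
    ----------
    time, values
        True series sampled at or above the channel's output rate.
    channel
        ``"depth"`` (quantized to ``depth_resolution`` at ``slow_rate``),
        ``"temperature"`` (first-order lag with ``tau = t90/ln 10``, then
        quantized to ``temp_resolution`` at ``slow_rate``) or
        ``"acceleration"`` (clipped to ``[accel_min, accel_max]`` at
        ``accel_rate``).

    Returns
    -------
    (time_out, values_out) arrays at the channel's output rate.
    """
    t = np.asarray(time, dtype=float)
    x = np.asarray(values, dtype=float)
    if t.shape != x.shape:
        raise ValueError("time and values must have the same shape")
    if channel == "temperature":
        dt = float(np.median(np.diff(t))) if t.size > 1 else 1.0 / sensors.slow_rate
        lagged = first_order_lag(x, dt, sensors.tau)
        t_out, v = _decimate_hold(t, lagged, sensors.slow_rate)
        return t_out, _quantize(v, sensors.temp_resolution)
    if channel == "depth":
        t_out, v = _decimate_hold(t, x, sensors.slow_rate)
        return t_out, _quantize(v, sensors.depth_resolution)
    if channel == "acceleration":
        t_out, v = _decimate_hold(t, x, sensors.accel_rate)
        return t_out, np.clip(v, sensors.accel_min, sensors.accel_max)
    raise ValueError(f"unknown channel {channel!r}")


# ---------------------------------------------------------------------------
# trip simulation
# ---------------------------------------------------------------------------

def _sample_dive_depths(scn: TripScenario, rng: np.random.Generator) -> np.ndarray:
    weights = np.array([m[0] for m in scn.depth_modes], dtype=float)
    weights /= weights.sum()
    means = np.array([m[1] for m in scn.depth_modes])
    sds = np.array([m[2] for m in scn.depth_modes])
    which = rng.choice(len(weights), size=scn.n_dives, p=weights)
    depths = rng.normal(means[which], sds[which])
    hi = scn.water_column.seabed_depth - 1.0
    return np.clip(depths, scn.min_depth, hi)


def simulate_trip(scenario: TripScenario) -> tuple[TripRecording, GroundTruth]:
    """Simulate one foraging trip and return the recording plus ground truth.

    The 1 Hz depth trajectory is built dive by dive (trapezoid/V shapes on
    the sample grid, exact 0 m at the surface), temperature is sampled from
    the water column at the instantaneous true depth, and the 32 Hz heave
    channel carries a sinusoidal flipper-stroke signal during descent and
    bottom phases (penguins ascend passively) with amplitude multiplied
    during pursuit segments.  All channels then pass through
    :func:`apply_sensor_model`.  The same scenario and seed give
    bit-identical output.
    """
    scenario.validate()
    scn = scenario
    rng = np.random.default_rng(scn.seed)
    sensors = scn.sensors
    column = make_water_column(scn.water_column)

    lead = 30  # s of surface before the first dive and after the last
    depth_chunks: list[np.ndarray] = [np.zeros(lead)]
    dive_rows: list[tuple[float, float, float]] = []   # start, end, max depth
    phase_bounds: list[tuple[int, int, int, int]] = []  # sample idx: d0, b0, b1, a1
    pursuit_segments: list[dict] = []
    pursuits_pending: list[tuple[int, float, float]] = []  # dive idx, rel t0, t1

    if not scn.water_column.mixed:
        layer_top = scn.water_column.thermocline_top - scn.prey_layer_thickness
        layer_bot = scn.water_column.thermocline_top
    else:
        layer_top = layer_bot = None

    cursor = lead
    depths = _sample_dive_depths(scn, rng)
    for i in range(scn.n_dives):
        depth = float(depths[i])
        nd = max(1, int(np.ceil(depth / scn.descent_rate)))
        na = max(1, int(np.ceil(depth / scn.ascent_rate)))
        if scn.dive_shape == "U":
            nb = int(round(rng.exponential(scn.bottom_duration_mean)))
        else:
            nb = 0
        lo, hi = scn.pursuit_depth_range
        eligible = lo <= depth <= hi
        p = scn.pursuit_probability
        if (
            scn.aggregated_pursuit_probability is not None
            and layer_top is not None
            and layer_top <= depth <= layer_bot
        ):
            p = scn.aggregated_pursuit_probability
        has_pursuit = eligible and (rng.random() < p)
        if has_pursuit:
            pdur = int(rng.integers(3, 7))  # s of sustained pursuit beating
            nb = max(nb, pdur + 2)
        descent = np.minimum(scn.descent_rate * np.arange(1, nd + 1), depth)
        bottom = np.full(nb, depth)
        ascent = np.maximum(depth - scn.ascent_rate * np.arange(1, na + 1), 0.0)
        profile = np.concatenate([descent, bottom, ascent])
        start = float(cursor)                      # first submerged sample
        end = float(cursor + len(profile) - 1)     # last submerged sample
        submerged = profile > 0
        if not submerged[-1]:
            end = float(cursor + np.flatnonzero(submerged)[-1])
        dive_rows.append((start, end, depth))
        b0 = cursor + nd               # first flat-bottom sample
        b1 = cursor + nd + nb          # last flat-bottom sample
        phase_bounds.append((cursor, b0, b1, cursor + len(profile) - 1))
        if has_pursuit:
            off = int(rng.integers(0, max(1, nb - pdur)))
            t0 = float(b0 + off)
            t1 = float(t0 + pdur)
            pursuit_segments.append(
                {"dive_index": i, "start": t0, "end": t1, "depth": depth}
            )
            pursuits_pending.append((i, t0, t1))
        gap = max(1, int(round(rng.exponential(scn.surface_interval_mean))))
        depth_chunks.append(profile)
        depth_chunks.append(np.zeros(gap))
        cursor += len(profile) + gap

    depth_chunks.append(np.zeros(lead))
    true_depth = np.concatenate(depth_chunks)
    n_slow = len(true_depth)
    t_slow = np.arange(n_slow, dtype=float) / sensors.slow_rate

    true_temp = column.temperature(true_depth, rng=rng)

    # fast channels -------------------------------------------------------
    n_fast = int(n_slow * sensors.accel_rate / sensors.slow_rate)
    t_fast = np.arange(n_fast, dtype=float) / sensors.accel_rate
    amp = np.zeros(n_fast)
    stroke = np.zeros(n_fast)
    stroke_times: list[np.ndarray] = []
    fs = sensors.accel_rate
    f = scn.stroke_frequency
    for (d0, _b0, b1, _a1) in phase_bounds:
        # strokes during descent + bottom, continuous phase within the bout
        j0 = int(d0 * fs)
        j1 = min(n_fast, int((b1 + 1) * fs))
        if j1 <= j0:
            continue
        amp[j0:j1] = scn.baseline_stroke_amplitude
        tt = t_fast[j0:j1]
        stroke[j0:j1] = np.sin(2 * np.pi * f * (tt - tt[0]))
        n_cycles = int(np.floor((tt[-1] - tt[0]) * f))
        stroke_times.append(tt[0] + (np.arange(n_cycles) + 0.25) / f)
    for (_i, t0, t1) in pursuits_pending:
        j0, j1 = int(t0 * fs), int(t1 * fs)
        amp[j0:j1] *= scn.pursuit_amplitude_multiplier

    posture = 9.8 + 0.3 * np.sin(2 * np.pi * 0.02 * t_fast)
    heave_true = posture + amp * stroke + rng.normal(0.0, scn.accel_noise_sd, n_fast)
    surge_true = 0.3 * amp * stroke + rng.normal(0.0, scn.accel_noise_sd, n_fast)

    # sensor model --------------------------------------------------------
    _, depth_m = apply_sensor_model(t_slow, true_depth, "depth", sensors)
    _, temp_m = apply_sensor_model(t_slow, true_temp, "temperature", sensors)
    _, heave_m = apply_sensor_model(t_fast, heave_true, "acceleration", sensors)
    _, surge_m = apply_sensor_model(t_fast, surge_true, "acceleration", sensors)

    slow = pd.DataFrame({"time_s": t_slow, "depth_m": depth_m, "temp_c": temp_m})
    fast = pd.DataFrame({"time_s": t_fast, "surge_ms2": surge_m, "heave_ms2": heave_m})
    recording = TripRecording(
        bird_id=scn.bird_id, date=scn.date, slow=slow, fast=fast,
        start_seconds=scn.start_seconds, sensors=sensors,
    )
    truth = GroundTruth(
        dive_intervals=np.array([(s, e) for s, e, _ in dive_rows]).reshape(-1, 2),
        dive_max_depths=np.array([d for _, _, d in dive_rows]),
        pursuit_segments=pursuit_segments,
        stroke_times=(
            np.concatenate(stroke_times) if stroke_times else np.empty(0)
        ),
        true_column=column,
    )
    return recording, truth
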