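"""Water-column thermal structure from logger temperature records.

The logger's temperature sensor responds slowly (T0.9 ~ 15 s), so the raw
record lags the water the bird is actually in.  After inverting that lag,
each clock hour's deepest dive (if deeper than 25 m) contributes a vertical
temperature profile from its descent and ascent samples; the hourly
profiles are averaged into one per-bird profile with mean +/- SD every
2 m, on which a thermocline — a zone of rapid temperature decrease — is
detected as a sustained-gradient run.
"""

from __future__ import annotations

import datetime as _dt
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dives import AnalysisConfig, Dive
from .synthetic import SensorSpec, TripRecording

__all__ = [
    "ThermalProfile",
    "Thermocline",
    "correct_temperature_lag",
    "extract_hourly_profiles",
    "aggregate_bird_profile",
    "detect_thermocline",
    "plot_profile",
]


@dataclass
class ThermalProfile:
    """Per-bird vertical profile: mean +/- SD temperature per depth bin.

    ``bins`` columns: ``bin_center_m, mean_temp_c, sd_temp_c, n_sources``
    (number of hourly profiles contributing), sorted by depth.
    """

    bird_id: str
    date: _dt.date
    bins: pd.DataFrame
    max_profiled_depth: float   # deepest populated bin center, m


@dataclass
class Thermocline:
    present: bool
    top_depth: float | None = None       # m, upper bound of the gradient zone
    bottom_depth: float | None = None    # m, None when bottom_undetected
    bottom_undetected: bool = False
    max_gradient: float = 0.0            # degC per m (decrease positive)
    total_drop: float = 0.0              # degC across the zone
    insufficient_data: bool = False


def correct_temperature_lag(
    time,
    temp,
    sensors: SensorSpec = SensorSpec(),
    window_s: float = 5.0,
) -> np.ndarray:
    """Invert the sensor's first-order lag on a 1 Hz temperature series.

    ``corrected(t) = measured(t) + tau * d(measured)/dt`` with
    ``tau = t90 / ln 10``.  The derivative is a centered difference across
    ``window_s`` (samples +/- window_s/2 apart, edges replicated): wide
    enough to keep 0.01 degC quantization noise from being amplified by
    tau, short enough to follow a ~1 m/s descent through 2-m bins.
    ``t90 = 0`` makes this the identity.
    """
    t = np.asarray(time, dtype=float)
    m = np.asarray(temp, dtype=float)
    if sensors.t90 == 0 or m.size < 3:
        return m.copy()
    dt = float(np.median(np.diff(t))) if t.size > 1 else 1.0
    half = max(1, int(round(window_s / 2.0 / dt)))
    padded = np.pad(m, half, mode="edge")
    deriv = (padded[2 * half:] - padded[:-2 * half]) / (2 * half * dt)
    return m + sensors.tau * deriv


def extract_hourly_profiles(
    trip: TripRecording,
    dives: list[Dive],
    corrected_temp,
    config: AnalysisConfig = AnalysisConfig(),
) -> list[pd.DataFrame]:
    """Raw hourly profiles from each clock hour's deepest deep dive.

    For each clock hour (00:00-00:59, ...) containing at least one dive
    deeper than ``deep_dive_depth``, the deepest such dive contributes a
    profile: its descent- and ascent-phase (depth, temperature) samples
    pooled and averaged in ``bin_width`` depth bins ``[2k, 2k+2)`` with
    centers ``2k+1``.  Bottom-phase samples are excluded.  Hours without a
    qualifying dive yield nothing; a trip without any deep dive returns an
    empty list with a warning (no profile possible).

    Each returned DataFrame has columns ``bin_center_m, temp_c`` and the
    source hour in ``.attrs["hour"]``.
    """
    depth = trip.slow["depth_m"].to_numpy()
    tempc = np.asarray(corrected_temp, dtype=float)
    deep = [d for d in dives if d.max_depth > config.deep_dive_depth]
    if not deep:
        warnings.warn("no dive deeper than deep_dive_depth; no thermal profile",
                      stacklevel=2)
        return []
    by_hour: dict[int, Dive] = {}
    for d in deep:
        hour = int((trip.start_seconds + d.start) // 3600)
        if hour not in by_hour or d.max_depth > by_hour[hour].max_depth:
            by_hour[hour] = d
    profiles: list[pd.DataFrame] = []
    bw = config.bin_width
    for hour in sorted(by_hour):
        d = by_hour[hour]
        idx = np.r_[d.i0:d.ib0, d.ib1 + 1:d.i1 + 1]   # descent + ascent samples
        if idx.size == 0:
            continue
        z = depth[idx]
        centers = np.floor(z / bw) * bw + bw / 2.0
        df = (
            pd.DataFrame({"bin_center_m": centers, "temp_c": tempc[idx]})
            .groupby("bin_center_m", as_index=False)["temp_c"].mean()
        )
        df.attrs["hour"] = hour
        profiles.append(df)
    return profiles


def aggregate_bird_profile(
    hourly_profiles: list[pd.DataFrame],
    bird_id: str = "",
    date: _dt.date | None = None,
    config: AnalysisConfig = AnalysisConfig(),
) -> ThermalProfile | None:
    """Average hourly profiles into the bird's single thermal profile.

    Per depth bin: mean and SD across the hourly profiles populating it
    (SD = 0 for a single source so downstream tables stay total); bins
    with no source are omitted.  Returns None for empty input.
    """
    if not hourly_profiles:
        return None
    allp = pd.concat(hourly_profiles, ignore_index=True)
    g = allp.groupby("bin_center_m")["temp_c"]
    bins = pd.DataFrame({
        "bin_center_m": g.mean().index.to_numpy(),
        "mean_temp_c": g.mean().to_numpy(),
        "sd_temp_c": g.std(ddof=1).fillna(0.0).to_numpy(),
        "n_sources": g.size().to_numpy(),
    }).sort_values("bin_center_m", ignore_index=True)
    return ThermalProfile(
        bird_id=bird_id,
        date=date or _dt.date.today(),
        bins=bins,
        max_profiled_depth=float(bins["bin_center_m"].iloc[-1]),
    )


def _refine_bounds(
    z: np.ndarray,
    temp: np.ndarray,
    top0: float,
    bottom0: float,
    span: float = 4.0,
    step: float = 0.25,
) -> tuple[float, float]:
    """Sharpen thermocline bounds by fitting the ramp model to the bins.

    The underlying column is warm-constant / linear ramp / cold-constant;
    a grid of (top, bottom) breakpoints around the screened run is scored
    by least squares (the warm/cold temperatures solve in closed form per
    candidate), and the best-fitting breakpoints are returned.  Exact on
    noise-free piecewise-linear profiles.
    """
    lo = max(float(z[0]), top0 - span)
    hi = min(float(z[-1]), bottom0 + span)
    tops = np.arange(lo, min(bottom0 + span, hi) + 1e-9, step)
    best = (np.inf, top0, bottom0)
    for zt in tops:
        bots = np.arange(max(zt + 1.0, bottom0 - span), hi + 1e-9, step)
        for zb in bots:
            w = np.clip((zb - z) / (zb - zt), 0.0, 1.0)
            x = np.column_stack([w, 1.0 - w])
            coef, *_ = np.linalg.lstsq(x, temp, rcond=None)
            if coef[0] <= coef[1]:   # must cool with depth
                continue
            sse = float(np.sum((x @ coef - temp) ** 2))
            if sse < best[0]:
                best = (sse, float(zt), float(zb))
    return best[1], best[2]


def detect_thermocline(
    profile: ThermalProfile,
    gradient_threshold: float | None = None,
    min_drop: float | None = None,
    config: AnalysisConfig = AnalysisConfig(),
    smooth_bins: int = 3,
    bridge_gaps: int = 1,
    refine: bool = True,
) -> Thermocline:
    """Locate a thermocline on a binned vertical profile.

    Two stages.  Screening: the profile is lightly smoothed
    (``smooth_bins``-bin moving average) and the between-bin cooling
    gradient computed; a thermocline is the contiguous run of bin pairs
    cooling at >= ``gradient_threshold`` (degC/m) — runs may bridge up to
    ``bridge_gaps`` consecutive sub-threshold pairs that are still
    cooling — whose cumulative (unsmoothed) drop is >= ``min_drop`` degC.
    Among qualifying runs the one with the largest drop wins; its bounds
    sit at the bin edges.  Refinement (``refine``): the bounds are
    sharpened by least-squares fitting of a warm/ramp/cold piecewise
    model around the run (bin noise can push the edge of a gradient run
    one bin out; the fit is exact on noise-free profiles).  If the run
    reaches the profile's deepest pair the bottom of the thermocline lies
    below the profiled water and ``bottom_undetected`` is set.  Fewer
    than 3 bins: absent, flagged insufficient.
    """
    thr = config.gradient_threshold if gradient_threshold is None else gradient_threshold
    drop_min = config.min_drop if min_drop is None else min_drop
    bins = profile.bins
    z = bins["bin_center_m"].to_numpy(dtype=float)
    temp = bins["mean_temp_c"].to_numpy(dtype=float)
    if z.size < 3:
        return Thermocline(present=False, insufficient_data=True)
    if smooth_bins > 1:
        half = smooth_bins // 2
        padded = np.pad(temp, half, mode="edge")
        kernel = np.ones(2 * half + 1) / (2 * half + 1)
        smoothed = np.convolve(padded, kernel, mode="valid")
    else:
        smoothed = temp
    dz = np.diff(z)
    grad = (smoothed[:-1] - smoothed[1:]) / dz          # cooling positive
    raw_grad = (temp[:-1] - temp[1:]) / dz
    qual = grad >= thr

    # assemble runs, bridging short still-cooling gaps
    runs: list[tuple[int, int]] = []
    i = 0
    n = qual.size
    while i < n:
        if not qual[i]:
            i += 1
            continue
        j = i
        while j + 1 < n:
            if qual[j + 1]:
                j += 1
                continue
            # try to bridge a short gap of still-cooling pairs
            g = j + 1
            while g < n and not qual[g] and g - j <= bridge_gaps and grad[g] > 0:
                g += 1
            if g < n and qual[g] and g - (j + 1) <= bridge_gaps:
                j = g
            else:
                break
        runs.append((i, j))
        i = j + 1

    best: tuple[float, int, int] | None = None
    for (r0, r1) in runs:
        drop = float(temp[r0] - temp[r1 + 1])
        if drop >= drop_min and (best is None or drop > best[0]):
            best = (drop, r0, r1)
    if best is None:
        return Thermocline(present=False)
    drop, r0, r1 = best
    top = float(0.5 * (z[r0] + z[r0 + 1]))
    undetected = r1 == n - 1
    bottom = None if undetected else float(0.5 * (z[r1] + z[r1 + 1]))
    if refine and not undetected:
        j0, j1 = max(0, r0 - 4), min(z.size, r1 + 6)
        top, bottom = _refine_bounds(z[j0:j1], temp[j0:j1], top, bottom)
    return Thermocline(
        present=True,
        top_depth=top,
        bottom_depth=bottom,
        bottom_undetected=undetected,
        max_gradient=float(raw_grad[r0:r1 + 1].max()),
        total_drop=drop,
    )


def plot_profile(profile: ThermalProfile, thermocline: Thermocline | None = None,
                 ax=None):
    """Depth-temperature panel (depth increasing downward, +/- SD bars);
    the thermocline zone, if present, is framed."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(3.5, 5))
    b = profile.bins
    ax.errorbar(b["mean_temp_c"], b["bin_center_m"], xerr=b["sd_temp_c"],
                fmt="o-", ms=3, lw=1, capsize=2)
    if thermocline is not None and thermocline.present:
        bot = thermocline.bottom_depth
        if bot is None:
            bot = profile.max_profiled_depth
        ax.axhspan(thermocline.top_depth, bot, facecolor="none",
                   edgecolor="k", lw=1.5)
    ax.invert_yaxis()
    ax.set_xlabel("Temperature (\N{DEGREE SIGN}C)")
    ax.set_ylabel("Depth (m)")
    ax.set_title(f"{profile.bird_id} {profile.date}")
    return ax
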