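"""Dive detection, phase segmentation and trip-level dive metrics.

A dive starts and ends at the water surface; because depth sensors are
inaccurate near the surface, only submergences whose maximum depth exceeds
1 m count as dives.  Each dive is split into descent / bottom / ascent:
the bottom phase runs from the first to the last sample at which the
magnitude of the vertical rate falls below 0.25 m s^-1 (little penguins
encounter most prey during the bottom phase).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AnalysisConfig",
    "Interval",
    "Dive",
    "TripMetrics",
    "zero_offset_correct",
    "detect_dives",
    "segment_phases",
    "trip_metrics",
]


@dataclass(frozen=True)
class AnalysisConfig:
    """Thresholds of the analysis chain (all depths in m, rates in m/s).

    ``min_dive_depth``: a submergence counts as a dive only if its max
    depth exceeds this (surface-accuracy rule).
    ``bottom_rate_threshold``: vertical-rate bound defining the bottom
    phase.  ``deep_dive_depth``: dives deeper than this are "deep" and the
    only source of thermal profiles.  ``prey_min_depth``: strokes above
    this depth are excluded from prey-encounter analysis (buoyancy affects
    flipper beating near the surface).  ``bin_width``: depth-bin width of
    thermal profiles.  ``surface_threshold``: depth above which a sample is
    considered submerged when splitting the record into submergences.
    """

    min_dive_depth: float = 1.0
    bottom_rate_threshold: float = 0.25
    deep_dive_depth: float = 25.0
    prey_min_depth: float = 10.0
    bin_width: float = 2.0
    surface_threshold: float = 0.1
    signed_rate: bool = False
    smooth_depth: bool = False
    # stroke / prey-encounter keys
    cutoff_hz: float = 1.0
    amplitude_k: float = 3.0
    min_run: int = 3
    stroke_noise_floor: float = 1.0
    # thermocline keys
    gradient_threshold: float = 0.05   # degC per m
    min_drop: float = 0.4              # degC

    def __post_init__(self) -> None:
        for name in ("min_dive_depth", "bottom_rate_threshold", "deep_dive_depth",
                     "prey_min_depth", "bin_width", "surface_threshold"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not self.prey_min_depth < self.deep_dive_depth:
            raise ValueError("prey_min_depth must be < deep_dive_depth")


@dataclass(frozen=True)
class Interval:
    start: float
    end: float

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass
class Dive:
    """One submergence with its phase partition.

    ``descent``/``bottom``/``ascent`` partition ``[start, end]``
    (``descent.end == bottom.start`` and ``bottom.end == ascent.start``, so
    the three durations always sum to ``duration``).  ``i0/i1`` and
    ``ib0/ib1`` are inclusive sample indices into the 1 Hz series of the
    whole dive and of the bottom phase (``ib1 < ib0`` when the bottom is
    empty).
    """

    index: int
    start: float
    end: float
    max_depth: float
    i0: int
    i1: int
    descent: Interval = field(default=Interval(0.0, 0.0))
    bottom: Interval = field(default=Interval(0.0, 0.0))
    ascent: Interval = field(default=Interval(0.0, 0.0))
    ib0: int = 0
    ib1: int = -1
    degenerate: bool = False

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass
class TripMetrics:
    """Per-trip dive statistics (hunting_efficiency filled downstream)."""

    n_dives: int = 0
    mean_dive_depth: float = 0.0       # m
    time_underwater: float = 0.0       # h
    bottom_proportion: float = 0.0     # fraction of underwater time
    deep_dive_fraction: float = 0.0    # fraction of dives > deep_dive_depth
    hunting_efficiency: float | None = None
    flagged_empty: bool = False


def zero_offset_correct(
    time: np.ndarray,
    depth: np.ndarray,
    window_s: float = 600.0,
    surface_band: float = 2.0,
) -> np.ndarray:
    """Remove slow surface drift from a depth record.

    Real pressure sensors drift, so the apparent depth of the surface
    wanders.  For each window the modal reading among near-surface samples
    (``< surface_band`` m) is taken as the surface offset; offsets are
    interpolated across windows and subtracted.  Windows without surface
    samples inherit the neighbouring offset.
    """
    t = np.asarray(time, dtype=float)
    d = np.asarray(depth, dtype=float)
    if d.size == 0:
        return d.copy()
    dt = float(np.median(np.diff(t))) if t.size > 1 else 1.0
    win = max(2, int(round(window_s / dt)))
    centers, offsets = [], []
    for j0 in range(0, d.size, win):
        chunk = d[j0:j0 + win]
        near = chunk[chunk < surface_band]
        if near.size == 0:
            continue
        vals, counts = np.unique(np.round(near, 3), return_counts=True)
        centers.append(t[min(j0 + win // 2, d.size - 1)])
        offsets.append(vals[np.argmax(counts)])
    if not centers:
        return d.copy()
    offset = np.interp(t, centers, offsets)
    return d - offset


def detect_dives(
    time: np.ndarray,
    depth: np.ndarray,
    config: AnalysisConfig = AnalysisConfig(),
) -> list[Dive]:
    """Detect dives on a 1 Hz depth series.

    Returns the maximal contiguous submergences (depth above
    ``surface_threshold``) whose maximum depth exceeds ``min_dive_depth``,
    ordered by start time and with phases already segmented.
    """
    t = np.asarray(time, dtype=float)
    d = np.asarray(depth, dtype=float)
    if t.shape != d.shape:
        raise ValueError("time and depth must have the same shape")
    if t.size > 1 and np.any(np.diff(t) <= 0):
        raise ValueError("timestamps must be strictly increasing")
    sub = d > config.surface_threshold
    if not sub.any():
        return []
    step = np.diff(sub.astype(np.int8))
    starts = list(np.flatnonzero(step == 1) + 1)
    ends = list(np.flatnonzero(step == -1))
    if sub[0]:
        starts.insert(0, 0)
    if sub[-1]:
        ends.append(d.size - 1)
    dives: list[Dive] = []
    for i0, i1 in zip(starts, ends):
        maxd = float(d[i0:i1 + 1].max())
        if maxd <= config.min_dive_depth:
            continue
        dive = Dive(index=len(dives), start=float(t[i0]), end=float(t[i1]),
                    max_depth=maxd, i0=int(i0), i1=int(i1))
        segment_phases(dive, t, d, config)
        dives.append(dive)
    return dives


def segment_phases(
    dive: Dive,
    time: np.ndarray,
    depth: np.ndarray,
    config: AnalysisConfig = AnalysisConfig(),
) -> tuple[Interval, Interval, Interval]:
    """Split a dive into descent / bottom / ascent in place.

    The vertical rate is the central difference of depth at 1 Hz
    (optionally after a 3-s moving average).  Bottom start/end are the
    first/last in-dive samples whose rate magnitude (or signed rate when
    ``config.signed_rate``) is below ``bottom_rate_threshold``; if no
    sample qualifies the dive splits at its deepest sample with an empty
    bottom.  Dives shorter than 3 samples degenerate to descent only.
    """
    t = np.asarray(time, dtype=float)[dive.i0:dive.i1 + 1]
    d = np.asarray(depth, dtype=float)[dive.i0:dive.i1 + 1]
    if d.size < 3:
        dive.descent = Interval(dive.start, dive.end)
        dive.bottom = Interval(dive.end, dive.end)
        dive.ascent = Interval(dive.end, dive.end)
        dive.ib0, dive.ib1 = dive.i1 + 1, dive.i1
        dive.degenerate = True
        return dive.descent, dive.bottom, dive.ascent
    if config.smooth_depth:
        kernel = np.ones(3) / 3.0
        d_rate = np.convolve(np.pad(d, 1, mode="edge"), kernel, mode="valid")
    else:
        d_rate = d
    rate = np.gradient(d_rate, t)
    cond = rate < config.bottom_rate_threshold if config.signed_rate \
        else np.abs(rate) < config.bottom_rate_threshold
    idx = np.flatnonzero(cond)
    if idx.size == 0:
        j = int(np.argmax(d))
        tb = float(t[j])
        dive.descent = Interval(dive.start, tb)
        dive.bottom = Interval(tb, tb)
        dive.ascent = Interval(tb, dive.end)
        dive.ib0, dive.ib1 = dive.i0 + j, dive.i0 + j - 1
    else:
        j0, j1 = int(idx[0]), int(idx[-1])
        dive.descent = Interval(dive.start, float(t[j0]))
        dive.bottom = Interval(float(t[j0]), float(t[j1]))
        dive.ascent = Interval(float(t[j1]), dive.end)
        dive.ib0, dive.ib1 = dive.i0 + j0, dive.i0 + j1
    return dive.descent, dive.bottom, dive.ascent


def trip_metrics(
    dives: list[Dive],
    config: AnalysisConfig = AnalysisConfig(),
) -> TripMetrics:
    """Trip-level dive statistics: count, mean max depth, time underwater
    (h), proportion of underwater time at the bottom, deep-dive fraction."""
    if not dives:
        warnings.warn("no dives in trip; metrics are all zero", stacklevel=2)
        return TripMetrics(flagged_empty=True)
    durations = np.array([d.duration for d in dives])
    bottoms = np.array([d.bottom.duration for d in dives])
    depths = np.array([d.max_depth for d in dives])
    total = float(durations.sum())
    return TripMetrics(
        n_dives=len(dives),
        mean_dive_depth=float(depths.mean()),
        time_underwater=total / 3600.0,
        bottom_proportion=float(bottoms.sum() / total) if total > 0 else 0.0,
        deep_dive_fraction=float(np.mean(depths > config.deep_dive_depth)),
    )
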