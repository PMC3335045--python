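"""Frequency separation, stroke extraction and prey-encounter flagging."""

import numpy as np
import pytest

import divetherm as dt
from divetherm.dives import AnalysisConfig

RATE = 32.0


def dft_band_split(x, rate, cutoff):
    """Independent oracle: split a series at `cutoff` in the Fourier domain."""
    freqs = np.fft.rfftfreq(len(x), d=1.0 / rate)
    spec = np.fft.rfft(x)
    low_spec = np.where(freqs <= cutoff, spec, 0.0)
    low = np.fft.irfft(low_spec, n=len(x))
    return low, x - low


class TestSeparateComponents:
    def test_constant_goes_entirely_to_low(self):
        x = np.full(32 * 20, 9.8)
        low, high = dt.separate_components(x, rate=RATE, cutoff=1.0)
        assert np.allclose(low, 9.8, atol=1e-9)
        assert np.allclose(high, 0.0, atol=1e-9)

    def test_pure_stroke_band_sine_recovered_in_high(self):
        t = np.arange(0, 30, 1 / RATE)
        x = 2.0 * np.sin(2 * np.pi * 2.5 * t)
        low, high = dt.separate_components(x, rate=RATE, cutoff=1.0)
        _, high_oracle = dft_band_split(x, RATE, 1.0)
        core = slice(64, -64)  # ignore filter warm-up at the ends
        rel = np.max(np.abs(high[core] - high_oracle[core])) / 2.0
        assert rel < 0.05
        assert np.max(np.abs(low[core])) < 0.1

    def test_two_band_mixture_split_per_band(self):
        t = np.arange(0, 60, 1 / RATE)
        slow_part = 1.5 * np.sin(2 * np.pi * 0.1 * t)
        fast_part = 2.0 * np.sin(2 * np.pi * 2.5 * t)
        low, high = dt.separate_components(slow_part + fast_part, rate=RATE,
                                           cutoff=1.0)
        core = slice(128, -128)
        assert np.max(np.abs(low[core] - slow_part[core])) / 1.5 < 0.05
        assert np.max(np.abs(high[core] - fast_part[core])) / 2.0 < 0.05

    def test_reconstruction_is_exact(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=32 * 10)
        low, high = dt.separate_components(x, rate=RATE, cutoff=1.0)
        assert np.allclose(low + high, x, rtol=0, atol=1e-10)

    @pytest.mark.parametrize("cutoff", [0.0, -1.0, 16.0, 20.0])
    def test_cutoff_outside_nyquist_rejected(self, cutoff):
        with pytest.raises(ValueError, match="cutoff"):
            dt.separate_components(np.zeros(64), rate=RATE, cutoff=cutoff)


class TestDetectStrokes:
    def test_silent_input_empty(self):
        t = np.arange(0, 10, 1 / RATE)
        assert len(dt.detect_strokes(t, np.zeros_like(t))) == 0

    def test_cycle_count_of_pure_sine(self):
        t = np.arange(0, 10, 1 / RATE)
        st = dt.detect_strokes(t, 2.0 * np.sin(2 * np.pi * 2.5 * t))
        assert abs(len(st) - 25) <= 1

    def test_amplitude_is_peak_to_trough(self):
        t = np.arange(0, 10, 1 / RATE)
        a = 2.0
        st = dt.detect_strokes(t, a * np.sin(2 * np.pi * 2.5 * t))
        assert np.all(np.abs(st["amplitude"] - 2 * a) / (2 * a) < 0.10)
        assert np.all(np.abs(st["period_s"] - 0.4) < 0.05)

    def test_counts_and_amplitudes_with_noise(self):
        rng = np.random.default_rng(8)
        t = np.arange(0, 60, 1 / RATE)
        a, sd = 2.5, 0.5  # amplitude SNR 5
        x = a * np.sin(2 * np.pi * 2.5 * t) + rng.normal(0, sd, t.size)
        _, high = dt.separate_components(x, rate=RATE, cutoff=1.0)
        st = dt.detect_strokes(t, high)
        assert abs(len(st) - 150) / 150 <= 0.02
        assert abs(st["amplitude"].median() - 2 * a) / (2 * a) < 0.10


def _synthetic_trip_for_flagging(burst_depth=None):
    """One 1 Hz dive (>= 25 m) with an optional 3x-amplitude stroke burst
    at `burst_depth` on the descent; returns pieces for flagging."""
    maxd = 25.0 if burst_depth is None else max(25.0, burst_depth + 5)
    n_down = int(maxd)
    down = np.arange(1, n_down + 1, dtype=float)
    depth = np.concatenate([np.zeros(5), down, np.full(20, maxd),
                            down[::-1][1:], np.zeros(5)])
    t_slow = np.arange(len(depth), dtype=float)
    t_fast = np.arange(0, len(depth), 1 / RATE)
    base = 2.0
    amp = np.zeros_like(t_fast)
    submerged_start, submerged_end = 5.0, 5.0 + n_down + 20.0
    stroking = (t_fast >= submerged_start) & (t_fast <= submerged_end)
    amp[stroking] = base
    if burst_depth is not None:
        burst_t = 5.0 + burst_depth  # descent crosses burst_depth here
        burst = (t_fast >= burst_t) & (t_fast < burst_t + 4.0)
        amp[burst] = 3 * base
    heave = amp * np.sin(2 * np.pi * 2.5 * t_fast)
    dives = dt.detect_dives(t_slow, depth)
    st = dt.detect_strokes(t_fast, heave)
    return st, dives, t_slow, depth


class TestFlagPreyEncounters:
    def test_uniform_amplitude_yields_no_segments(self):
        st, dives, t_slow, depth = _synthetic_trip_for_flagging(burst_depth=None)
        segs = dt.flag_prey_encounters(st, dives, t_slow, depth)
        assert segs == []

    def test_burst_at_20m_flagged_in_correct_dive(self):
        st, dives, t_slow, depth = _synthetic_trip_for_flagging(burst_depth=20)
        segs = dt.flag_prey_encounters(st, dives, t_slow, depth)
        assert len(segs) == 1
        assert segs[0].dive_index == 0
        assert segs[0].mean_depth > 10.0

    def test_same_burst_at_5m_not_flagged(self):
        st, dives, t_slow, depth = _synthetic_trip_for_flagging(burst_depth=5)
        segs = dt.flag_prey_encounters(st, dives, t_slow, depth)
        assert segs == []

    def test_scale_equivariance_of_flagged_set(self, deep_trip):
        _, rec, _ = deep_trip
        t_slow = rec.slow["time_s"].to_numpy()
        depth = rec.slow["depth_m"].to_numpy()
        t_fast = rec.fast["time_s"].to_numpy()
        heave = rec.fast["heave_ms2"].to_numpy()
        dives = dt.detect_dives(t_slow, depth)
        flagged = {}
        for c in (1.0, 2.0, 10.0):
            _, high = dt.separate_components(c * heave, rate=RATE, cutoff=1.0)
            st = dt.detect_strokes(t_fast, high, noise_floor=c * 1.0)
            segs = dt.flag_prey_encounters(st, dives, t_slow, depth)
            flagged[c] = {s.dive_index for s in segs}
        assert flagged[1.0] == flagged[2.0] == flagged[10.0]

    def test_no_deep_strokes_warns_and_flags_nothing(self):
        depth = np.concatenate([np.zeros(5), [1.0, 2.0, 2.0, 1.0],
                                np.zeros(5)])
        t_slow = np.arange(len(depth), dtype=float)
        t_fast = np.arange(0, len(depth), 1 / RATE)
        heave = 2.0 * np.sin(2 * np.pi * 2.5 * t_fast)
        dives = dt.detect_dives(t_slow, depth)
        st = dt.detect_strokes(t_fast, heave)
        with pytest.warns(UserWarning, match="baseline"):
            segs = dt.flag_prey_encounters(st, dives, t_slow, depth)
        assert segs == []


class TestHuntingEfficiency:
    def test_no_segments_zero(self, small_dives):
        assert dt.hunting_efficiency(small_dives, []) == 0.0

    def test_ratio_definition(self):
        dives = [dt.Dive(index=i, start=i * 100.0, end=i * 100.0 + 50,
                         max_depth=20.0, i0=0, i1=50) for i in range(600)]
        segs = [dt.PreyEncounterSegment(dive_index=i, start_time=0,
                                        end_time=1, mean_amplitude=8.0,
                                        mean_depth=20.0, n_strokes=5)
                for i in range(300)]
        assert dt.hunting_efficiency(dives, segs) == pytest.approx(0.5)

    def test_adding_segment_never_decreases(self):
        dives = [dt.Dive(index=i, start=i * 100.0, end=i * 100.0 + 50,
                         max_depth=20.0, i0=0, i1=50) for i in range(10)]
        segs = []
        prev = dt.hunting_efficiency(dives, segs)
        for i in range(10):
            segs.append(dt.PreyEncounterSegment(
                dive_index=i, start_time=0, end_time=1,
                mean_amplitude=8.0, mean_depth=20.0, n_strokes=5))
            eff = dt.hunting_efficiency(dives, segs)
            assert eff >= prev
            prev = eff

    def test_zero_dives_undefined(self):
        with pytest.warns(UserWarning, match="undefined"):
            assert np.isnan(dt.hunting_efficiency([], []))

    def test_recovery_on_simulated_trip(self, deep_trip):
        scn, rec, truth = deep_trip
        t_slow = rec.slow["time_s"].to_numpy()
        depth = rec.slow["depth_m"].to_numpy()
        dives = dt.detect_dives(t_slow, depth)
        _, high = dt.separate_components(rec.fast["heave_ms2"].to_numpy(),
                                         rate=RATE, cutoff=1.0)
        st = dt.detect_strokes(rec.fast["time_s"].to_numpy(), high)
        segs = dt.flag_prey_encounters(st, dives, t_slow, depth)
        flagged = {s.dive_index for s in segs}
        truthset = truth.pursuit_dive_indices
        tp = len(flagged & truthset)
        sens = tp / len(truthset)
        spec = 1 - len(flagged - truthset) / (len(dives) - len(truthset))
        assert sens >= 0.95 and spec >= 0.95
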