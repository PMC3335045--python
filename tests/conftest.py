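import numpy as np
import pytest

import divetherm as dt


@pytest.fixture(scope="session")
def sensors():
    return dt.SensorSpec()


@pytest.fixture(scope="session")
def small_trip():
    """An 80-dive trip with mixed shallow/deep modes and pursuits."""
    scn = dt.TripScenario(
        n_dives=80,
        depth_modes=((0.6, 10.0, 3.0), (0.4, 32.0, 6.0)),
        pursuit_probability=0.4,
        seed=11,
    )
    rec, truth = dt.simulate_trip(scn)
    return scn, rec, truth


@pytest.fixture(scope="session")
def deep_trip():
    """All-deep trip: every dive eligible for pursuit (depth 15-45 m)."""
    scn = dt.TripScenario(
        n_dives=150,
        depth_modes=((1.0, 30.0, 5.0),),
        min_depth=15.0,
        pursuit_probability=0.4,
        seed=5,
    )
    rec, truth = dt.simulate_trip(scn)
    return scn, rec, truth


@pytest.fixture(scope="session")
def small_dives(small_trip):
    _, rec, _ = small_trip
    return dt.detect_dives(
        rec.slow["time_s"].to_numpy(), rec.slow["depth_m"].to_numpy()
    )


def brute_force_dives(time, depth, surface_threshold=0.1, min_dive_depth=1.0):
    """Exhaustive linear-scan oracle: enumerate every submergence sample by
    sample and apply the two thresholds.  Returns (i0, i1) index pairs."""
    out = []
    run = None
    for i, d in enumerate(np.asarray(depth, dtype=float)):
        if d > surface_threshold:
            if run is None:
                run = [i, i]
            run[1] = i
        else:
            if run is not None:
                if max(depth[run[0]:run[1] + 1]) > min_dive_depth:
                    out.append(tuple(run))
                run = None
    if run is not None and max(depth[run[0]:run[1] + 1]) > min_dive_depth:
        out.append(tuple(run))
    return out
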