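"""Weekly grouping and summary tables of per-trip metrics.

Trips are binned into fixed 7-day study weeks from the study start date
(default 13 Nov 2005, a 5-week guard-phase window) and summarized as
mean +/- SE per metric per week.  Mixed-model inference (GLMM, post-hoc
contrasts) is deliberately left to external statistics tooling: this
module only exports tidy tables shaped for it.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dives import TripMetrics

__all__ = [
    "StudyDesign",
    "assign_week",
    "trips_table",
    "weekly_table",
    "tidy_long",
    "METRIC_COLUMNS",
]

METRIC_COLUMNS = [
    "n_dives",
    "mean_dive_depth",
    "time_underwater",
    "bottom_proportion",
    "deep_dive_fraction",
    "hunting_efficiency",
]


@dataclass(frozen=True)
class StudyDesign:
    study_start: _dt.date = _dt.date(2005, 11, 13)
    n_weeks: int = 5

    def __post_init__(self) -> None:
        if self.n_weeks < 1:
            raise ValueError("n_weeks must be >= 1")


def assign_week(trip_date: _dt.date, design: StudyDesign = StudyDesign()) -> int:
    """1-based study week of a trip date: ``1 + floor(days since start / 7)``.

    Dates outside the study window are rejected.
    """
    days = (trip_date - design.study_start).days
    if not 0 <= days < 7 * design.n_weeks:
        raise ValueError(
            f"{trip_date} outside the {design.n_weeks}-week study window "
            f"starting {design.study_start}"
        )
    return 1 + days // 7


def trips_table(records: list[tuple[str, _dt.date, TripMetrics]]) -> pd.DataFrame:
    """One row per trip: bird_id, date and every metric column."""
    rows = []
    for bird_id, date, m in records:
        row = {"bird_id": bird_id, "date": date}
        row.update({k: getattr(m, k) for k in METRIC_COLUMNS})
        rows.append(row)
    return pd.DataFrame(rows)


def weekly_table(
    trips: pd.DataFrame,
    design: StudyDesign = StudyDesign(),
) -> pd.DataFrame:
    """Weekly summary: per metric, mean and SE (= sd/sqrt(n)) across trips.

    ``trips`` is the output of :func:`trips_table`.  A week with a single
    trip reports SE 0.  Empty input yields an empty table.  Row order of
    the input does not affect the result.
    """
    if len(trips) == 0:
        return pd.DataFrame(columns=["week", "n_birds"])
    df = trips.copy()
    df["week"] = [assign_week(d, design) for d in df["date"]]
    out_rows = []
    for week, grp in df.groupby("week"):
        row: dict = {"week": int(week), "n_birds": len(grp)}
        for col in METRIC_COLUMNS:
            vals = grp[col].astype(float).to_numpy()
            vals = vals[~np.isnan(vals)]
            if vals.size == 0:
                row[f"{col}_mean"] = np.nan
                row[f"{col}_se"] = np.nan
                continue
            row[f"{col}_mean"] = float(vals.mean())
            row[f"{col}_se"] = (
                float(vals.std(ddof=1) / np.sqrt(vals.size)) if vals.size > 1 else 0.0
            )
        out_rows.append(row)
    return pd.DataFrame(out_rows).sort_values("week", ignore_index=True)


def tidy_long(
    trips: pd.DataFrame,
    design: StudyDesign = StudyDesign(),
    log_transform: tuple[str, ...] = (),
) -> pd.DataFrame:
    """Long-format export (one row per trip per metric) for external
    mixed-model tooling; ``log_transform`` names metrics to ship on the
    log scale (never applied silently)."""
    df = trips.copy()
    df["week"] = [assign_week(d, design) for d in df["date"]]
    long = df.melt(
        id_vars=["bird_id", "date", "week"],
        value_vars=METRIC_COLUMNS,
        var_name="metric",
        value_name="value",
    )
    if log_transform:
        sel = long["metric"].isin(log_transform)
        long.loc[sel, "value"] = np.log(long.loc[sel, "value"].astype(float))
        long.loc[sel, "metric"] = "log_" + long.loc[sel, "metric"]
    return long
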