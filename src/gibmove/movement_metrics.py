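"""Step-level movement metrics: lengths, rates, daily and seasonal
displacement, directionality, and infrastructure crossings.

A *step* is the straight-line geodesic segment between two successive
fixes; step lengths are computed on the WGS84 ellipsoid, never in the
projected plane. A step belongs to the calendar date (local time) of
its start fix, which makes the daily-distance decomposition exactly
conservative: the per-day distances sum to the trajectory total.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import LineString
from shapely.strtree import STRtree

from ._geodesy import geodesic_inverse
from .trajectory_io import IST, SEASON_OF_MONTH, SEASONS, Trajectory

__all__ = [
    "StepSeries",
    "step_series",
    "hourly_rate",
    "daily_summaries",
    "seasonal_summaries",
    "turning_histogram",
    "count_line_crossings",
]

log = logging.getLogger(__name__)


@dataclass
class StepSeries:
    """Per-step table.

    Columns: ``start_time``, ``end_time`` (tz-aware), ``length_m``,
    ``duration_h``, ``bearing_deg`` in [0, 360), ``turning_angle_deg``
    in (-180, 180] (NaN for the first step, where it is undefined),
    ``season`` (of the start fix) and ``date`` (local calendar date of
    the start fix).
    """

    steps: pd.DataFrame
    animal_id: str = ""

    def __len__(self) -> int:
        return len(self.steps)

    @property
    def total_distance_km(self) -> float:
        return float(self.steps["length_m"].sum()) / 1000.0


def _wrap_signed(angles_deg: np.ndarray) -> np.ndarray:
    """Wrap to (-180, 180]."""
    wrapped = np.mod(angles_deg, 360.0)
    return np.where(wrapped > 180.0, wrapped - 360.0, wrapped)


def step_series(traj: Trajectory) -> StepSeries:
    """Build the step table from successive fixes.

    Zero-duration pairs (identical timestamps should not survive
    cleaning, but defensively) are dropped and logged.
    """
    if len(traj) < 2:
        raise ValueError("need at least 2 fixes to form steps")
    df = traj.fixes
    lon = df["lon"].to_numpy(float)
    lat = df["lat"].to_numpy(float)
    t = df["timestamp"]

    length, bearing = geodesic_inverse(lon[:-1], lat[:-1], lon[1:], lat[1:])
    length = np.atleast_1d(length)
    bearing = np.atleast_1d(bearing)
    duration_h = (t.iloc[1:].to_numpy() - t.iloc[:-1].to_numpy()) \
        / np.timedelta64(1, "h")

    keep = duration_h > 0
    if not np.all(keep):
        log.warning("dropped %d zero-duration step(s)", int((~keep).sum()))

    start = t.iloc[:-1].reset_index(drop=True)
    end = t.iloc[1:].reset_index(drop=True)
    local_start = start.dt.tz_convert(IST)
    season = local_start.dt.month.map(SEASON_OF_MONTH)

    steps = pd.DataFrame({
        "start_time": start,
        "end_time": end,
        "length_m": length,
        "duration_h": duration_h,
        "bearing_deg": bearing,
        "season": season,
        "date": local_start.dt.date,
    })[keep]
    steps = steps.reset_index(drop=True)

    turn = np.full(len(steps), np.nan)
    if len(steps) > 1:
        b = steps["bearing_deg"].to_numpy()
        turn[1:] = _wrap_signed(np.diff(b))
    steps["turning_angle_deg"] = turn
    return StepSeries(steps=steps, animal_id=traj.animal_id)


def hourly_rate(steps: StepSeries) -> dict[str, float]:
    """Mean/min/max per-step movement rate in km/h."""
    if len(steps) == 0:
        raise ValueError("empty step series")
    rate = (steps.steps["length_m"] / 1000.0) / steps.steps["duration_h"]
    return {"mean_kmh": float(rate.mean()),
            "min_kmh": float(rate.min()),
            "max_kmh": float(rate.max())}


def daily_summaries(steps: StepSeries) -> pd.DataFrame:
    """Distance travelled per calendar date (local time).

    A step contributes wholly to its start date, so the daily distances
    sum exactly to the total trajectory distance. Dates with fixes but
    no started step do not appear.
    """
    if len(steps) == 0:
        raise ValueError("empty step series")
    df = steps.steps
    grouped = df.groupby("date", sort=True).agg(
        distance_km=("length_m", lambda v: v.sum() / 1000.0),
        n_steps=("length_m", "size"),
        season=("season", "first"),
    ).reset_index()
    grouped["n_fixes"] = grouped["n_steps"] + 1
    return grouped


def seasonal_summaries(daily: pd.DataFrame,
                       seasons: tuple[str, ...] = SEASONS) -> pd.DataFrame:
    """Per-season mean/min/max daily distance and seasonal total (km)."""
    if len(daily) == 0:
        raise ValueError("empty daily summaries")
    rows = []
    for season in seasons:
        sub = daily[daily["season"] == season]
        if len(sub) == 0:
            log.info("season %s has no days with movement; omitted", season)
            continue
        d = sub["distance_km"]
        rows.append({"season": season, "n_days": len(sub),
                     "mean_km_per_day": float(d.mean()),
                     "min_km_per_day": float(d.min()),
                     "max_km_per_day": float(d.max()),
                     "total_km": float(d.sum())})
    return pd.DataFrame(rows)


def turning_histogram(steps: StepSeries, n_bins: int = 36
                      ) -> tuple[np.ndarray, np.ndarray, float]:
    """Histogram of turning angles over (-180, 180] plus mean resultant
    length R-bar in [0, 1] (0 = no directional persistence).

    Returns ``(counts, bin_edges, rbar)``; undefined (first-step)
    angles are excluded.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be at least 2")
    if len(steps) < 2:
        raise ValueError("need at least 2 steps for turning angles")
    angles = steps.steps["turning_angle_deg"].dropna().to_numpy()
    counts, edges = np.histogram(angles, bins=n_bins, range=(-180.0, 180.0))
    rad = np.radians(angles)
    rbar = float(np.hypot(np.cos(rad).mean(), np.sin(rad).mean()))
    return counts, edges, rbar


def count_line_crossings(track_xy: np.ndarray,
                         lines: list[LineString]) -> int:
    """Count step-segment/polyline crossings in projected coordinates.

    Each step segment contributes one crossing per *distinct* polyline
    it intersects (touching an endpoint counts). A segment crossing the
    same polyline twice still counts once per that polyline; zig-zag
    fixtures therefore count per step.
    """
    track_xy = np.asarray(track_xy, dtype=float)
    if len(lines) == 0 or len(track_xy) < 2:
        return 0
    segments = [LineString([track_xy[i], track_xy[i + 1]])
                for i in range(len(track_xy) - 1)]
    tree = STRtree(lines)
    total = 0
    for seg in segments:
        idx = tree.query(seg)
        total += int(np.sum(shapely.intersects(seg, tree.geometries.take(idx))))
    return total
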