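"""Read, validate, season-label and project GPS/Argos fix tables.

A *fix* is one timestamped geographic location of the tracked bird.
Input is a CSV with at least timestamp, longitude and latitude columns;
fixes are validated, de-duplicated, time-sorted and carried in a
:class:`Trajectory`. Timestamps without an explicit UTC offset are
interpreted as Indian local time (UTC+05:30), matching the fixed
on-board fix schedule. The metric working CRS for density estimation
and clustering is UTM zone 43N (EPSG:32643), chosen from the study
extent around 75–76.5°E.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import timedelta, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from ._geodesy import lonlat_to_utm43n, utm43n_to_lonlat

__all__ = [
    "IST",
    "SEASONS",
    "SEASON_OF_MONTH",
    "Trajectory",
    "read_fixes",
    "write_fixes",
    "assign_seasons",
    "project",
    "unproject",
]

log = logging.getLogger(__name__)

#: Study-region local time (no DST).
IST = timezone(timedelta(hours=5, minutes=30))

#: Season order used throughout reports.
SEASONS = ("summer", "monsoon", "post_monsoon", "winter")

#: Calendar-month season map: Mar-Jun summer, Jul-Sep monsoon,
#: Oct-Nov post-monsoon, Dec-Feb winter.
SEASON_OF_MONTH = {
    1: "winter", 2: "winter", 3: "summer", 4: "summer", 5: "summer",
    6: "summer", 7: "monsoon", 8: "monsoon", 9: "monsoon",
    10: "post_monsoon", 11: "post_monsoon", 12: "winter",
}

_SOURCES = ("GPS", "ARGOS3")


@dataclass
class Trajectory:
    """Time-ordered sequence of fixes for one animal.

    ``fixes`` is a DataFrame with columns ``timestamp`` (tz-aware),
    ``lon``, ``lat`` (WGS84 decimal degrees) and ``source``.
    """

    animal_id: str
    fixes: pd.DataFrame
    crs_note: str = field(default="EPSG:4326 input, EPSG:32643 working")

    def __len__(self) -> int:
        return len(self.fixes)

    @property
    def timestamps(self) -> pd.Series:
        return self.fixes["timestamp"]

    def local_timestamps(self) -> pd.Series:
        return self.fixes["timestamp"].dt.tz_convert(IST)


def read_fixes(path: str | Path,
               column_map: dict[str, str] | None = None,
               animal_id: str | None = None) -> Trajectory:
    """Read a fix CSV into a validated :class:`Trajectory`.

    ``column_map`` maps the canonical names ``timestamp``, ``lon``,
    ``lat``, ``source``, ``animal_id`` to the file's column names.
    Rows with out-of-range coordinates are rejected (logged with their
    1-based data row numbers); exact duplicate rows and repeated
    timestamps are dropped. Raises ``ValueError`` on unparseable
    timestamps or when fewer than two valid fixes remain.
    """
    path = Path(path)
    raw = pd.read_csv(path)
    colmap = {"timestamp": "timestamp", "lon": "lon", "lat": "lat",
              "source": "source", "animal_id": "animal_id"}
    if column_map:
        colmap.update(column_map)

    for key in ("timestamp", "lon", "lat"):
        if colmap[key] not in raw.columns:
            raise ValueError(f"{path}: missing required column {colmap[key]!r}")

    df = pd.DataFrame({
        "timestamp": raw[colmap["timestamp"]],
        "lon": pd.to_numeric(raw[colmap["lon"]], errors="coerce"),
        "lat": pd.to_numeric(raw[colmap["lat"]], errors="coerce"),
    })
    df["source"] = (raw[colmap["source"]].astype(str).str.upper()
                    if colmap["source"] in raw.columns else "GPS")
    if animal_id is None:
        if colmap["animal_id"] in raw.columns:
            animal_id = str(raw[colmap["animal_id"]].iloc[0])
        else:
            animal_id = path.stem

    ts = pd.to_datetime(df["timestamp"], errors="coerce", utc=False,
                        format="mixed")
    bad_ts = ts.isna()
    if bad_ts.any():
        rows = (np.flatnonzero(bad_ts.to_numpy()) + 1).tolist()
        raise ValueError(f"{path}: unparseable timestamp in data row(s) {rows}")
    if ts.dt.tz is None:
        ts = ts.dt.tz_localize(IST)
    else:
        ts = ts.dt.tz_convert(IST)
    df["timestamp"] = ts

    in_range = (df["lon"].between(-180, 180) & df["lat"].between(-90, 90)
                & df["lon"].notna() & df["lat"].notna())
    n_bad = int((~in_range).sum())
    if n_bad:
        rows = (np.flatnonzero(~in_range.to_numpy()) + 1).tolist()
        log.warning("%s: rejected %d row(s) with invalid coordinates: %s",
                    path, n_bad, rows)
        df = df[in_range]

    n_before = len(df)
    df = df.drop_duplicates(subset=["timestamp", "lon", "lat"])
    n_dupes = n_before - len(df)
    df = df.sort_values("timestamp", kind="stable")
    df = df.drop_duplicates(subset=["timestamp"], keep="first")
    n_ts_dupes = n_before - n_dupes - len(df)
    df = df.reset_index(drop=True)

    log.info("%s: retained %d fixes (%d duplicate rows, %d repeated "
             "timestamps, %d invalid-coordinate rows dropped)",
             path, len(df), n_dupes, n_ts_dupes, n_bad)
    if len(df) < 2:
        raise ValueError(f"{path}: fewer than 2 valid fixes after cleaning")
    return Trajectory(animal_id=animal_id, fixes=df)


def write_fixes(traj: Trajectory, path: str | Path) -> None:
    """Write the canonical fix CSV dialect (ISO-8601 local timestamps)."""
    df = traj.fixes.copy()
    out = pd.DataFrame({
        "animal_id": traj.animal_id,
        "timestamp": df["timestamp"].dt.tz_convert(IST)
                                    .map(lambda t: t.isoformat()),
        "lon": df["lon"],
        "lat": df["lat"],
        "source": df["source"],
    })
    out.to_csv(path, index=False)


def assign_seasons(traj: Trajectory) -> pd.Series:
    """Season label per fix, by calendar month of the local timestamp."""
    months = traj.local_timestamps().dt.month
    return months.map(SEASON_OF_MONTH).rename("season")


def project(traj: Trajectory) -> np.ndarray:
    """Project the fixes into UTM 43N; returns an (n, 2) array of metres.

    Longitudes far outside the zone (72–78°E) produce a warning, not an
    error: the projection degrades gracefully near the zone edges.
    """
    if len(traj) == 0:
        raise ValueError("cannot project an empty trajectory")
    lon = traj.fixes["lon"].to_numpy(dtype=float)
    lat = traj.fixes["lat"].to_numpy(dtype=float)
    if np.any((lon < 72.0) | (lon > 78.0)):
        log.warning("fixes outside UTM zone 43N validity (72-78E); "
                    "projected coordinates will be increasingly distorted")
    x, y = lonlat_to_utm43n(lon, lat)
    return np.column_stack([np.atleast_1d(x), np.atleast_1d(y)])


def unproject(xy: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Inverse of :func:`project`: (n, 2) metres back to lon/lat arrays."""
    xy = np.asarray(xy, dtype=float)
    return utm43n_to_lonlat(xy[..., 0], xy[..., 1])
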