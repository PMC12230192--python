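"""Synthetic telemetry and landscapes with the statistical structure the
analysis assumes.

The trajectory simulator emulates a solar GPS tag on a nomadic
grassland bird: seven scheduled fixes per day in daylight hours
(05:30–19:30 local), truncated-Pareto (bounded power-law) step lengths
whose exponent switches with the season, uniform headings (no
directional persistence), and optional multi-day stationary "cluster
phases" during which the bird stays within a small disk — the ground
truth for the sequential clustering stage. Steps are the straight
lines between consecutive scheduled fixes; the overnight gap is an
ordinary step.

Seasonal exponents default to the study values for the tracked bird
(summer 2.44, monsoon 2.20, post-monsoon 2.89, winter 1.74). The upper
truncation (default 40 km) reflects the finite extent of the Deccan
study landscape and keeps simulated daily sums in the observed range.

The landscape generator produces a categorical land-cover grid
(builtup / crop / open / others / water), dated NDVI fields in [0, 1],
and powerline/road polylines — everything the habitat stage consumes —
as smooth seeded random fields on the working metric CRS.
"""

from __future__ import annotations

import datetime as dt
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from shapely.geometry import LineString

from ._geodesy import lonlat_to_utm43n
from .grids import Grid
from .trajectory_io import IST, SEASON_OF_MONTH, Trajectory, unproject
from .vectors import write_lines_geojson

__all__ = [
    "ClusterPhase",
    "SimConfig",
    "SyntheticLandscape",
    "sample_step_lengths",
    "simulate_levy_trajectory",
    "simulate_landscape",
    "landscape_for_trajectory",
    "write_landscape",
]

log = logging.getLogger(__name__)

DEFAULT_FIX_HOURS = (dt.time(5, 30), dt.time(7, 30), dt.time(9, 30),
                     dt.time(11, 30), dt.time(13, 30), dt.time(17, 30),
                     dt.time(19, 30))

DEFAULT_SEASON_MU = {"summer": 2.44, "monsoon": 2.20,
                     "post_monsoon": 2.89, "winter": 1.74}

LANDCOVER_CLASSES = ("builtup", "crop", "open", "others", "water")

#: semi-arid cropland/grassland mosaic mix used by default
DEFAULT_CLASS_PROBS = {"builtup": 0.02, "crop": 0.45, "open": 0.48,
                       "others": 0.02, "water": 0.03}


@dataclass(frozen=True)
class ClusterPhase:
    """A stationary multi-day phase around a fixed centre.

    ``center_offset_m`` is the (east, north) offset of the phase centre
    from the trajectory origin, in metres.
    """

    start: dt.date
    duration_days: int
    center_offset_m: tuple[float, float]

    def covers(self, day: dt.date) -> bool:
        return self.start <= day < self.start + dt.timedelta(
            days=self.duration_days)


@dataclass
class SimConfig:
    seed: int = 0
    start_date: dt.date = dt.date(2015, 4, 15)
    end_date: dt.date = dt.date(2016, 5, 28)
    fix_hours: tuple[dt.time, ...] = DEFAULT_FIX_HOURS
    season_mu: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SEASON_MU))
    xmin_m: float = 150.0
    xmax_m: float = 40000.0
    cluster_phases: tuple[ClusterPhase, ...] = ()
    origin_lonlat: tuple[float, float] = (75.87, 17.81)
    miss_prob: float = 0.0

    def __post_init__(self) -> None:
        if self.end_date < self.start_date:
            raise ValueError("empty date range: end_date before start_date")
        for season, mu in self.season_mu.items():
            if not 1.0 < mu <= 3.5:
                raise ValueError(f"season {season}: mu={mu} outside (1, 3.5]")
        if not 0.0 < self.xmin_m < self.xmax_m:
            raise ValueError("require 0 < xmin_m < xmax_m")
        if not 0.0 <= self.miss_prob < 1.0:
            raise ValueError("miss_prob must be in [0, 1)")
        if list(self.fix_hours) != sorted(set(self.fix_hours)):
            raise ValueError("fix_hours must be strictly increasing")


def sample_step_lengths(n: int, mu: float, xmin: float,
                        xmax: float | None = None,
                        rng: np.random.Generator | None = None
                        ) -> np.ndarray:
    """Inverse-CDF draws from a (truncated) Pareto with exponent mu.

    Density ∝ x**(-mu) on [xmin, xmax] (or [xmin, ∞) when ``xmax`` is
    None). ``alpha = mu - 1`` is the Pareto tail index.
    """
    if mu <= 1.0:
        raise ValueError("mu must exceed 1")
    if rng is None:
        rng = np.random.default_rng()
    alpha = mu - 1.0
    u = rng.random(n)
    if xmax is None:
        return xmin * u ** (-1.0 / alpha)
    ratio_term = 1.0 - (xmax / xmin) ** (-alpha)
    return xmin * (1.0 - u * ratio_term) ** (-1.0 / alpha)


def _phase_for(day: dt.date,
               phases: tuple[ClusterPhase, ...]) -> ClusterPhase | None:
    for phase in phases:
        if phase.covers(day):
            return phase
    return None


def simulate_levy_trajectory(config: SimConfig) -> Trajectory:
    """Simulate one tagged individual; deterministic given the seed.

    One fix per scheduled non-missing time. Outside cluster phases the
    displacement from the previous fix has truncated-Pareto length
    (exponent of the season of the step's start fix) and a uniform
    heading; during a phase the fix is drawn uniformly within a disk of
    radius ``xmin_m`` around the phase centre.
    """
    rng = np.random.default_rng(config.seed)
    days = pd.date_range(config.start_date, config.end_date, freq="D")
    schedule = [dt.datetime.combine(day.date(), hour, tzinfo=IST)
                for day in days for hour in config.fix_hours]
    keep = rng.random(len(schedule)) >= config.miss_prob
    schedule = [t for t, k in zip(schedule, keep) if k]
    if len(schedule) < 2:
        raise ValueError("fewer than 2 scheduled fixes survive miss_prob")

    origin = np.array(lonlat_to_utm43n(*config.origin_lonlat))
    centers = {phase: origin + np.asarray(phase.center_offset_m, float)
               for phase in config.cluster_phases}

    def mu_for(when: dt.datetime) -> float:
        season = SEASON_OF_MONTH[when.month]
        try:
            return config.season_mu[season]
        except KeyError:
            raise ValueError(
                f"no exponent configured for season {season!r} "
                f"(month {when.strftime('%B')})") from None

    def disk_point(center: np.ndarray, radius: float) -> np.ndarray:
        r = radius * np.sqrt(rng.random())
        theta = rng.random() * 2 * np.pi
        return center + r * np.array([np.cos(theta), np.sin(theta)])

    positions = np.empty((len(schedule), 2))
    phase0 = _phase_for(schedule[0].date(), config.cluster_phases)
    positions[0] = (disk_point(centers[phase0], config.xmin_m)
                    if phase0 else origin)
    for i in range(1, len(schedule)):
        t = schedule[i]
        phase = _phase_for(t.date(), config.cluster_phases)
        if phase is not None:
            positions[i] = disk_point(centers[phase], config.xmin_m)
            continue
        mu = mu_for(schedule[i - 1])
        length = sample_step_lengths(1, mu, config.xmin_m,
                                     config.xmax_m, rng)[0]
        heading = rng.random() * 2 * np.pi
        positions[i] = positions[i - 1] + length * np.array(
            [np.sin(heading), np.cos(heading)])

    lon, lat = unproject(positions)
    fixes = pd.DataFrame({
        "timestamp": pd.DatetimeIndex(schedule),
        "lon": np.atleast_1d(lon),
        "lat": np.atleast_1d(lat),
        "source": "GPS",
    })
    return Trajectory(animal_id=f"SIM-{config.seed}", fixes=fixes)


# ----------------------------------------------------------------------
# Landscape
# ----------------------------------------------------------------------

@dataclass
class SyntheticLandscape:
    """Land-cover, NDVI and line features on a shared metric grid."""

    landcover: Grid  # integer class codes indexing ``classes``
    classes: tuple[str, ...]
    ndvi_layers: list[tuple[dt.date, Grid]]
    powerlines: list[LineString]
    roads: list[LineString]
    seed: int


def _smooth_field(rng: np.random.Generator, shape: tuple[int, int],
                  sigma_cells: float) -> np.ndarray:
    noise = rng.normal(size=shape)
    return ndimage.gaussian_filter(noise, sigma=sigma_cells)


def _rank_uniform(field_: np.ndarray) -> np.ndarray:
    """Map a field monotonically onto [0, 1) by rank."""
    flat = field_.ravel()
    ranks = np.empty_like(flat)
    ranks[np.argsort(flat, kind="stable")] = np.arange(flat.size)
    return (ranks / flat.size).reshape(field_.shape)


def _random_crossing_line(rng: np.random.Generator,
                          extent: tuple[float, float, float, float],
                          n_vertices: int = 6) -> LineString:
    x0, y0, x1, y1 = extent
    horizontal = rng.random() < 0.5
    if horizontal:
        ys = y0 + rng.random() * (y1 - y0)
        xs = np.linspace(x0, x1, n_vertices)
        jitter = rng.normal(scale=(y1 - y0) * 0.03, size=n_vertices)
        coords = np.column_stack([xs, ys + jitter])
    else:
        xs = x0 + rng.random() * (x1 - x0)
        ys = np.linspace(y0, y1, n_vertices)
        jitter = rng.normal(scale=(x1 - x0) * 0.03, size=n_vertices)
        coords = np.column_stack([xs + jitter, ys])
    return LineString(coords)


def simulate_landscape(seed: int,
                       extent: tuple[float, float, float, float],
                       cell_m: float,
                       class_probs: dict[str, float] | None = None,
                       ndvi_dates: list[dt.date] | None = None,
                       ndvi_range: tuple[float, float] = (0.15, 0.45),
                       constant_ndvi: float | None = None,
                       n_powerlines: int = 1,
                       n_roads: int = 3,
                       smooth_sigma_cells: float = 3.0
                       ) -> SyntheticLandscape:
    """Reproducible landscape over ``extent = (x0, y0, x1, y1)`` metres.

    Land-cover classes are assigned by thresholding a smoothed random
    field at the requested class proportions; NDVI layers are smooth
    fields rank-mapped into ``ndvi_range`` (or a constant when
    ``constant_ndvi`` is given).
    """
    if cell_m <= 0:
        raise ValueError("cell size must be positive")
    x0, y0, x1, y1 = extent
    ncols = int(np.floor((x1 - x0) / cell_m))
    nrows = int(np.floor((y1 - y0) / cell_m))
    if ncols < 1 or nrows < 1:
        raise ValueError("extent smaller than one cell")

    rng = np.random.default_rng(seed)
    probs = dict(DEFAULT_CLASS_PROBS if class_probs is None else class_probs)
    for name in probs:
        if name not in LANDCOVER_CLASSES:
            raise ValueError(f"unknown land-cover class {name!r}")
    total = sum(probs.values())
    cum = np.cumsum([probs.get(name, 0.0) / total
                     for name in LANDCOVER_CLASSES])

    u = _rank_uniform(_smooth_field(rng, (nrows, ncols), smooth_sigma_cells))
    codes = np.searchsorted(cum, u, side="right")
    codes = np.clip(codes, 0, len(LANDCOVER_CLASSES) - 1)
    landcover = Grid(x0, y0, cell_m, codes.astype(np.int16))

    if ndvi_dates is None:
        ndvi_dates = [dt.date(2015, 7, 1)]
    layers: list[tuple[dt.date, Grid]] = []
    for date in sorted(ndvi_dates):
        if constant_ndvi is not None:
            vals = np.full((nrows, ncols), float(constant_ndvi))
        else:
            f = _rank_uniform(_smooth_field(rng, (nrows, ncols),
                                            smooth_sigma_cells))
            lo, hi = ndvi_range
            vals = lo + f * (hi - lo)
        layers.append((date, Grid(x0, y0, cell_m, vals)))

    powerlines = [_random_crossing_line(rng, extent)
                  for _ in range(max(n_powerlines, 1))]
    roads = [_random_crossing_line(rng, extent)
             for _ in range(max(n_roads, 1))]
    return SyntheticLandscape(landcover=landcover,
                              classes=LANDCOVER_CLASSES,
                              ndvi_layers=layers, powerlines=powerlines,
                              roads=roads, seed=seed)


def landscape_for_trajectory(traj: Trajectory, seed: int,
                             cell_m: float = 250.0,
                             margin_m: float = 5000.0,
                             **kwargs) -> SyntheticLandscape:
    """Landscape whose extent covers the projected trajectory."""
    from .trajectory_io import project

    xy = project(traj)
    extent = (xy[:, 0].min() - margin_m, xy[:, 1].min() - margin_m,
              xy[:, 0].max() + margin_m, xy[:, 1].max() + margin_m)
    if "ndvi_dates" not in kwargs:
        local = traj.local_timestamps()
        months = pd.period_range(local.min(), local.max(), freq="M")
        kwargs["ndvi_dates"] = [p.to_timestamp().date() for p in months]
    return simulate_landscape(seed, extent, cell_m, **kwargs)


def write_landscape(landscape: SyntheticLandscape,
                    outdir: str | Path) -> None:
    """Write grids as ASCII rasters, lines as GeoJSON, plus metadata."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    landscape.landcover.write_ascii(outdir / "landcover.asc")
    for date, grid in landscape.ndvi_layers:
        grid.write_ascii(outdir / f"ndvi_{date.isoformat()}.asc")
    write_lines_geojson(landscape.powerlines, outdir / "powerlines.geojson")
    write_lines_geojson(landscape.roads, outdir / "roads.geojson")
    meta = {"seed": landscape.seed, "classes": list(landscape.classes),
            "cell_m": landscape.landcover.cell,
            "ndvi_dates": [d.isoformat() for d, _ in landscape.ndvi_layers],
            "crs": "EPSG:32643"}
    (outdir / "landscape_meta.json").write_text(json.dumps(meta, indent=2))
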