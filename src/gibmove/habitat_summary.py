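"""Habitat configuration of movement-cluster footprints.

For each cluster footprint polygon (projected CRS, metres) this module
summarises: land-cover class percentages, distance from the footprint
edge to the nearest powerline (0 when a line crosses it), road density
(km of road per km² of footprint) and mean NDVI from the dated layer
nearest the cluster's start date.

Raster statistics use the cell-centre rule: a cell belongs to the
footprint iff its centre lies inside the polygon. This is the common
zonal-statistics default and keeps every statistic deterministic.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
import shapely
from shapely.geometry.base import BaseGeometry

from .grids import Grid

__all__ = [
    "HabitatSummary",
    "landcover_pct",
    "nearest_line_distance",
    "road_density",
    "ndvi_mean",
    "summarize_table",
    "column_stats",
]

log = logging.getLogger(__name__)

LANDCOVER_CLASSES = ("builtup", "crop", "open", "others", "water")


@dataclass
class HabitatSummary:
    """One habitat-configuration row (one movement cluster)."""

    cluster_id: int
    area_km2: float
    builtup: float
    crop: float
    open: float
    others: float
    water: float
    nearest_powerline_m: float | None
    road_density_km_per_km2: float
    ndvi_mean: float | None
    ndvi_layer_date: str | None


def _cells_inside(footprint: BaseGeometry, grid: Grid) -> np.ndarray:
    xx, yy = grid.center_mesh()
    return shapely.contains_xy(footprint, xx.ravel(),
                               yy.ravel()).reshape(xx.shape)


def landcover_pct(footprint: BaseGeometry, landcover: Grid,
                  classes: tuple[str, ...] = LANDCOVER_CLASSES
                  ) -> dict[str, float]:
    """Percent of footprint cells (by centre) in each land-cover class.

    ``landcover.values`` holds integer class codes indexing ``classes``.
    """
    inside = _cells_inside(footprint, landcover)
    codes = landcover.values[inside].astype(int)
    if codes.size == 0:
        raise ValueError("footprint contains no raster cell centres")
    pct = {}
    for code, name in enumerate(classes):
        pct[name] = float(np.sum(codes == code) / codes.size * 100.0)
    return pct


def nearest_line_distance(footprint: BaseGeometry,
                          lines: list[BaseGeometry]) -> float | None:
    """Minimum distance (m) from the footprint edge to any polyline;
    0 if any line intersects the footprint, None for an empty line set."""
    if not lines:
        log.warning("no lines supplied; nearest-line distance is missing")
        return None
    if any(footprint.intersects(line) for line in lines):
        return 0.0
    boundary = footprint.boundary
    return float(min(boundary.distance(line) for line in lines))


def road_density(footprint: BaseGeometry,
                 roads: list[BaseGeometry]) -> float:
    """Total road length clipped to the footprint (km) per km² of
    footprint area."""
    area_km2 = footprint.area / 1e6
    if area_km2 <= 0:
        raise ValueError("footprint has zero area")
    clipped_km = sum(footprint.intersection(r).length for r in roads) / 1e3
    return float(clipped_km / area_km2)


def ndvi_mean(footprint: BaseGeometry,
              layers: list[tuple[dt.date, Grid]],
              at_date: dt.date) -> tuple[float | None, dt.date | None]:
    """Mean NDVI over footprint cells from the layer dated nearest
    ``at_date`` (ties resolved toward the earlier layer)."""
    if not layers:
        raise ValueError("no NDVI layers supplied")
    # stable sort by (|date gap|, date) implements the earlier-on-tie rule
    date, grid = min(layers,
                     key=lambda lg: (abs((lg[0] - at_date).days), lg[0]))
    inside = _cells_inside(footprint, grid)
    vals = np.asarray(grid.values, dtype=float)[inside]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        log.warning("no finite NDVI cells inside footprint; value missing")
        return None, date
    return float(vals.mean()), date


def summarize_table(clusters, landscape, params=None) -> pd.DataFrame:
    """Habitat-configuration table: one row per movement cluster.

    ``clusters`` is a list of :class:`~gibmove.seq_cluster.MovementCluster`;
    ``landscape`` provides ``landcover`` (+ ``classes``), ``ndvi_layers``,
    ``powerlines`` and ``roads`` (see
    :class:`~gibmove.synthetic_data.SyntheticLandscape`).
    """
    from .seq_cluster import ClusterParams, cluster_footprint

    if not clusters:
        raise ValueError("no clusters to summarize")
    params = params or ClusterParams()
    classes = getattr(landscape, "classes", LANDCOVER_CLASSES)

    rows = []
    for cluster in clusters:
        fp = cluster_footprint(cluster, params)
        pct = landcover_pct(fp, landscape.landcover, classes)
        nd, nd_date = ndvi_mean(fp, landscape.ndvi_layers,
                                cluster.start.date())
        rows.append(HabitatSummary(
            cluster_id=cluster.cluster_id,
            area_km2=fp.area / 1e6,
            nearest_powerline_m=nearest_line_distance(fp,
                                                      landscape.powerlines),
            road_density_km_per_km2=road_density(fp, landscape.roads),
            ndvi_mean=nd,
            ndvi_layer_date=nd_date.isoformat() if nd_date else None,
            **pct,
        ))
    return pd.DataFrame([asdict(r) for r in rows])


def column_stats(table: pd.DataFrame) -> pd.DataFrame:
    """Mean and SD rows over the numeric columns of a habitat table.

    SD uses the n-1 denominator over the population of clusters; with a
    single cluster the SD row is NaN.
    """
    numeric = table.select_dtypes(include=[np.number]).drop(
        columns=[c for c in ("cluster_id",) if c in table.columns])
    mean = numeric.mean()
    sd = numeric.std(ddof=1)
    return pd.DataFrame({"mean": mean, "sd": sd}).T
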