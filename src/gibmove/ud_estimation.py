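"""Kernel-density utilization distributions, isopleths and overlap.

The utilization distribution (UD) is the probability surface of the
animal's occurrence, estimated here with a bivariate Gaussian product
kernel of isotropic bandwidth ``h`` (metres) on a regular grid in the
projected working CRS. Cell values are probability *masses* (the grid
sums to one), so isopleth construction is a sort-and-accumulate over
cells: the p-isopleth is the smallest set of highest-density cells
holding at least fraction ``p`` of the mass — 50% is the core area,
95% the overall range.

Monthly overlap compares per-month UDs evaluated on one common grid.
Three indices are available:

* ``jaccard`` (default) — area overlap of the p-isopleth regions,
  area(A∩B)/area(A∪B);
* ``vi`` — volume of intersection, sum of cellwise min(UD_A, UD_B);
* ``ba`` — Bhattacharyya affinity, sum of cellwise sqrt(UD_A·UD_B).

All three live in [0, 1] with 1 for identical distributions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .grids import Grid
from .trajectory_io import IST, Trajectory, project

__all__ = [
    "UDGrid",
    "Isopleth",
    "OverlapMatrix",
    "reference_bandwidth",
    "kde_ud",
    "isopleth",
    "monthly_overlap",
]

log = logging.getLogger(__name__)

#: default cell size (m) for UD grids
DEFAULT_CELL_M = 250.0
#: grid margin around the data, in bandwidths; 5h keeps the truncated
#: kernel mass negligible (< 1e-5), so isopleth areas are unbiased
MARGIN_BANDWIDTHS = 5.0

_EIGHT_CONN = np.ones((3, 3), dtype=int)


@dataclass
class UDGrid:
    """Gridded utilization distribution (cell masses sum to 1)."""

    grid: Grid
    h: float
    n_fixes: int

    @property
    def density(self) -> np.ndarray:
        return self.grid.values


@dataclass
class Isopleth:
    """A probability-level region of a UD."""

    level: float
    mask: np.ndarray = field(repr=False)  # bool, same shape as the UD
    area_km2: float
    n_components: int
    component_areas_km2: list[float]
    cell_area_km2: float


@dataclass
class OverlapMatrix:
    """Pairwise monthly overlap values in [0, 1]."""

    months: list[str]  # "YYYY-MM", chronological
    matrix: np.ndarray
    index: str  # jaccard | vi | ba

    def consecutive(self) -> pd.Series:
        """Overlap between each pair of consecutive qualifying months."""
        pairs = [f"{a}->{b}" for a, b in zip(self.months, self.months[1:])]
        vals = [self.matrix[i, i + 1] for i in range(len(self.months) - 1)]
        return pd.Series(vals, index=pairs, name=f"overlap_{self.index}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.months,
                            columns=self.months)


def reference_bandwidth(xy: np.ndarray) -> float:
    """Bivariate-normal reference bandwidth h = n^(-1/6) * sqrt((var_x+var_y)/2)."""
    xy = np.asarray(xy, dtype=float)
    n = len(xy)
    var = np.var(xy[:, 0], ddof=1) + np.var(xy[:, 1], ddof=1)
    return float(n ** (-1.0 / 6.0) * np.sqrt(var / 2.0))


def _build_grid(xy: np.ndarray, h: float, cell_m: float) -> Grid:
    margin = MARGIN_BANDWIDTHS * h
    x_lo = np.floor((xy[:, 0].min() - margin) / cell_m) * cell_m
    x_hi = np.ceil((xy[:, 0].max() + margin) / cell_m) * cell_m
    y_lo = np.floor((xy[:, 1].min() - margin) / cell_m) * cell_m
    y_hi = np.ceil((xy[:, 1].max() + margin) / cell_m) * cell_m
    ncols = max(int(round((x_hi - x_lo) / cell_m)), 1)
    nrows = max(int(round((y_hi - y_lo) / cell_m)), 1)
    return Grid(x_lo, y_lo, cell_m, np.zeros((nrows, ncols)))


def _evaluate_kde(grid: Grid, xy: np.ndarray, h: float) -> np.ndarray:
    """Separable Gaussian product kernel summed over points, then
    normalised to unit total mass over the grid."""
    xc = grid.x_centers()
    yc = grid.y_centers()
    # (ncols, n) and (nrows, n) one-dimensional kernels
    kx = np.exp(-0.5 * ((xc[:, None] - xy[None, :, 0]) / h) ** 2)
    ky = np.exp(-0.5 * ((yc[:, None] - xy[None, :, 1]) / h) ** 2)
    dens = ky @ kx.T  # (nrows, ncols)
    total = dens.sum()
    if total <= 0:
        raise ValueError("kernel mass vanished on the grid; widen the grid "
                         "or the bandwidth")
    return dens / total


def kde_ud(points_xy: np.ndarray, h: float | None = None,
           cell_m: float = DEFAULT_CELL_M, grid: Grid | None = None,
           min_points: int = 5) -> UDGrid:
    """Estimate a UD from projected points (metres).

    ``h`` defaults to the bivariate-normal reference bandwidth; for
    degenerate (all-identical) point sets an explicit ``h`` is required.
    A precomputed ``grid`` pins the evaluation domain (used for the
    common-grid monthly overlap).
    """
    xy = np.asarray(points_xy, dtype=float)
    if xy.ndim != 2 or xy.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array of metres")
    if len(xy) < min_points:
        raise ValueError(f"need at least {min_points} points, got {len(xy)}")
    if cell_m <= 0:
        raise ValueError("cell size must be positive")
    if h is None:
        h = reference_bandwidth(xy)
        if not np.isfinite(h) or h <= 0:
            raise ValueError("degenerate point set (zero spread): pass an "
                             "explicit bandwidth h")
    if grid is None:
        grid = _build_grid(xy, h, cell_m)
    dens = _evaluate_kde(grid, xy, h)
    return UDGrid(grid=grid.like(dens), h=float(h), n_fixes=len(xy))


def isopleth(ud: UDGrid, p: float) -> Isopleth:
    """Smallest highest-density cell set holding mass >= p.

    Cells are ranked by density (stable order), so isopleths nest:
    members(0.5) is a subset of members(0.95). Components use
    8-connectivity; areas are cell counts times cell area.
    """
    if not 0.0 < p < 1.0:
        raise ValueError("isopleth level must be in (0, 1)")
    dens = ud.density
    flat = dens.ravel()
    order = np.argsort(-flat, kind="stable")
    csum = np.cumsum(flat[order])
    k = int(np.searchsorted(csum, p, side="left")) + 1
    k = min(k, flat.size)
    mask = np.zeros(flat.size, dtype=bool)
    mask[order[:k]] = True
    mask = mask.reshape(dens.shape)

    labels, n_comp = ndimage.label(mask, structure=_EIGHT_CONN)
    cell_area = ud.grid.cell_area_km2
    comp_areas = [float(np.sum(labels == i) * cell_area)
                  for i in range(1, n_comp + 1)]
    return Isopleth(level=float(p), mask=mask,
                    area_km2=float(mask.sum() * cell_area),
                    n_components=int(n_comp),
                    component_areas_km2=comp_areas,
                    cell_area_km2=cell_area)


def _overlap_value(ud_a: UDGrid, ud_b: UDGrid, index: str, p: float) -> float:
    if index == "jaccard":
        a = isopleth(ud_a, p).mask
        b = isopleth(ud_b, p).mask
        union = np.logical_or(a, b).sum()
        if union == 0:
            return 0.0
        return float(np.logical_and(a, b).sum() / union)
    if index == "vi":
        return float(np.minimum(ud_a.density, ud_b.density).sum())
    if index == "ba":
        return float(np.sqrt(ud_a.density * ud_b.density).sum())
    raise ValueError(f"unknown overlap index {index!r}")


def monthly_overlap(traj: Trajectory, p: float = 0.95,
                    index: str = "jaccard", h: float | None = None,
                    cell_m: float = DEFAULT_CELL_M,
                    min_fixes: int = 5) -> OverlapMatrix:
    """Month-by-month UD overlap on a common grid.

    Months with fewer than ``min_fixes`` fixes are skipped (logged).
    ``h=None`` uses each month's own reference bandwidth; the common
    grid margin uses the largest per-month bandwidth.
    """
    xy = project(traj)
    months = traj.local_timestamps().dt.strftime("%Y-%m").to_numpy()

    keys = sorted(set(months))
    groups: dict[str, np.ndarray] = {}
    for key in keys:
        pts = xy[months == key]
        if len(pts) < min_fixes:
            log.info("month %s has %d fixes (< %d): skipped", key,
                     len(pts), min_fixes)
            continue
        groups[key] = pts
    if len(groups) < 2:
        raise ValueError("need at least 2 months with enough fixes")

    hs = {key: (h if h is not None else reference_bandwidth(pts))
          for key, pts in groups.items()}
    h_max = max(hs.values())
    common = _build_grid(np.vstack(list(groups.values())), h_max, cell_m)

    uds = {key: kde_ud(pts, h=hs[key], cell_m=cell_m, grid=common)
           for key, pts in groups.items()}

    keys = list(groups)
    n = len(keys)
    mat = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            val = _overlap_value(uds[keys[i]], uds[keys[j]], index, p)
            mat[i, j] = mat[j, i] = val
    return OverlapMatrix(months=keys, matrix=mat, index=index)
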