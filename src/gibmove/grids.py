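"""Lightweight regular-grid raster container with plain-text I/O.

Grids are stored in Esri ASCII grid layout: row 0 is the northernmost
row, ``(x0, y0)`` is the south-west corner of the grid, and cells are
square with side ``cell`` metres. Coordinates are in the working metric
CRS (UTM 43N).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = ["Grid"]


@dataclass
class Grid:
    x0: float
    y0: float
    cell: float
    values: np.ndarray  # (nrows, ncols); row 0 = north

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("grid values must be 2-D")
        if self.cell <= 0:
            raise ValueError("cell size must be positive")

    @property
    def nrows(self) -> int:
        return self.values.shape[0]

    @property
    def ncols(self) -> int:
        return self.values.shape[1]

    @property
    def cell_area_km2(self) -> float:
        return (self.cell / 1000.0) ** 2

    def x_centers(self) -> np.ndarray:
        return self.x0 + (np.arange(self.ncols) + 0.5) * self.cell

    def y_centers(self) -> np.ndarray:
        """Centre y per row, row 0 first (north to south)."""
        return self.y0 + (self.nrows - np.arange(self.nrows) - 0.5) * self.cell

    def center_mesh(self) -> tuple[np.ndarray, np.ndarray]:
        xx, yy = np.meshgrid(self.x_centers(), self.y_centers())
        return xx, yy

    def like(self, values: np.ndarray) -> "Grid":
        if values.shape != self.values.shape:
            raise ValueError("shape mismatch")
        return Grid(self.x0, self.y0, self.cell, values)

    # ------------------------------------------------------------------
    # Esri ASCII grid I/O (plain text)
    # ------------------------------------------------------------------
    def write_ascii(self, path: str | Path, nodata: float = -9999.0) -> None:
        path = Path(path)
        vals = np.where(np.isfinite(self.values.astype(float)),
                        self.values, nodata)
        header = (
            f"ncols {self.ncols}\n"
            f"nrows {self.nrows}\n"
            f"xllcorner {float(self.x0)!r}\n"
            f"yllcorner {float(self.y0)!r}\n"
            f"cellsize {float(self.cell)!r}\n"
            f"NODATA_value {float(nodata)!r}\n"
        )
        with open(path, "w") as fh:
            fh.write(header)
            np.savetxt(fh, vals, fmt="%.10g")

    @classmethod
    def read_ascii(cls, path: str | Path) -> "Grid":
        path = Path(path)
        meta: dict[str, float] = {}
        with open(path) as fh:
            for _ in range(6):
                key, val = fh.readline().split()
                meta[key.lower()] = float(val)
            vals = np.loadtxt(fh)
        vals = np.atleast_2d(vals)
        nodata = meta.get("nodata_value")
        if nodata is not None:
            vals = np.where(vals == nodata, np.nan, vals)
        grid = cls(meta["xllcorner"], meta["yllcorner"], meta["cellsize"], vals)
        if grid.nrows != int(meta["nrows"]) or grid.ncols != int(meta["ncols"]):
            raise ValueError(f"grid shape does not match header in {path}")
        return grid
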