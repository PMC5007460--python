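"""Lightweight gridded-raster container with plain-text (ESRI ASCII grid) I/O.

All coordinates are projected metres.  Grid values are stored as a 2-D numpy
array ``values[iy, ix]`` with row 0 at the *southern* edge, so that the y
coordinate increases with the row index; the ESRI ASCII serialization flips
rows, as that format stores the northern row first.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["Raster", "read_ascii_grid", "write_ascii_grid"]

_NODATA = -9999.0


@dataclass
class Raster:
    """A single-band grid of cell values on a regular projected lattice.

    Parameters
    ----------
    values
        2-D array indexed ``[iy, ix]``, row 0 at the southern edge.
    x0, y0
        Coordinates of the *lower-left corner* of the grid (metres).
    cell_size
        Side length of the square cells (metres).
    crs
        Free-form label of the projected coordinate reference system.
    """

    values: np.ndarray
    x0: float = 0.0
    y0: float = 0.0
    cell_size: float = 1000.0
    crs: str = "local-metric"
    nodata: float = field(default=_NODATA)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("raster values must be a 2-D array")
        if self.values.shape[0] < 1 or self.values.shape[1] < 1:
            raise ValueError("raster must have positive dimensions")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")

    # -- geometry ---------------------------------------------------------
    @property
    def ny(self) -> int:
        return self.values.shape[0]

    @property
    def nx(self) -> int:
        return self.values.shape[1]

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the outer grid edges."""
        return (
            self.x0,
            self.y0,
            self.x0 + self.nx * self.cell_size,
            self.y0 + self.ny * self.cell_size,
        )

    def cell_of(self, x: float | np.ndarray, y: float | np.ndarray):
        """Row/column indices of the cell(s) containing point(s) (x, y)."""
        ix = np.floor((np.asarray(x) - self.x0) / self.cell_size).astype(int)
        iy = np.floor((np.asarray(y) - self.y0) / self.cell_size).astype(int)
        oob = (ix < 0) | (ix >= self.nx) | (iy < 0) | (iy >= self.ny)
        if np.any(oob):
            raise ValueError("point outside raster extent")
        return iy, ix

    def value_at(self, x, y):
        """Cell value(s) at projected point(s); raises on nodata cells."""
        iy, ix = self.cell_of(x, y)
        v = self.values[iy, ix]
        if np.any(v == self.nodata) or not np.all(np.isfinite(v)):
            raise ValueError("nodata cell at requested location")
        return v

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Arrays (X, Y) of cell-centre coordinates, shaped like ``values``."""
        xs = self.x0 + (np.arange(self.nx) + 0.5) * self.cell_size
        ys = self.y0 + (np.arange(self.ny) + 0.5) * self.cell_size
        return np.meshgrid(xs, ys)

    def copy_with(self, values: np.ndarray) -> "Raster":
        return Raster(values, self.x0, self.y0, self.cell_size, self.crs, self.nodata)


def write_ascii_grid(raster: Raster, path: str | Path) -> None:
    """Serialize as an ESRI ASCII grid (text; CRS recorded in a sidecar line)."""
    path = Path(path)
    vals = np.where(np.isfinite(raster.values), raster.values, raster.nodata)
    header = (
        f"ncols {raster.nx}\n"
        f"nrows {raster.ny}\n"
        f"xllcorner {raster.x0:.6f}\n"
        f"yllcorner {raster.y0:.6f}\n"
        f"cellsize {raster.cell_size:.6f}\n"
        f"NODATA_value {raster.nodata:.6f}\n"
    )
    with path.open("w") as fh:
        fh.write(header)
        # ASCII grids store the northern row first
        np.savetxt(fh, vals[::-1], fmt="%.6f")
    path.with_suffix(path.suffix + ".crs").write_text(raster.crs + "\n")


def read_ascii_grid(path: str | Path) -> Raster:
    path = Path(path)
    meta: dict[str, float] = {}
    with path.open() as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            meta[key.lower()] = float(val)
        vals = np.loadtxt(fh)
    vals = np.atleast_2d(vals)[::-1].copy()
    crs_file = path.with_suffix(path.suffix + ".crs")
    crs = crs_file.read_text().strip() if crs_file.exists() else "unknown"
    nodata = meta.get("nodata_value", _NODATA)
    vals[vals == nodata] = np.nan
    return Raster(
        vals,
        x0=meta["xllcorner"],
        y0=meta["yllcorner"],
        cell_size=meta["cellsize"],
        crs=crs,
        nodata=nodata,
    )
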