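"""Georeferenced raster grids (DEM / DSM / CSM / spectral bands / masks).

A :class:`RasterGrid` is a plain 2-D array with a local planar georeference:
the field coordinate frame has its origin at the south-west corner, x
pointing east and y pointing north, units of meters, and cell-center
registration.  Row 0 of ``values`` is the northernmost row, matching the
usual raster convention.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["RasterGrid", "GridMismatchError"]


class GridMismatchError(ValueError):
    """Two rasters do not share origin / cell size / shape."""


@dataclass
class RasterGrid:
    """2-D grid of values with origin, cell size and a nodata marker.

    Parameters
    ----------
    origin : (float, float)
        (x, y) of the grid's south-west *corner* in field meters.
    cell_size : float
        Edge length of a square cell, meters.
    values : ndarray of shape (n_rows, n_cols)
        Cell values; row 0 is the northernmost row.
    nodata : float
        Marker for missing cells.  NaN is used internally; any nodata
        value found in ``values`` is converted to NaN on construction.
    """

    origin: tuple[float, float]
    cell_size: float
    values: np.ndarray
    nodata: float = float("nan")

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ValueError(f"cell_size must be positive, got {self.cell_size}")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or min(self.values.shape) < 1:
            raise ValueError("values must be a 2-D array with at least one cell")
        if not np.isnan(self.nodata):
            self.values = np.where(self.values == self.nodata, np.nan, self.values)
            self.nodata = float("nan")

    # -- geometry -----------------------------------------------------------
    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the grid's outer edges."""
        x0, y0 = self.origin
        return (x0, y0, x0 + self.n_cols * self.cell_size, y0 + self.n_rows * self.cell_size)

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (x, y) arrays of cell-center coordinates, shape (n_rows, n_cols)."""
        x0, y0 = self.origin
        cs = self.cell_size
        xs = x0 + (np.arange(self.n_cols) + 0.5) * cs
        # row 0 is northernmost
        ys = y0 + (self.n_rows - np.arange(self.n_rows) - 0.5) * cs
        return np.meshgrid(xs, ys)

    def same_geometry(self, other: "RasterGrid", tol: float = 1e-9) -> bool:
        return (
            self.values.shape == other.values.shape
            and abs(self.cell_size - other.cell_size) <= tol
            and abs(self.origin[0] - other.origin[0]) <= tol
            and abs(self.origin[1] - other.origin[1]) <= tol
        )

    def require_same_geometry(self, other: "RasterGrid") -> None:
        if not self.same_geometry(other):
            raise GridMismatchError(
                f"grid geometry mismatch: {self.values.shape}@{self.origin} vs "
                f"{other.values.shape}@{other.origin}"
            )

    def copy_with(self, values: np.ndarray) -> "RasterGrid":
        return RasterGrid(self.origin, self.cell_size, np.asarray(values, float))

    @property
    def mask_valid(self) -> np.ndarray:
        return ~np.isnan(self.values)

    # -- I/O ----------------------------------------------------------------
    def to_ascii(self, path: str | Path, nodata: float = -9999.0) -> None:
        """Write an ESRI ASCII grid (plain text, self-describing)."""
        vals = np.where(np.isnan(self.values), nodata, self.values)
        header = (
            f"ncols {self.n_cols}\n"
            f"nrows {self.n_rows}\n"
            f"xllcorner {self.origin[0]:.6f}\n"
            f"yllcorner {self.origin[1]:.6f}\n"
            f"cellsize {self.cell_size:.6f}\n"
            f"NODATA_value {nodata}\n"
        )
        with open(path, "w") as fh:
            fh.write(header)
            np.savetxt(fh, vals, fmt="%.6g")

    @classmethod
    def from_ascii(cls, path: str | Path) -> "RasterGrid":
        meta: dict[str, float] = {}
        with open(path) as fh:
            lines = fh.readlines()
        n_header = 0
        for line in lines:
            parts = line.split()
            if len(parts) == 2 and parts[0].lower() in {
                "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value",
            }:
                meta[parts[0].lower()] = float(parts[1])
                n_header += 1
            else:
                break
        vals = np.loadtxt(lines[n_header:], ndmin=2)
        nodata = meta.get("nodata_value", -9999.0)
        vals = np.where(vals == nodata, np.nan, vals)
        return cls(
            origin=(meta["xllcorner"], meta["yllcorner"]),
            cell_size=meta["cellsize"],
            values=vals,
        )

    def to_geotiff(self, path: str | Path) -> None:
        """Write a single-band GeoTIFF with ModelPixelScale/ModelTiepoint tags."""
        import tifffile

        x0, y0 = self.origin
        cs = self.cell_size
        y_top = y0 + self.n_rows * cs
        pixel_scale = (cs, cs, 0.0)
        tiepoint = (0.0, 0.0, 0.0, x0, y_top, 0.0)
        extratags = [
            (33550, "d", 3, pixel_scale, True),   # ModelPixelScaleTag
            (33922, "d", 6, tiepoint, True),      # ModelTiepointTag
        ]
        tifffile.imwrite(path, self.values.astype(np.float32), extratags=extratags)

    @classmethod
    def from_geotiff(cls, path: str | Path) -> "RasterGrid":
        import tifffile

        with tifffile.TiffFile(path) as tf:
            page = tf.pages[0]
            vals = page.asarray().astype(float)
            scale = page.tags.get(33550)
            tie = page.tags.get(33922)
            if scale is None or tie is None:
                raise ValueError(f"{path}: missing GeoTIFF georeference tags")
            cs = float(scale.value[0])
            x0 = float(tie.value[3])
            y_top = float(tie.value[4])
        origin = (x0, y_top - vals.shape[0] * cs)
        return cls(origin=origin, cell_size=cs, values=vals)

    def meta_dict(self) -> dict:
        return {
            "origin": list(self.origin),
            "cell_size": self.cell_size,
            "n_rows": self.n_rows,
            "n_cols": self.n_cols,
        }
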