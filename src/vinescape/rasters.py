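"""Single-band planar rasters on a regular grid.

All landscape layers in this package live on one axis-aligned 100 m grid in a
planar (projected, metre-based) coordinate system.  A :class:`Raster` couples
the cell array with the grid geometry; values are addressed either by row /
column index or by map coordinates.  TIFF round-trips store the geometry in
the ImageDescription tag as JSON, which keeps files readable by any TIFF tool
while preserving the georeferencing this package needs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import tifffile

__all__ = ["Raster", "read_raster", "write_raster"]


@dataclass
class Raster:
    """A single-band raster with planar-grid metadata.

    Parameters
    ----------
    values
        2-D array indexed ``[row, col]``; row 0 is the northernmost row.
    x_origin, y_origin
        Map coordinates of the *outer corner* of cell ``[0, 0]`` (west edge,
        north edge).
    cell_size
        Cell edge length in metres (cells are square).
    crs
        Free-text CRS descriptor; planar metre-based systems only.
    """

    values: np.ndarray
    x_origin: float = 0.0
    y_origin: float = 0.0
    cell_size: float = 100.0
    crs: str = "local-planar-metres"
    nodata: float | None = None
    tags: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("raster values must be 2-D")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, xmax, ymin, ymax) of the outer raster edge."""
        nrow, ncol = self.values.shape
        return (
            self.x_origin,
            self.x_origin + ncol * self.cell_size,
            self.y_origin - nrow * self.cell_size,
            self.y_origin,
        )

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Map coordinates (x, y) of every cell centre, as 2-D arrays."""
        nrow, ncol = self.values.shape
        xs = self.x_origin + (np.arange(ncol) + 0.5) * self.cell_size
        ys = self.y_origin - (np.arange(nrow) + 0.5) * self.cell_size
        return np.meshgrid(xs, ys)

    def index_of(self, x: float, y: float) -> tuple[int, int]:
        """Row/column of the cell containing map point (x, y)."""
        col = int(np.floor((x - self.x_origin) / self.cell_size))
        row = int(np.floor((self.y_origin - y) / self.cell_size))
        nrow, ncol = self.values.shape
        if not (0 <= row < nrow and 0 <= col < ncol):
            raise ValueError(f"point ({x}, {y}) lies outside the raster")
        return row, col

    def contains(self, x: float, y: float, margin: float = 0.0) -> bool:
        xmin, xmax, ymin, ymax = self.extent
        return (
            xmin + margin <= x <= xmax - margin
            and ymin + margin <= y <= ymax - margin
        )


def write_raster(path, raster: Raster) -> None:
    """Write a raster as single-band TIFF with JSON grid metadata."""
    meta = {
        "x_origin": raster.x_origin,
        "y_origin": raster.y_origin,
        "cell_size": raster.cell_size,
        "crs": raster.crs,
        "nodata": raster.nodata,
        "tags": raster.tags,
    }
    tifffile.imwrite(str(path), raster.values, description=json.dumps(meta))


def read_raster(path) -> Raster:
    """Read a raster written by :func:`write_raster`."""
    with tifffile.TiffFile(str(path)) as tif:
        page = tif.pages[0]
        values = page.asarray()
        desc = page.tags.get("ImageDescription")
        meta = json.loads(desc.value) if desc is not None else {}
    return Raster(
        values=values,
        x_origin=meta.get("x_origin", 0.0),
        y_origin=meta.get("y_origin", 0.0),
        cell_size=meta.get("cell_size", 100.0),
        crs=meta.get("crs", "local-planar-metres"),
        nodata=meta.get("nodata"),
        tags=meta.get("tags", {}),
    )
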