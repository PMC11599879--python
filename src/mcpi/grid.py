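"""Planar raster lattice with an explicit geotransform.

All geometry in this package is planar (projected metres).  A grid is a
rectangular array of cells of side ``pixel_size``; cell ``(row, col)`` has its
centre at ``(x0 + (col + 0.5) * pixel_size, y0 + (row + 0.5) * pixel_size)``
where ``(x0, y0)`` is the lower-left corner of the lattice.  Row index grows
with y.  Grids are persisted as ESRI ASCII grid (.asc), a plain-text format.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["RasterGrid", "RegistrationError"]


class RegistrationError(ValueError):
    """Raised when two rasters that must be co-registered are not."""


@dataclass
class RasterGrid:
    """A 2D value lattice on a square-cell planar grid.

    Parameters
    ----------
    values : ndarray, shape (n_rows, n_cols)
        Cell values; boolean arrays are allowed for masks.
    x0, y0 : float
        Planar coordinates (m) of the lower-left corner of the lattice.
    pixel_size : float
        Cell side length in metres; must be positive.
    nodata : float
        Sentinel marking missing cells in float-valued grids.
    """

    values: np.ndarray
    x0: float = 0.0
    y0: float = 0.0
    pixel_size: float = 30.0
    nodata: float = -9999.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("raster values must be 2-D")
        if self.pixel_size <= 0:
            raise ValueError(f"pixel size must be positive, got {self.pixel_size}")
        if np.issubdtype(self.values.dtype, np.floating):
            bad = ~np.isfinite(self.values) & (self.values != self.nodata)
            if bad.any():
                raise ValueError("raster contains non-finite values that are not nodata")

    # -- geometry ---------------------------------------------------------

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the lattice in planar metres."""
        return (
            self.x0,
            self.y0,
            self.x0 + self.n_cols * self.pixel_size,
            self.y0 + self.n_rows * self.pixel_size,
        )

    def same_geometry(self, other: "RasterGrid") -> bool:
        return (
            self.shape == other.shape
            and np.isclose(self.x0, other.x0)
            and np.isclose(self.y0, other.y0)
            and np.isclose(self.pixel_size, other.pixel_size)
        )

    def require_registered(self, other: "RasterGrid") -> None:
        if not self.same_geometry(other):
            raise RegistrationError(
                "rasters are not co-registered: "
                f"{self.shape}@({self.x0},{self.y0},{self.pixel_size}) vs "
                f"{other.shape}@({other.x0},{other.y0},{other.pixel_size})"
            )

    def world_to_index(self, x, y):
        """Map planar coordinates to (row, col) of the containing cell.

        Cells are half-open: a point on a shared cell edge belongs to the
        cell with the larger index.  Out-of-extent points yield indices
        outside ``[0, n)``; callers filter with :meth:`in_bounds`.
        """
        col = np.floor((np.asarray(x) - self.x0) / self.pixel_size).astype(int)
        row = np.floor((np.asarray(y) - self.y0) / self.pixel_size).astype(int)
        return row, col

    def index_to_world(self, row, col):
        """Planar coordinates of cell centres."""
        x = self.x0 + (np.asarray(col) + 0.5) * self.pixel_size
        y = self.y0 + (np.asarray(row) + 0.5) * self.pixel_size
        return x, y

    def in_bounds(self, row, col):
        row = np.asarray(row)
        col = np.asarray(col)
        return (row >= 0) & (row < self.n_rows) & (col >= 0) & (col < self.n_cols)

    def cell_centres(self, where: np.ndarray | None = None):
        """Planar (x, y) of all cell centres, or of cells where ``where`` is True."""
        if where is None:
            rows, cols = np.indices(self.shape)
            rows, cols = rows.ravel(), cols.ravel()
        else:
            rows, cols = np.nonzero(where)
        return self.index_to_world(rows, cols)

    def is_nodata(self, values=None) -> np.ndarray:
        v = self.values if values is None else values
        return np.asarray(v) == self.nodata

    def copy(self) -> "RasterGrid":
        return RasterGrid(self.values.copy(), self.x0, self.y0, self.pixel_size, self.nodata)

    # -- text persistence (ESRI ASCII grid) -------------------------------

    def write_ascii(self, path: str | Path, fmt: str = "%.6g") -> None:
        path = Path(path)
        v = self.values
        if v.dtype == bool:
            v = v.astype(np.uint8)
        header = (
            f"ncols {self.n_cols}\n"
            f"nrows {self.n_rows}\n"
            f"xllcorner {self.x0!r}\n"
            f"yllcorner {self.y0!r}\n"
            f"cellsize {self.pixel_size!r}\n"
            f"NODATA_value {self.nodata!r}\n"
        )
        with open(path, "w") as fh:
            fh.write(header)
            # .asc rows run north to south: flip so row 0 of the file is max-y
            np.savetxt(fh, v[::-1], fmt=fmt)

    @classmethod
    def read_ascii(cls, path: str | Path, dtype=float) -> "RasterGrid":
        path = Path(path)
        header: dict[str, float] = {}
        with open(path) as fh:
            for _ in range(6):
                key, val = fh.readline().split()
                header[key.lower()] = float(val)
            body = np.loadtxt(fh, dtype=dtype)
        body = np.atleast_2d(body)[::-1]
        return cls(
            body,
            x0=header["xllcorner"],
            y0=header["yllcorner"],
            pixel_size=header["cellsize"],
            nodata=header["nodata_value"],
        )
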