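"""Minimal single-band raster container with ESRI ASCII-grid text I/O.

All geometry in this package lives in one projected planar CRS with
coordinates in metres.  A :class:`Raster` is a 2-D float array plus the
affine information of a north-up, square-pixel grid: the lower-left corner
of the extent and the pixel size.  Row 0 of ``data`` is the *top* (northern)
row, matching the ESRI ASCII-grid convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = ["Raster", "read_ascii_grid", "write_ascii_grid"]

_NODATA = -9999.0


@dataclass
class Raster:
    """A single-band, north-up raster with square pixels.

    Parameters
    ----------
    data
        2-D array of shape ``(nrows, ncols)``; row 0 is the northern row.
        Missing cells are NaN.
    xll, yll
        Coordinates (m) of the lower-left corner of the extent.
    cellsize
        Pixel edge length in metres.
    """

    data: np.ndarray
    xll: float
    yll: float
    cellsize: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("raster data must be 2-D")
        if self.cellsize <= 0:
            raise ValueError("cellsize must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the pixel extent."""
        ny, nx = self.data.shape
        return (
            self.xll,
            self.yll,
            self.xll + nx * self.cellsize,
            self.yll + ny * self.cellsize,
        )

    def pixel_centroids(self) -> tuple[np.ndarray, np.ndarray]:
        """Coordinates of every pixel centre as two ``(nrows, ncols)`` arrays."""
        ny, nx = self.data.shape
        xs = self.xll + (np.arange(nx) + 0.5) * self.cellsize
        ys = self.yll + (ny - np.arange(ny) - 0.5) * self.cellsize
        return np.meshgrid(xs, ys)

    def copy_with(self, data: np.ndarray) -> "Raster":
        """New raster on the same grid with different values."""
        if data.shape != self.data.shape:
            raise ValueError("shape mismatch")
        return Raster(np.asarray(data, dtype=float), self.xll, self.yll, self.cellsize)


def write_ascii_grid(raster: Raster, path: str | Path) -> None:
    """Write a raster as an ESRI ASCII grid (plain text)."""
    ny, nx = raster.data.shape
    out = np.where(np.isnan(raster.data), _NODATA, raster.data)
    header = (
        f"ncols {nx}\n"
        f"nrows {ny}\n"
        f"xllcorner {raster.xll!r}\n"
        f"yllcorner {raster.yll!r}\n"
        f"cellsize {raster.cellsize!r}\n"
        f"NODATA_value {_NODATA!r}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, out, fmt="%.10g")


def read_ascii_grid(path: str | Path) -> Raster:
    """Read an ESRI ASCII grid written by :func:`write_ascii_grid`."""
    header: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            key, value = fh.readline().split()
            header[key.lower()] = float(value)
        data = np.loadtxt(fh, ndmin=2)
    nodata = header.get("nodata_value", _NODATA)
    data = np.where(data == nodata, np.nan, data)
    if data.shape != (int(header["nrows"]), int(header["ncols"])):
        raise ValueError(f"grid shape {data.shape} disagrees with header")
    return Raster(data, header["xllcorner"], header["yllcorner"], header["cellsize"])
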