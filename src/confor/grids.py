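"""Raster data model, GeoTIFF I/O, alignment checks and area accounting.

Every stage of the pipeline operates on :class:`Grid` objects: 2-D numpy
arrays with square pixels, a simple affine placement (top-left origin plus
pixel size) and an explicit nodata sentinel. All areas derive from pixel
counts — at the native 100 m resolution one pixel is exactly 1 ha — and no
vector geometry is involved anywhere.

GeoTIFFs are read and written through :mod:`tifffile` using the standard
GeoTIFF georeferencing tags (ModelPixelScale, ModelTiepoint) and the
GDAL_NODATA tag. Only single-band, square-pixel rasters are supported;
reprojection and CRS handling are out of scope.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import tifffile

__all__ = [
    "Grid",
    "Mask",
    "read_grid",
    "write_grid",
    "assert_aligned",
    "area_of",
]

TAG_MODEL_PIXEL_SCALE = 33550
TAG_MODEL_TIEPOINT = 33922
TAG_GDAL_NODATA = 42113


@dataclass(eq=False)
class Grid:
    """A single-band raster with square pixels.

    Parameters
    ----------
    values
        2-D array of cell values (numeric or categorical codes).
    pixel_size_m
        Edge length of one (square) pixel in meters. The default of 100 m
        gives the 1-ha cells the analysis is defined on.
    origin
        ``(x, y)`` world coordinates of the top-left corner of the top-left
        pixel, or ``None`` for a grid without georeferencing (such grids
        cannot be written to disk).
    nodata
        Sentinel marking cells outside the data extent. ``NaN`` is allowed
        for float grids. ``None`` means every cell is valid.
    """

    values: np.ndarray
    pixel_size_m: float = 100.0
    origin: tuple[float, float] | None = (0.0, 0.0)
    nodata: float | int | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError(f"Grid values must be 2-D, got shape {self.values.shape}")
        if not self.pixel_size_m > 0:
            raise ValueError(f"pixel_size_m must be positive, got {self.pixel_size_m}")

    # -- geometry -----------------------------------------------------------

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def pixel_area_ha(self) -> float:
        """Area of one pixel in hectares (exactly 1.0 at 100 m pixels)."""
        return self.pixel_size_m**2 / 10_000.0

    @property
    def valid(self) -> np.ndarray:
        """Boolean array of cells inside the data extent."""
        if self.nodata is None:
            return np.ones(self.shape, dtype=bool)
        if isinstance(self.nodata, float) and np.isnan(self.nodata):
            return ~np.isnan(self.values)
        return self.values != self.nodata

    def like(self, values: np.ndarray, nodata: float | int | None = None) -> "Grid":
        """A new grid sharing this grid's placement but holding ``values``."""
        return Grid(np.asarray(values), self.pixel_size_m, self.origin, nodata)

    def copy(self) -> "Grid":
        return replace(self, values=self.values.copy())


class Mask(Grid):
    """Boolean membership raster.

    Values are stored as uint8: 1 = member, 0 = non-member, and the nodata
    code (255) marks cells outside the data extent — nodata is deliberately
    distinct from "not a member".
    """

    NODATA = 255

    @classmethod
    def from_bool(
        cls,
        members: np.ndarray,
        like: Grid,
        valid: np.ndarray | None = None,
    ) -> "Mask":
        vals = np.asarray(members, dtype=bool).astype(np.uint8)
        if valid is not None:
            vals = np.where(np.asarray(valid, dtype=bool), vals, cls.NODATA)
        return cls(vals, like.pixel_size_m, like.origin, nodata=cls.NODATA)

    @classmethod
    def from_grid(cls, grid: Grid) -> "Mask":
        """Reinterpret a 0/1 grid (e.g. freshly read from disk) as a Mask."""
        nodata = cls.NODATA if grid.nodata is None else grid.nodata
        vals = np.asarray(grid.values)
        out = np.where(vals == 1, 1, 0).astype(np.uint8)
        if grid.nodata is not None:
            out = np.where(grid.valid, out, cls.NODATA)
        return cls(out, grid.pixel_size_m, grid.origin, nodata=nodata)

    @property
    def members(self) -> np.ndarray:
        return self.values == 1


# -- GeoTIFF I/O -------------------------------------------------------------


def write_grid(grid: Grid, path: str | os.PathLike) -> Path:
    """Write ``grid`` to ``path`` as a single-band GeoTIFF.

    Boolean arrays are stored as uint8. Round-trips losslessly for integer
    and float data. Raises if the grid carries no georeferencing.
    """
    if grid.origin is None:
        raise ValueError("cannot write a grid without georeferencing (origin is None)")
    path = Path(path)
    values = grid.values
    if values.dtype == bool:
        values = values.astype(np.uint8)
    px = float(grid.pixel_size_m)
    x0, y0 = (float(c) for c in grid.origin)
    extratags = [
        (TAG_MODEL_PIXEL_SCALE, "d", 3, (px, px, 0.0)),
        (TAG_MODEL_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, x0, y0, 0.0)),
    ]
    if grid.nodata is not None:
        extratags.append((TAG_GDAL_NODATA, "s", 0, repr(grid.nodata)))
    tifffile.imwrite(path, values, extratags=extratags)
    return path


def _parse_nodata(text: str, dtype: np.dtype) -> float | int:
    value = float(text)
    if np.issubdtype(dtype, np.integer):
        return int(value)
    return value


def read_grid(path: str | os.PathLike) -> Grid:
    """Read a single-band GeoTIFF written by :func:`write_grid` (or any
    square-pixel GeoTIFF with ModelPixelScale/ModelTiepoint tags)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"raster not found: {path}")
    with tifffile.TiffFile(path) as tif:
        if len(tif.pages) != 1:
            raise ValueError(f"{path}: multi-band (multi-page) rasters are not supported")
        page = tif.pages[0]
        if getattr(page, "samplesperpixel", 1) != 1:
            raise ValueError(f"{path}: multi-band rasters are not supported")
        tags = page.tags
        if TAG_MODEL_PIXEL_SCALE not in tags or TAG_MODEL_TIEPOINT not in tags:
            raise ValueError(f"{path}: missing GeoTIFF georeferencing tags")
        sx, sy = (float(v) for v in tags[TAG_MODEL_PIXEL_SCALE].value[:2])
        if not np.isclose(sx, sy, rtol=1e-9):
            raise ValueError(f"{path}: non-square pixels ({sx} x {sy} m)")
        tie = tags[TAG_MODEL_TIEPOINT].value
        origin = (float(tie[3]), float(tie[4]))
        values = page.asarray()
        nodata = None
        if TAG_GDAL_NODATA in tags:
            nodata = _parse_nodata(str(tags[TAG_GDAL_NODATA].value), values.dtype)
    return Grid(values, pixel_size_m=sx, origin=origin, nodata=nodata)


# -- alignment & areas -------------------------------------------------------


def assert_aligned(grids: Sequence[Grid], names: Sequence[str] | None = None) -> None:
    """Check that all grids share shape, pixel size and placement.

    Raises ``ValueError`` naming the offending grid and property on the
    first mismatch.
    """
    grids = list(grids)
    if len(grids) < 2:
        raise ValueError("assert_aligned needs at least two grids")
    if names is None:
        names = [f"grid[{i}]" for i in range(len(grids))]
    ref = grids[0]
    for name, g in zip(names[1:], grids[1:]):
        if g.shape != ref.shape:
            raise ValueError(f"{name}: shape {g.shape} != {ref.shape} of {names[0]}")
        if not np.isclose(g.pixel_size_m, ref.pixel_size_m, rtol=1e-9):
            raise ValueError(
                f"{name}: pixel size {g.pixel_size_m} != {ref.pixel_size_m} of {names[0]}"
            )
        if (g.origin is None) != (ref.origin is None) or (
            g.origin is not None
            and not np.allclose(g.origin, ref.origin, rtol=0, atol=1e-6)
        ):
            raise ValueError(f"{name}: origin {g.origin} != {ref.origin} of {names[0]}")


def area_of(mask: Mask) -> float:
    """Total member area in hectares: member pixel count x pixel area."""
    return float(mask.members.sum()) * mask.pixel_area_ha
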