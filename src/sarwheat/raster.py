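"""Grid data model and GeoTIFF I/O shared by every pipeline stage.

A :class:`Raster` is a 2-D array on a north-up, square-pixel grid described
by :class:`GridMeta`.  Conventions used throughout the package:

* pixel ``(0, 0)`` is the north-west pixel; rows increase southwards;
* map<->pixel conversion refers to pixel *centres*;
* extents are half-open ``[min, max)`` rectangles in map units;
* invalid pixels carry ``meta.nodata_value`` and are excluded from all
  statistics downstream.

GeoTIFF files are written with the standard ModelPixelScale / ModelTiepoint
tags plus the GDAL nodata tag, and a small JSON payload in the image
description carrying the CRS identifier and the value units.  Class-code
maps are written as uint8 with a JSON legend sidecar.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import tifffile

__all__ = [
    "GridMeta",
    "Raster",
    "CLASS_LEGEND",
    "read_raster",
    "write_raster",
    "mosaic_same_date",
    "crop",
]

# canonical class codes for the four-class land-cover problem
CLASS_LEGEND: dict[int, str] = {
    1: "winter_wheat",
    2: "other_vegetation",
    3: "building",
    4: "water",
    255: "nodata",
}

FLOAT_NODATA = -9999.0
CLASS_NODATA = 255

# TIFF tag codes
_TAG_PIXEL_SCALE = 33550
_TAG_TIEPOINT = 33922
_TAG_GDAL_NODATA = 42113


@dataclass(frozen=True)
class GridMeta:
    """Geometry of a north-up raster grid with square pixels."""

    n_rows: int
    n_cols: int
    pixel_size: float
    origin: tuple[float, float]  # map (x, y) of the grid's top-left corner
    crs_id: str = "local"
    nodata_value: float = FLOAT_NODATA

    def __post_init__(self) -> None:
        if self.n_rows <= 0 or self.n_cols <= 0:
            raise ValueError("grid must have positive dimensions")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    def aligned_with(self, other: "GridMeta") -> bool:
        """Two rasters are aligned iff every GridMeta field matches."""
        return (
            self.shape == other.shape
            and self.pixel_size == other.pixel_size
            and self.origin == other.origin
            and self.crs_id == other.crs_id
            and self.nodata_value == other.nodata_value
        )

    def pixel_center(self, row: int, col: int) -> tuple[float, float]:
        x0, y0 = self.origin
        return (
            x0 + (col + 0.5) * self.pixel_size,
            y0 - (row + 0.5) * self.pixel_size,
        )

    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the full grid in map units."""
        x0, y0 = self.origin
        return (
            x0,
            y0 - self.n_rows * self.pixel_size,
            x0 + self.n_cols * self.pixel_size,
            y0,
        )


@dataclass
class Raster:
    """A single-band grid of values with units metadata."""

    meta: GridMeta
    values: np.ndarray
    units: str = "index"  # DN | dB | reflectance | index | class-code

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.shape != self.meta.shape:
            raise ValueError(
                f"array shape {self.values.shape} != grid shape {self.meta.shape}"
            )

    @property
    def valid_mask(self) -> np.ndarray:
        return self.values != self.meta.nodata_value

    def valid_values(self) -> np.ndarray:
        return self.values[self.valid_mask]

    def with_values(self, values: np.ndarray, units: str | None = None) -> "Raster":
        return Raster(self.meta, values, units if units is not None else self.units)


def _require_aligned(rasters: Sequence[Raster]) -> None:
    first = rasters[0].meta
    for r in rasters[1:]:
        if not first.aligned_with(r.meta):
            raise ValueError("rasters are not on one aligned grid")


def write_raster(raster: Raster, path: str | os.PathLike) -> None:
    """Write a raster to GeoTIFF.

    Class-code rasters are written as uint8 with a ``<path>.legend.json``
    sidecar mapping codes to labels; everything else as float32/float64.
    """
    meta = raster.meta
    values = raster.values
    if raster.units == "class-code":
        values = values.astype(np.uint8)
    else:
        values = values.astype(np.float32)
    desc = json.dumps(
        {"crs_id": meta.crs_id, "units": raster.units, "nodata": meta.nodata_value}
    )
    x0, y0 = meta.origin
    extratags = [
        (_TAG_PIXEL_SCALE, "d", 3, (meta.pixel_size, meta.pixel_size, 0.0)),
        # raster point (0,0,0) maps to the top-left corner
        (_TAG_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, x0, y0, 0.0)),
        (_TAG_GDAL_NODATA, "s", 0, str(meta.nodata_value)),
    ]
    tifffile.imwrite(path, values, description=desc, extratags=extratags)
    if raster.units == "class-code":
        legend = {str(k): v for k, v in CLASS_LEGEND.items()}
        with open(str(path) + ".legend.json", "w") as fh:
            json.dump(legend, fh, indent=1)


def read_raster(path: str | os.PathLike) -> Raster:
    """Read a single-band GeoTIFF written by :func:`write_raster` (or any
    GeoTIFF carrying pixel-scale and tiepoint tags)."""
    if not os.path.exists(path):
        raise FileNotFoundError(f"raster file not found: {path}")
    try:
        with tifffile.TiffFile(path) as tif:
            page = tif.pages[0]
            values = page.asarray()
            tags = page.tags
            scale = tags.get(_TAG_PIXEL_SCALE)
            tie = tags.get(_TAG_TIEPOINT)
            if scale is None or tie is None:
                raise ValueError(f"missing georeferencing tags in {path}")
            pixel_size = float(scale.value[0])
            # tiepoint: raster (i, j, k) -> map (x, y, z); shift back to corner
            i, j = float(tie.value[0]), float(tie.value[1])
            x, y = float(tie.value[3]), float(tie.value[4])
            origin = (x - i * pixel_size, y + j * pixel_size)
            nodata_tag = tags.get(_TAG_GDAL_NODATA)
            desc_tag = tags.get("ImageDescription")
    except tifffile.TiffFileError as exc:
        raise ValueError(f"unreadable raster format: {path}") from exc
    crs_id, units = "local", "index"
    nodata = FLOAT_NODATA
    if desc_tag is not None:
        try:
            info = json.loads(desc_tag.value)
            crs_id = info.get("crs_id", crs_id)
            units = info.get("units", units)
            nodata = info.get("nodata", nodata)
        except (json.JSONDecodeError, TypeError):
            pass
    if nodata_tag is not None:
        nodata = float(nodata_tag.value)
    if values.dtype == np.uint8 and units == "class-code":
        values = values.astype(np.uint8)
        nodata = int(nodata)
    else:
        values = values.astype(np.float64)
    meta = GridMeta(
        n_rows=values.shape[0],
        n_cols=values.shape[1],
        pixel_size=pixel_size,
        origin=origin,
        crs_id=crs_id,
        nodata_value=nodata,
    )
    return Raster(meta, values, units)


def mosaic_same_date(tiles: Sequence[Raster]) -> Raster:
    """Mosaic same-date tiles onto their union extent.

    Where tiles overlap the first tile's valid pixel wins; output nodata
    only where no tile has data.  All tiles must share CRS, pixel size and
    units, and their origins must sit on one common pixel lattice.
    """
    if not tiles:
        raise ValueError("no tiles to mosaic")
    first = tiles[0]
    ps = first.meta.pixel_size
    for t in tiles[1:]:
        if t.meta.pixel_size != ps:
            raise ValueError("mismatched pixel_size among tiles")
        if t.meta.crs_id != first.meta.crs_id:
            raise ValueError("mismatched crs among tiles")
        if t.units != first.units:
            raise ValueError("mismatched units among tiles")
    if len(tiles) == 1:
        return first

    xmin = min(t.meta.origin[0] for t in tiles)
    ymax = max(t.meta.origin[1] for t in tiles)
    xmax = max(t.meta.extent()[2] for t in tiles)
    ymin = min(t.meta.extent()[1] for t in tiles)
    n_cols = int(round((xmax - xmin) / ps))
    n_rows = int(round((ymax - ymin) / ps))
    nodata = first.meta.nodata_value
    meta = GridMeta(
        n_rows, n_cols, ps, (xmin, ymax), first.meta.crs_id, nodata
    )
    dtype = first.values.dtype
    out = np.full((n_rows, n_cols), nodata, dtype=dtype)
    filled = np.zeros((n_rows, n_cols), dtype=bool)
    for t in tiles:
        r0 = int(round((ymax - t.meta.origin[1]) / ps))
        c0 = int(round((t.meta.origin[0] - xmin) / ps))
        if not np.isclose(r0 * ps, ymax - t.meta.origin[1]) or not np.isclose(
            c0 * ps, t.meta.origin[0] - xmin
        ):
            raise ValueError("tile origins are not on a common pixel lattice")
        sl = (slice(r0, r0 + t.meta.n_rows), slice(c0, c0 + t.meta.n_cols))
        valid = t.values != t.meta.nodata_value
        take = valid & ~filled[sl]
        out[sl][take] = t.values[take]
        filled[sl] |= take
    return Raster(meta, out, first.units)


def crop(raster: Raster, extent: tuple[float, float, float, float]) -> Raster:
    """Crop to the pixels whose centres fall inside the half-open
    ``(xmin, ymin, xmax, ymax)`` rectangle.  Never resamples."""
    xmin, ymin, xmax, ymax = extent
    meta = raster.meta
    ps = meta.pixel_size
    x0, y0 = meta.origin
    cols = np.arange(meta.n_cols)
    rows = np.arange(meta.n_rows)
    cx = x0 + (cols + 0.5) * ps
    cy = y0 - (rows + 0.5) * ps
    keep_c = (cx >= xmin) & (cx < xmax)
    keep_r = (cy < ymax) & (cy >= ymin)
    if not keep_c.any() or not keep_r.any():
        raise ValueError("crop extent does not intersect the raster")
    c_lo, c_hi = np.flatnonzero(keep_c)[[0, -1]]
    r_lo, r_hi = np.flatnonzero(keep_r)[[0, -1]]
    sub = raster.values[r_lo : r_hi + 1, c_lo : c_hi + 1]
    new_meta = replace(
        meta,
        n_rows=sub.shape[0],
        n_cols=sub.shape[1],
        origin=(x0 + c_lo * ps, y0 - r_lo * ps),
    )
    return Raster(new_meta, sub.copy(), raster.units)
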