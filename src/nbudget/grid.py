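"""Single-band rasters on the analysis grid and GeoTIFF I/O.

The analysis grid is a north-up regular grid: row 0 is the northern edge,
cell (r, c) spans the half-open extent
``[x0 + c*dx, x0 + (c+1)*dx) x (y0 - (r+1)*dy, y0 - r*dy]`` and its center is
``(x0 + (c+0.5)*dx, y0 - (r+0.5)*dy)``.  Flux layers hold whole-cell totals
(kg N per cell) in float64; class and region-membership layers are int32.

GeoTIFF files are written with :mod:`tifffile`, carrying the georeference in
the standard ModelPixelScale (33550) and ModelTiepoint (33922) tags, the
nodata sentinel in GDAL_NODATA (42113), and the CRS identifier in the image
description.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile

from .errors import GridIncompatibleError, ValidationError

_TAG_MODEL_PIXEL_SCALE = 33550
_TAG_MODEL_TIEPOINT = 33922
_TAG_GDAL_NODATA = 42113


@dataclass(frozen=True)
class GridTransform:
    """North-up affine georeference: top-left corner and positive cell sizes."""

    x0: float
    y0: float
    dx: float
    dy: float

    def cell_centers(self, shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
        """Return (xs, ys) broadcastable center coordinates for an array shape."""
        rows, cols = shape
        xs = self.x0 + (np.arange(cols) + 0.5) * self.dx
        ys = self.y0 - (np.arange(rows) + 0.5) * self.dy
        return xs, ys

    def index_of(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Row/col indices of the cells containing points (half-open pixels)."""
        col = np.floor((np.asarray(x) - self.x0) / self.dx).astype(np.int64)
        row = np.floor((self.y0 - np.asarray(y)) / self.dy).astype(np.int64)
        return row, col

    def almost_equal(self, other: "GridTransform", rtol: float = 1e-9) -> bool:
        return all(
            math.isclose(a, b, rel_tol=rtol, abs_tol=1e-9)
            for a, b in zip(
                (self.x0, self.y0, self.dx, self.dy),
                (other.x0, other.y0, other.dx, other.dy),
            )
        )


@dataclass
class GridMap:
    """A single-variable raster: values + georeference + nodata sentinel.

    ``nodata`` may be NaN (the float-layer default), any finite sentinel
    (int layers use -1), or None for a gap-free layer.
    """

    values: np.ndarray
    transform: GridTransform
    nodata: float | int | None = math.nan
    crs: str = "local-synthetic-equal-area"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValidationError("GridMap values must be a 2-D array")

    # -- masks and aggregates -------------------------------------------------

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape  # type: ignore[return-value]

    def valid_mask(self) -> np.ndarray:
        if self.nodata is None:
            return np.ones(self.shape, dtype=bool)
        if isinstance(self.nodata, float) and math.isnan(self.nodata):
            return ~np.isnan(self.values)
        return self.values != self.nodata

    def total(self) -> float:
        """Sum over valid cells (the layer's total mass for kg-per-cell layers)."""
        return float(self.values[self.valid_mask()].sum())

    def copy_with(self, values: np.ndarray, nodata: float | int | None = None) -> "GridMap":
        return GridMap(
            values=values,
            transform=self.transform,
            nodata=self.nodata if nodata is None else nodata,
            crs=self.crs,
        )

    def assert_compatible(self, other: "GridMap") -> None:
        if self.shape != other.shape or not self.transform.almost_equal(other.transform):
            raise GridIncompatibleError(
                f"grids differ: {self.shape}/{self.transform} vs "
                f"{other.shape}/{other.transform}"
            )


def full_like(template: GridMap, fill: float, dtype=np.float64) -> GridMap:
    return template.copy_with(np.full(template.shape, fill, dtype=dtype))


# -- GeoTIFF I/O ---------------------------------------------------------------


def write_geotiff(grid: GridMap, path: str | Path) -> Path:
    """Write a single-band GeoTIFF (float64 flux layers, int32 class layers)."""
    path = Path(path)
    values = grid.values
    if values.dtype.kind in "iu":
        values = values.astype(np.int32)
    else:
        values = values.astype(np.float64)
    t = grid.transform
    extratags = [
        (_TAG_MODEL_PIXEL_SCALE, "d", 3, (t.dx, t.dy, 0.0), True),
        (_TAG_MODEL_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, t.x0, t.y0, 0.0), True),
    ]
    if grid.nodata is not None:
        extratags.append((_TAG_GDAL_NODATA, "s", 0, str(grid.nodata), True))
    description = json.dumps({"crs": grid.crs})
    tifffile.imwrite(
        path,
        values,
        photometric="minisblack",
        extratags=extratags,
        description=description,
    )
    return path


def read_geotiff(path: str | Path) -> GridMap:
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        values = page.asarray()
        tags = page.tags
        scale = tags[_TAG_MODEL_PIXEL_SCALE].value
        tiepoint = tags[_TAG_MODEL_TIEPOINT].value
        nodata: float | int | None = None
        if _TAG_GDAL_NODATA in tags:
            raw = tags[_TAG_GDAL_NODATA].value
            nodata = float(raw)
            if values.dtype.kind in "iu" and not math.isnan(nodata):
                nodata = int(nodata)
        crs = "unknown"
        if 270 in tags:
            try:
                crs = json.loads(tags[270].value).get("crs", "unknown")
            except (json.JSONDecodeError, AttributeError):
                pass
    transform = GridTransform(
        x0=float(tiepoint[3]), y0=float(tiepoint[4]),
        dx=float(scale[0]), dy=float(scale[1]),
    )
    return GridMap(values=values, transform=transform, nodata=nodata, crs=crs)
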