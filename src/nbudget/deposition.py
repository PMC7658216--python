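"""Atmospheric-deposition weighting from satellite trace-gas columns.

Daily NO2 and NH3 column fields on a coarse (nominally 0.25 degree) grid are
composited into monthly means by a per-cell arithmetic mean over valid
observations.  The two monthly composites are max-normalised per species and
blended into a dimensionless column index, which serves purely as a spatial
weight: configured national deposition totals per land-use class are then
allocated over that class's fine-grid cells in proportion to the index,
conserving each class total exactly.  No column-to-deposition conversion is
attempted — the totals are inputs, the columns only shape the map.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import xarray as xr

from .budget import FluxRecord, FluxTable
from .disagg import allocate
from .errors import ValidationError
from .grid import GridMap, GridTransform
from .vocab import LANDUSE_CODES, LANDUSE_ORDER, validate_landuse


@dataclass
class ColumnSeries:
    """Ordered daily column fields of one species on a shared coarse grid.

    ``fields``: (n_days, rows, cols) float array; ``valid``: same-shape bool
    observation mask.  Masked cells are excluded from compositing.
    """

    species: str
    fields: np.ndarray
    transform: GridTransform
    valid: np.ndarray
    crs: str = "local-synthetic-equal-area"

    def __post_init__(self) -> None:
        self.fields = np.asarray(self.fields, dtype=np.float64)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.fields.ndim != 3:
            raise ValidationError("ColumnSeries.fields must be (time, rows, cols)")
        if self.valid.shape != self.fields.shape:
            raise ValidationError("valid mask must match fields shape")
        if self.species not in ("NO2", "NH3"):
            raise ValidationError(f"species must be NO2 or NH3, got {self.species!r}")

    # NetCDF I/O (classic format via the scipy backend)

    def to_netcdf(self, path: str | Path) -> Path:
        t = self.transform
        ds = xr.Dataset(
            {
                "column": (("time", "y", "x"), self.fields),
                "valid": (("time", "y", "x"), self.valid.astype(np.int8)),
            },
            coords={
                "time": np.arange(self.fields.shape[0], dtype=np.int32),
                "y": t.y0 - (np.arange(self.fields.shape[1]) + 0.5) * t.dy,
                "x": t.x0 + (np.arange(self.fields.shape[2]) + 0.5) * t.dx,
            },
            attrs={
                "species": self.species,
                "crs": self.crs,
                "x0": t.x0, "y0": t.y0, "dx": t.dx, "dy": t.dy,
                "Conventions": "CF-1.8",
            },
        )
        ds["column"].attrs.update(long_name=f"{self.species} vertical column",
                                  units="index")
        ds.to_netcdf(path, engine="scipy")
        return Path(path)

    @classmethod
    def from_netcdf(cls, path: str | Path) -> "ColumnSeries":
        with xr.open_dataset(path, engine="scipy") as ds:
            transform = GridTransform(
                x0=float(ds.attrs["x0"]), y0=float(ds.attrs["y0"]),
                dx=float(ds.attrs["dx"]), dy=float(ds.attrs["dy"]),
            )
            return cls(
                species=str(ds.attrs["species"]),
                fields=np.asarray(ds["column"].values, dtype=np.float64),
                valid=np.asarray(ds["valid"].values, dtype=bool),
                transform=transform,
                crs=str(ds.attrs.get("crs", "unknown")),
            )


def monthly_mean(series: ColumnSeries) -> GridMap:
    """Per-cell arithmetic mean over valid daily observations.

    Cells with zero valid observations in the month become nodata (NaN).
    """
    if series.fields.shape[0] == 0:
        raise ValidationError("empty column series: no daily fields")
    counts = series.valid.sum(axis=0)
    sums = np.where(series.valid, series.fields, 0.0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(counts > 0, sums / counts, np.nan)
    return GridMap(mean, series.transform, nodata=np.nan, crs=series.crs)


def deposition_index(
    no2_monthly: GridMap,
    nh3_monthly: GridMap,
    weights: tuple[float, float] = (0.5, 0.5),
) -> GridMap:
    """Blend the two monthly composites into a non-negative spatial weight.

    Each species is normalised by its maximum over valid cells (making the
    index invariant to common rescaling of the columns), then combined as a
    weighted sum.  Cells unobserved for a species contribute zero for it.
    """
    no2_monthly.assert_compatible(nh3_monthly)
    w_no2, w_nh3 = weights
    if w_no2 < 0 or w_nh3 < 0 or (w_no2 == 0 and w_nh3 == 0):
        raise ValidationError("index weights must be >= 0 and not both zero")

    def normed(gm: GridMap) -> np.ndarray:
        valid = gm.valid_mask()
        vals = np.where(valid, gm.values, 0.0).astype(np.float64)
        vals = np.clip(vals, 0.0, None)
        peak = vals.max() if valid.any() else 0.0
        return vals / peak if peak > 0 else vals

    index = w_no2 * normed(no2_monthly) + w_nh3 * normed(nh3_monthly)
    return GridMap(index, no2_monthly.transform, nodata=None, crs=no2_monthly.crs)


def resample_nearest(coarse: GridMap, fine_template: GridMap) -> GridMap:
    """Block-constant transfer of a coarse layer onto the fine grid.

    Each fine cell takes the value of the coarse cell containing its center;
    fine centers outside the coarse extent are clipped to the edge cells.
    Nearest-neighbour keeps the subsequent class-wise renormalisation exact.
    """
    xs, ys = fine_template.transform.cell_centers(fine_template.shape)
    xg, yg = np.meshgrid(xs, ys)
    rows, cols = coarse.transform.index_of(xg, yg)
    rows = np.clip(rows, 0, coarse.shape[0] - 1)
    cols = np.clip(cols, 0, coarse.shape[1] - 1)
    values = np.asarray(coarse.values, dtype=np.float64)[rows, cols]
    return GridMap(values, fine_template.transform, nodata=coarse.nodata,
                   crs=fine_template.crs)


def deposition_by_landuse(
    index: GridMap,
    landuse: GridMap,
    national_totals: dict[str, float],
) -> tuple[FluxTable, GridMap]:
    """Allocate per-class national deposition totals over the fine grid.

    The coarse column index is resampled to the fine grid (nearest cell),
    then each land-use class's configured total (kg N/yr) is spread over that
    class's cells in proportion to the index.  Returns the one-record-per-
    class national flux table and the fine kg-per-cell deposition map; the
    map's class-wise zonal sums equal the configured totals exactly.
    """
    for cls in national_totals:
        validate_landuse(cls)
    fine_index = (
        resample_nearest(index, landuse)
        if index.shape != landuse.shape or not index.transform.almost_equal(landuse.transform)
        else index
    )
    fine_vals = np.where(fine_index.valid_mask(),
                         np.clip(fine_index.values, 0.0, None), 0.0)
    proxy = landuse.copy_with(fine_vals.astype(np.float64), nodata=None)

    # treat each land-use class as one allocation zone
    class_raster = GridMap(
        np.where(landuse.valid_mask(), landuse.values, -1).astype(np.int32),
        landuse.transform, nodata=-1, crs=landuse.crs,
    )
    totals_by_code = {
        LANDUSE_CODES[cls]: float(total) for cls, total in national_totals.items()
    }
    dep_map = allocate(totals_by_code, class_raster, proxy)
    records = [
        FluxRecord(cls, "N deposition", float(national_totals.get(cls, 0.0)))
        for cls in LANDUSE_ORDER
        if cls in national_totals
    ]
    return FluxTable(records), dep_map
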