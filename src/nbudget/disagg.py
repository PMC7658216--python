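"""Dasymetric, mass-conserving disaggregation of regional totals.

Each regional flux is spread over that region's eligible grid cells in
proportion to a non-negative proxy surface (population, GDP, livestock
density, a land-use mask, ...):

    cell = region_total * proxy_cell / sum(proxy over eligible region cells)

so the zonal sum over any region reproduces its input total to floating-point
precision.  Regions whose eligible proxy mass is zero fall back to a uniform
spread over their eligible cells, then over all their cells, with a logged
warning — mass is never silently dropped unless a region has no cells at all.
"""

from __future__ import annotations

import logging
from typing import Mapping

import numpy as np

from .budget import NATIONAL, FluxTable
from .errors import ValidationError
from .grid import GridMap

logger = logging.getLogger(__name__)


def _regional_totals(
    regional_fluxes: "FluxTable | Mapping[int, float]",
    item: str | None,
    landuse: str | None,
    code_of: Mapping[str, int] | None,
) -> dict[int, float]:
    if isinstance(regional_fluxes, FluxTable):
        df = regional_fluxes.frame
        df = df[df.region_id != NATIONAL]
        if item is not None:
            df = df[df.item == item]
        if landuse is not None:
            df = df[df.landuse == landuse]
        if code_of is None:
            code_of = {rid: int(rid) for rid in df.region_id}
        return {code_of[rid]: float(v) for rid, v in zip(df.region_id, df.kgN_per_yr)}
    return {int(k): float(v) for k, v in regional_fluxes.items()}


def allocate(
    regional_fluxes: "FluxTable | Mapping[int, float]",
    region_raster: GridMap,
    proxy: GridMap,
    eligible_mask: GridMap | None = None,
    *,
    item: str | None = None,
    landuse: str | None = None,
    region_codes: Mapping[str, int] | None = None,
) -> GridMap:
    """Allocate per-region totals onto the grid by proxy weight.

    Parameters
    ----------
    regional_fluxes
        Either a mapping region-code -> kg N/yr, or a FluxTable whose
        regional rows (optionally filtered by ``item``/``landuse``) are used;
        ``region_codes`` maps region_id strings to raster codes (defaults to
        ``int(region_id)``).
    region_raster
        int raster labelling every non-nodata cell with its region code.
    proxy
        non-negative weight surface on the same grid.
    eligible_mask
        optional raster; cells where it is 0/nodata receive nothing.
    """
    region_raster.assert_compatible(proxy)
    codes = region_raster.values
    region_valid = region_raster.valid_mask()
    pvals = np.where(proxy.valid_mask(), proxy.values, 0.0).astype(np.float64)
    if (pvals < 0).any():
        raise ValidationError("proxy surface must be non-negative")

    if eligible_mask is not None:
        region_raster.assert_compatible(eligible_mask)
        eligible = region_valid & eligible_mask.valid_mask() & (eligible_mask.values != 0)
    else:
        eligible = region_valid

    totals = _regional_totals(regional_fluxes, item, landuse, region_codes)
    out = np.zeros(region_raster.shape, dtype=np.float64)
    if not totals:
        return region_raster.copy_with(out, nodata=None)

    ncodes = max(int(codes[region_valid].max()) if region_valid.any() else 0,
                 max(totals)) + 1
    flat_codes = codes[eligible].astype(np.int64)
    weight_sum = np.bincount(flat_codes, weights=pvals[eligible], minlength=ncodes)
    cell_count = np.bincount(flat_codes, minlength=ncodes)
    all_count = np.bincount(codes[region_valid].astype(np.int64), minlength=ncodes)

    total_arr = np.zeros(ncodes)
    for code, t in totals.items():
        total_arr[code] = t

    # main proportional path
    ok = weight_sum > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        share = np.where(ok[codes.astype(np.int64).clip(0)],
                         total_arr[codes.astype(np.int64).clip(0)]
                         * pvals / weight_sum[codes.astype(np.int64).clip(0)], 0.0)
    out[eligible] = share[eligible]

    # fallbacks for regions with flux but zero proxy mass
    for code, t in totals.items():
        if t == 0 or ok[code]:
            continue
        if cell_count[code] > 0:
            logger.warning(
                "region %d: zero proxy over %d eligible cells; allocating uniformly",
                code, int(cell_count[code]))
            mask = eligible & (codes == code)
            out[mask] = t / cell_count[code]
        elif all_count[code] > 0:
            logger.warning(
                "region %d: no eligible cells; allocating uniformly over all "
                "%d region cells", code, int(all_count[code]))
            mask = region_valid & (codes == code)
            out[mask] = t / all_count[code]
        else:
            logger.warning("region %d has flux %.3g kg but no cells; mass dropped",
                           code, t)
    return region_raster.copy_with(out, nodata=None)


def per_hectare(map_kg: GridMap, cell_area_ha: float) -> GridMap:
    """Convert a kg-per-cell layer to kg/ha; nodata cells are preserved."""
    if not cell_area_ha > 0:
        raise ValidationError(f"cell area must be positive, got {cell_area_ha}")
    valid = map_kg.valid_mask()
    values = np.array(map_kg.values, dtype=np.float64, copy=True)
    values[valid] = values[valid] / cell_area_ha
    return map_kg.copy_with(values)


def combine(maps: list[GridMap]) -> GridMap:
    """Element-wise sum of kg-per-cell layers.

    nodata counts as 0 wherever at least one layer has data; cells where
    every layer is nodata stay nodata.  Total mass is the sum of the layer
    masses exactly (up to float addition order).
    """
    if not maps:
        raise ValidationError("combine() needs at least one map")
    first = maps[0]
    total = np.zeros(first.shape, dtype=np.float64)
    any_valid = np.zeros(first.shape, dtype=bool)
    for gm in maps:
        first.assert_compatible(gm)
        valid = gm.valid_mask()
        total[valid] += np.asarray(gm.values, dtype=np.float64)[valid]
        any_valid |= valid
    total[~any_valid] = np.nan
    return GridMap(total, first.transform, nodata=np.nan, crs=first.crs)


def zonal_sum(map_kg: GridMap, zones: GridMap) -> dict[int, float]:
    """Sum a kg-per-cell layer within each integer zone (region or basin)."""
    map_kg.assert_compatible(zones)
    valid = zones.valid_mask() & map_kg.valid_mask()
    codes = zones.values[valid].astype(np.int64)
    if codes.size == 0:
        return {}
    sums = np.bincount(codes, weights=map_kg.values[valid].astype(np.float64))
    return {int(c): float(sums[c]) for c in np.unique(codes)}
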