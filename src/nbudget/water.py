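"""Surface-water nitrogen inputs and watershed aggregation.

Seven items feed the surface-water budget: runoff exports from cropland,
livestock manure and forest (export coefficient x the source subsystem's
input, mapped on the source distribution), three socioeconomic discharges
(human wastewater by population, industrial wastewater by GDP, treatment-
plant effluent by urban population) and atmospheric deposition to water
cells.  Watershed loads are zonal sums of these maps over a basin partition.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import mapping as shp_mapping, shape as shp_shape

from .budget import AdminSet, CoefficientLibrary, FluxRecord
from .disagg import allocate, zonal_sum
from .errors import ConfigError, ValidationError
from .grid import GridMap, GridTransform


# ---------------------------------------------------------------------------
# Watersheds
# ---------------------------------------------------------------------------


@dataclass
class WatershedSet:
    """Non-overlapping basin polygons; membership on the grid by cell center."""

    basin_ids: list[str]
    polygons: list[shapely.Geometry]

    def __post_init__(self) -> None:
        if len(self.basin_ids) != len(self.polygons):
            raise ValidationError("basin_ids and polygons must align")
        if len(set(self.basin_ids)) != len(self.basin_ids):
            raise ValidationError("basin ids must be unique")

    def __len__(self) -> int:
        return len(self.basin_ids)

    def rasterize(self, transform: GridTransform, shape: tuple[int, int]) -> GridMap:
        """Basin-membership raster (int codes = list position, nodata -1).

        A cell belongs to the first basin (in list order) covering its
        center — a deterministic tie-break for centers on shared edges.
        """
        xs, ys = transform.cell_centers(shape)
        xg, yg = np.meshgrid(xs, ys)
        out = np.full(shape, -1, dtype=np.int32)
        unassigned = np.ones(shape, dtype=bool)
        for code, poly in enumerate(self.polygons):
            hit = shapely.covers(poly, shapely.points(xg, yg)) & unassigned
            out[hit] = code
            unassigned &= ~hit
        return GridMap(out, transform, nodata=-1)

    # GeoJSON I/O

    def to_geojson(self, path: str | Path) -> Path:
        fc = {
            "type": "FeatureCollection",
            "features": [
                {
                    "type": "Feature",
                    "properties": {"basin_id": bid},
                    "geometry": shp_mapping(poly),
                }
                for bid, poly in zip(self.basin_ids, self.polygons)
            ],
        }
        Path(path).write_text(json.dumps(fc))
        return Path(path)

    @classmethod
    def from_geojson(cls, path: str | Path) -> "WatershedSet":
        fc = json.loads(Path(path).read_text())
        ids, polys = [], []
        for feat in fc["features"]:
            ids.append(str(feat["properties"]["basin_id"]))
            polys.append(shp_shape(feat["geometry"]))
        return cls(ids, polys)


# ---------------------------------------------------------------------------
# Water-input fluxes
# ---------------------------------------------------------------------------


def runoff_flux(
    source_map: GridMap, coeff: float, item: str
) -> tuple[GridMap, FluxRecord]:
    """Export-coefficient runoff: cell-wise ``coeff * source`` (kg N/cell).

    The map inherits the source distribution, so e.g. cropland runoff peaks
    where cropland input peaks.  The national record is coeff x source mass.
    """
    if not (0.0 <= coeff <= 1.0):
        raise ValidationError(f"runoff coefficient must lie in [0,1], got {coeff}")
    valid = source_map.valid_mask()
    values = np.where(valid, np.asarray(source_map.values, dtype=np.float64) * coeff,
                      np.nan)
    out = GridMap(values, source_map.transform, nodata=np.nan, crs=source_map.crs)
    record = FluxRecord("water", item, coeff * source_map.total())
    return out, record


def wastewater_fluxes(
    regions: AdminSet,
    coeffs: CoefficientLibrary,
    proxies: dict[str, GridMap],
    region_raster: GridMap,
    region_codes: dict[str, int],
) -> tuple[dict[str, GridMap], list[FluxRecord]]:
    """The three socioeconomic discharges to surface water.

    human wastewater = per-capita coeff x (urban + rural population), mapped
    by the total-population proxy; industrial wastewater = per-GDP coeff x
    GDP, mapped by GDP; treatment-plant effluent = per-urban-capita coeff x
    urban population, mapped by urban population.  Each map conserves its
    per-region magnitudes.
    """
    needed = {
        "human wastewater discharged": "population",
        "industrial wastewater": "gdp",
        "WTP effluent": "urban-population",
    }
    for item, proxy_name in needed.items():
        if proxy_name not in proxies:
            raise ConfigError(f"missing proxy grid {proxy_name!r} for {item!r}")

    per_region: dict[str, dict[int, float]] = {item: {} for item in needed}
    for region in regions:
        code = region_codes[region.region_id]
        per_region["human wastewater discharged"][code] = (
            coeffs.wastewater_per_capita * (region.pop_urban + region.pop_rural)
        )
        per_region["industrial wastewater"][code] = (
            coeffs.industrial_n_per_gdp * region.gdp
        )
        per_region["WTP effluent"][code] = (
            coeffs.wtp_effluent_per_capita * region.pop_urban
        )

    maps: dict[str, GridMap] = {}
    records: list[FluxRecord] = []
    for item, proxy_name in needed.items():
        maps[item] = allocate(per_region[item], region_raster, proxies[proxy_name])
        records.append(FluxRecord("water", item, sum(per_region[item].values())))
    return maps, records


def watershed_totals(
    water_maps: dict[str, GridMap], basins: WatershedSet, basin_raster: GridMap
) -> pd.DataFrame:
    """Zonal sums of the water-input maps per basin.

    Returns a tidy frame (basin_id, item, kgN_per_yr) including an
    ``unassigned`` row per item for mass on cells outside every basin, so
    basin totals plus unassigned equal the national total exactly.
    """
    if len(basins) == 0:
        raise ValidationError("no basins defined")
    rows = []
    for item, gm in water_maps.items():
        gm.assert_compatible(basin_raster)
        sums = zonal_sum(gm, basin_raster)
        assigned = 0.0
        for code, bid in enumerate(basins.basin_ids):
            v = sums.get(code, 0.0)
            assigned += v
            rows.append({"basin_id": bid, "item": item, "kgN_per_yr": v})
        rows.append({"basin_id": "unassigned", "item": item,
                     "kgN_per_yr": gm.total() - assigned})
    return pd.DataFrame(rows, columns=["basin_id", "item", "kgN_per_yr"])
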