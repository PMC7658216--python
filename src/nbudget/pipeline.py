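"""End-to-end orchestration: budget -> deposition -> maps -> water -> report.

``run_pipeline`` consumes a :class:`RunConfig` pointing at the input files
(admin table, land-use / region rasters, proxy rasters, daily column files,
watershed polygons, coefficient library, per-class deposition totals) and
emits a data directory: one GeoTIFF per budget item, combined per-class and
national maps, the flux-table and basin CSVs, the formatted budget report,
and a manifest (abbreviations, units, config hash, package version) plus a
sources/provenance file — the three-file database layout (data / readme /
sources).  Every allocation is followed by a logged conservation audit.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .budget import (
    NATIONAL,
    AdminSet,
    CoefficientLibrary,
    assemble_budget,
)
from .deposition import ColumnSeries, deposition_by_landuse, deposition_index, monthly_mean
from .disagg import allocate, combine, zonal_sum
from .errors import ConfigError
from .grid import GridMap, read_geotiff, write_geotiff
from .report import budget_report, qaqc_screen
from .vocab import BUDGET_ITEMS, LANDUSE_CODES, LANDUSE_ORDER
from .water import WatershedSet, runoff_flux, wastewater_fluxes, watershed_totals

logger = logging.getLogger(__name__)

#: default proxy assignment per allocatable (landuse, item); deposition and
#: the water items are produced by the deposition / water modules instead.
DEFAULT_PROXIES: dict[tuple[str, str], str] = {
    ("cropland", "N fertilizer"): "landuse-mask:cropland",
    ("cropland", "irrigation"): "landuse-mask:cropland",
    ("cropland", "livestock manure"): "livestock-density",
    ("cropland", "human excretion"): "population",
    ("cropland", "cropland BNF"): "landuse-mask:cropland",
    ("cropland", "straw recycle"): "landuse-mask:cropland",
    ("forest", "N fertilizer"): "landuse-mask:forest",
    ("forest", "forest BNF"): "landuse-mask:forest",
    ("grassland", "N fertilizer"): "landuse-mask:grassland",
    ("grassland", "grassland BNF"): "landuse-mask:grassland",
    ("grassland", "irrigation for artificial grassland"): "landuse-mask:grassland",
    ("grassland", "livestock manure"): "livestock-density",
}

_ABBREVIATIONS = {
    "Nr": "reactive nitrogen (all N species other than N2)",
    "BNF": "biological N fixation (kg N/yr = area x fixation rate)",
    "WTP": "wastewater treatment plant",
    "kgN_per_yr": "kilograms of nitrogen per year",
    "Tg": "teragram = 1e9 kg",
}


@dataclass
class RunConfig:
    """Paths and parameters of one pipeline run."""

    admin_csv: Path
    landuse_tif: Path
    region_tif: Path
    proxy_tifs: dict[str, Path]
    column_ncs: dict[str, Path]          # species -> file
    watersheds_geojson: Path
    coefficients_yaml: Path
    deposition_totals: dict[str, float]  # kg N/yr per land-use class
    out_dir: Path
    cell_area_ha: float = 100.0
    index_weights: tuple[float, float] = (0.5, 0.5)
    proxy_assignments: dict[tuple[str, str], str] = dc_field(
        default_factory=lambda: dict(DEFAULT_PROXIES))
    qaqc_enabled: bool = True
    qaqc_p_low: float = 0.5
    qaqc_p_high: float = 99.5
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        base = Path(path).parent

        def p(rel: str) -> Path:
            q = Path(rel)
            return q if q.is_absolute() else base / q

        assignments = dict(DEFAULT_PROXIES)
        for key, proxy in d.get("proxy_assignments", {}).items():
            landuse, item = key.split("/", 1)
            assignments[(landuse, item)] = proxy
        return cls(
            admin_csv=p(d["admin_csv"]),
            landuse_tif=p(d["landuse_tif"]),
            region_tif=p(d["region_tif"]),
            proxy_tifs={k: p(v) for k, v in d["proxies"].items()},
            column_ncs={k: p(v) for k, v in d["columns"].items()},
            watersheds_geojson=p(d["watersheds_geojson"]),
            coefficients_yaml=p(d["coefficients_yaml"]),
            deposition_totals={k: float(v)
                               for k, v in d["deposition_totals"].items()},
            out_dir=p(d.get("out_dir", "out")),
            cell_area_ha=float(d.get("cell_area_ha", 100.0)),
            index_weights=tuple(d.get("index_weights", (0.5, 0.5))),
            proxy_assignments=assignments,
            qaqc_enabled=bool(d.get("qaqc", {}).get("enabled", True)),
            qaqc_p_low=float(d.get("qaqc", {}).get("p_low", 0.5)),
            qaqc_p_high=float(d.get("qaqc", {}).get("p_high", 99.5)),
            log_level=str(d.get("log_level", "INFO")),
        )

    def validate(self) -> None:
        """Fail fast before any computation."""
        missing = [str(f) for f in (
            self.admin_csv, self.landuse_tif, self.region_tif,
            self.watersheds_geojson, self.coefficients_yaml,
            *self.proxy_tifs.values(), *self.column_ncs.values(),
        ) if not Path(f).exists()]
        if missing:
            raise ConfigError("missing input files: " + ", ".join(missing))
        for landuse, items in BUDGET_ITEMS.items():
            if landuse in ("water", "built-up", "unused"):
                continue
            for item in items:
                if item == "N deposition":
                    continue
                if (landuse, item) not in self.proxy_assignments:
                    raise ConfigError(
                        f"no proxy assignment for ({landuse}, {item})")
        for cls_name in LANDUSE_ORDER:
            if cls_name not in self.deposition_totals:
                raise ConfigError(f"no deposition total for class {cls_name!r}")

    def config_hash(self) -> str:
        payload = json.dumps(
            {k: str(v) for k, v in sorted(self.__dict__.items(), key=lambda kv: kv[0])},
            sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:8]


def _slug(name: str) -> str:
    return name.replace(" ", "-").replace("/", "-")


def _audit(name: str, gm: GridMap, expected: dict[int, float],
           zones: GridMap) -> float:
    """Log the worst relative zonal-conservation error of one layer."""
    sums = zonal_sum(gm, zones)
    worst = 0.0
    for code, want in expected.items():
        got = sums.get(code, 0.0)
        denom = max(abs(want), 1.0)
        worst = max(worst, abs(got - want) / denom)
    logger.info("conservation audit %-40s max rel err %.3e", name, worst)
    return worst


def run_pipeline(config: RunConfig) -> dict[str, object]:
    """Execute the full pipeline and write the output bundle.

    Returns a dict with the assembled ``budget`` FluxTable, the per-item
    ``maps``, the ``basin_totals`` frame, the ``report`` frame and the
    ``run_dir`` the files were written to.
    """
    logging.basicConfig(level=config.log_level)
    config.validate()

    admin = AdminSet.read_csv(config.admin_csv)
    coeffs = CoefficientLibrary.read_yaml(config.coefficients_yaml)
    landuse = read_geotiff(config.landuse_tif)
    region_raster = read_geotiff(config.region_tif)
    proxies = {name: read_geotiff(path)
               for name, path in config.proxy_tifs.items()}
    watersheds = WatershedSet.from_geojson(config.watersheds_geojson)
    region_codes = {r.region_id: int(r.region_id) for r in admin}

    # ---- deposition: composite columns, build the index, allocate totals
    composites = {}
    for species, path in config.column_ncs.items():
        composites[species] = monthly_mean(ColumnSeries.from_netcdf(path))
    index = deposition_index(composites["NO2"], composites["NH3"],
                             config.index_weights)
    dep_table, dep_map = deposition_by_landuse(
        index, landuse, config.deposition_totals)

    # ---- budget assembly
    budget = assemble_budget(admin, coeffs, dep_table)
    qaqc = qaqc_screen(budget, config.qaqc_p_low, config.qaqc_p_high) \
        if config.qaqc_enabled else None

    # ---- per-item disaggregation
    landuse_vals = landuse.values
    def class_mask(cls_name: str) -> GridMap:
        return landuse.copy_with(
            (landuse_vals == LANDUSE_CODES[cls_name]).astype(np.int32), nodata=None)

    regional = budget.frame.query("region_id != @NATIONAL")
    maps: dict[tuple[str, str], GridMap] = {}
    for (lu, item), proxy_name in config.proxy_assignments.items():
        if proxy_name.startswith("landuse-mask:"):
            proxy = class_mask(proxy_name.split(":", 1)[1])
        elif proxy_name == "uniform":
            proxy = landuse.copy_with(np.ones(landuse.shape), nodata=None)
        elif proxy_name in proxies:
            proxy = proxies[proxy_name]
        else:
            raise ConfigError(f"unknown proxy {proxy_name!r} for ({lu}, {item})")
        totals = {
            region_codes[rid]: float(v)
            for rid, v in regional.query("landuse == @lu and item == @item")[
                ["region_id", "kgN_per_yr"]].itertuples(index=False)
        }
        gm = allocate(totals, region_raster, proxy,
                      eligible_mask=class_mask(lu))
        _audit(f"{lu}/{item}", gm, totals, region_raster)
        maps[(lu, item)] = gm

    # deposition items: the class-allocated deposition map split by class
    for lu in LANDUSE_ORDER:
        mask = landuse_vals == LANDUSE_CODES[lu]
        vals = np.where(mask, dep_map.values, 0.0)
        maps[(lu, "N deposition")] = dep_map.copy_with(vals, nodata=None)

    combined = {
        lu: combine([maps[(lu, item)] for item in BUDGET_ITEMS[lu]
                     if (lu, item) in maps])
        for lu in ("cropland", "forest", "grassland", "built-up", "unused")
    }

    # ---- surface-water fluxes
    nat = budget.national()
    manure_maps = [maps[("cropland", "livestock manure")],
                   maps[("grassland", "livestock manure")]]
    water_sources = {
        "cropland runoff": (combined["cropland"], "cropland"),
        "livestock runoff": (combine(manure_maps), "livestock"),
        "forest runoff": (combined["forest"], "forest"),
    }
    for item, (source, key) in water_sources.items():
        gm, _rec = runoff_flux(source, coeffs.runoff_coeffs[key], item)
        maps[("water", item)] = gm
    ww_maps, _ww_records = wastewater_fluxes(
        admin, coeffs, proxies, region_raster, region_codes)
    for item, gm in ww_maps.items():
        maps[("water", item)] = gm

    combined["water"] = combine(
        [maps[("water", item)] for item in BUDGET_ITEMS["water"]])
    national_map = combine(list(combined.values()))

    # ---- watershed aggregation
    basin_raster = watersheds.rasterize(landuse.transform, landuse.shape)
    water_maps = {item: maps[("water", item)] for item in BUDGET_ITEMS["water"]}
    basins = watershed_totals(water_maps, watersheds, basin_raster)

    # ---- report + outputs
    report_frame, report_text = budget_report(nat)
    run_dir = Path(config.out_dir) / f"run-{config.config_hash()}"
    run_dir.mkdir(parents=True, exist_ok=True)

    for (lu, item), gm in maps.items():
        write_geotiff(gm, run_dir / f"{_slug(lu)}_{_slug(item)}.tif")
    for lu, gm in combined.items():
        write_geotiff(gm, run_dir / f"{_slug(lu)}_total.tif")
    write_geotiff(national_map, run_dir / "national_total.tif")
    budget.to_csv(run_dir / "flux_table.csv")
    basins.to_csv(run_dir / "basin_totals.csv", index=False,
                  float_format="%.17g")
    report_frame.to_csv(run_dir / "report.csv", index=False,
                        float_format="%.17g")
    (run_dir / "report.txt").write_text(report_text + "\n")
    if qaqc is not None:
        qaqc.report.to_csv(run_dir / "qaqc_report.csv", index=False)

    manifest = {
        "package": "nbudget",
        "version": __version__,
        "config_hash": config.config_hash(),
        "abbreviations": _ABBREVIATIONS,
        "units": {"maps": "kg N per cell per year", "tables": "kg N per year",
                  "report Tg column": "Tg N per year"},
        "layers": sorted(f"{_slug(lu)}_{_slug(item)}.tif" for lu, item in maps),
    }
    (run_dir / "README.json").write_text(json.dumps(manifest, indent=2))
    (run_dir / "SOURCES.txt").write_text(
        "Inputs consumed by this run (paths as configured):\n"
        + "\n".join(f"  {name}: {path}" for name, path in [
            ("admin table", config.admin_csv),
            ("land-use raster", config.landuse_tif),
            ("region raster", config.region_tif),
            ("watersheds", config.watersheds_geojson),
            ("coefficients", config.coefficients_yaml),
        ] + [(f"proxy {k}", v) for k, v in config.proxy_tifs.items()]
          + [(f"columns {k}", v) for k, v in config.column_ncs.items()])
        + "\n")

    return {
        "budget": budget,
        "maps": maps,
        "combined": combined,
        "national_map": national_map,
        "basin_totals": basins,
        "report": report_frame,
        "report_text": report_text,
        "run_dir": run_dir,
    }
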