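"""Synthetic-country fixture generator with exact ground truth.

Builds a fully specified desk-scale country: a rectangular province/county
hierarchy tiling a regular grid, a categorical land-use raster, smooth
hotspot-style proxy surfaces (population, GDP, livestock, fertilizer) built
from Gaussian bumps on a low uniform floor, noisy daily trace-gas column
fields around a known monthly mean, and a watershed partition.  County
activity tables are defined as the zonal sums of the proxy rasters, so
table and raster are consistent by construction, and a ground-truth flux
table is computed by direct arithmetic over the county tables — giving every
pipeline stage an exact oracle.

All randomness flows through one ``numpy.random.default_rng`` (PCG64)
stream, so a fixed seed reproduces every output bit-for-bit.
"""

from __future__ import annotations

import importlib.resources
import math
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import shapely
from shapely.geometry import mapping as shp_mapping
import yaml

from .budget import (
    NATIONAL,
    AdminRegion,
    AdminSet,
    CoefficientLibrary,
    FluxRecord,
    FluxTable,
)
from .deposition import ColumnSeries
from .errors import ValidationError
from .grid import GridMap, GridTransform, write_geotiff
from .vocab import LANDUSE_CODES, LANDUSE_ORDER
from .water import WatershedSet

# ---------------------------------------------------------------------------
# Specification
# ---------------------------------------------------------------------------


def default_library() -> CoefficientLibrary:
    """Illustrative coefficient values for the synthetic country.

    The published accounting defers all rates to external model protocols,
    so these are documented stand-ins of realistic magnitude: excretion
    9/50/0.5 kg N/head/yr for pigs/cattle/poultry and 4 kg N/person/yr for
    humans; manure return fractions 0.3-0.4 to cropland, with only cattle
    manure (0.15) reaching grassland; urban/rural excretion return 0.1/0.4;
    fixation 10-80 kg N/ha/yr by crop and 12/9 for forest/grassland; straw
    recycle 15 and irrigation 5 kg N/ha/yr; runoff export fractions of
    roughly 5-12% consistent with the ratios of the national budget rows;
    wastewater 2 (all persons) and 1 (urban persons) kg N/yr, and
    2e-5 kg N per currency unit of GDP.
    """
    return CoefficientLibrary(
        excre_an={"pigs": 9.0, "cattle": 50.0, "poultry": 0.5},
        re_an_cropland={"pigs": 0.4, "cattle": 0.35, "poultry": 0.3},
        re_an_grassland={"pigs": 0.0, "cattle": 0.15, "poultry": 0.0},
        excre_hu=4.0,
        re_ur=0.1,
        re_ru=0.4,
        r_fix_crop={"grain": 10.0, "soy": 80.0, "vegetables": 15.0},
        r_fix_land={"forest": 12.0, "grassland": 9.0},
        uniform_rates={
            "straw recycle": 15.0,
            "irrigation": 5.0,
            "irrigation for artificial grassland": 0.5,
        },
        runoff_coeffs={"cropland": 0.05, "livestock": 0.10, "forest": 0.12},
        wastewater_per_capita=2.0,
        wtp_effluent_per_capita=1.0,
        industrial_n_per_gdp=2.0e-5,
    )


@dataclass
class SynthSpec:
    """Parameters of the synthetic country.

    Defaults describe a 200 x 200 km country (1-km cells) of 4 provinces /
    100 counties with 6 M inhabitants (60% urban), 2 M pigs, 0.2 M cattle,
    20 M poultry, 240 kt fertilizer N (200 kg N/ha of cropland) and
    deposition rates of 8-30 kg N/ha/yr by land-use class — per-hectare
    intensities on the order of the national statistics the accounting
    scheme was built for.
    """

    seed: int = 0
    grid_shape: tuple[int, int] = (200, 200)
    cell_size_km: float = 1.0
    n_provinces: int = 4
    counties_per_province: int = 25
    landuse_fractions: dict[str, float] = dc_field(default_factory=lambda: {
        "cropland": 0.30, "forest": 0.25, "grassland": 0.20,
        "water": 0.05, "built-up": 0.10, "unused": 0.10,
    })
    population_total: float = 6.0e6
    urban_fraction: float = 0.6
    gdp_total: float = 6.0e10
    livestock_totals: dict[str, float] = dc_field(default_factory=lambda: {
        "pigs": 2.0e6, "cattle": 2.0e5, "poultry": 2.0e7,
    })
    fertilizer_total: float = 2.4e8          # kg N/yr on cropland
    forest_fertilizer_rate: float = 2.0      # kg N/ha/yr of forest
    grassland_fertilizer_rate: float = 0.75  # kg N/ha/yr of grassland
    crop_shares: dict[str, float] = dc_field(default_factory=lambda: {
        "grain": 0.7, "soy": 0.2, "vegetables": 0.1,
    })
    deposition_rates: dict[str, float] = dc_field(default_factory=lambda: {
        "cropland": 25.0, "forest": 15.0, "grassland": 12.0,
        "water": 20.0, "built-up": 30.0, "unused": 8.0,
    })
    n_basins: int = 6
    n_days: int = 30
    column_noise_sd: float = 0.2
    observation_prob: float = 0.7
    coarse_factor: int = 20

    def __post_init__(self) -> None:
        total = sum(self.landuse_fractions.values())
        if abs(total - 1.0) > 1e-12:
            raise ValidationError(f"landuse fractions must sum to 1, got {total!r}")
        if abs(sum(self.crop_shares.values()) - 1.0) > 1e-12:
            raise ValidationError("crop shares must sum to 1")
        for name in ("population_total", "gdp_total", "fertilizer_total"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        rows, cols = self.grid_shape
        if self.n_provinces * self.counties_per_province > rows * cols:
            raise ValidationError("more counties than grid cells: infeasible spec")
        if rows % self.coarse_factor or cols % self.coarse_factor:
            raise ValidationError("grid_shape must be divisible by coarse_factor")

    @property
    def cell_area_ha(self) -> float:
        return self.cell_size_km ** 2 * 100.0

    @property
    def transform(self) -> GridTransform:
        cell_m = self.cell_size_km * 1000.0
        return GridTransform(x0=0.0, y0=self.grid_shape[0] * cell_m,
                             dx=cell_m, dy=cell_m)

    def to_yaml(self, path: str | Path) -> None:
        d = {k: v for k, v in self.__dict__.items()}
        d["grid_shape"] = list(self.grid_shape)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def read_yaml(cls, path: str | Path) -> "SynthSpec":
        d = yaml.safe_load(Path(path).read_text())
        if "grid_shape" in d:
            d["grid_shape"] = tuple(d["grid_shape"])
        return cls(**d)


# ---------------------------------------------------------------------------
# Helpers
# ---------------------------------------------------------------------------


def _factor_pair(n: int) -> tuple[int, int]:
    """The most nearly square factorisation n = a*b with a <= b."""
    a = int(math.isqrt(n))
    while n % a:
        a -= 1
    return a, n // a


def _bump_field(rng: np.random.Generator, shape: tuple[int, int], n_bumps: int,
                width_frac: float = 0.10, floor: float = 0.0) -> np.ndarray:
    """Sum of 2-D Gaussian bumps over a uniform floor: the hotspot motif."""
    rows, cols = shape
    r = np.arange(rows)[:, None]
    c = np.arange(cols)[None, :]
    out = np.full(shape, floor, dtype=np.float64)
    scale = width_frac * min(rows, cols)
    for _ in range(n_bumps):
        r0, c0 = rng.uniform(0, rows), rng.uniform(0, cols)
        amp = rng.uniform(0.5, 1.5)
        w = rng.uniform(0.5, 1.5) * scale
        out += amp * np.exp(-((r - r0) ** 2 + (c - c0) ** 2) / (2.0 * w * w))
    return out


def _integer_split(fractions: np.ndarray, total: int) -> np.ndarray:
    """Largest-remainder rounding of total*fractions to integers summing to total."""
    raw = fractions * total
    base = np.floor(raw).astype(np.int64)
    short = total - int(base.sum())
    order = np.argsort(-(raw - base), kind="stable")
    base[order[:short]] += 1
    return base


def _tile_bounds(n_cells: int, n_tiles: int) -> list[tuple[int, int]]:
    edges = np.linspace(0, n_cells, n_tiles + 1).round().astype(int)
    return [(int(edges[i]), int(edges[i + 1])) for i in range(n_tiles)]


# ---------------------------------------------------------------------------
# Bundle
# ---------------------------------------------------------------------------


@dataclass
class SynthBundle:
    """Everything the pipeline consumes, plus its exact ground truth."""

    spec: SynthSpec
    admin: AdminSet
    region_codes: dict[str, int]
    region_raster: GridMap
    landuse: GridMap
    proxies: dict[str, GridMap]
    columns: dict[str, ColumnSeries]
    watersheds: WatershedSet
    coeffs: CoefficientLibrary
    deposition_totals: dict[str, float]
    ground_truth: FluxTable
    paths: dict[str, Path] = dc_field(default_factory=dict)


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------


def generate(spec: SynthSpec, outdir: str | Path | None = None) -> SynthBundle:
    """Generate the synthetic country; optionally write all files to outdir."""
    rng = np.random.default_rng(spec.seed)
    rows, cols = spec.grid_shape
    transform = spec.transform
    cell_ha = spec.cell_area_ha

    # --- admin tiling: provinces are rectangular tiles, counties sub-tiles
    pr, pc = _factor_pair(spec.n_provinces)
    cr, cc = _factor_pair(spec.counties_per_province)
    region = np.empty((rows, cols), dtype=np.int32)
    county_slices: list[tuple[slice, slice]] = []
    county_parents: list[str] = []
    code = 0
    for pi, (r0, r1) in enumerate(_tile_bounds(rows, pr)):
        for pj, (c0, c1) in enumerate(_tile_bounds(cols, pc)):
            province_id = f"P{pi * pc + pj:02d}"
            for sr0, sr1 in _tile_bounds(r1 - r0, cr):
                for sc0, sc1 in _tile_bounds(c1 - c0, cc):
                    sl = (slice(r0 + sr0, r0 + sr1), slice(c0 + sc0, c0 + sc1))
                    region[sl] = code
                    county_slices.append(sl)
                    county_parents.append(province_id)
                    code += 1
    n_counties = code
    region_raster = GridMap(region, transform, nodata=-1)
    region_codes = {str(i): i for i in range(n_counties)}

    # --- land-use raster: per-county class runs along a smooth field
    relief = _bump_field(rng, (rows, cols), 12) + rng.normal(0, 1e-6, (rows, cols))
    landuse_arr = np.empty((rows, cols), dtype=np.int32)
    frac_vec = np.array([spec.landuse_fractions[c] for c in LANDUSE_ORDER])
    for sl in county_slices:
        block = relief[sl]
        n = block.size
        jitter = rng.dirichlet(frac_vec * 60.0 + 1e-9)
        counts = _integer_split(jitter, n)
        order = np.argsort(block, axis=None, kind="stable")
        labels = np.repeat([LANDUSE_CODES[c] for c in LANDUSE_ORDER], counts)
        flat = np.empty(n, dtype=np.int32)
        flat[order] = labels
        landuse_arr[sl] = flat.reshape(block.shape)
    landuse = GridMap(landuse_arr, transform, nodata=-1)

    masks = {c: landuse_arr == LANDUSE_CODES[c] for c in LANDUSE_ORDER}

    # --- proxy surfaces (per-cell person / currency / head / kg totals)
    def _normalize(weight: np.ndarray, total: float) -> np.ndarray:
        s = weight.sum()
        return weight * (total / s) if s > 0 else np.zeros_like(weight)

    pop_field = _bump_field(rng, (rows, cols), 8, floor=0.05)
    urban_w = pop_field ** 2 * np.where(masks["built-up"], 1.0, 0.02)
    rural_w = pop_field * np.where(masks["cropland"] | masks["grassland"], 1.0, 0.1)
    urban_pop = _normalize(urban_w, spec.population_total * spec.urban_fraction)
    rural_pop = _normalize(rural_w, spec.population_total * (1 - spec.urban_fraction))
    gdp_noise = rng.lognormal(0.0, 0.1, (rows, cols))
    gdp = _normalize((urban_pop + 0.1 * rural_pop) * gdp_noise, spec.gdp_total)

    ag_mask = np.where(masks["cropland"] | masks["grassland"], 1.0, 0.05)
    livestock_surfaces = {
        cat: _normalize(_bump_field(rng, (rows, cols), 6, floor=0.02) * ag_mask, tot)
        for cat, tot in sorted(spec.livestock_totals.items())
    }
    fert_field = _bump_field(rng, (rows, cols), 6, floor=1.0)
    fertilizer = _normalize(np.where(masks["cropland"], fert_field, 0.0),
                            spec.fertilizer_total)

    coeffs = default_library()
    livestock_density = sum(
        surf * coeffs.excre_an.get(cat, 1.0)
        for cat, surf in livestock_surfaces.items()
    )

    proxies = {
        "population": GridMap(urban_pop + rural_pop, transform, nodata=None),
        "urban-population": GridMap(urban_pop, transform, nodata=None),
        "rural-population": GridMap(rural_pop, transform, nodata=None),
        "gdp": GridMap(gdp, transform, nodata=None),
        "livestock-density": GridMap(np.asarray(livestock_density), transform,
                                     nodata=None),
        "fertilizer": GridMap(fertilizer, transform, nodata=None),
    }

    # --- county activity tables = exact zonal sums of the surfaces
    flat_region = region.ravel()

    def _zonal(surface: np.ndarray) -> np.ndarray:
        return np.bincount(flat_region, weights=surface.ravel(),
                           minlength=n_counties)

    z_urban = _zonal(urban_pop)
    z_rural = _zonal(rural_pop)
    z_gdp = _zonal(gdp)
    z_fert = _zonal(fertilizer)
    z_livestock = {cat: _zonal(surf) for cat, surf in livestock_surfaces.items()}
    z_area = {
        c: np.bincount(flat_region, weights=masks[c].ravel().astype(np.float64),
                       minlength=n_counties) * cell_ha
        for c in LANDUSE_ORDER
    }

    crop_names = sorted(spec.crop_shares)
    share_vec = np.array([spec.crop_shares[c] for c in crop_names])
    regions = []
    for i in range(n_counties):
        shares = rng.dirichlet(share_vec * 40.0 + 1e-9)
        cropland_area = z_area["cropland"][i]
        planting = {c: float(s * cropland_area) for c, s in zip(crop_names, shares)}
        regions.append(AdminRegion(
            region_id=str(i),
            parent_id=county_parents[i],
            pop_urban=float(z_urban[i]),
            pop_rural=float(z_rural[i]),
            livestock_pop={cat: float(z_livestock[cat][i])
                           for cat in sorted(z_livestock)},
            planting_area=planting,
            cropland_fertilizer=float(z_fert[i]),
            forest_fertilizer=float(spec.forest_fertilizer_rate * z_area["forest"][i]),
            grassland_fertilizer=float(
                spec.grassland_fertilizer_rate * z_area["grassland"][i]),
            gdp=float(z_gdp[i]),
            landuse_areas={c: float(z_area[c][i]) for c in LANDUSE_ORDER},
        ))
    admin = AdminSet(regions)

    deposition_totals = {
        c: float(spec.deposition_rates[c] * z_area[c].sum()) for c in LANDUSE_ORDER
    }

    # --- daily trace-gas columns on the coarse grid
    f = spec.coarse_factor
    coarse_shape = (rows // f, cols // f)
    cell_m = spec.cell_size_km * 1000.0
    coarse_transform = GridTransform(x0=0.0, y0=rows * cell_m,
                                     dx=cell_m * f, dy=cell_m * f)

    def _block_sum(surface: np.ndarray) -> np.ndarray:
        return surface.reshape(coarse_shape[0], f, coarse_shape[1], f).sum(axis=(1, 3))

    def _truth(surface: np.ndarray) -> np.ndarray:
        blocks = _block_sum(surface)
        peak = blocks.max()
        return blocks / peak if peak > 0 else blocks

    truths = {"NO2": _truth(gdp + urban_pop),
              "NH3": _truth(np.asarray(livestock_density) + fertilizer)}
    columns: dict[str, ColumnSeries] = {}
    for species in ("NO2", "NH3"):
        noise = rng.normal(0.0, spec.column_noise_sd,
                           (spec.n_days,) + coarse_shape)
        fields = np.clip(truths[species][None, :, :] * (1.0 + noise), 0.0, None)
        valid = rng.random((spec.n_days,) + coarse_shape) < spec.observation_prob
        valid[0] = True  # guarantee >= 1 observation per cell
        columns[species] = ColumnSeries(species, fields, coarse_transform, valid)

    # --- watershed partition: jittered rectangular tiles
    br, bc = _factor_pair(spec.n_basins)
    row_edges = _jittered_edges(rng, rows, br)
    col_edges = _jittered_edges(rng, cols, bc)
    basin_ids, polys = [], []
    for i in range(br):
        for j in range(bc):
            r0, r1 = row_edges[i], row_edges[i + 1]
            c0, c1 = col_edges[j], col_edges[j + 1]
            basin_ids.append(f"B{i * bc + j:02d}")
            polys.append(shapely.box(
                transform.x0 + c0 * transform.dx,
                transform.y0 - r1 * transform.dy,
                transform.x0 + c1 * transform.dx,
                transform.y0 - r0 * transform.dy,
            ))
    watersheds = WatershedSet(basin_ids, polys)

    ground_truth = _ground_truth(admin, coeffs, deposition_totals)

    bundle = SynthBundle(
        spec=spec, admin=admin, region_codes=region_codes,
        region_raster=region_raster, landuse=landuse, proxies=proxies,
        columns=columns, watersheds=watersheds, coeffs=coeffs,
        deposition_totals=deposition_totals, ground_truth=ground_truth,
    )
    if outdir is not None:
        _write_bundle(bundle, Path(outdir))
    return bundle


def _jittered_edges(rng: np.random.Generator, n_cells: int, n_tiles: int) -> list[int]:
    edges = np.linspace(0, n_cells, n_tiles + 1).round().astype(int)
    out = [0]
    max_shift = max(1, n_cells // (n_tiles * 4))
    for e in edges[1:-1]:
        out.append(int(e + rng.integers(-max_shift, max_shift + 1)))
    out.append(n_cells)
    return out


# ---------------------------------------------------------------------------
# Ground truth (independent arithmetic — no calls into the budget assembler)
# ---------------------------------------------------------------------------


def _ground_truth(
    admin: AdminSet, coeffs: CoefficientLibrary, dep_totals: dict[str, float]
) -> FluxTable:
    records: list[FluxRecord] = []
    class_area = {c: admin.national_landuse_area(c) for c in LANDUSE_ORDER}
    for r in admin:
        areas = r.landuse_areas
        dep = {c: (dep_totals[c] * areas.get(c, 0.0) / class_area[c]
                   if class_area[c] > 0 else dep_totals[c] / len(admin))
               for c in LANDUSE_ORDER}
        manure_c = sum(pop * coeffs.excre_an[a] * coeffs.re_an_cropland[a]
                       for a, pop in r.livestock_pop.items())
        manure_g = (sum(pop * coeffs.excre_an[a] * coeffs.re_an_grassland[a]
                        for a, pop in r.livestock_pop.items())
                    if r.landuse_areas.get("grassland", 0.0) > 0 else 0.0)
        excr = (r.pop_urban * coeffs.re_ur + r.pop_rural * coeffs.re_ru) * coeffs.excre_hu
        cbnf = sum(area * coeffs.r_fix_crop[c] for c, area in r.planting_area.items())
        crop_area = areas.get("cropland", 0.0)
        grass_area = areas.get("grassland", 0.0)
        forest_area = areas.get("forest", 0.0)
        straw = coeffs.uniform_rates["straw recycle"] * crop_area
        irr = coeffs.uniform_rates["irrigation"] * crop_area
        irr_g = coeffs.uniform_rates["irrigation for artificial grassland"] * grass_area

        cropland = {
            "N fertilizer": r.cropland_fertilizer, "N deposition": dep["cropland"],
            "irrigation": irr, "livestock manure": manure_c,
            "human excretion": excr, "cropland BNF": cbnf, "straw recycle": straw,
        }
        forest = {
            "N fertilizer": r.forest_fertilizer, "N deposition": dep["forest"],
            "forest BNF": coeffs.r_fix_land["forest"] * forest_area,
        }
        grass = {
            "N fertilizer": r.grassland_fertilizer,
            "grassland BNF": coeffs.r_fix_land["grassland"] * grass_area,
            "N deposition": dep["grassland"],
            "irrigation for artificial grassland": irr_g,
            "livestock manure": manure_g,
        }
        water = {
            "cropland runoff": coeffs.runoff_coeffs["cropland"] * sum(cropland.values()),
            "livestock runoff": coeffs.runoff_coeffs["livestock"] * (manure_c + manure_g),
            "forest runoff": coeffs.runoff_coeffs["forest"] * sum(forest.values()),
            "human wastewater discharged":
                coeffs.wastewater_per_capita * (r.pop_urban + r.pop_rural),
            "industrial wastewater": coeffs.industrial_n_per_gdp * r.gdp,
            "WTP effluent": coeffs.wtp_effluent_per_capita * r.pop_urban,
            "N deposition": dep["water"],
        }
        for landuse, items in (("cropland", cropland), ("forest", forest),
                               ("grassland", grass), ("water", water)):
            for item, v in items.items():
                records.append(FluxRecord(landuse, item, v, r.region_id))
        records.append(FluxRecord("built-up", "N deposition", dep["built-up"],
                                  r.region_id))
        records.append(FluxRecord("unused", "N deposition", dep["unused"],
                                  r.region_id))

    table = FluxTable(records)
    national = [FluxRecord(lu, item, float(v), NATIONAL)
                for (lu, item), v in table.item_totals().items()]
    return table.extend(national)


# ---------------------------------------------------------------------------
# File output
# ---------------------------------------------------------------------------


def _write_bundle(bundle: SynthBundle, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["admin_csv"] = outdir / "admin.csv"
    bundle.admin.to_csv(paths["admin_csv"])
    paths["admin_geojson"] = outdir / "admin.geojson"
    _write_admin_geojson(bundle, paths["admin_geojson"])

    paths["landuse_tif"] = write_geotiff(bundle.landuse, outdir / "landuse.tif")
    paths["region_tif"] = write_geotiff(bundle.region_raster, outdir / "region.tif")
    for name, gm in bundle.proxies.items():
        paths[f"proxy_{name}"] = write_geotiff(gm, outdir / f"proxy_{name}.tif")

    for species, series in bundle.columns.items():
        paths[f"columns_{species.lower()}"] = series.to_netcdf(
            outdir / f"columns_{species.lower()}.nc")

    paths["watersheds_geojson"] = bundle.watersheds.to_geojson(
        outdir / "watersheds.geojson")

    paths["coefficients_yaml"] = outdir / "coefficients.yaml"
    bundle.coeffs.to_yaml(paths["coefficients_yaml"])

    paths["deposition_yaml"] = outdir / "deposition_totals.yaml"
    paths["deposition_yaml"].write_text(
        yaml.safe_dump({k: float(v) for k, v in bundle.deposition_totals.items()}))

    paths["ground_truth_csv"] = outdir / "ground_truth.csv"
    bundle.ground_truth.to_csv(paths["ground_truth_csv"])

    paths["spec_yaml"] = outdir / "spec.yaml"
    bundle.spec.to_yaml(paths["spec_yaml"])
    bundle.paths = paths


def _write_admin_geojson(bundle: SynthBundle, path: Path) -> None:
    """County rectangles derived from the region raster (exact bounding boxes)."""
    import json

    t = bundle.region_raster.transform
    arr = bundle.region_raster.values
    features = []
    for rid, code in bundle.region_codes.items():
        rs, cs = np.nonzero(arr == code)
        r0, r1, c0, c1 = rs.min(), rs.max() + 1, cs.min(), cs.max() + 1
        box = shapely.box(t.x0 + c0 * t.dx, t.y0 - r1 * t.dy,
                          t.x0 + c1 * t.dx, t.y0 - r0 * t.dy)
        features.append({
            "type": "Feature",
            "properties": {"region_id": rid,
                           "parent_id": bundle.admin[rid].parent_id},
            "geometry": shp_mapping(box),
        })
    path.write_text(json.dumps({"type": "FeatureCollection", "features": features}))


# ---------------------------------------------------------------------------
# Packaged national flux-table fixture
# ---------------------------------------------------------------------------


def table1_fixture() -> FluxTable:
    """The packaged national budget table (24 rows, stored in kg N/yr).

    Transcribed from the published 2017 national summary of N inputs to the
    six land-use types; report-scale values are Tg N/yr (1 Tg = 1e9 kg).
    """
    ref = importlib.resources.files("nbudget.data") / "table1.csv"
    with importlib.resources.as_file(ref) as path:
        return FluxTable.read_csv(path)
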