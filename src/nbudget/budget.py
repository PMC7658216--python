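"""Per-region nitrogen-input accounting.

Every flux is a simple mass-balance product of an activity level and a rate
coefficient, aggregated over open category vocabularies:

* livestock manure returned to land:  ``sum_a POP_an(a) * EXCRE_an(a) * RE_an(a)``
* human excretion returned to cropland:
  ``(POP_ur * RE_ur + POP_ru * RE_ru) * EXCRE_hu``
* biological N fixation:  ``sum_c area(c) * r_fix(c)``
* nationally uniform area rates (straw recycle, irrigation):  ``rate * area``

``assemble_budget`` applies these to every administrative region, distributes
externally supplied atmospheric-deposition totals across regions by class
area, derives the seven surface-water items, and stacks regional plus
national records into one flux table.  All internal magnitudes are kg N/yr;
the report layer converts to Tg N/yr.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
import yaml

from .errors import (
    AssemblyError,
    CoefficientGapError,
    ValidationError,
    VocabularyError,
)
from .vocab import BUDGET_ITEMS, KG_PER_TG, LANDUSE_ORDER, validate_item, validate_landuse

NATIONAL = "national"


# ============================================================================
# Flux records and tables
# ============================================================================


@dataclass(frozen=True)
class FluxRecord:
    """One nitrogen input: source item -> receiving land-use class, kg N/yr."""

    landuse: str
    item: str
    magnitude: float
    region_id: str = NATIONAL

    def __post_init__(self) -> None:
        validate_item(self.landuse, self.item)
        if not (self.magnitude >= 0.0):  # also rejects NaN
            raise ValidationError(
                f"flux magnitude must be >= 0, got {self.magnitude!r} "
                f"for ({self.landuse}, {self.item}, {self.region_id})"
            )

    @property
    def magnitude_tg(self) -> float:
        return self.magnitude / KG_PER_TG


class FluxTable:
    """A collection of flux records, unique on (region_id, landuse, item).

    Internally a pandas DataFrame with columns
    ``region_id, landuse, item, kgN_per_yr``.
    """

    COLUMNS = ["region_id", "landuse", "item", "kgN_per_yr"]

    def __init__(self, records: Iterable[FluxRecord] = ()) -> None:
        rows = [(r.region_id, r.landuse, r.item, float(r.magnitude)) for r in records]
        self._df = pd.DataFrame(rows, columns=self.COLUMNS)
        self._check_unique()

    def _check_unique(self) -> None:
        dup = self._df.duplicated(subset=["region_id", "landuse", "item"])
        if dup.any():
            rows = self._df.loc[dup, ["region_id", "landuse", "item"]]
            raise ValidationError(f"duplicate flux records:\n{rows}")

    # -- construction ---------------------------------------------------------

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "FluxTable":
        table = cls()
        table._df = df.loc[:, cls.COLUMNS].reset_index(drop=True).copy()
        table._df["kgN_per_yr"] = table._df["kgN_per_yr"].astype(float)
        table._check_unique()
        for landuse, item in zip(table._df["landuse"], table._df["item"]):
            validate_item(landuse, item)
        if (table._df["kgN_per_yr"] < 0).any():
            raise ValidationError("negative flux magnitude in table")
        return table

    def extend(self, records: Iterable[FluxRecord]) -> "FluxTable":
        rows = pd.DataFrame(
            [(r.region_id, r.landuse, r.item, float(r.magnitude)) for r in records],
            columns=self.COLUMNS,
        )
        self._df = pd.concat([self._df, rows], ignore_index=True)
        self._check_unique()
        return self

    # -- queries --------------------------------------------------------------

    @property
    def frame(self) -> pd.DataFrame:
        return self._df.copy()

    def __len__(self) -> int:
        return len(self._df)

    def records(self) -> list[FluxRecord]:
        return [
            FluxRecord(landuse=r.landuse, item=r.item, magnitude=r.kgN_per_yr,
                       region_id=r.region_id)
            for r in self._df.itertuples()
        ]

    def get(self, landuse: str, item: str, region_id: str = NATIONAL) -> float:
        """Magnitude in kg N/yr; VocabularyError on unknown names, KeyError if absent."""
        validate_item(landuse, item)
        sel = self._df[
            (self._df.region_id == region_id)
            & (self._df.landuse == landuse)
            & (self._df.item == item)
        ]
        if sel.empty:
            raise KeyError((region_id, landuse, item))
        return float(sel.kgN_per_yr.iloc[0])

    def get_tg(self, landuse: str, item: str, region_id: str = NATIONAL) -> float:
        return self.get(landuse, item, region_id) / KG_PER_TG

    def regional(self) -> "FluxTable":
        return FluxTable.from_frame(self._df[self._df.region_id != NATIONAL])

    def national(self) -> "FluxTable":
        """The national table: stored national rows, else the sum over regions."""
        nat = self._df[self._df.region_id == NATIONAL]
        if nat.empty:
            nat = (
                self._df.groupby(["landuse", "item"], as_index=False)["kgN_per_yr"]
                .sum()
                .assign(region_id=NATIONAL)
            )
        return FluxTable.from_frame(nat[self.COLUMNS])

    def item_totals(self, landuse: str | None = None) -> pd.Series:
        """National totals per (landuse, item) computed by summing regions."""
        df = self._df[self._df.region_id != NATIONAL]
        if df.empty:
            df = self._df
        if landuse is not None:
            df = df[df.landuse == landuse]
        return df.groupby(["landuse", "item"])["kgN_per_yr"].sum()

    # -- I/O ------------------------------------------------------------------

    def to_csv(self, path: str | Path | io.TextIOBase) -> None:
        self._df.to_csv(path, index=False, float_format="%.17g")

    @classmethod
    def read_csv(cls, path: str | Path | io.TextIOBase) -> "FluxTable":
        return cls.from_frame(pd.read_csv(path, dtype={"region_id": str}))


# ============================================================================
# Administrative regions
# ============================================================================


@dataclass
class AdminRegion:
    """One administrative unit (county scale) carrying its activity data.

    Quantities: persons, head, ha, kg N/yr, currency units/yr — all >= 0.
    """

    region_id: str
    parent_id: str | None = None
    pop_urban: float = 0.0
    pop_rural: float = 0.0
    livestock_pop: dict[str, float] = dc_field(default_factory=dict)
    planting_area: dict[str, float] = dc_field(default_factory=dict)
    cropland_fertilizer: float = 0.0
    forest_fertilizer: float = 0.0
    grassland_fertilizer: float = 0.0
    gdp: float = 0.0
    landuse_areas: dict[str, float] = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("pop_urban", "pop_rural", "cropland_fertilizer",
                     "forest_fertilizer", "grassland_fertilizer", "gdp"):
            v = getattr(self, name)
            if not (v >= 0):
                raise ValidationError(f"{self.region_id}: {name} must be >= 0, got {v}")
        for mapping_name in ("livestock_pop", "planting_area", "landuse_areas"):
            for key, v in getattr(self, mapping_name).items():
                if not (v >= 0):
                    raise ValidationError(
                        f"{self.region_id}: {mapping_name}[{key}] must be >= 0, got {v}"
                    )
        for cls in self.landuse_areas:
            validate_landuse(cls)

    def landuse_area(self, landuse: str) -> float:
        validate_landuse(landuse)
        return float(self.landuse_areas.get(landuse, 0.0))


class AdminSet:
    """The admin hierarchy: leaf regions (counties) plus optional parents."""

    def __init__(self, regions: Iterable[AdminRegion]) -> None:
        self.regions: list[AdminRegion] = list(regions)
        ids = [r.region_id for r in self.regions]
        if len(set(ids)) != len(ids):
            raise ValidationError("region_id values must be unique within an AdminSet")
        self._by_id = {r.region_id: r for r in self.regions}

    def __len__(self) -> int:
        return len(self.regions)

    def __iter__(self):
        return iter(self.regions)

    def __getitem__(self, region_id: str) -> AdminRegion:
        return self._by_id[region_id]

    def national_landuse_area(self, landuse: str) -> float:
        return sum(r.landuse_area(landuse) for r in self.regions)

    # -- CSV I/O: map-valued fields use dotted column prefixes ---------------

    _PREFIXES = {"livestock.": "livestock_pop", "croparea.": "planting_area",
                 "area.": "landuse_areas"}
    _SCALARS = ["pop_urban", "pop_rural", "cropland_fertilizer",
                "forest_fertilizer", "grassland_fertilizer", "gdp"]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.regions:
            row: dict[str, object] = {"region_id": r.region_id,
                                      "parent_id": r.parent_id or ""}
            for name in self._SCALARS:
                row[name] = getattr(r, name)
            for cat, v in sorted(r.livestock_pop.items()):
                row[f"livestock.{cat}"] = v
            for crop, v in sorted(r.planting_area.items()):
                row[f"croparea.{crop}"] = v
            for cls, v in sorted(r.landuse_areas.items()):
                row[f"area.{cls}"] = v
            rows.append(row)
        return pd.DataFrame(rows).fillna(0.0)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.17g")

    @classmethod
    def read_csv(cls, path: str | Path) -> "AdminSet":
        df = pd.read_csv(path, dtype={"region_id": str, "parent_id": str})
        regions = []
        for _, row in df.iterrows():
            maps: dict[str, dict[str, float]] = {v: {} for v in cls._PREFIXES.values()}
            for col in df.columns:
                for prefix, attr in cls._PREFIXES.items():
                    if col.startswith(prefix):
                        maps[attr][col[len(prefix):]] = float(row[col])
            parent = row.get("parent_id", "")
            regions.append(
                AdminRegion(
                    region_id=str(row["region_id"]),
                    parent_id=str(parent) if parent and not pd.isna(parent) else None,
                    **{name: float(row.get(name, 0.0)) for name in cls._SCALARS},
                    livestock_pop=maps["livestock_pop"],
                    planting_area=maps["planting_area"],
                    landuse_areas=maps["landuse_areas"],
                )
            )
        return cls(regions)


# ============================================================================
# Coefficient library
# ============================================================================


@dataclass
class CoefficientLibrary:
    """All rate parameters of the accounting scheme.

    The published budget defers every coefficient to external model
    protocols, so values here are configuration: excretion factors
    (kg N/head/yr, kg N/person/yr), return-rate fractions, fixation rates
    (kg N/ha/yr), nationally uniform area rates, runoff-export fractions and
    wastewater intensities.  Manure return rates are per receiving land use
    (cropland vs grassland) because grassland also receives manure.
    """

    excre_an: dict[str, float] = dc_field(default_factory=dict)
    re_an_cropland: dict[str, float] = dc_field(default_factory=dict)
    re_an_grassland: dict[str, float] = dc_field(default_factory=dict)
    excre_hu: float = 0.0
    re_ur: float = 0.0
    re_ru: float = 0.0
    r_fix_crop: dict[str, float] = dc_field(default_factory=dict)
    r_fix_land: dict[str, float] = dc_field(default_factory=dict)  # forest, grassland
    uniform_rates: dict[str, float] = dc_field(default_factory=dict)
    runoff_coeffs: dict[str, float] = dc_field(default_factory=dict)
    wastewater_per_capita: float = 0.0
    wtp_effluent_per_capita: float = 0.0
    industrial_n_per_gdp: float = 0.0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        fracs: list[tuple[str, float]] = [("re_ur", self.re_ur), ("re_ru", self.re_ru)]
        fracs += [(f"re_an_cropland[{k}]", v) for k, v in self.re_an_cropland.items()]
        fracs += [(f"re_an_grassland[{k}]", v) for k, v in self.re_an_grassland.items()]
        fracs += [(f"runoff_coeffs[{k}]", v) for k, v in self.runoff_coeffs.items()]
        for name, v in fracs:
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"fraction {name} must lie in [0,1], got {v}")
        rates: list[tuple[str, float]] = [
            ("excre_hu", self.excre_hu),
            ("wastewater_per_capita", self.wastewater_per_capita),
            ("wtp_effluent_per_capita", self.wtp_effluent_per_capita),
            ("industrial_n_per_gdp", self.industrial_n_per_gdp),
        ]
        for mapping_name in ("excre_an", "r_fix_crop", "r_fix_land", "uniform_rates"):
            rates += [(f"{mapping_name}[{k}]", v)
                      for k, v in getattr(self, mapping_name).items()]
        for name, v in rates:
            if not (v >= 0):
                raise ValidationError(f"rate {name} must be >= 0, got {v}")

    def re_an(self, landuse: str) -> dict[str, float]:
        if landuse == "cropland":
            return self.re_an_cropland
        if landuse == "grassland":
            return self.re_an_grassland
        raise VocabularyError(f"no manure return-rate vector for land use {landuse!r}")

    # -- YAML I/O -------------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "excretion": {"animal": dict(self.excre_an), "human": self.excre_hu},
            "return_rates": {
                "manure_to_cropland": dict(self.re_an_cropland),
                "manure_to_grassland": dict(self.re_an_grassland),
                "urban_excretion": self.re_ur,
                "rural_excretion": self.re_ru,
            },
            "fixation": {"crops": dict(self.r_fix_crop), **dict(self.r_fix_land)},
            "uniform_rates": dict(self.uniform_rates),
            "runoff_coefficients": dict(self.runoff_coeffs),
            "wastewater": {
                "human_per_capita": self.wastewater_per_capita,
                "wtp_effluent_per_urban_capita": self.wtp_effluent_per_capita,
                "industrial_per_gdp": self.industrial_n_per_gdp,
            },
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "CoefficientLibrary":
        fix = dict(d.get("fixation", {}))
        crops = fix.pop("crops", {})
        ww = d.get("wastewater", {})
        rr = d.get("return_rates", {})
        return cls(
            excre_an=dict(d.get("excretion", {}).get("animal", {})),
            excre_hu=float(d.get("excretion", {}).get("human", 0.0)),
            re_an_cropland=dict(rr.get("manure_to_cropland", {})),
            re_an_grassland=dict(rr.get("manure_to_grassland", {})),
            re_ur=float(rr.get("urban_excretion", 0.0)),
            re_ru=float(rr.get("rural_excretion", 0.0)),
            r_fix_crop={k: float(v) for k, v in crops.items()},
            r_fix_land={k: float(v) for k, v in fix.items()},
            uniform_rates=dict(d.get("uniform_rates", {})),
            runoff_coeffs=dict(d.get("runoff_coefficients", {})),
            wastewater_per_capita=float(ww.get("human_per_capita", 0.0)),
            wtp_effluent_per_capita=float(ww.get("wtp_effluent_per_urban_capita", 0.0)),
            industrial_n_per_gdp=float(ww.get("industrial_per_gdp", 0.0)),
        )

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def read_yaml(cls, path: str | Path) -> "CoefficientLibrary":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


# ============================================================================
# Flux operations
# ============================================================================


def livestock_manure_flux(
    region: AdminRegion, coeffs: CoefficientLibrary, landuse: str = "cropland"
) -> FluxRecord:
    """Manure N returned to cropland (or grassland): sum of POP*EXCRE*RE.

    A region with none of the receiving land class returns no manure to it
    (no land to spread on), regardless of the configured return rates.
    """
    re_map = coeffs.re_an(landuse)
    if landuse != "cropland" and region.landuse_area(landuse) == 0.0:
        return FluxRecord(landuse, "livestock manure", 0.0, region.region_id)
    total = 0.0
    for category, pop in region.livestock_pop.items():
        if category not in coeffs.excre_an:
            raise CoefficientGapError(
                f"no excretion factor for animal category {category!r}"
            )
        if category not in re_map:
            raise CoefficientGapError(
                f"no manure return rate ({landuse}) for animal category {category!r}"
            )
        total += pop * coeffs.excre_an[category] * re_map[category]
    return FluxRecord(landuse, "livestock manure", total, region.region_id)


def human_excretion_flux(region: AdminRegion, coeffs: CoefficientLibrary) -> FluxRecord:
    """Human excretion N returned to cropland."""
    total = (region.pop_urban * coeffs.re_ur + region.pop_rural * coeffs.re_ru) * coeffs.excre_hu
    return FluxRecord("cropland", "human excretion", total, region.region_id)


def bnf_flux(
    region: AdminRegion, coeffs: CoefficientLibrary, landuse: str = "cropland"
) -> FluxRecord:
    """Biological N fixation: planting area x crop rate (cropland) or
    land-use area x land rate (forest, grassland)."""
    validate_landuse(landuse)
    if landuse == "cropland":
        total = 0.0
        for crop, area in region.planting_area.items():
            if area > 0 and crop not in coeffs.r_fix_crop:
                raise CoefficientGapError(f"no fixation rate for crop {crop!r}")
            total += area * coeffs.r_fix_crop.get(crop, 0.0)
        item = "cropland BNF"
    elif landuse in ("forest", "grassland"):
        area = region.landuse_area(landuse)
        if area > 0 and landuse not in coeffs.r_fix_land:
            raise CoefficientGapError(f"no fixation rate for land class {landuse!r}")
        total = area * coeffs.r_fix_land.get(landuse, 0.0)
        item = f"{landuse} BNF"
    else:
        raise VocabularyError(f"no BNF item defined for land use {landuse!r}")
    return FluxRecord(landuse, item, total, region.region_id)


#: uniform-rate items -> the land-use class whose area they multiply
_UNIFORM_ITEM_AREA = {
    "straw recycle": ("cropland", "cropland"),
    "irrigation": ("cropland", "cropland"),
    "irrigation for artificial grassland": ("grassland", "grassland"),
}


def uniform_rate_flux(
    region: AdminRegion, coeffs: CoefficientLibrary, item: str
) -> FluxRecord:
    """Nationally uniform per-hectare rate x the region's relevant land-use area."""
    if item not in _UNIFORM_ITEM_AREA:
        raise VocabularyError(
            f"{item!r} is not a uniform-rate item; expected one of "
            f"{sorted(_UNIFORM_ITEM_AREA)}"
        )
    if item not in coeffs.uniform_rates:
        raise CoefficientGapError(f"no uniform rate configured for {item!r}")
    landuse, area_class = _UNIFORM_ITEM_AREA[item]
    magnitude = coeffs.uniform_rates[item] * region.landuse_area(area_class)
    return FluxRecord(landuse, item, magnitude, region.region_id)


def fertilizer_flux(region: AdminRegion, landuse: str) -> FluxRecord:
    """Synthetic-fertilizer N taken directly from the activity statistics."""
    amounts = {
        "cropland": region.cropland_fertilizer,
        "forest": region.forest_fertilizer,
        "grassland": region.grassland_fertilizer,
    }
    if landuse not in amounts:
        raise VocabularyError(f"no fertilizer item for land use {landuse!r}")
    return FluxRecord(landuse, "N fertilizer", amounts[landuse], region.region_id)


# ============================================================================
# Budget assembly
# ============================================================================


def _distribute_deposition(
    regions: AdminSet, deposition: FluxTable
) -> dict[tuple[str, str], float]:
    """Per-(region, landuse) deposition, kg N/yr.

    If the deposition table already carries regional rows they are used as
    given; otherwise each class's national total is spread over regions in
    proportion to the region's area of that class (uniformly over regions if
    the class has no area anywhere).
    """
    out: dict[tuple[str, str], float] = {}
    regional_rows = deposition.frame.query("region_id != @NATIONAL and item == 'N deposition'")
    if not regional_rows.empty:
        for row in regional_rows.itertuples():
            out[(row.region_id, row.landuse)] = row.kgN_per_yr
        return out
    national = deposition.national()
    for landuse in LANDUSE_ORDER:
        try:
            total = national.get(landuse, "N deposition")
        except KeyError as exc:
            raise AssemblyError(
                f"deposition table lacks an 'N deposition' record for {landuse}"
            ) from exc
        class_area = regions.national_landuse_area(landuse)
        for region in regions:
            if class_area > 0:
                share = region.landuse_area(landuse) / class_area
            else:
                share = 1.0 / len(regions)
            out[(region.region_id, landuse)] = total * share
    return out


def _require(coeffs: CoefficientLibrary, gaps: list[str]) -> None:
    for key in ("cropland", "livestock", "forest"):
        if key not in coeffs.runoff_coeffs:
            gaps.append(f"runoff coefficient {key!r}")
    for item in _UNIFORM_ITEM_AREA:
        if item not in coeffs.uniform_rates:
            gaps.append(f"uniform rate {item!r}")


def assemble_budget(
    regions: AdminSet, coeffs: CoefficientLibrary, deposition: FluxTable
) -> FluxTable:
    """Build the full regional + national budget table.

    The composition is fixed: cropland receives fertilizer, deposition,
    irrigation, manure, human excretion, BNF and straw recycle; forest
    fertilizer, deposition and BNF; grassland fertilizer, BNF, deposition,
    artificial-grassland irrigation and manure; surface water the three
    runoff items, three wastewater items and deposition; built-up and unused
    land deposition only.  Surface-water runoff items are derived from this
    same table: export coefficient x the source subsystem's total input.
    """
    gaps: list[str] = []
    _require(coeffs, gaps)
    if gaps:
        raise AssemblyError("missing configuration: " + "; ".join(gaps))

    dep = _distribute_deposition(regions, deposition)
    records: list[FluxRecord] = []
    for region in regions:
        rid = region.region_id
        cropland = [
            fertilizer_flux(region, "cropland"),
            FluxRecord("cropland", "N deposition", dep[(rid, "cropland")], rid),
            uniform_rate_flux(region, coeffs, "irrigation"),
            livestock_manure_flux(region, coeffs, "cropland"),
            human_excretion_flux(region, coeffs),
            bnf_flux(region, coeffs, "cropland"),
            uniform_rate_flux(region, coeffs, "straw recycle"),
        ]
        forest = [
            fertilizer_flux(region, "forest"),
            FluxRecord("forest", "N deposition", dep[(rid, "forest")], rid),
            bnf_flux(region, coeffs, "forest"),
        ]
        grass = [
            fertilizer_flux(region, "grassland"),
            bnf_flux(region, coeffs, "grassland"),
            FluxRecord("grassland", "N deposition", dep[(rid, "grassland")], rid),
            uniform_rate_flux(region, coeffs, "irrigation for artificial grassland"),
            livestock_manure_flux(region, coeffs, "grassland"),
        ]
        cropland_input = sum(r.magnitude for r in cropland)
        forest_input = sum(r.magnitude for r in forest)
        manure_total = (
            livestock_manure_flux(region, coeffs, "cropland").magnitude
            + livestock_manure_flux(region, coeffs, "grassland").magnitude
        )
        water = [
            FluxRecord("water", "cropland runoff",
                       coeffs.runoff_coeffs["cropland"] * cropland_input, rid),
            FluxRecord("water", "livestock runoff",
                       coeffs.runoff_coeffs["livestock"] * manure_total, rid),
            FluxRecord("water", "forest runoff",
                       coeffs.runoff_coeffs["forest"] * forest_input, rid),
            FluxRecord("water", "human wastewater discharged",
                       coeffs.wastewater_per_capita
                       * (region.pop_urban + region.pop_rural), rid),
            FluxRecord("water", "industrial wastewater",
                       coeffs.industrial_n_per_gdp * region.gdp, rid),
            FluxRecord("water", "WTP effluent",
                       coeffs.wtp_effluent_per_capita * region.pop_urban, rid),
            FluxRecord("water", "N deposition", dep[(rid, "water")], rid),
        ]
        other = [
            FluxRecord("built-up", "N deposition", dep[(rid, "built-up")], rid),
            FluxRecord("unused", "N deposition", dep[(rid, "unused")], rid),
        ]
        records.extend(cropland + forest + grass + water + other)

    table = FluxTable(records)
    national = [
        FluxRecord(landuse, item, float(total), NATIONAL)
        for (landuse, item), total in table.item_totals().items()
    ]
    # ensure every Table-1 slot exists nationally, even if zero
    present = {(r.landuse, r.item) for r in national}
    for landuse, items in BUDGET_ITEMS.items():
        for item in items:
            if (landuse, item) not in present:
                national.append(FluxRecord(landuse, item, 0.0, NATIONAL))
    return table.extend(national)
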