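"""Closed vocabularies of the nitrogen-input budget.

Six receiving land-use classes and the fixed item-per-class composition of
the national budget table.  Animal and crop categories, by contrast, are
open (configuration-defined) vocabularies and live in the coefficient
library, not here.
"""

from __future__ import annotations

# Report ordering of the land-use classes.
LANDUSE_ORDER: tuple[str, ...] = (
    "cropland",
    "forest",
    "grassland",
    "water",
    "built-up",
    "unused",
)

# Integer codes used in land-use rasters (0 reserved for nodata-free use;
# rasters use -1 as nodata). Ties in class assignment resolve to the lowest code.
LANDUSE_CODES: dict[str, int] = {name: i + 1 for i, name in enumerate(LANDUSE_ORDER)}
CODE_TO_LANDUSE: dict[int, str] = {v: k for k, v in LANDUSE_CODES.items()}

# The budget composition: which input items each land-use class receives.
# Cropland 7, forest 3, grassland 5, water 7, built-up 1, unused 1 = 24 rows.
BUDGET_ITEMS: dict[str, tuple[str, ...]] = {
    "cropland": (
        "N fertilizer",
        "N deposition",
        "irrigation",
        "livestock manure",
        "human excretion",
        "cropland BNF",
        "straw recycle",
    ),
    "forest": (
        "N fertilizer",
        "N deposition",
        "forest BNF",
    ),
    "grassland": (
        "N fertilizer",
        "grassland BNF",
        "N deposition",
        "irrigation for artificial grassland",
        "livestock manure",
    ),
    "water": (
        "cropland runoff",
        "livestock runoff",
        "forest runoff",
        "human wastewater discharged",
        "industrial wastewater",
        "WTP effluent",
        "N deposition",
    ),
    "built-up": ("N deposition",),
    "unused": ("N deposition",),
}

ALL_ITEMS: frozenset[str] = frozenset(
    item for items in BUDGET_ITEMS.values() for item in items
)

#: kg per teragram, the report-scale unit conversion.
KG_PER_TG = 1.0e9


def validate_landuse(name: str) -> str:
    from .errors import VocabularyError

    if name not in LANDUSE_CODES:
        raise VocabularyError(
            f"unknown land-use class {name!r}; expected one of {LANDUSE_ORDER}"
        )
    return name


def validate_item(landuse: str, item: str) -> str:
    from .errors import VocabularyError

    validate_landuse(landuse)
    if item not in BUDGET_ITEMS[landuse]:
        raise VocabularyError(
            f"item {item!r} is not part of the {landuse} budget; "
            f"expected one of {BUDGET_ITEMS[landuse]}"
        )
    return item
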