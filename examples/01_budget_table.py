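"""Assemble a national N-input budget for a tiny two-county country.

Builds the activity data by hand, applies the flux equations (manure =
POP x EXCRE x RE; excretion = (POP_ur x RE_ur + POP_ru x RE_ru) x EXCRE_hu;
BNF = area x r_fix; uniform per-hectare rates) and prints the resulting
budget table in Tg N/yr.
"""

from nbudget import (
    AdminRegion,
    AdminSet,
    FluxRecord,
    FluxTable,
    assemble_budget,
    budget_report,
    default_library,
)
from nbudget.vocab import LANDUSE_ORDER

counties = AdminSet([
    AdminRegion(
        "0", pop_urban=600_000, pop_rural=400_000,
        livestock_pop={"pigs": 300_000, "cattle": 20_000, "poultry": 2e6},
        planting_area={"grain": 60_000, "soy": 15_000, "vegetables": 5_000},
        cropland_fertilizer=1.6e7, gdp=8e9,
        landuse_areas={"cropland": 80_000, "forest": 50_000, "grassland": 30_000,
                       "water": 5_000, "built-up": 20_000, "unused": 15_000},
    ),
    AdminRegion(
        "1", pop_urban=150_000, pop_rural=650_000,
        livestock_pop={"pigs": 500_000, "cattle": 60_000, "poultry": 4e6},
        planting_area={"grain": 90_000, "soy": 25_000, "vegetables": 5_000},
        cropland_fertilizer=2.5e7, gdp=2e9,
        landuse_areas={"cropland": 120_000, "forest": 90_000, "grassland": 60_000,
                       "water": 10_000, "built-up": 8_000, "unused": 12_000},
    ),
])

# per-class national deposition totals (kg N/yr), normally from the
# satellite-column pathway; here simply 15 kg N/ha on every class
deposition = FluxTable([
    FluxRecord(cls, "N deposition",
               15.0 * sum(r.landuse_area(cls) for r in counties))
    for cls in LANDUSE_ORDER
])

table = assemble_budget(counties, default_library(), deposition)
frame, text = budget_report(table.national())
print(text)
print()
print("Each row is one N input (Tg N/yr = 1e9 kg N/yr) to the receiving")
print("land-use class; subtotals give each class's total N load and the")
print("grand total the country-wide input, runoff items being derived")
print("from the land budgets via export coefficients.")
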