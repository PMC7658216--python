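"""Run the whole pipeline on the synthetic country and audit it.

Generates the bundle to disk, executes budget -> deposition -> maps ->
water -> report, then compares the assembled national table with the
generator's ground truth and prints the watershed loads.
"""

import tempfile
from pathlib import Path

from nbudget import RunConfig, SynthSpec, generate, run_pipeline
from nbudget.vocab import BUDGET_ITEMS, LANDUSE_ORDER

workdir = Path(tempfile.mkdtemp(prefix="nbudget-example-"))
bundle = generate(SynthSpec(seed=1), outdir=workdir / "bundle")
p = bundle.paths

config = RunConfig(
    admin_csv=p["admin_csv"], landuse_tif=p["landuse_tif"],
    region_tif=p["region_tif"],
    proxy_tifs={k.removeprefix("proxy_"): v
                for k, v in p.items() if k.startswith("proxy_")},
    column_ncs={"NO2": p["columns_no2"], "NH3": p["columns_nh3"]},
    watersheds_geojson=p["watersheds_geojson"],
    coefficients_yaml=p["coefficients_yaml"],
    deposition_totals=bundle.deposition_totals,
    out_dir=workdir / "out", log_level="WARNING",
)
result = run_pipeline(config)

got = result["budget"].national()
want = bundle.ground_truth.national()
worst = max(
    abs(got.get(lu, item) - want.get(lu, item)) / max(want.get(lu, item), 1.0)
    for lu in LANDUSE_ORDER for item in BUDGET_ITEMS[lu])
print(f"worst relative error vs ground truth over all 24 items: {worst:.2e}")

basins = result["basin_totals"]
loads = basins.groupby("basin_id").kgN_per_yr.sum() / 1e6
print("\nwatershed N loads (kt N/yr):")
for bid, load in loads.items():
    print(f"  {bid}: {load:8.2f}")
print(f"\noutputs written to {result['run_dir']}")
print("The budget, every map and the basin table all derive from the same")
print("county activity data; ground-truth recovery shows the chain is exact.")
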