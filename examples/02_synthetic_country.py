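"""Generate the seeded synthetic country and inspect its ground truth.

The generator tiles a 200x200 km grid into 4 provinces / 100 counties,
draws a coherent land-use mosaic and Gaussian-bump proxy surfaces, and
derives every county's activity table as the exact zonal sum of those
surfaces — so the bundled ground-truth flux table is an exact oracle for
the pipeline.
"""

from nbudget import SynthSpec, generate

bundle = generate(SynthSpec(seed=1))
nat = bundle.ground_truth.national()

print(f"counties: {len(bundle.admin)}, grid: {bundle.landuse.shape}")
print(f"population: {sum(r.pop_urban + r.pop_rural for r in bundle.admin):,.0f}")
print()
for landuse, item in [("cropland", "N fertilizer"),
                      ("cropland", "livestock manure"),
                      ("forest", "forest BNF"),
                      ("water", "human wastewater discharged")]:
    print(f"{landuse:10s} {item:28s} {nat.get_tg(landuse, item):8.4f} Tg N/yr")
print()
print("These magnitudes are the generator's ground truth: the budget")
print("assembler must reproduce each of them from the county tables alone.")
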