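# nbudget

Reactive-nitrogen (Nr) input accounting and mass-conserving 1-km mapping for
land and surface-water budgets.

National element-cycle databases report how much nitrogen reaches each
land-use class — cropland, forest, grassland, surface water, built-up and
unused land — but the underlying statistics live at county or province
scale. `nbudget` is for biogeochemists and environmental modellers who need
both sides: the mass-balance budget table per administrative region, and
gridded maps of every flux in which each region's total is preserved
exactly, so the maps can feed watershed loading or impact models without
inventing or losing mass.

## The accounting scheme

Each flux is an activity level times a rate coefficient, in kg N yr⁻¹:

- livestock manure returned to land: `MANURE_an = Σ_a POP_an(a) · EXCRE_an(a) · RE_an(a)`
  over animal categories *a* (head × kg N head⁻¹ yr⁻¹ × return fraction);
- human excretion returned to cropland:
  `MANURE_hu = (POP_ur · RE_ur + POP_ru · RE_ru) · EXCRE_hu`;
- biological N fixation: `BNF = Σ_c area(c) · r_fix(c)` (ha × kg N ha⁻¹ yr⁻¹);
- straw recycle and irrigation: nationally uniform per-hectare rates;
- fertilizer N taken directly from county statistics;
- surface-water inputs: export coefficients times the source subsystem's
  input (cropland, livestock, forest runoff) plus per-capita and per-GDP
  wastewater intensities and deposition to water cells.

Atmospheric deposition is handled separately: daily satellite NO₂/NH₃
column fields are composited to monthly means (arithmetic mean over valid
observations), blended into a normalized column index, and configured
national per-class deposition totals are spread over each class's cells in
proportion to that index.

Spatial disaggregation is dasymetric and mass-conserving: for a region with
total *T* and proxy surface *w* (population, GDP, livestock density, a
land-use mask, …), cell *i* of the region receives `T · w_i / Σ_j w_j`, so
zonal re-aggregation returns *T* to floating-point precision. Watershed
loads are zonal sums of the water-input maps over a basin partition.

Because the published coefficient sets behind such budgets are not part of
the package, all rates are configuration (`CoefficientLibrary`) with
documented illustrative defaults, and correctness is demonstrated on a
seeded synthetic country whose ground-truth flux table is known exactly.

## Worked example

`examples/` contains one short script per capability. Compositing the
synthetic daily columns and allocating the packaged national deposition
totals (`examples/04_deposition_mapping.py`) prints:

```
class       configured (Tg)   map zonal sum (Tg)
cropland                5.9         5.9000000000
forest                  5.5         5.5000000000
grassland               3.5         3.5000000000
water                   0.6         0.6000000000
built-up                1.0         1.0000000000
unused                  1.6         1.6000000000
```

Each class's configured national deposition total (left) is recovered
exactly by re-aggregating the 1-km map (right): the column index decides
*where* deposition falls within a class, never *how much*. The end-to-end
run (`examples/05_full_pipeline.py`) reports the worst relative error of
the assembled budget against the generator's ground truth (≈1e-12) and the
per-basin N loads.

A thin CLI mirrors the stages:

```sh
nbudget synth --seed 1 --out bundle/
nbudget report --table bundle/ground_truth.csv
nbudget run --config run.yaml
```

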