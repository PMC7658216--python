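# Methods

## Model

`nbudget` implements a static, annual nitrogen-input account: every flux is
the product of an activity level and a rate coefficient, summed over open
category vocabularies, with no internal cycling (volatilization,
denitrification, crop uptake and in-stream retention are out of scope —
the quantities are *inputs* to each land-use class, not net balances).

The budget composition is fixed at 24 (class, item) pairs: cropland
receives fertilizer, deposition, irrigation, livestock manure, human
excretion, BNF and straw recycle; forest fertilizer, deposition and BNF;
grassland fertilizer, BNF, deposition, artificial-grassland irrigation and
manure; surface water three runoff items, three wastewater items and
deposition; built-up and unused land deposition only. `FluxTable` enforces
this closed item vocabulary; animal and crop categories are open and
config-defined.

Assumptions worth making explicit:

- county fertilizer statistics are nitrogen mass, not product mass;
- manure return rates are a separate vector per receiving land use
  (cropland vs grassland), and a region with zero area of the receiving
  class returns no manure to it — there is no land to spread on;
- forest runoff is export coefficient × total forest N input, mapped on the
  forest input distribution (the narrower alternative — scaling with forest
  area alone — is recoverable by assigning the forest-mask proxy);
- livestock runoff is export coefficient × total manure returned to land
  (cropland plus grassland records);
- fertilizer within a county is spread uniformly over its cropland cells;
  weighting by crop type would need sub-county crop maps the scheme does
  not assume.

## Coefficients

All rates live in `CoefficientLibrary` (YAML-serializable); none are
hard-coded because published national budgets of this kind defer their
coefficient sets to external model protocols. `default_library()` provides
documented illustrative values: excretion 9/50/0.5 kg N head⁻¹ yr⁻¹
(pigs/cattle/poultry), 4 kg N person⁻¹ yr⁻¹; return fractions 0.3–0.4 to
cropland, 0.15 (cattle only) to grassland, 0.1/0.4 urban/rural; fixation
10/80/15 kg N ha⁻¹ yr⁻¹ by crop and 12/9 for forest/grassland; straw
recycle 15 and irrigation 5 kg N ha⁻¹ yr⁻¹; runoff export fractions
0.05/0.10/0.12 for cropland/livestock/forest, consistent with the ratios
visible in national budget tables (e.g. cropland runoff ≈ 5% of cropland
input); wastewater 2 and 1 kg N person⁻¹ yr⁻¹ and 2×10⁻⁵ kg N per currency
unit of GDP. These magnitudes make the synthetic country's per-hectare
intensities realistic; they carry no empirical authority.

## Spatial disaggregation

Dasymetric, mass-conserving: cell = region_total × proxy / Σ(proxy over the
region's eligible cells). Conventions: row 0 is north; cell values are
whole-cell totals (kg N cell⁻¹); pixels are half-open; region and basin
membership is by cell center, so every cell belongs to exactly one region
and conservation is exact by construction; class-assignment ties resolve to
the lowest class id. Cells are treated as equal-area (the synthetic grid is
an equal-area 1-km grid); latitude-dependent cell areas would enter as a
multiplicative weight on the proxy and are not implemented.

Zero-proxy fallback: a region whose eligible proxy mass is zero but whose
flux is positive is allocated uniformly over its eligible cells; if it has
no eligible cells, uniformly over all its cells; both paths log a warning.
Mass is dropped (with a warning) only for a region with no cells at all.

## Deposition

The column-to-deposition conversion is deliberately absent: national
per-class totals are configuration, and the satellite columns act only as a
spatial weight. Monthly compositing is a per-cell arithmetic mean over
valid daily observations (cells with zero valid days are nodata, and the
generator guarantees at least one observation per cell). The index is a
weighted sum (default 0.5/0.5) of the per-species max-normalized monthly
composites, which makes it invariant to common rescaling of either column.
Coarse-to-fine transfer is nearest-neighbour (block-constant), not
interpolation, so the class-wise renormalization stays exact.

## Synthetic country

The generator emulates the qualitative structure of national activity
data: provinces are rectangular tiles and counties sub-tiles (so region
rasterization is exact); the land-use mosaic is drawn per county by
splitting cells, ordered along a smooth Gaussian-bump relief field, into
jittered class fractions (Dirichlet around the national fractions);
population, GDP, livestock and fertilizer surfaces are Gaussian-bump
mixtures over a low uniform floor, masked to plausible classes and
normalized to the spec totals; county activity values are defined as the
zonal sums of these surfaces, so table/raster consistency is exact, not
approximate. Daily column fields are the coarse block-aggregated
socioeconomic surfaces (NO₂ ~ GDP + urban population, NH₃ ~ livestock +
fertilizer) times multiplicative Gaussian noise (sd 0.2), with a Bernoulli
0.7 observation mask. Watersheds are jittered rectangular tiles.

Defaults: 200×200 grid of 1-km cells, 4 provinces × 25 counties, 6 M
people (60% urban), 6×10¹⁰ currency units GDP, 2 M pigs / 0.2 M cattle /
20 M poultry, 2.4×10⁸ kg fertilizer N (200 kg N ha⁻¹ of cropland),
deposition 8–30 kg N ha⁻¹ yr⁻¹ by class — per-hectare intensities of the
order seen in intensively managed regions. A full generate-plus-pipeline
run takes about a second.

What the generator does *not* emulate: real administrative geometry,
spatially correlated reporting errors in yearbook statistics, seasonality,
retrieval artefacts in satellite columns, or any correlation structure
between coefficients and activity. Passing tests therefore demonstrate the
*accounting and allocation machinery* is exact and deterministic, not that
any particular national estimate is right.

The ground-truth flux table is computed inside the generator by direct
arithmetic over the county tables — a second, independent code path from
the budget assembler — so end-to-end recovery is a genuine dual-route
check. All randomness flows through one seeded `numpy.random.default_rng`
(PCG64) stream; a fixed seed reproduces every output file bit-for-bit.

## QA/QC

Per (class, item), regional records strictly outside the
[p0.5, p99.5] percentile band are flagged; with exclusion enabled the
remaining records are rescaled to preserve the item's national total, and
excluding every record of an item is a hard error. The strict inequality
means a set of identical records yields no flags, and a single gross
outlier among otherwise identical records is the unique flag. On
continuously distributed data the band necessarily flags ≈1% of records;
the rule is a screening aid, not an outlier test with a false-positive
guarantee.

## Numerical choices

- Internal unit kg N yr⁻¹ throughout; reporting converts to Tg N yr⁻¹
  (10⁹ kg) rounded to one decimal, half-up (`decimal` module, matching
  printed-table conventions rather than banker's rounding).
- Conservation tolerances in tests are 1e-9 relative with an absolute
  floor of 1 kg for near-zero fluxes; observed errors are ~1e-12.
- CSV floats are written with `%.17g` (exact double round-trip); GeoTIFFs
  are float64/int32 single-band with ModelPixelScale/ModelTiepoint/
  GDAL_NODATA tags; column series are classic NetCDF via the scipy
  backend.
- Degenerate inputs: empty column series, zero-weight index pairs, empty
  map lists, non-positive cell areas and out-of-range fractions raise
  typed errors rather than propagating NaNs.

## Outputs

A pipeline run writes per-item GeoTIFFs (`<class>_<item>.tif`), combined
class and national maps, the regional+national flux-table CSV, the basin
CSV, the formatted report, a QA/QC report, and a manifest (abbreviations,
units, config hash, package version) plus a sources file — a three-file
data/readme/sources layout. Run directories are namespaced by config hash
to avoid silent overwrites.

## Known limitations

- The water-input maps live on their source/proxy distributions; no
  routing moves mass to the stream network, so "watershed load" means
  mass generated within the basin.
- Deposition is annual; monthly composites exist but the allocator uses
  their mean.
- Provinces are purely organisational in the budget (fluxes are computed
  at county level and summed); no province-level conservation constraint
  beyond additivity is imposed.
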