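"""Surface-water fluxes, proportionality oracles and watershed aggregation."""

import numpy as np
import pytest
import shapely

from nbudget import (
    AdminRegion,
    AdminSet,
    GridMap,
    GridTransform,
    WatershedSet,
    default_library,
    runoff_flux,
    wastewater_fluxes,
    watershed_totals,
)
from nbudget.errors import ConfigError, ValidationError

T = GridTransform(0.0, 4000.0, 1000.0, 1000.0)


def gm(values, nodata=None, dtype=None):
    return GridMap(np.asarray(values, dtype=dtype), T, nodata=nodata)


class TestRunoff:
    def test_zero_coefficient_gives_zero_map(self):
        out, rec = runoff_flux(gm(np.ones((4, 4))), 0.0, "cropland runoff")
        assert out.total() == 0.0 and rec.magnitude == 0.0

    def test_mass_scales_with_coefficient(self):
        source = gm(np.full((4, 4), 62.5))  # 1000 kg total
        out, rec = runoff_flux(source, 0.1, "cropland runoff")
        assert rec.magnitude == pytest.approx(100.0)
        assert out.total() == pytest.approx(100.0)

    def test_map_argmax_colocated_with_source_argmax(self):
        rng = np.random.default_rng(9)
        source = gm(rng.uniform(0, 50, (4, 4)))
        out, _ = runoff_flux(source, 0.2, "cropland runoff")
        assert np.unravel_index(np.argmax(out.values), (4, 4)) == \
            np.unravel_index(np.argmax(source.values), (4, 4))

    def test_coefficient_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            runoff_flux(gm(np.ones((4, 4))), 1.5, "cropland runoff")


class TestWastewater:
    def two_city_setup(self, pop_scale=1.0):
        # city 0 occupies the left half, city 1 the right half
        codes = np.zeros((4, 4), dtype=np.int32)
        codes[:, 2:] = 1
        regions = AdminSet([
            AdminRegion("0", pop_urban=1000 * pop_scale, pop_rural=500 * pop_scale,
                        gdp=1e6),
            AdminRegion("1", pop_urban=3000 * pop_scale, pop_rural=0.0, gdp=3e6),
        ])
        pop = np.where(codes == 0, 1500 / 8, 3000 / 8) * pop_scale
        proxies = {
            "population": gm(pop),
            "urban-population": gm(np.where(codes == 0, 1000 / 8, 3000 / 8)),
            "gdp": gm(np.where(codes == 0, 1e6 / 8, 3e6 / 8)),
        }
        return regions, proxies, gm(codes, nodata=-1)

    def test_city_mass_proportional_to_population(self):
        coeffs = default_library()
        regions, proxies, raster = self.two_city_setup()
        maps, records = wastewater_fluxes(regions, coeffs, proxies, raster,
                                          {"0": 0, "1": 1})
        hw = maps["human wastewater discharged"]
        left, right = hw.values[:, :2].sum(), hw.values[:, 2:].sum()
        assert left / right == pytest.approx(1500 / 3000, rel=1e-9)

    def test_doubling_population_doubles_magnitude(self):
        coeffs = default_library()
        out = {}
        for scale in (1.0, 2.0):
            regions, proxies, raster = self.two_city_setup(scale)
            _, records = wastewater_fluxes(regions, coeffs, proxies, raster,
                                           {"0": 0, "1": 1})
            out[scale] = next(r.magnitude for r in records
                              if r.item == "human wastewater discharged")
        assert out[2.0] == pytest.approx(2 * out[1.0], rel=1e-12)

    def test_zero_gdp_gives_zero_industrial_map(self):
        coeffs = default_library()
        regions, proxies, raster = self.two_city_setup()
        regions = AdminSet([AdminRegion(r.region_id, pop_urban=r.pop_urban,
                                        pop_rural=r.pop_rural, gdp=0.0)
                            for r in regions])
        maps, _ = wastewater_fluxes(regions, coeffs, proxies, raster,
                                    {"0": 0, "1": 1})
        assert maps["industrial wastewater"].total() == 0.0

    def test_missing_proxy_rejected(self):
        regions, proxies, raster = self.two_city_setup()
        del proxies["gdp"]
        with pytest.raises(ConfigError, match="gdp"):
            wastewater_fluxes(regions, default_library(), proxies, raster,
                              {"0": 0, "1": 1})


class TestWatersheds:
    def test_single_basin_captures_national_total(self):
        ws = WatershedSet(["B0"], [shapely.box(0, 0, 4000, 4000)])
        raster = ws.rasterize(T, (4, 4))
        maps = {"cropland runoff": gm(np.full((4, 4), 3.0))}
        out = watershed_totals(maps, ws, raster)
        assert out.set_index("basin_id").loc["B0", "kgN_per_yr"] == pytest.approx(48.0)

    def test_symmetric_halves_split_evenly(self):
        ws = WatershedSet(["L", "R"], [shapely.box(0, 0, 2000, 4000),
                                       shapely.box(2000, 0, 4000, 4000)])
        raster = ws.rasterize(T, (4, 4))
        out = watershed_totals({"WTP effluent": gm(np.ones((4, 4)))}, ws, raster)
        vals = out.set_index("basin_id").kgN_per_yr
        assert vals["L"] == vals["R"] == pytest.approx(8.0)

    def test_random_partition_conserves_national_totals(self, bundle):
        raster = bundle.watersheds.rasterize(bundle.landuse.transform,
                                             bundle.landuse.shape)
        rng = np.random.default_rng(13)
        water_map = GridMap(rng.uniform(0, 4, bundle.landuse.shape),
                            bundle.landuse.transform)
        out = watershed_totals({"cropland runoff": water_map},
                               bundle.watersheds, raster)
        total = out.kgN_per_yr.sum()  # basins + unassigned
        assert abs(total - water_map.total()) <= 1e-9 * water_map.total()

    def test_no_basins_rejected(self):
        ws = WatershedSet([], [])
        with pytest.raises(ValidationError):
            watershed_totals({"WTP effluent": gm(np.ones((4, 4)))}, ws,
                             gm(np.zeros((4, 4)), nodata=-1, dtype=np.int32))

    def test_geojson_roundtrip(self, tmp_path, bundle):
        path = tmp_path / "ws.geojson"
        bundle.watersheds.to_geojson(path)
        back = WatershedSet.from_geojson(path)
        assert back.basin_ids == bundle.watersheds.basin_ids
        for a, b in zip(back.polygons, bundle.watersheds.polygons):
            assert a.equals(b)

    def test_rasterization_assigns_every_cell(self, bundle):
        raster = bundle.watersheds.rasterize(bundle.landuse.transform,
                                             bundle.landuse.shape)
        assert (raster.values >= 0).all()
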