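"""Column compositing, the blended index, and deposition allocation."""

import numpy as np
import pytest

from nbudget import (
    ColumnSeries,
    GridMap,
    GridTransform,
    deposition_by_landuse,
    deposition_index,
    monthly_mean,
    resample_nearest,
    table1_fixture,
    zonal_sum,
)
from nbudget.errors import GridIncompatibleError, ValidationError
from nbudget.vocab import KG_PER_TG, LANDUSE_CODES, LANDUSE_ORDER

COARSE = GridTransform(0.0, 4000.0, 2000.0, 2000.0)


def series(fields, valid=None, species="NO2"):
    fields = np.asarray(fields, dtype=float)
    if valid is None:
        valid = np.ones_like(fields, dtype=bool)
    return ColumnSeries(species, fields, COARSE, np.asarray(valid, dtype=bool))


class TestMonthlyMean:
    def test_plain_mean(self):
        s = series([np.full((2, 2), 2.0), np.full((2, 2), 4.0), np.full((2, 2), 6.0)])
        np.testing.assert_allclose(monthly_mean(s).values, 4.0)

    def test_masked_day_excluded(self):
        fields = [np.full((2, 2), 2.0), np.full((2, 2), 99.0), np.full((2, 2), 6.0)]
        valid = [np.ones((2, 2), bool), np.zeros((2, 2), bool), np.ones((2, 2), bool)]
        np.testing.assert_allclose(monthly_mean(series(fields, valid)).values, 4.0)

    def test_all_masked_cell_is_nodata(self):
        valid = np.ones((2, 2, 2), bool)
        valid[:, 0, 0] = False
        out = monthly_mean(series(np.ones((2, 2, 2)), valid))
        assert np.isnan(out.values[0, 0])
        assert out.values[1, 1] == 1.0

    def test_empty_series_rejected(self):
        with pytest.raises(ValidationError):
            monthly_mean(series(np.empty((0, 2, 2))))

    def test_matches_brute_force_loop_on_random_fields(self):
        rng = np.random.default_rng(3)
        fields = rng.uniform(0, 5, (12, 4, 5))
        valid = rng.random((12, 4, 5)) < 0.6
        valid[0] = True
        got = monthly_mean(series(fields, valid)).values
        for r in range(4):
            for c in range(5):
                vals = [fields[t, r, c] for t in range(12) if valid[t, r, c]]
                assert got[r, c] == pytest.approx(sum(vals) / len(vals), rel=1e-14)


class TestIndex:
    def grid(self, values):
        return GridMap(np.asarray(values, dtype=float), COARSE, nodata=np.nan)

    def test_single_species_weight(self):
        no2 = self.grid([[1.0, 2.0], [3.0, 4.0]])
        nh3 = self.grid(np.ones((2, 2)))
        idx = deposition_index(no2, nh3, weights=(1.0, 0.0))
        np.testing.assert_allclose(idx.values, no2.values / 4.0)

    def test_uniform_columns_give_uniform_index(self):
        idx = deposition_index(self.grid(np.full((2, 2), 5.0)),
                               self.grid(np.full((2, 2), 9.0)))
        np.testing.assert_allclose(idx.values, 1.0)

    def test_invariant_under_common_rescaling(self):
        rng = np.random.default_rng(5)
        a, b = rng.uniform(0, 3, (2, 2)), rng.uniform(0, 3, (2, 2))
        one = deposition_index(self.grid(a), self.grid(b))
        other = deposition_index(self.grid(a * 1e6), self.grid(b * 1e6))
        np.testing.assert_allclose(one.values, other.values, rtol=1e-12)

    def test_bimodal_maxima_colocated(self):
        a = np.zeros((4, 4)); a[1, 1] = 10.0
        b = np.zeros((4, 4)); b[2, 3] = 7.0
        idx = deposition_index(self.grid(a), self.grid(b)).values
        top2 = set(map(tuple, np.argwhere(idx >= np.sort(idx, axis=None)[-2])))
        assert top2 == {(1, 1), (2, 3)}

    def test_grid_mismatch_rejected(self):
        other = GridMap(np.ones((3, 3)), COARSE)
        with pytest.raises(GridIncompatibleError):
            deposition_index(self.grid(np.ones((2, 2))), other)

    def test_zero_weights_rejected(self):
        g = self.grid(np.ones((2, 2)))
        with pytest.raises(ValidationError):
            deposition_index(g, g, weights=(0.0, 0.0))


def test_nearest_resampling_is_block_constant():
    coarse = GridMap(np.array([[1.0, 2.0], [3.0, 4.0]]), COARSE)
    fine_t = GridTransform(0.0, 4000.0, 1000.0, 1000.0)
    fine = GridMap(np.zeros((4, 4)), fine_t)
    out = resample_nearest(coarse, fine)
    np.testing.assert_array_equal(out.values[:2, :2], 1.0)
    np.testing.assert_array_equal(out.values[2:, 2:], 4.0)


class TestAllocation:
    def test_uniform_index_single_class(self):
        fine_t = GridTransform(0.0, 4000.0, 1000.0, 1000.0)
        landuse = GridMap(np.full((4, 4), LANDUSE_CODES["forest"], dtype=np.int32),
                          fine_t, nodata=-1)
        index = GridMap(np.ones((2, 2)), COARSE)
        table, dep = deposition_by_landuse(index, landuse, {"forest": 160.0})
        np.testing.assert_allclose(dep.values, 10.0)
        assert table.get("forest", "N deposition") == 160.0

    def test_class_totals_conserved_on_synthetic_country(self, bundle):
        index = deposition_index(
            monthly_mean(bundle.columns["NO2"]), monthly_mean(bundle.columns["NH3"]))
        table, dep = deposition_by_landuse(index, bundle.landuse,
                                           bundle.deposition_totals)
        class_raster = bundle.landuse
        sums = zonal_sum(dep, class_raster)
        for cls in LANDUSE_ORDER:
            want = bundle.deposition_totals[cls]
            got = sums.get(LANDUSE_CODES[cls], 0.0)
            assert abs(got - want) <= 1e-9 * max(want, 1.0)

    def test_fixture_totals_reproduced_exactly(self, bundle):
        """Allocating the published per-class totals returns them unchanged."""
        fixture = table1_fixture()
        totals = {cls: fixture.get(cls, "N deposition") for cls in LANDUSE_ORDER}
        index = deposition_index(
            monthly_mean(bundle.columns["NO2"]), monthly_mean(bundle.columns["NH3"]))
        table, dep = deposition_by_landuse(index, bundle.landuse, totals)
        assert table.get_tg("forest", "N deposition") == 5.5
        sums = zonal_sum(dep, bundle.landuse)
        for cls in LANDUSE_ORDER:
            got = sums.get(LANDUSE_CODES[cls], 0.0)
            assert got / KG_PER_TG == pytest.approx(totals[cls] / KG_PER_TG,
                                                    rel=1e-9)


def test_netcdf_roundtrip(tmp_path, bundle):
    path = tmp_path / "no2.nc"
    orig = bundle.columns["NO2"]
    orig.to_netcdf(path)
    back = ColumnSeries.from_netcdf(path)
    assert back.species == "NO2"
    np.testing.assert_allclose(back.fields, orig.fields, rtol=1e-12)
    np.testing.assert_array_equal(back.valid, orig.valid)
    assert back.transform.almost_equal(orig.transform)
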