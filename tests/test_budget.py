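"""Unit and property tests for the per-region flux equations and assembly."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from nbudget import (
    AdminRegion,
    AdminSet,
    CoefficientLibrary,
    FluxRecord,
    FluxTable,
    assemble_budget,
    bnf_flux,
    human_excretion_flux,
    livestock_manure_flux,
    uniform_rate_flux,
)
from nbudget.errors import (
    AssemblyError,
    CoefficientGapError,
    ValidationError,
    VocabularyError,
)
from nbudget.vocab import BUDGET_ITEMS, LANDUSE_ORDER


def lib(**kw) -> CoefficientLibrary:
    base = dict(
        runoff_coeffs={"cropland": 0.0, "livestock": 0.0, "forest": 0.0},
        uniform_rates={"straw recycle": 0.0, "irrigation": 0.0,
                       "irrigation for artificial grassland": 0.0},
    )
    base.update(kw)
    return CoefficientLibrary(**base)


class TestManure:
    def test_single_category_product(self):
        region = AdminRegion("r", livestock_pop={"cattle": 1000})
        coeffs = lib(excre_an={"cattle": 10.0}, re_an_cropland={"cattle": 0.5})
        assert livestock_manure_flux(region, coeffs).magnitude == 5000.0

    def test_zero_return_rate(self):
        region = AdminRegion("r", livestock_pop={"cattle": 1000, "pigs": 7})
        coeffs = lib(excre_an={"cattle": 10.0, "pigs": 8.0},
                     re_an_cropland={"cattle": 0.0, "pigs": 0.0})
        assert livestock_manure_flux(region, coeffs).magnitude == 0.0

    def test_two_categories_hand_summed(self):
        # pigs: 200*8*0.25 = 400; cattle: 50*40*0.1 = 200
        region = AdminRegion("r", livestock_pop={"pigs": 200, "cattle": 50})
        coeffs = lib(excre_an={"pigs": 8.0, "cattle": 40.0},
                     re_an_cropland={"pigs": 0.25, "cattle": 0.1})
        rec = livestock_manure_flux(region, coeffs)
        assert rec.magnitude == 600.0
        assert (rec.landuse, rec.item) == ("cropland", "livestock manure")

    def test_missing_coefficient_names_category(self):
        region = AdminRegion("r", livestock_pop={"yaks": 10})
        with pytest.raises(CoefficientGapError, match="yaks"):
            livestock_manure_flux(region, lib(excre_an={"pigs": 8.0}))


class TestHumanExcretion:
    def test_hand_computed(self):
        region = AdminRegion("r", pop_urban=10000, pop_rural=5000)
        coeffs = lib(excre_hu=4.0, re_ur=0.1, re_ru=0.4)
        assert human_excretion_flux(region, coeffs).magnitude == 12000.0

    def test_zero_return(self):
        region = AdminRegion("r", pop_urban=10000, pop_rural=5000)
        assert human_excretion_flux(region, lib(excre_hu=4.0)).magnitude == 0.0

    def test_all_urban_degenerate(self):
        region = AdminRegion("r", pop_urban=777, pop_rural=0)
        coeffs = lib(excre_hu=4.5, re_ur=1.0, re_ru=0.3)
        assert human_excretion_flux(region, coeffs).magnitude == 777 * 4.5

    def test_negative_population_rejected(self):
        with pytest.raises(ValidationError):
            AdminRegion("r", pop_urban=-1)


class TestBnf:
    def test_single_crop_product(self):
        region = AdminRegion("r", planting_area={"soy": 100.0})
        assert bnf_flux(region, lib(r_fix_crop={"soy": 15.0})).magnitude == 1500.0

    def test_zero_area(self):
        region = AdminRegion("r", planting_area={"soy": 0.0})
        assert bnf_flux(region, lib(r_fix_crop={"soy": 15.0})).magnitude == 0.0

    def test_two_crops_hand_summed(self):
        region = AdminRegion("r", planting_area={"soy": 40.0, "rice": 60.0})
        coeffs = lib(r_fix_crop={"soy": 80.0, "rice": 20.0})
        assert bnf_flux(region, coeffs).magnitude == 4400.0

    def test_forest_and_grassland_use_landuse_area(self):
        region = AdminRegion("r", landuse_areas={"forest": 10.0, "grassland": 5.0})
        coeffs = lib(r_fix_land={"forest": 12.0, "grassland": 9.0})
        assert bnf_flux(region, coeffs, "forest").magnitude == 120.0
        assert bnf_flux(region, coeffs, "grassland").item == "grassland BNF"

    def test_unknown_landuse_rejected(self):
        with pytest.raises(VocabularyError):
            bnf_flux(AdminRegion("r"), lib(), "wetland")


class TestUniformRate:
    def test_rate_times_area(self):
        region = AdminRegion("r", landuse_areas={"cropland": 50.0})
        coeffs = lib(uniform_rates={"straw recycle": 10.0, "irrigation": 0.0,
                                    "irrigation for artificial grassland": 0.0})
        assert uniform_rate_flux(region, coeffs, "straw recycle").magnitude == 500.0

    def test_zero_rate(self):
        region = AdminRegion("r", landuse_areas={"cropland": 50.0})
        assert uniform_rate_flux(region, lib(), "irrigation").magnitude == 0.0

    def test_shared_national_rate_scales_with_area(self):
        coeffs = lib(uniform_rates={"straw recycle": 0.0, "irrigation": 10.0,
                                    "irrigation for artificial grassland": 0.0})
        a = uniform_rate_flux(
            AdminRegion("a", landuse_areas={"cropland": 30.0}), coeffs, "irrigation")
        b = uniform_rate_flux(
            AdminRegion("b", landuse_areas={"cropland": 70.0}), coeffs, "irrigation")
        assert (a.magnitude, b.magnitude) == (300.0, 700.0)

    def test_unconfigured_item_is_a_gap(self):
        with pytest.raises(CoefficientGapError):
            uniform_rate_flux(AdminRegion("r"), lib(uniform_rates={}), "irrigation")


def test_equations_match_hand_computation_on_random_draws():
    """Eqs for manure, excretion and BNF vs an independent loop oracle, 120 draws."""
    rng = np.random.default_rng(42)
    cats = ["a", "b", "c"]
    for _ in range(120):
        pops = {c: float(rng.uniform(0, 1e5)) for c in cats}
        excre = {c: float(rng.uniform(0, 60)) for c in cats}
        re = {c: float(rng.uniform(0, 1)) for c in cats}
        areas = {c: float(rng.uniform(0, 1e4)) for c in cats}
        rfix = {c: float(rng.uniform(0, 100)) for c in cats}
        pu, pr = float(rng.uniform(0, 1e6)), float(rng.uniform(0, 1e6))
        eh, ru_, rr_ = float(rng.uniform(0, 8)), float(rng.uniform(0, 1)), float(rng.uniform(0, 1))
        region = AdminRegion("r", pop_urban=pu, pop_rural=pr,
                             livestock_pop=pops, planting_area=areas)
        coeffs = lib(excre_an=excre, re_an_cropland=re, excre_hu=eh,
                     re_ur=ru_, re_ru=rr_, r_fix_crop=rfix)

        manure_oracle = 0.0
        for c in cats:
            manure_oracle += pops[c] * excre[c] * re[c]
        bnf_oracle = 0.0
        for c in cats:
            bnf_oracle += areas[c] * rfix[c]
        excr_oracle = (pu * ru_ + pr * rr_) * eh

        assert livestock_manure_flux(region, coeffs).magnitude == pytest.approx(
            manure_oracle, rel=1e-13)
        assert bnf_flux(region, coeffs).magnitude == pytest.approx(
            bnf_oracle, rel=1e-13)
        assert human_excretion_flux(region, coeffs).magnitude == pytest.approx(
            excr_oracle, rel=1e-13)


@settings(deadline=None, max_examples=50, derandomize=True)
@given(k=st.floats(min_value=1e-3, max_value=1e3, allow_nan=False))
def test_homogeneity_scaling(k):
    """Scaling all activity levels by k scales every flux magnitude by k."""
    coeffs = lib(excre_an={"pigs": 8.0}, re_an_cropland={"pigs": 0.3},
                 excre_hu=4.0, re_ur=0.2, re_ru=0.5,
                 r_fix_crop={"soy": 80.0},
                 uniform_rates={"straw recycle": 15.0, "irrigation": 5.0,
                                "irrigation for artificial grassland": 0.5})

    def make(scale):
        return AdminRegion("r", pop_urban=1e4 * scale, pop_rural=2e4 * scale,
                           livestock_pop={"pigs": 1e3 * scale},
                           planting_area={"soy": 50.0 * scale},
                           landuse_areas={"cropland": 80.0 * scale,
                                          "grassland": 30.0 * scale})

    base, scaled = make(1.0), make(k)
    for op in (
        lambda r: livestock_manure_flux(r, coeffs).magnitude,
        lambda r: human_excretion_flux(r, coeffs).magnitude,
        lambda r: bnf_flux(r, coeffs).magnitude,
        lambda r: uniform_rate_flux(r, coeffs, "straw recycle").magnitude,
    ):
        assert op(scaled) == pytest.approx(k * op(base), rel=1e-9)


class TestAssembly:
    def test_composition_is_exactly_the_budget_vocabulary(self, bundle):
        nat = bundle.ground_truth.national().frame
        got = set(zip(nat.landuse, nat.item))
        want = {(lu, item) for lu, items in BUDGET_ITEMS.items() for item in items}
        assert got == want
        counts = {lu: len(items) for lu, items in BUDGET_ITEMS.items()}
        assert counts == {"cropland": 7, "forest": 3, "grassland": 5,
                          "water": 7, "built-up": 1, "unused": 1}

    def test_national_equals_sum_of_regions(self, bundle, coeffs):
        dep = FluxTable([FluxRecord(lu, "N deposition", v)
                         for lu, v in bundle.deposition_totals.items()])
        table = assemble_budget(bundle.admin, coeffs, dep)
        nat, regional = table.national(), table.item_totals()
        for (lu, item), total in regional.items():
            assert nat.get(lu, item) == pytest.approx(total, rel=1e-12)

    def test_fertilizer_only_when_other_coefficients_zero(self):
        regions = AdminSet([AdminRegion(
            "0", pop_urban=10, pop_rural=10, livestock_pop={"pigs": 5},
            planting_area={"soy": 3.0}, cropland_fertilizer=1234.0,
            landuse_areas={lu: 1.0 for lu in LANDUSE_ORDER})])
        coeffs = lib(excre_an={"pigs": 0.0}, re_an_cropland={"pigs": 0.0},
                     re_an_grassland={"pigs": 0.0}, r_fix_crop={"soy": 0.0},
                     r_fix_land={"forest": 0.0, "grassland": 0.0})
        dep = FluxTable([FluxRecord(lu, "N deposition", 0.0)
                         for lu in LANDUSE_ORDER])
        nat = assemble_budget(regions, coeffs, dep).national()
        nonzero = {(lu, item) for lu, items in BUDGET_ITEMS.items()
                   for item in items if nat.get(lu, item) > 0}
        assert nonzero == {("cropland", "N fertilizer")}

    def test_missing_runoff_coefficient_fails_assembly(self, bundle):
        coeffs = lib()
        coeffs.runoff_coeffs = {}
        dep = FluxTable([FluxRecord(lu, "N deposition", 0.0)
                         for lu in LANDUSE_ORDER])
        with pytest.raises(AssemblyError, match="runoff"):
            assemble_budget(bundle.admin, coeffs, dep)


class TestFluxTable:
    def test_duplicate_records_rejected(self):
        with pytest.raises(ValidationError):
            FluxTable([FluxRecord("cropland", "irrigation", 1.0),
                       FluxRecord("cropland", "irrigation", 2.0)])

    def test_unknown_item_rejected(self):
        with pytest.raises(VocabularyError):
            FluxRecord("cropland", "forest BNF", 1.0)

    def test_negative_magnitude_rejected(self):
        with pytest.raises(ValidationError):
            FluxRecord("cropland", "irrigation", -1.0)

    def test_csv_roundtrip_preserves_values(self, tmp_path, bundle):
        path = tmp_path / "t.csv"
        bundle.ground_truth.to_csv(path)
        back = FluxTable.read_csv(path)
        a = bundle.ground_truth.frame.set_index(["region_id", "landuse", "item"])
        b = back.frame.set_index(["region_id", "landuse", "item"])
        pd.testing.assert_series_equal(a.kgN_per_yr, b.kgN_per_yr,
                                       rtol=1e-12, check_exact=False)
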