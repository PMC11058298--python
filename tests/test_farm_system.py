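"""Farm system: loading, milk standardization, excreta and fertilization."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dairylca import (
    FPCMSpec,
    excreta_budget,
    fertilization_plan,
    fpcm_standardize,
    load_farm,
)
from dairylca.farm_system import DAIRY, HEIFER


def minimal_config(**overrides):
    cfg = {
        "region": "test",
        "milk_production": {"dairy_cows": 100, "heifers": 50,
                            "milk_yield_kg_fpcm": 10000},
        "farm_land": {"total_ha": 120.0},
        "crop_plan": {
            "maize_silage": {"area_ha": 40, "yield_t_fm_per_ha": 35,
                             "n_rate_cap_kg_per_ha": 160},
            "grass_silage": {"area_ha": 20, "yield_t_fm_per_ha": 16,
                             "n_rate_cap_kg_per_ha": 80},
            "grass_production": {"area_ha": 20, "yield_t_fm_per_ha": 12,
                                 "n_rate_cap_kg_per_ha": 80},
        },
    }
    cfg.update(overrides)
    return cfg


class TestLoadFarm:
    def test_packaged_farms_match_their_declared_structure(self, bundle):
        os_farm = bundle.farms["oder_spree"]
        assert os_farm.category(DAIRY).count == 666
        assert os_farm.category(HEIFER).count == 361
        assert os_farm.total_land == 806
        assert os_farm.annual_milk == 6_660_000
        dh = bundle.farms["diepholz"]
        assert dh.category(DAIRY).count == 121
        assert dh.category(HEIFER).count == 134
        assert dh.total_land == 111
        assert dh.annual_milk == 1_210_000

    def test_degenerate_empty_farm_is_valid(self):
        farm = load_farm({"region": "empty",
                          "milk_production": {"dairy_cows": 0, "heifers": 0},
                          "farm_land": {"total_ha": 0}})
        assert farm.annual_milk == 0

    @pytest.mark.parametrize("patch", [
        {"milk_production": {"dairy_cows": -1, "heifers": 0,
                             "milk_yield_kg_fpcm": 10000}},
        {"farm_land": {"total_ha": 10.0}},  # crop areas exceed the land
        {"milk_production": {"dairy_cows": 10, "heifers": 5,
                             "milk_yield_kg_fpcm": 10000,
                             "annual_milk_kg_fpcm": 1.0}},
    ])
    def test_invalid_configs_rejected(self, patch):
        with pytest.raises(Exception):
            load_farm(minimal_config(**patch))


class TestFPCM:
    def test_identity_at_reference_composition(self):
        assert fpcm_standardize(10_000, 4.0, 3.3) == pytest.approx(10_000, rel=1e-3)
        assert fpcm_standardize(0, 4.0, 3.3) == 0

    def test_hand_computed_value_at_richer_composition(self):
        # 10000 x (0.1226*4.4 + 0.0776*3.6 + 0.2534) = 10722.0
        value = fpcm_standardize(10_000, 4.4, 3.6)
        assert value == pytest.approx(10_722.0, abs=0.1)
        assert value > 10_000

    @settings(max_examples=50, derandomize=True)
    @given(fat=st.floats(1, 8), protein=st.floats(1, 6), d=st.floats(0.01, 1))
    def test_monotone_in_fat_and_protein(self, fat, protein, d):
        base = fpcm_standardize(1000, fat, protein)
        assert fpcm_standardize(1000, fat + d, protein) > base
        assert fpcm_standardize(1000, fat, protein + d) > base

    def test_rejects_nonfinite_and_out_of_range(self):
        with pytest.raises(ValueError):
            fpcm_standardize(float("nan"), 4.0, 3.3)
        with pytest.raises(ValueError):
            fpcm_standardize(100, 0.0, 3.3)

    def test_bad_coefficients_rejected(self):
        with pytest.raises(Exception):
            FPCMSpec(constant=0.9)


class TestExcretaBudget:
    def test_dairy_share_of_housing_relevant_n(self, bundle):
        """The calibrated per-head N rates give the dairy cows ~90 % of the
        excreted N on the large farm and ~81 % on the small one."""
        shares = {}
        for region in ("oder_spree", "diepholz"):
            b = excreta_budget(bundle.farms[region])
            shares[region] = b.get(DAIRY).excreted_n / b.total_n
        assert shares["oder_spree"] == pytest.approx(0.898, abs=0.002)
        assert shares["diepholz"] == pytest.approx(0.812, abs=0.002)

    def test_nitrogen_conserved_exactly(self, bundle):
        b = excreta_budget(bundle.farms["oder_spree"])
        for cat in b.categories:
            assert cat.excreted_n == pytest.approx(cat.urine_n + cat.feces_n,
                                                   abs=1e-9)

    @settings(max_examples=25, derandomize=True)
    @given(scale=st.integers(1, 50))
    def test_budget_is_homogeneous_in_herd_size(self, scale):
        base = load_farm(minimal_config())
        cfg = minimal_config()
        cfg["milk_production"]["dairy_cows"] = 100 * scale
        cfg["milk_production"]["heifers"] = 50 * scale
        big = load_farm(cfg)
        b0, b1 = excreta_budget(base), excreta_budget(big)
        assert b1.total_n == pytest.approx(scale * b0.total_n, rel=1e-12)
        assert b1.total_urine_volume_m3 == pytest.approx(
            scale * b0.total_urine_volume_m3, rel=1e-12)

    def test_empty_herd_gives_zero_budget(self):
        farm = load_farm({"region": "empty",
                          "milk_production": {"dairy_cows": 0, "heifers": 0},
                          "farm_land": {"total_ha": 0}})
        assert excreta_budget(farm).total_n == 0

    def test_missing_rate_for_present_category_raises(self, bundle):
        with pytest.raises(KeyError):
            excreta_budget(bundle.farms["oder_spree"],
                           rates={DAIRY: {"n_excretion": 141}})


class TestFertilizationPlan:
    def test_declared_mineral_total_is_honored(self, bundle):
        farm = bundle.farms["oder_spree"]
        plan = fertilization_plan(farm, excreta_budget(farm))
        assert plan.total_mineral_n == pytest.approx(53 * 806, rel=1e-6)
        dh = bundle.farms["diepholz"]
        plan_dh = fertilization_plan(dh, excreta_budget(dh))
        assert plan_dh.total_mineral_n == pytest.approx(55 * 111, rel=1e-6)

    def test_zero_slurry_fills_caps_with_mineral(self):
        farm = load_farm(minimal_config())
        plan = fertilization_plan(farm, excreta_budget(farm), organic_supply_n=0.0)
        for app in plan.applications:
            assert app.organic_n == 0
            assert app.mineral_n == pytest.approx(app.cap_n)

    def test_organic_supply_exactly_at_caps_needs_no_mineral(self):
        farm = load_farm(minimal_config())
        caps = sum(c.n_rate_cap * c.area for c in farm.crop_plan.crops)
        plan = fertilization_plan(farm, excreta_budget(farm), organic_supply_n=caps)
        assert plan.total_mineral_n == pytest.approx(0.0, abs=1e-9)
        assert plan.surplus_organic_n == pytest.approx(0.0, abs=1e-9)

    def test_caps_never_exceeded_and_no_negative_mineral(self, bundle):
        for region in ("oder_spree", "diepholz"):
            farm = bundle.farms[region]
            plan = fertilization_plan(farm, excreta_budget(farm))
            for app in plan.applications:
                assert app.organic_n <= app.cap_n + 1e-9
                assert app.mineral_n >= 0

    def test_alfalfa_gets_fixation_credit_and_no_mineral(self, bundle):
        farm = bundle.farms["oder_spree"]
        plan = fertilization_plan(farm, excreta_budget(farm))
        alfalfa = next(a for a in plan.applications if a.crop == "alfalfa_silage")
        assert alfalfa.mineral_n == 0
        assert alfalfa.fixation_n == pytest.approx(40 * 72)

    def test_surplus_beyond_all_caps_is_reported(self):
        farm = load_farm(minimal_config())
        huge = 1e6
        plan = fertilization_plan(farm, excreta_budget(farm), organic_supply_n=huge)
        assert plan.surplus_organic_n > 0
        assert plan.total_organic_n + plan.surplus_organic_n == pytest.approx(huge)
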