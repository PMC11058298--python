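"""Inventory algebra: per-stage emission operations and the stage builder."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dairylca import (
    EmissionFactorSet,
    GasFlowVector,
    STAGES,
    application_emissions,
    build_inventory,
    enteric_ch4,
    housing_emissions,
    liming_co2,
    mineral_fertilizer_emissions,
    storage_emissions,
)
from dairylca.emission_inventory import TechniqueModifiers, whole_farm_flows
from dairylca.farm_system import DAIRY, HEIFER, HerdCategory, excreta_budget

EFS = EmissionFactorSet()


def herd(dairy=100, heifers=0):
    cats = [HerdCategory(name=DAIRY, count=dairy, milk_yield=10_000,
                         n_excretion=141, urine_volume=30,
                         organic_matter_intake=19.13, enteric_ef=135.0)]
    if heifers:
        cats.append(HerdCategory(name=HEIFER, count=heifers, n_excretion=29.5,
                                 urine_volume=12, organic_matter_intake=4.71,
                                 enteric_ef=52.43))
    return cats


class TestEnteric:
    def test_direct_product_of_count_and_ef(self):
        efs = EFS.model_copy(update={"enteric_ef": {DAIRY: 135.0}})
        flows = enteric_ch4(herd(100), efs)
        assert flows.ch4_enteric == pytest.approx(13_500)
        assert flows.nh3 == 0 and flows.n2o_direct == 0

    def test_feed_multiplier_scales_the_category(self):
        efs = EFS.model_copy(update={"enteric_ef": {DAIRY: 135.0}})
        flows = enteric_ch4(herd(100), efs, multipliers={DAIRY: 0.33})
        assert flows.ch4_enteric == pytest.approx(13_500 * 0.33)

    def test_category_without_ef_raises(self):
        efs = EFS.model_copy(update={"enteric_ef": {"llama": 1.0}})
        with pytest.raises(KeyError):
            enteric_ch4(herd(10), efs)


class TestHousing:
    def test_toilet_multiplier_applies_to_dairy_pool_only(self, bundle):
        """A 40 % cut on a 0.898 dairy N share cuts total housing NH3 by
        1 - (0.6 x 0.898 + 0.102) = 35.9 %."""
        budget = excreta_budget(bundle.farms["oder_spree"])
        ref = housing_emissions(budget, EFS)
        mitigated = housing_emissions(budget, EFS, nh3_multipliers={DAIRY: 0.6})
        assert 1 - mitigated.nh3 / ref.nh3 == pytest.approx(0.359, abs=0.001)

    def test_identity_multiplier_changes_nothing(self, bundle):
        budget = excreta_budget(bundle.farms["oder_spree"])
        assert housing_emissions(budget, EFS, {DAIRY: 1.0}).nh3 == \
            housing_emissions(budget, EFS).nh3

    def test_zero_herd_zero_flows(self):
        from dairylca.farm_system import NitrogenBudget
        assert housing_emissions(NitrogenBudget(categories=[]), EFS).nh3 == 0


class TestStorage:
    def test_closed_container_emits_exactly_nothing(self):
        flows = storage_emissions(50_000, 1e6, EFS, cover="closed")
        assert flows == GasFlowVector.zero()

    def test_crusted_tank_flows_scale_linearly_with_the_pool(self):
        base = storage_emissions(10_000, 2e5, EFS)
        scaled = storage_emissions(10_000 * 0.77, 2e5 * 0.77, EFS)
        for field in GasFlowVector.model_fields:
            assert getattr(scaled, field) == pytest.approx(
                0.77 * getattr(base, field), rel=1e-12)

    def test_zero_pool_zero_flows(self):
        assert storage_emissions(0, 0, EFS) == GasFlowVector.zero()

    def test_unknown_cover_rejected(self):
        with pytest.raises(ValueError):
            storage_emissions(1, 1, EFS, cover="lagoon")


class TestApplication:
    @pytest.mark.parametrize("technique,nh3_mult,n2o_mult", [
        ("trailing_hose", 0.67, 1.25),
        ("injection", 0.39, 1.19),
    ])
    def test_technique_multipliers_vs_broadcast(self, technique, nh3_mult, n2o_mult):
        broadcast = application_emissions(10_000, "broadcast", EFS)
        low_em = application_emissions(10_000, technique, EFS)
        assert low_em.nh3 / broadcast.nh3 == pytest.approx(nh3_mult)
        assert low_em.n2o_direct / broadcast.n2o_direct == pytest.approx(n2o_mult)

    def test_acidification_modifiers_compose_multiplicatively(self):
        mods = TechniqueModifiers(nh3=0.543, n2o=0.79, no3=0.82)
        plain = application_emissions(10_000, "trailing_hose", EFS)
        acidified = application_emissions(10_000, "trailing_hose", EFS, mods)
        assert acidified.nh3 / plain.nh3 == pytest.approx(0.543)
        assert acidified.n2o_direct / plain.n2o_direct == pytest.approx(0.79)
        assert acidified.no3_leached / plain.no3_leached == pytest.approx(0.82)

    def test_modifier_order_independent_of_technique(self):
        mods = TechniqueModifiers(nh3=0.543, n2o=0.79, no3=0.82)
        via_broadcast = application_emissions(5_000, "broadcast", EFS, mods)
        via_hose = application_emissions(5_000, "trailing_hose", EFS, mods)
        assert via_hose.nh3 == pytest.approx(via_broadcast.nh3 * 0.67)

    def test_unknown_technique_rejected(self):
        with pytest.raises(KeyError):
            application_emissions(1.0, "catapult", EFS)


class TestMineralAndLime:
    def test_zero_and_linearity(self):
        assert mineral_fertilizer_emissions(0, EFS) == GasFlowVector.zero()
        one = mineral_fertilizer_emissions(1_000, EFS)
        two = mineral_fertilizer_emissions(2_000, EFS)
        assert two.nh3 == pytest.approx(2 * one.nh3)

    def test_mineral_efs_strictly_below_organic_broadcast(self):
        assert EFS.mineral_nh3n_frac < EFS.field_broadcast_nh3n_frac
        assert EFS.mineral_n2on_frac < EFS.field_org_n2on_frac
        with pytest.raises(Exception):
            EmissionFactorSet(mineral_nh3n_frac=0.5)

    def test_lime_co2_is_mass_times_ef(self):
        assert liming_co2(0, EFS).co2_lime == 0
        assert liming_co2(1_000, EFS).co2_lime == pytest.approx(1_000 * EFS.lime_co2_ef)

    def test_technique_table_requires_broadcast_identity(self):
        with pytest.raises(Exception):
            EmissionFactorSet(technique_multipliers={
                "trailing_hose": {"nh3": 0.67, "n2o": 1.25}})


class TestBuildInventory:
    def test_reference_structure(self, bundle, models):
        model = models["oder_spree"]
        invs = build_inventory(model.farm, bundle.scenarios()["Ref"], model.efs)
        assert [i.stage for i in invs] == list(STAGES)
        enteric = next(i for i in invs if i.stage == "enteric")
        assert enteric.flows.ch4_enteric > 0
        for field in GasFlowVector.model_fields:
            if field != "ch4_enteric":
                assert getattr(enteric.flows, field) == 0

    def test_stage_flows_sum_to_whole_farm_vector(self, bundle, models):
        model = models["oder_spree"]
        for name, spec in bundle.scenarios().items():
            invs = build_inventory(model.farm, spec, model.efs)
            total = whole_farm_flows(invs)
            manual = sum((getattr(i.flows, f) for i in invs
                          for f in GasFlowVector.model_fields), 0.0)
            summed = sum(getattr(total, f) for f in GasFlowVector.model_fields)
            assert summed == pytest.approx(manual, rel=1e-12)

    def test_urine_separation_scales_storage_and_keeps_urine_store_silent(
            self, bundle, models):
        model = models["oder_spree"]
        scen = bundle.scenarios()
        ref = build_inventory(model.farm, scen["Ref"], model.efs)
        ct2 = build_inventory(model.farm, scen["CT2"], model.efs)
        ref_store = next(i for i in ref if i.stage == "outside_storage")
        ct2_store = next(i for i in ct2 if i.stage == "outside_storage")
        frac = ct2_store.background_units["slurry_fraction"]
        assert 0 < frac < 1
        for field in GasFlowVector.model_fields:
            assert getattr(ct2_store.flows, field) == pytest.approx(
                frac * getattr(ref_store.flows, field), rel=1e-12)

    def test_ct1_changes_only_the_housing_stage(self, bundle, models):
        model = models["oder_spree"]
        scen = bundle.scenarios()
        ref = {i.stage: i for i in build_inventory(model.farm, scen["Ref"], model.efs)}
        ct1 = {i.stage: i for i in build_inventory(model.farm, scen["CT1"], model.efs)}
        assert ct1["in_house"].flows.nh3 < ref["in_house"].flows.nh3
        for stage in ("enteric", "outside_storage", "forage_production"):
            assert ct1[stage].flows == ref[stage].flows

    def test_reactive_n_never_exceeds_chain_input(self, bundle, models):
        for region, model in models.items():
            budget = excreta_budget(model.farm)
            mineral = model.farm.mineral_fertilizer_total_kg or 0.0
            for spec in bundle.scenarios().values():
                invs = build_inventory(model.farm, spec, model.efs)
                total = whole_farm_flows(invs)
                emitted_n = total.nh3_n + total.n2o_n + total.no3_n
                assert emitted_n <= budget.total_n + mineral


@settings(max_examples=30, derandomize=True)
@given(n=st.floats(0, 1e6), scale=st.floats(0.01, 10))
def test_application_is_degree_one_homogeneous(n, scale):
    base = application_emissions(n, "trailing_hose", EFS)
    scaled = application_emissions(n * scale, "trailing_hose", EFS)
    assert scaled.nh3 == pytest.approx(scale * base.nh3, rel=1e-9, abs=1e-12)
    assert scaled.n2o_direct == pytest.approx(scale * base.n2o_direct,
                                              rel=1e-9, abs=1e-12)
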