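"""Comparison surfaces: scenario runs, stage tables, gas contributions,
percent-change summaries and trade-off classification.

Three trade-off types are distinguished when comparing a scenario against the
reference:

1. between impact categories — one category total falls while another rises
   (e.g. GWP down, abiotic depletion up);
2. location shift — within one category, the off-farm production-and-transport
   stage moves opposite to the on-farm stages;
3. pollution swapping — within one management stage, one gas falls while
   another rises (e.g. injection: NH3 down, N2O up).

Changes smaller than a configurable fraction of the reference (default 0.5 %)
are treated as no change so that rounding noise never raises a flag.
"""

from __future__ import annotations

import math
from typing import Mapping, Optional, Sequence

import pandas as pd
from pydantic import BaseModel, Field

from .abatement import ScenarioSpec, scenario_effects
from .emission_inventory import (
    EmissionFactorSet,
    StageInventory,
    build_inventory,
)
from .farm_system import DAIRY, FarmSystem
from .impact_assessment import (
    CATEGORIES,
    BackgroundIntensities,
    CharacterizationFactors,
    ImpactTable,
    characterize,
)

SCENARIO_ORDER = ("Ref", "SW_low", "SW_high", "CT1", "CT2", "AS", "CM")

GAS_COLUMNS = (
    "ch4_enteric", "ch4_storage",
    "n2o_direct_storage", "n2o_direct_forage",
    "n2o_indirect_storage", "n2o_indirect_forage",
    "nh3_in_house", "nh3_storage", "nh3_forage",
)


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round half away from zero (report convention)."""
    factor = 10.0 ** ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


def percent_change(ref_value: float, scen_value: float) -> float:
    """Signed percent change of a scenario value against the reference."""
    if ref_value == 0:
        raise ZeroDivisionError("percent change undefined for a zero reference")
    return 100.0 * (scen_value - ref_value) / ref_value


# ---------------------------------------------------------------------------
# scenario pipeline


class CalibratedFarm(BaseModel):
    """A farm together with its calibrated factor sets, ready to run scenarios."""

    farm: FarmSystem
    efs: EmissionFactorSet
    background: BackgroundIntensities
    cfs: CharacterizationFactors = Field(default_factory=CharacterizationFactors)


class ScenarioResult(BaseModel):
    name: str
    inventories: list[StageInventory]
    impacts: ImpactTable
    gas: dict[str, float]
    demands: dict[str, float]


def run_scenario(
    model: CalibratedFarm,
    scenario: ScenarioSpec,
    propagate_milk_penalty: bool = False,
) -> ScenarioResult:
    """Build the inventory of one scenario and characterize it.

    ``propagate_milk_penalty`` switches the functional-unit denominator to the
    reduced milk output under high seaweed inclusion; by default the reference
    denominator is kept, matching the reference tables' convention of leaving
    the non-enteric stage intensities unchanged.
    """
    farm = model.farm
    eff = scenario_effects(farm, scenario, efs=model.efs)
    inventories = build_inventory(farm, scenario, model.efs)
    fpcm = farm.annual_milk
    if propagate_milk_penalty and eff.milk_yield_override is not None:
        dairy = farm.category(DAIRY)
        fpcm = (dairy.count * eff.milk_yield_override) if dairy else fpcm
    impacts = characterize(inventories, model.cfs, model.background, fpcm)
    return ScenarioResult(
        name=scenario.name,
        inventories=inventories,
        impacts=impacts,
        gas=gas_contribution(inventories, model.cfs, fpcm),
        demands={
            "seaweed_kg": eff.seaweed_demand_kg,
            "n_plants_required": float(eff.n_plants_required),
            "n_toilets": float(eff.n_toilets),
            "acid_l": eff.acid_demand_l,
            "lime_kg": eff.lime_demand_kg,
            "displaced_mineral_n_kg": eff.displaced_mineral_n,
            "urine_surplus_n_kg": eff.urine_surplus_n,
        },
    )


def run_all_scenarios(
    model: CalibratedFarm,
    scenarios: Mapping[str, ScenarioSpec],
    propagate_milk_penalty: bool = False,
) -> dict[str, ScenarioResult]:
    return {name: run_scenario(model, spec, propagate_milk_penalty)
            for name, spec in scenarios.items()}


# ---------------------------------------------------------------------------
# tables


def stage_table(
    results: Mapping[str, "ScenarioResult | ImpactTable"],
    order: Sequence[str] = SCENARIO_ORDER,
) -> pd.DataFrame:
    """Stage x category impact table over scenarios, totals as exact row sums.

    Rows are (category, scenario) in the canonical scenario order; values are
    per kg FPCM.  An empty result set yields an empty table with the header
    only.
    """
    stages = None
    rows = []
    index = []
    names = [n for n in order if n in results] + \
        [n for n in results if n not in order]
    for cat in CATEGORIES:
        for name in names:
            item = results[name]
            table = item.impacts if isinstance(item, ScenarioResult) else item
            if stages is None:
                stages = list(table.values.keys())
            row = [table.cell(s, cat) for s in stages]
            rows.append(row + [sum(row)])
            index.append((cat, name))
    columns = (stages or []) + ["total"]
    return pd.DataFrame(
        rows,
        index=pd.MultiIndex.from_tuples(index, names=["category", "scenario"])
        if index else None,
        columns=columns,
    )


def gas_contribution(
    inventories: list[StageInventory],
    cfs: CharacterizationFactors,
    annual_fpcm: float,
) -> dict[str, float]:
    """Gas-resolved contributions: CH4/N2O to GWP (kg CO2e) and NH3 to EP
    (g PO4e) per kg FPCM, split by management stage."""
    if annual_fpcm <= 0:
        raise ValueError("annual FPCM must be > 0")
    inv = {i.stage: i.flows for i in inventories}
    gwp = cfs.factors
    ch4 = gwp["ch4_enteric"]["GWP"]
    n2o = gwp["n2o_direct"]["GWP"]
    nh3_ep = gwp["nh3"]["EP"] * 1000.0  # report in grams
    return {
        "ch4_enteric": inv["enteric"].ch4_enteric * ch4 / annual_fpcm,
        "ch4_storage": inv["outside_storage"].ch4_manure * ch4 / annual_fpcm,
        "n2o_direct_storage": inv["outside_storage"].n2o_direct * n2o / annual_fpcm,
        "n2o_direct_forage": inv["forage_production"].n2o_direct * n2o / annual_fpcm,
        "n2o_indirect_storage": inv["outside_storage"].n2o_indirect * n2o / annual_fpcm,
        "n2o_indirect_forage": inv["forage_production"].n2o_indirect * n2o / annual_fpcm,
        "nh3_in_house": inv["in_house"].nh3 * nh3_ep / annual_fpcm,
        "nh3_storage": inv["outside_storage"].nh3 * nh3_ep / annual_fpcm,
        "nh3_forage": inv["forage_production"].nh3 * nh3_ep / annual_fpcm,
    }


def chain_nh3_ep(gas_row: Mapping[str, float]) -> float:
    """Whole manure-chain NH3 contribution to EP (housing + storage + field)."""
    return gas_row["nh3_in_house"] + gas_row["nh3_storage"] + gas_row["nh3_forage"]


# ---------------------------------------------------------------------------
# trade-off classification


class TradeoffFlag(BaseModel):
    type: str  # between_categories | location_shift | pollution_swapping
    evidence: dict[str, float]


class TradeoffReport(BaseModel):
    scenario: str
    flags: list[TradeoffFlag] = Field(default_factory=list)

    def has(self, flag_type: str) -> bool:
        return any(f.type == flag_type for f in self.flags)


def _sign(delta: float, ref: float, threshold_pct: float) -> int:
    """-1 / 0 / +1 with a dead band of ``threshold_pct`` percent of the reference."""
    band = abs(ref) * threshold_pct / 100.0
    if delta > band:
        return 1
    if delta < -band:
        return -1
    return 0


def tradeoff_flags(
    ref_table: ImpactTable,
    scen_table: ImpactTable,
    ref_gas: Optional[Mapping[str, float]] = None,
    scen_gas: Optional[Mapping[str, float]] = None,
    scenario: str = "",
    threshold_pct: float = 0.5,
) -> TradeoffReport:
    """Classify the trade-offs of a scenario relative to the reference."""
    report = TradeoffReport(scenario=scenario)

    # type 1: between impact categories
    cat_signs = {}
    for cat in CATEGORIES:
        ref_total = ref_table.total(cat)
        cat_signs[cat] = _sign(scen_table.total(cat) - ref_total, ref_total,
                               threshold_pct)
    if 1 in cat_signs.values() and -1 in cat_signs.values():
        report.flags.append(TradeoffFlag(
            type="between_categories",
            evidence={c: scen_table.total(c) - ref_table.total(c)
                      for c in CATEGORIES}))

    # type 2: off-farm vs on-farm shift within a category
    for cat in CATEGORIES:
        off_ref = ref_table.cell("production_and_transport", cat)
        off_delta = scen_table.cell("production_and_transport", cat) - off_ref
        on_ref = ref_table.total(cat) - off_ref
        on_delta = (scen_table.total(cat) - scen_table.cell(
            "production_and_transport", cat)) - on_ref
        s_off = _sign(off_delta, ref_table.total(cat), threshold_pct)
        s_on = _sign(on_delta, ref_table.total(cat), threshold_pct)
        if s_off * s_on == -1:
            report.flags.append(TradeoffFlag(
                type="location_shift",
                evidence={f"{cat}_off_farm": off_delta, f"{cat}_on_farm": on_delta}))

    # type 3: pollution swapping between gases within a stage
    if ref_gas is not None and scen_gas is not None:
        stage_gases = {
            "outside_storage": ("nh3_storage", "n2o_direct_storage",
                                "n2o_indirect_storage", "ch4_storage"),
            "forage_production": ("nh3_forage", "n2o_direct_forage",
                                  "n2o_indirect_forage"),
        }
        for stage, keys in stage_gases.items():
            signs = {k: _sign(scen_gas[k] - ref_gas[k], ref_gas[k], threshold_pct)
                     for k in keys if k in ref_gas and k in scen_gas}
            nh3_key = next(k for k in keys if k.startswith("nh3"))
            other = [k for k in keys if not k.startswith("nh3")]
            if signs.get(nh3_key, 0) != 0 and any(
                    signs.get(k, 0) == -signs[nh3_key] for k in other):
                report.flags.append(TradeoffFlag(
                    type="pollution_swapping",
                    evidence={k: scen_gas[k] - ref_gas[k] for k in keys
                              if k in scen_gas}))
    return report


# ---------------------------------------------------------------------------
# exports


def export_results(
    results: Mapping[str, ScenarioResult],
    directory,
) -> dict[str, str]:
    """Write the stage table, gas table and demands of a run as CSV files."""
    from pathlib import Path

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {}
    st = stage_table(results)
    paths["stage_table"] = str(directory / "stage_impacts.csv")
    st.to_csv(paths["stage_table"])
    gas = pd.DataFrame({n: r.gas for n, r in results.items()}).T
    paths["gas_table"] = str(directory / "gas_contributions.csv")
    gas.to_csv(paths["gas_table"])
    demands = pd.DataFrame({n: r.demands for n, r in results.items()}).T
    paths["demands"] = str(directory / "demands.csv")
    demands.to_csv(paths["demands"])
    return paths
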