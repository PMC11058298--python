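"""Impact characterization: stage inventories -> per-kg-FPCM impact tables.

Four CML-style baseline categories are assessed: global warming (GWP-100,
kg CO2e; CH4 28, N2O 265), eutrophication (EP, g PO4(3-)e; NH3 0.35),
acidification (AP, g SO2e) and abiotic fossil depletion (AD, MJ).  Each
stage x category cell is

    (sum over flows of flow x factor + sum over activities of amount x
     background intensity) / annual FPCM

where the background intensities stand in for the upstream burdens of
purchased inputs (feed, fertilizer, seaweed, acid, lime, hardware, energy,
transport).  Upstream stage intensities are not process data here: they are
calibrated once against the reference stage-impact table of each farm and
held fixed across scenarios, changing only through explicit activity
bookkeeping (e.g. displaced mineral fertilizer, a smaller stored slurry
volume).

The milk/meat co-product split follows the physical allocation of the
International Dairy Federation, AF_milk = 1 - 6.04 x (meat/milk mass ratio);
scenario tables are reported unallocated, the allocation being applied only
when checking the reference farms against literature values.
"""

from __future__ import annotations

from typing import Mapping, Optional

import pandas as pd
from pydantic import BaseModel, Field, model_validator

from .emission_inventory import GasFlowVector, StageInventory, STAGES
from .farm_system import FarmSystem

CATEGORIES = ("GWP", "EP", "AP", "AD")

#: per-kg-FPCM report units per category (mass-type categories are reported in
#: grams, hence the factor applied to the absolute kg amounts)
_UNIT_SCALE = {"GWP": 1.0, "EP": 1000.0, "AP": 1000.0, "AD": 1.0}

_PINNED = {
    ("ch4_enteric", "GWP"): 28.0,
    ("ch4_manure", "GWP"): 28.0,
    ("n2o_direct", "GWP"): 265.0,
    ("n2o_indirect", "GWP"): 265.0,
    ("nh3", "EP"): 0.35,
}


class CharacterizationFactors(BaseModel):
    """Flow -> category conversion factors (kg category-equivalent per kg flow)."""

    factors: dict[str, dict[str, float]] = Field(default_factory=lambda: {
        "ch4_enteric": {"GWP": 28.0},
        "ch4_manure": {"GWP": 28.0},
        "n2o_direct": {"GWP": 265.0},
        "n2o_indirect": {"GWP": 265.0},
        "nh3": {"EP": 0.35, "AP": 1.60},
        "no3_leached": {"EP": 0.10},
        "co2_lime": {"GWP": 1.0},
        "fossil_energy": {"AD": 1.0},
    })

    @model_validator(mode="after")
    def _pinned_and_nonnegative(self) -> "CharacterizationFactors":
        for (flow, cat), value in _PINNED.items():
            if self.factors.get(flow, {}).get(cat) != value:
                raise ValueError(f"pinned factor {flow}->{cat} must be {value}")
        for flow, m in self.factors.items():
            if any(v < 0 for v in m.values()):
                raise ValueError(f"negative factor for {flow!r}")
        return self

    def characterize_flows(self, flows: GasFlowVector) -> dict[str, float]:
        """Absolute category amounts (kg or MJ per year) of a flow vector."""
        out = {c: 0.0 for c in CATEGORIES}
        for flow in GasFlowVector.model_fields:
            amount = getattr(flows, flow)
            if amount == 0.0:
                continue
            if flow not in self.factors:
                raise KeyError(f"no characterization factors for flow {flow!r}")
            for cat, factor in self.factors[flow].items():
                out[cat] += amount * factor
        return out


def _zero_by_cat() -> dict[str, float]:
    return {c: 0.0 for c in CATEGORIES}


class BackgroundIntensities(BaseModel):
    """Calibrated upstream burdens: per-stage bases and per-activity intensities.

    ``stage_base`` holds the absolute reference-farm burden of each stage and
    category (kg CO2e, kg PO4e, kg SO2e, MJ per year); the remaining fields
    are per-unit intensities of the explicit activities.  Displaced mineral
    fertilizer enters only through a smaller ``mineral_n_kg`` activity amount
    — never as a free-standing negative intensity.
    """

    stage_base: dict[str, dict[str, float]] = Field(default_factory=dict)
    mineral_n: dict[str, float] = Field(default_factory=lambda: {
        "GWP": 3.0, "EP": 0.001, "AP": 0.0, "AD": 35.0})
    seaweed_kg: dict[str, float] = Field(default_factory=lambda: {
        "GWP": 9.4, "EP": 0.0233, "AP": 0.0617, "AD": 109.4})
    toilet_unit: dict[str, float] = Field(default_factory=lambda: {
        "GWP": 740.0, "EP": 1.727, "AP": 2.713, "AD": 7646.0})
    acid_kg: dict[str, float] = Field(default_factory=lambda: {
        "GWP": 0.09, "EP": 0.0002, "AP": 0.0065, "AD": 8.0})
    lime_production_kg: dict[str, float] = Field(default_factory=lambda: {
        "GWP": 0.05, "EP": 0.0001, "AP": 0.0012, "AD": 1.8})
    transport_tkm: dict[str, float] = Field(default_factory=lambda: {
        "GWP": 0.10, "EP": 0.00006, "AP": 0.0004, "AD": 1.6})
    residuals: dict[str, float] = Field(default_factory=dict)

    @model_validator(mode="after")
    def _nonnegative(self) -> "BackgroundIntensities":
        for stage, cats in self.stage_base.items():
            if any(v < 0 for v in cats.values()):
                raise ValueError(f"negative background base in stage {stage!r}")
        for name in ("mineral_n", "seaweed_kg", "toilet_unit", "acid_kg",
                     "lime_production_kg", "transport_tkm"):
            if any(v < 0 for v in getattr(self, name).values()):
                raise ValueError(f"negative intensity in {name!r}")
        return self

    def stage_background(self, inv: StageInventory) -> dict[str, float]:
        """Absolute background amounts of one stage given its activity units."""
        units = inv.background_units
        base = self.stage_base.get(inv.stage, _zero_by_cat())
        scale = units.get("slurry_fraction", 1.0) if inv.stage == "outside_storage" else 1.0
        out = {c: base.get(c, 0.0) * scale for c in CATEGORIES}
        for key, intensity in (
            ("mineral_n_kg", self.mineral_n),
            ("seaweed_kg", self.seaweed_kg),
            ("toilets", self.toilet_unit),
            ("acid_kg", self.acid_kg),
            ("lime_production_kg", self.lime_production_kg),
            ("transport_tkm", self.transport_tkm),
        ):
            amount = units.get(key, 0.0)
            if amount:
                for c in CATEGORIES:
                    out[c] += amount * intensity.get(c, 0.0)
        return out


class ImpactTable(BaseModel):
    """Stage x category impacts per kg FPCM (GWP kg CO2e, EP g PO4e, AP g SO2e, AD MJ)."""

    model_config = {"arbitrary_types_allowed": True}

    values: dict[str, dict[str, float]]  # stage -> category -> value
    annual_fpcm: float

    def cell(self, stage: str, category: str) -> float:
        return self.values[stage][category]

    def total(self, category: str) -> float:
        return sum(self.values[s][category] for s in self.values)

    @property
    def totals(self) -> dict[str, float]:
        return {c: self.total(c) for c in CATEGORIES}

    def to_frame(self, include_total: bool = True) -> pd.DataFrame:
        df = pd.DataFrame(self.values).T.reindex(index=list(STAGES),
                                                 columns=list(CATEGORIES))
        if include_total:
            df.loc["total"] = df.sum(axis=0)
        return df


def characterize(
    inventories: list[StageInventory],
    cfs: CharacterizationFactors,
    background: BackgroundIntensities,
    annual_fpcm: float,
) -> ImpactTable:
    """Characterize stage inventories into a per-kg-FPCM impact table.

    Linear in both the physical flows and the background activity amounts;
    raises on a flow without characterization factors.
    """
    if annual_fpcm <= 0:
        raise ValueError("annual FPCM must be > 0")
    values: dict[str, dict[str, float]] = {}
    for inv in inventories:
        fg = cfs.characterize_flows(inv.flows)
        bg = background.stage_background(inv)
        values[inv.stage] = {
            c: (fg[c] + bg[c]) * _UNIT_SCALE[c] / annual_fpcm for c in CATEGORIES}
    return ImpactTable(values=values, annual_fpcm=annual_fpcm)


def calibrate_background(
    reference_table: Mapping[str, Mapping[str, float]],
    farm: FarmSystem,
    inventories: list[StageInventory],
    cfs: Optional[CharacterizationFactors] = None,
    template: Optional[BackgroundIntensities] = None,
    tolerance: float = 2e-3,
) -> BackgroundIntensities:
    """Solve the per-stage background bases from a reference impact table.

    For every stage and category the base is the residual between the
    reference cell and the characterized foreground flows plus explicit
    activity terms of the reference inventories.  Residuals more negative
    than ``tolerance`` (per kg FPCM, native units) indicate an infeasible
    calibration and raise, naming the offending cell; smaller negatives are
    clipped to zero and reported in ``residuals``.
    """
    cfs = cfs or CharacterizationFactors()
    template = template or BackgroundIntensities()
    fpcm = farm.annual_milk
    if fpcm <= 0:
        raise ValueError("calibration requires a milk-producing farm")

    stage_base: dict[str, dict[str, float]] = {}
    residuals: dict[str, float] = {}
    probe = template.model_copy(update={"stage_base": {}})
    for inv in inventories:
        fg = cfs.characterize_flows(inv.flows)
        activity = probe.stage_background(inv)
        scale = inv.background_units.get("slurry_fraction", 1.0) \
            if inv.stage == "outside_storage" else 1.0
        if scale <= 0:
            raise ValueError("reference inventories must have a positive slurry fraction")
        stage_base[inv.stage] = {}
        for cat in CATEGORIES:
            ref_abs = reference_table[inv.stage][cat] * fpcm / _UNIT_SCALE[cat]
            base = (ref_abs - fg[cat] - activity[cat]) / scale
            per_kg = base * _UNIT_SCALE[cat] / fpcm
            if per_kg < -tolerance:
                raise ValueError(
                    f"calibration infeasible: stage {inv.stage!r}, category "
                    f"{cat!r} needs a negative background intensity ({per_kg:.4f})")
            if base < 0:
                residuals[f"{inv.stage}/{cat}"] = per_kg
                base = 0.0
            stage_base[inv.stage][cat] = base
    return template.model_copy(update={"stage_base": stage_base,
                                       "residuals": residuals})


class AllocationSpec(BaseModel):
    """IDF physical milk/meat allocation: AF_milk = 1 - 6.04 x meat/milk ratio."""

    formula_constant: float = 6.04
    meat_milk_ratio: float = Field(default=0.02, ge=0)

    @property
    def af_milk(self) -> float:
        return 1.0 - self.formula_constant * self.meat_milk_ratio

    @property
    def af_meat(self) -> float:
        return 1.0 - self.af_milk

    @model_validator(mode="after")
    def _in_range(self) -> "AllocationSpec":
        if not (0 < self.af_milk < 1):
            raise ValueError("AF_milk must be in (0, 1)")
        return self


def allocate_idf(value: float, spec: Optional[AllocationSpec] = None) -> float:
    """Share of an impact allocated to milk (the rest goes to the meat co-product)."""
    spec = spec or AllocationSpec()
    if not pd.notna(value):
        raise ValueError("value must be finite")
    return value * spec.af_milk
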