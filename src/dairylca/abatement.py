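"""Abatement measures and their composition into scenarios.

Three measures are encoded as transformations of the farm/inventory
configuration, each occupying one management slot:

* feed — red-seaweed (bromoform-bearing macroalga) inclusion in the ration,
  cutting enteric methane at a low (0.5 % of organic-matter intake for dairy
  cows, 0.25 % for heifers) or high (1 % / 0.5 %) level, the high level also
  depressing milk yield;
* housing — an in-house cow toilet capturing part of the dairy cows' urine at
  the source, cutting housing ammonia on the served animals by 40 %; with
  adapted management (CT2) the urine is stored closed (emission-free) and
  injected on the field, displacing mineral fertilizer;
* field application — on-field sulfuric-acid treatment of the spread slurry
  (trailing hose), with counter-liming, yield gains, and NH3/N2O/NO3
  multipliers on the application emissions.

Composition is by slot (at most one measure per slot), so a combined scenario
is order-invariant by construction; input demands (seaweed, acid, lime,
toilet units) are derived bookkeeping, not extra degrees of freedom.
"""

from __future__ import annotations

import math
from typing import Optional, Sequence

from pydantic import BaseModel, Field, model_validator

from .farm_system import DAIRY, HEIFER, FarmSystem, NitrogenBudget, excreta_budget
from .emission_inventory import EmissionFactorSet, TechniqueModifiers

SCENARIO_ORDER = ("Ref", "SW_low", "SW_high", "CT1", "CT2", "AS", "CM")


class SeaweedParams(BaseModel):
    inclusion: dict[str, dict[str, float]] = Field(default_factory=lambda: {
        "low": {DAIRY: 0.005, HEIFER: 0.0025},
        "high": {DAIRY: 0.010, HEIFER: 0.0050},
    })
    ch4_multipliers: dict[str, dict[str, float]] = Field(default_factory=lambda: {
        "low": {DAIRY: 0.74, HEIFER: 0.55},    # -26 % / -45 %
        "high": {DAIRY: 0.33, HEIFER: 0.32},   # -67 % / -68 %
    })
    milk_yield_high: float = 8800.0            # kg FPCM/head/yr under high inclusion
    plant_capacity_kg_per_day: float = 12.0    # dried output of one production system
    transport_distance_km: float = 1000.0      # lorry, Sweden -> Germany
    production_intensity: dict[str, float] = Field(default_factory=lambda: {
        # per kg dried seaweed, land-based production (energy-dominated)
        "GWP": 9.4, "EP": 0.0233, "AP": 0.0617, "AD": 109.4,
    })

    @model_validator(mode="after")
    def _check(self) -> "SeaweedParams":
        for level in self.ch4_multipliers.values():
            if any(not (0 < m < 1) for m in level.values()):
                raise ValueError("CH4 multipliers must be in (0, 1)")
        for level in self.inclusion.values():
            if any(v < 0 for v in level.values()):
                raise ValueError("inclusion levels must be >= 0")
        return self


class CowToiletParams(BaseModel):
    cows_per_toilet: int = 25
    collected_urine_l_per_cow_day: float = 15.0  # half of a dairy cow's excretion
    nh3_reduction: float = Field(default=0.40, ge=0, le=1)
    urine_technique: str = "injection"
    slurry_technique: str = "trailing_hose"
    hardware_intensity_per_toilet: dict[str, float] = Field(default_factory=lambda: {
        # steel, rubber, pump and energy per toilet unit and year
        "GWP": 740.0, "EP": 1.727, "AP": 2.713, "AD": 7646.0,
    })


class AcidificationParams(BaseModel):
    acid_dose_l_per_m3: float = Field(default=1.5, gt=0)
    lime_kg_per_l_acid: float = Field(default=75.0, gt=0)
    acid_density_kg_per_l: float = 1.84
    yield_multipliers: dict[str, float] = Field(default_factory=lambda: {
        "maize_silage": 1.05,
        "grass_silage": 1.30,
        "grass_production": 1.30,
        "alfalfa_silage": 1.30,
    })
    nh3_multiplier: float = Field(default=0.543, gt=0, lt=2)  # -45.7 %
    n2o_multiplier: float = Field(default=0.79, gt=0, lt=2)   # -21 %
    no3_multiplier: float = Field(default=0.82, gt=0, lt=2)   # -18 %
    tank_capacity_l: float = 1000.0
    transport_distance_km: float = 300.0
    acid_intensity_per_kg: dict[str, float] = Field(default_factory=lambda: {
        "GWP": 0.09, "EP": 0.0002, "AP": 0.0065, "AD": 8.0})
    lime_intensity_per_kg: dict[str, float] = Field(default_factory=lambda: {
        "GWP": 0.05, "EP": 0.0001, "AP": 0.0012, "AD": 1.8})

    @property
    def lime_kg_per_ha(self) -> float:
        """Counter-liming per hectare of slurry-fertilized forage (75 x 1.5 = 112.5)."""
        return self.lime_kg_per_l_acid * self.acid_dose_l_per_m3


class SeaweedMeasure(BaseModel):
    slot: str = "feed"
    level: str
    params: SeaweedParams = Field(default_factory=SeaweedParams)

    @model_validator(mode="after")
    def _level(self) -> "SeaweedMeasure":
        if self.level not in self.params.inclusion:
            raise ValueError(f"unknown inclusion level {self.level!r}")
        return self


class CowToiletMeasure(BaseModel):
    slot: str = "housing"
    adapted_management: bool  # False: CT1 (urine remixed); True: CT2
    params: CowToiletParams = Field(default_factory=CowToiletParams)


class AcidificationMeasure(BaseModel):
    slot: str = "application"
    params: AcidificationParams = Field(default_factory=AcidificationParams)


Measure = SeaweedMeasure | CowToiletMeasure | AcidificationMeasure


class ScenarioSpec(BaseModel):
    """A named composition of measures, at most one per management slot."""

    name: str
    feed: Optional[SeaweedMeasure] = None
    housing: Optional[CowToiletMeasure] = None
    application: Optional[AcidificationMeasure] = None

    @property
    def measures(self) -> list[Measure]:
        return [m for m in (self.feed, self.housing, self.application) if m is not None]

    def __eq__(self, other: object) -> bool:  # name-independent equality
        if not isinstance(other, ScenarioSpec):
            return NotImplemented
        return (self.feed, self.housing, self.application) == \
            (other.feed, other.housing, other.application)


def compose(measures: Sequence[Measure], name: Optional[str] = None) -> ScenarioSpec:
    """Compose measures into a scenario; duplicate slot occupancy is an error.

    The result is independent of the order of ``measures`` and the empty
    composition is the reference scenario.
    """
    slots: dict[str, Measure] = {}
    for m in measures:
        if m.slot in slots:
            raise ValueError(f"slot {m.slot!r} already occupied")
        slots[m.slot] = m
    return ScenarioSpec(
        name=name or _canonical_name(slots),
        feed=slots.get("feed"),
        housing=slots.get("housing"),
        application=slots.get("application"),
    )


def _canonical_name(slots: dict[str, Measure]) -> str:
    if not slots:
        return "Ref"
    parts = []
    feed = slots.get("feed")
    if feed is not None:
        parts.append(f"SW_{feed.level}")
    housing = slots.get("housing")
    if housing is not None:
        parts.append("CT2" if housing.adapted_management else "CT1")
    if "application" in slots:
        parts.append("AS")
    if set(parts) == {"SW_high", "CT2", "AS"}:
        return "CM"
    return "+".join(parts)


def standard_scenarios(
    seaweed: Optional[SeaweedParams] = None,
    toilet: Optional[CowToiletParams] = None,
    acid: Optional[AcidificationParams] = None,
) -> dict[str, ScenarioSpec]:
    """The seven study scenarios: Ref, SW low/high, CT1/CT2, AS and CM."""
    sw = seaweed or SeaweedParams()
    ct = toilet or CowToiletParams()
    ac = acid or AcidificationParams()
    return {
        "Ref": compose([]),
        "SW_low": compose([SeaweedMeasure(level="low", params=sw)]),
        "SW_high": compose([SeaweedMeasure(level="high", params=sw)]),
        "CT1": compose([CowToiletMeasure(adapted_management=False, params=ct)]),
        "CT2": compose([CowToiletMeasure(adapted_management=True, params=ct)]),
        "AS": compose([AcidificationMeasure(params=ac)]),
        "CM": compose([
            SeaweedMeasure(level="high", params=sw),
            CowToiletMeasure(adapted_management=True, params=ct),
            AcidificationMeasure(params=ac),
        ]),
    }


# ---------------------------------------------------------------------------
# measure application


class SeaweedApplication(BaseModel):
    level: str
    ch4_multipliers: dict[str, float]
    demand_kg_per_year: float
    n_plants_required: int
    milk_yield_override: Optional[float]
    transport_tkm: float


def apply_seaweed(farm: FarmSystem, params: SeaweedParams, level: str) -> SeaweedApplication:
    """Seaweed feeding: CH4 multipliers plus the dried-biomass demand it implies.

    Demand is head count x inclusion share of organic-matter intake x 365; the
    number of land-based production systems needed follows from the per-plant
    capacity (12 kg dried/day).
    """
    if level not in params.inclusion:
        raise ValueError(f"unknown inclusion level {level!r}")
    demand = 0.0
    for h in farm.herd:
        if h.organic_matter_intake <= 0:
            raise ValueError(f"missing organic-matter intake for {h.name!r}")
        demand += h.count * params.inclusion[level].get(h.name, 0.0) \
            * h.organic_matter_intake * 365.0
    capacity = params.plant_capacity_kg_per_day * 365.0
    return SeaweedApplication(
        level=level,
        ch4_multipliers=dict(params.ch4_multipliers[level]),
        demand_kg_per_year=demand,
        n_plants_required=math.ceil(demand / capacity) if demand > 0 else 0,
        milk_yield_override=params.milk_yield_high if level == "high" else None,
        transport_tkm=demand / 1000.0 * params.transport_distance_km,
    )


class CowToiletApplication(BaseModel):
    n_toilets: int
    captured_urine_m3: float
    captured_urine_n: float


def apply_cow_toilet(
    farm: FarmSystem,
    params: CowToiletParams,
    budget: Optional[NitrogenBudget] = None,
) -> CowToiletApplication:
    """Cow toilet: housing NH3 multiplier on dairy cows plus the urine split.

    The captured stream is the farm's configured capture fraction of the total
    herd urine; it may not exceed half of the dairy cows' excreted urine (the
    system's technical limit), and only dairy cows use the toilet — heifers
    keep excreting unseparated slurry.
    """
    dairy = farm.category(DAIRY)
    if dairy is None or dairy.count <= 0:
        raise ValueError("cow toilet requires dairy cows")
    budget = budget or excreta_budget(farm)
    captured_m3 = farm.urine_capture_fraction * budget.total_urine_volume_m3
    dairy_urine_m3 = budget.get(DAIRY).urine_volume_m3
    if captured_m3 > 0.5 * dairy_urine_m3 + 1e-9:
        raise ValueError(
            f"capture of {captured_m3:.0f} m3 exceeds half of the dairy cows' "
            f"urine ({dairy_urine_m3:.0f} m3)")
    return CowToiletApplication(
        n_toilets=math.ceil(dairy.count / params.cows_per_toilet),
        captured_urine_m3=captured_m3,
        captured_urine_n=captured_m3 * budget.urine_n_conc,
    )


class AcidificationApplication(BaseModel):
    acid_demand_l: float
    lime_demand_kg: float
    modifiers: TechniqueModifiers
    yield_multipliers: dict[str, float]


def apply_acidification(
    farm: FarmSystem,
    params: AcidificationParams,
    slurry_volume_m3: float,
) -> AcidificationApplication:
    """On-field acidification of the applied slurry.

    Acid demand follows the dose (1.5 L per m3 of spread slurry); the
    counter-liming requirement is 75 kg CaCO3 per L-per-tonne of dose, i.e.
    112.5 kg/ha, applied on the slurry-fertilized forage area.  Crop yields
    rise (maize +5 %, grassland forage +30 %) while total applied N stays
    unchanged.
    """
    if slurry_volume_m3 < 0:
        raise ValueError("slurry volume must be >= 0")
    area = farm.crop_plan.total_area
    return AcidificationApplication(
        acid_demand_l=params.acid_dose_l_per_m3 * slurry_volume_m3,
        lime_demand_kg=params.lime_kg_per_ha * area,
        modifiers=TechniqueModifiers(
            nh3=params.nh3_multiplier,
            n2o=params.n2o_multiplier,
            no3=params.no3_multiplier,
        ),
        yield_multipliers=dict(params.yield_multipliers),
    )


# ---------------------------------------------------------------------------
# consolidated scenario effects (consumed by the inventory builder)


class ScenarioEffects(BaseModel):
    enteric_multipliers: Optional[dict[str, float]] = None
    housing_multipliers: Optional[dict[str, float]] = None
    slurry_fraction: float = 1.0
    urine_n_separated: float = 0.0
    urine_n_applied: float = 0.0
    urine_technique: str = "injection"
    slurry_technique: str = "trailing_hose"
    slurry_modifiers: Optional[TechniqueModifiers] = None
    mineral_n_applied: float = 0.0
    displaced_mineral_n: float = 0.0
    urine_surplus_n: float = 0.0
    seaweed_demand_kg: float = 0.0
    n_plants_required: int = 0
    n_toilets: int = 0
    acid_demand_kg: float = 0.0
    acid_demand_l: float = 0.0
    lime_demand_kg: float = 0.0
    transport_tkm: float = 0.0
    milk_yield_override: Optional[float] = None


def scenario_effects(
    farm: FarmSystem,
    scenario: ScenarioSpec,
    budget: Optional[NitrogenBudget] = None,
    efs: Optional[EmissionFactorSet] = None,
) -> ScenarioEffects:
    """Resolve a scenario into the concrete pool splits, multipliers and demands."""
    budget = budget or excreta_budget(farm)
    eff = ScenarioEffects(mineral_n_applied=farm.mineral_fertilizer_total_kg or 0.0)

    if scenario.feed is not None:
        sw = apply_seaweed(farm, scenario.feed.params, scenario.feed.level)
        eff.enteric_multipliers = sw.ch4_multipliers
        eff.seaweed_demand_kg = sw.demand_kg_per_year
        eff.n_plants_required = sw.n_plants_required
        eff.transport_tkm += sw.transport_tkm
        eff.milk_yield_override = sw.milk_yield_override

    if scenario.housing is not None:
        ct = scenario.housing
        split = apply_cow_toilet(farm, ct.params, budget)
        eff.housing_multipliers = {DAIRY: 1.0 - ct.params.nh3_reduction}
        eff.n_toilets = split.n_toilets
        if ct.adapted_management:
            # urine to closed storage and injection; slurry pools shrink
            housing_nh3n = budget.total_n * _housing_frac(efs)
            n_to_storage = budget.total_n - housing_nh3n
            eff.urine_n_separated = split.captured_urine_n
            eff.slurry_fraction = max(0.0, 1.0 - split.captured_urine_n / n_to_storage)
            mineral = eff.mineral_n_applied
            applied = min(split.captured_urine_n, mineral) if mineral > 0 \
                else split.captured_urine_n
            eff.urine_n_applied = applied
            eff.urine_surplus_n = split.captured_urine_n - applied
            eff.displaced_mineral_n = min(applied, mineral)
            eff.mineral_n_applied = mineral - eff.displaced_mineral_n
            eff.urine_technique = ct.params.urine_technique
            eff.slurry_technique = ct.params.slurry_technique
        # CT1: urine is remixed downstream — storage and application unchanged

    if scenario.application is not None:
        ac = scenario.application.params
        slurry_volume = budget.slurry_volume_m3 * eff.slurry_fraction
        app = apply_acidification(farm, ac, slurry_volume)
        eff.slurry_modifiers = app.modifiers
        eff.acid_demand_l = app.acid_demand_l
        eff.acid_demand_kg = app.acid_demand_l * ac.acid_density_kg_per_l
        eff.lime_demand_kg = app.lime_demand_kg
        eff.transport_tkm += (eff.acid_demand_kg + eff.lime_demand_kg) / 1000.0 \
            * ac.transport_distance_km

    return eff


def _housing_frac(efs: Optional[EmissionFactorSet]) -> float:
    return (efs or EmissionFactorSet()).housing_nh3n_frac
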