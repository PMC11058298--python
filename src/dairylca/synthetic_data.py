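"""Packaged reference fixtures and synthetic farm/ensemble generation.

The two reference farms (Oder-Spree, Diepholz), the measure parameter set and
the reference impact tables ship as checksummed plain-text fixtures inside
the package, so every pipeline stage is testable offline.  A seeded farm
sampler and a parameter-perturbation ensemble support sensitivity-style runs
that the point model alone cannot provide.
"""

from __future__ import annotations

import hashlib
import json
from importlib import resources
from typing import Mapping, Optional

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict

from .abatement import (
    AcidificationParams,
    CowToiletParams,
    ScenarioSpec,
    SeaweedParams,
    standard_scenarios,
)
from .emission_inventory import build_inventory, calibrate_emission_factors
from .farm_system import FarmSystem, load_farm
from .impact_assessment import (
    CATEGORIES,
    CharacterizationFactors,
    ImpactTable,
    calibrate_background,
)
from .reporting import CalibratedFarm, GAS_COLUMNS, ScenarioResult, run_scenario

REGIONS = ("oder_spree", "diepholz")

_DATA_FILES = (
    "oder_spree.yaml",
    "diepholz.yaml",
    "measures.yaml",
    "table_stage_impacts.csv",
    "table_gas_contributions.csv",
    "table_forage_acidification.csv",
)


def _data_bytes(name: str) -> bytes:
    return (resources.files("dairylca") / "data" / name).read_bytes()


def _verify_checksums() -> None:
    expected = json.loads(_data_bytes("checksums.json"))
    for name in _DATA_FILES:
        digest = hashlib.sha256(_data_bytes(name)).hexdigest()
        if expected.get(name) != digest:
            raise RuntimeError(
                f"fixture checksum mismatch for {name!r}: packaged data was altered")


class FixtureBundle(BaseModel):
    """All in-package reference data, loaded and validated."""

    model_config = ConfigDict(arbitrary_types_allowed=True)

    farms: dict[str, FarmSystem]
    seaweed: SeaweedParams
    cow_toilet: CowToiletParams
    acidification: AcidificationParams
    stage_impacts: pd.DataFrame
    gas_contributions: pd.DataFrame
    forage_acidification: pd.DataFrame

    def scenarios(self) -> dict[str, ScenarioSpec]:
        return standard_scenarios(self.seaweed, self.cow_toilet, self.acidification)

    def stage_impact_table(self, region: str, scenario: str) -> ImpactTable:
        """One fixture scenario as an :class:`ImpactTable` (per kg FPCM)."""
        df = self.stage_impacts
        sub = df[(df.region == region) & (df.scenario == scenario)]
        if sub.empty:
            raise KeyError(f"no fixture rows for {region}/{scenario}")
        stages = [c for c in df.columns
                  if c not in ("region", "category", "scenario", "total")]
        values = {s: {} for s in stages}
        for _, row in sub.iterrows():
            for s in stages:
                values[s][row.category] = float(row[s])
        return ImpactTable(values=values,
                           annual_fpcm=self.farms[region].annual_milk)

    def gas_row(self, region: str, scenario: str) -> dict[str, float]:
        df = self.gas_contributions
        sub = df[(df.region == region) & (df.scenario == scenario)]
        if sub.empty:
            raise KeyError(f"no fixture gas row for {region}/{scenario}")
        row = sub.iloc[0]
        return {c: float(row[c]) for c in GAS_COLUMNS}


def packaged_fixtures() -> FixtureBundle:
    """Load and checksum-verify the packaged fixtures (deterministic, offline)."""
    _verify_checksums()
    farms = {r: load_farm(yaml.safe_load(_data_bytes(f"{r}.yaml"))) for r in REGIONS}
    measures = yaml.safe_load(_data_bytes("measures.yaml"))
    sw = measures["seaweed"]
    return FixtureBundle(
        farms=farms,
        seaweed=SeaweedParams(
            inclusion=sw["inclusion"],
            ch4_multipliers=sw["ch4_multipliers"],
            milk_yield_high=sw["milk_yield_high"],
            plant_capacity_kg_per_day=sw["plant_capacity_kg_per_day"],
            transport_distance_km=sw["transport_distance_km"],
            production_intensity=sw["production_intensity"],
        ),
        cow_toilet=CowToiletParams(**measures["cow_toilet"]),
        acidification=AcidificationParams(**{
            k: v for k, v in measures["acidification"].items()
            if k in AcidificationParams.model_fields}),
        stage_impacts=pd.read_csv(
            (resources.files("dairylca") / "data" / "table_stage_impacts.csv").open()),
        gas_contributions=pd.read_csv(
            (resources.files("dairylca") / "data" / "table_gas_contributions.csv").open()),
        forage_acidification=pd.read_csv(
            (resources.files("dairylca") / "data" / "table_forage_acidification.csv").open()),
    )


def reference_model(
    region: str,
    bundle: Optional[FixtureBundle] = None,
) -> CalibratedFarm:
    """Calibrate a farm's emission factors and background intensities against
    its reference fixture columns and return the ready-to-run model."""
    bundle = bundle or packaged_fixtures()
    farm = bundle.farms[region]
    ref_impacts = bundle.stage_impact_table(region, "Ref").values
    efs = calibrate_emission_factors(
        farm, ref_impacts, bundle.gas_row(region, "Ref"))
    # background intensities: seaweed/toilet/acid/lime from the measure set
    from .impact_assessment import BackgroundIntensities

    measures = yaml.safe_load(_data_bytes("measures.yaml"))
    template = BackgroundIntensities(
        seaweed_kg=measures["seaweed"]["production_intensity"],
        toilet_unit=measures["cow_toilet"]["hardware_intensity_per_toilet"],
        acid_kg=measures["acidification"]["acid_intensity_per_kg"],
        lime_production_kg=measures["acidification"]["lime_intensity_per_kg"],
    )
    ref_inventories = build_inventory(farm, bundle.scenarios()["Ref"], efs)
    background = calibrate_background(
        ref_impacts, farm, ref_inventories, template=template)
    return CalibratedFarm(farm=farm, efs=efs, background=background,
                          cfs=CharacterizationFactors())


# ---------------------------------------------------------------------------
# seeded synthetic farms


DEFAULT_RANGES: dict[str, tuple[float, float]] = {
    "dairy_cows": (100, 700),
    "heifers_per_dairy": (0.4, 1.1),
    "dairy_per_ha": (0.45, 1.2),   # inclusion rule: specialized dairy farms only
    "milk_yield": (8672, 11355),
    "maize_yield": (30, 45),
    "grass_yield": (10, 30),
    "n_rate_cap": (80, 170),
}


def generate_farm(
    seed: int,
    ranges: Optional[Mapping[str, tuple[float, float]]] = None,
) -> FarmSystem:
    """Sample a random specialized dairy farm (uniform within ranges).

    Reproducible under the seed; every sampled farm respects the
    specialization rule of at least 0.45 dairy cows per hectare by
    construction and passes :func:`~dairylca.farm_system.load_farm`
    validation.
    """
    rng = np.random.default_rng(seed)
    r = dict(DEFAULT_RANGES)
    if ranges:
        r.update({k: tuple(v) for k, v in ranges.items()})
    if any(lo > hi for lo, hi in r.values()):
        raise ValueError("empty sampling range")

    def u(key: str) -> float:
        lo, hi = r[key]
        return float(rng.uniform(lo, hi))

    dairy = round(u("dairy_cows"))
    heifers = round(dairy * u("heifers_per_dairy"))
    land = dairy / u("dairy_per_ha")
    milk_yield = round(u("milk_yield"))
    maize_area = 0.40 * land
    grass_silage_area = 0.10 * land
    grass_area = 0.15 * land
    cap = u("n_rate_cap")
    config = {
        "region": f"synthetic_{seed}",
        "milk_production": {
            "dairy_cows": dairy,
            "heifers": heifers,
            "milk_yield_kg_fpcm": milk_yield,
        },
        "farm_land": {"total_ha": land},
        "crop_plan": {
            "maize_silage": {"area_ha": maize_area,
                             "yield_t_fm_per_ha": u("maize_yield"),
                             "n_rate_cap_kg_per_ha": cap},
            "grass_silage": {"area_ha": grass_silage_area,
                             "yield_t_fm_per_ha": u("grass_yield"),
                             "n_rate_cap_kg_per_ha": cap},
            "grass_production": {"area_ha": grass_area,
                                 "yield_t_fm_per_ha": u("grass_yield"),
                                 "n_rate_cap_kg_per_ha": cap},
        },
        "further_characteristics": {
            "urine_capture_fraction": float(rng.uniform(0.20, 0.30)),
        },
    }
    return load_farm(config)


# ---------------------------------------------------------------------------
# perturbation ensembles


#: perturbable parameters: name -> how the relative factor is applied
PERTURBABLE = ("seaweed_ch4", "urine_capture_fraction", "acidification_nh3")


class PerturbationSummary(BaseModel):
    parameter_draws: dict[str, list[float]]
    outputs: dict[str, list[float]]  # per-output ensemble values
    summary: dict[str, dict[str, float]]  # output -> min/median/max


def perturb(
    model: CalibratedFarm,
    scenario_name: str,
    relative_ranges: Mapping[str, tuple[float, float]],
    n: int,
    seed: int,
    bundle: Optional[FixtureBundle] = None,
) -> PerturbationSummary:
    """Run a scenario ensemble with relatively perturbed measure parameters.

    ``relative_ranges`` maps parameter names (:data:`PERTURBABLE`) to a
    relative band, e.g. ``{"seaweed_ch4": (-0.1, 0.1)}`` for +-10 % on the
    enteric CH4 multiplier of the fed seaweed.  Deterministic under the seed;
    zero-width ranges reproduce the point run exactly.
    """
    if n < 1:
        raise ValueError("ensemble size must be >= 1")
    unknown = set(relative_ranges) - set(PERTURBABLE)
    if unknown:
        raise KeyError(f"unknown perturbation parameters: {sorted(unknown)}")
    bundle = bundle or packaged_fixtures()
    rng = np.random.default_rng(seed)

    draws: dict[str, list[float]] = {k: [] for k in relative_ranges}
    outputs: dict[str, list[float]] = {c: [] for c in CATEGORIES}
    outputs["chain_nh3_ep"] = []
    for _ in range(n):
        factors = {}
        for key, (lo, hi) in relative_ranges.items():
            factors[key] = 1.0 + float(rng.uniform(lo, hi))
            draws[key].append(factors[key])
        result = _run_perturbed(model, scenario_name, factors, bundle)
        for c in CATEGORIES:
            outputs[c].append(result.impacts.total(c))
        outputs["chain_nh3_ep"].append(
            result.gas["nh3_in_house"] + result.gas["nh3_storage"]
            + result.gas["nh3_forage"])
    summary = {
        k: {"min": float(np.min(v)), "median": float(np.median(v)),
            "max": float(np.max(v))}
        for k, v in outputs.items()}
    return PerturbationSummary(parameter_draws=draws, outputs=outputs,
                               summary=summary)


def _clip_mult(x: float) -> float:
    return min(max(x, 1e-6), 0.999999)


def _run_perturbed(
    model: CalibratedFarm,
    scenario_name: str,
    factors: Mapping[str, float],
    bundle: FixtureBundle,
) -> ScenarioResult:
    sw = bundle.seaweed.model_copy(deep=True)
    ct = bundle.cow_toilet.model_copy(deep=True)
    ac = bundle.acidification.model_copy(deep=True)
    farm = model.farm
    if "seaweed_ch4" in factors:
        f = factors["seaweed_ch4"]
        sw.ch4_multipliers = {
            level: {cat: _clip_mult(m * f) for cat, m in mults.items()}
            for level, mults in sw.ch4_multipliers.items()}
    if "acidification_nh3" in factors:
        ac.nh3_multiplier = _clip_mult(ac.nh3_multiplier * factors["acidification_nh3"])
    if "urine_capture_fraction" in factors:
        frac = min(0.5, farm.urine_capture_fraction * factors["urine_capture_fraction"])
        farm = farm.model_copy(update={"urine_capture_fraction": frac})
    scenarios = standard_scenarios(sw, ct, ac)
    perturbed_model = model.model_copy(update={"farm": farm})
    return run_scenario(perturbed_model, scenarios[scenario_name])
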