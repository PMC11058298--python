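# dairylca

A farm-gate (cradle-to-farm-gate) attributional life-cycle-assessment
scenario engine for specialized dairy farms, built to quantify what three
novel abatement measures — feeding the red seaweed *Asparagopsis*, an
in-house cow-toilet urine-separation system, and on-field slurry
acidification — do to the environmental profile of milk, singly and in
combination, and which trade-offs they create.

It is aimed at agri-environmental modellers who want a transparent,
configuration-driven alternative to GUI LCA software for scenario
screening: every emission factor, characterization factor and upstream
intensity is an inspectable, overridable value, and every reported number is
reproducible from plain-text inputs.

## Model

The functional unit is 1 kg of fat- and protein-corrected milk
(FPCM = milk × (0.1226·fat% + 0.0776·protein% + 0.2534), standardized to
4 % fat / 3.3 % true protein).  The farm system is a fixed herd of dairy
cows and heifers in loose housing without grazing; the manure chain is
housing → crusted outdoor slurry tank → field application by trailing hose.

Emissions follow tier-1 inventory algebra: per-head enteric CH₄ factors;
N-pool × factor products for NH₃ and N₂O along the manure chain; a
volatile-solids pool for manure CH₄; fixed fractions for indirect N₂O from
volatilized NH₃ and leached NO₃; low-emission application techniques and
acidification act as multipliers on the broadcast/organic baselines
(trailing hose NH₃ ×0.67 / N₂O ×1.25, injection ×0.39 / ×1.19,
acidification NH₃ ×0.543 / N₂O ×0.79 / NO₃ ×0.82).  Four impact categories
are characterized: GWP-100 (CH₄ 28, N₂O 265 kg CO₂e/kg), eutrophication
(NH₃ 0.35 kg PO₄³⁻e/kg), acidification (g SO₂e) and abiotic fossil
depletion (MJ).  Upstream burdens (feed purchase, fertilizer production,
seaweed, acid, lime, hardware, transport) enter as calibrated per-stage
background intensities rather than a process network; the calibration
reproduces the packaged reference stage tables of the two fixture farms
exactly and is held fixed across scenarios.  Milk/meat co-product splitting
uses the International Dairy Federation physical allocation,
AF_milk = 1 − 6.04 × (meat/milk ratio) = 0.8792.

Seven scenarios are built in: `Ref`, `SW_low`, `SW_high` (seaweed at 0.5/1 %
of organic-matter intake for cows), `CT1`, `CT2` (cow toilet without/with
adapted separate urine management), `AS` (slurry acidification) and `CM`
(= SW_high + CT2 + AS, composed by slot and order-invariant).

## Worked example

```sh
$ dairylca compare oder_spree
scenario       GWP      EP      AP      AD
SW_low        -9.9    +1.9    +2.6   +10.2
           trade-offs: between_categories, location_shift
SW_high      -23.8    +3.9    +5.2   +20.5
           trade-offs: between_categories, location_shift
CT1           +0.3    -4.4   -10.3    +0.8
           trade-offs: between_categories
CT2           -2.4    -9.0   -18.3    -1.1
           trade-offs: location_shift
AS            +0.1    -1.9    -1.0    +3.3
           trade-offs: between_categories
CM           -26.1    -6.8   -14.0   +22.3
           trade-offs: between_categories, location_shift
```

Each row is the percent change of a scenario's total impact against the
reference on the Oder-Spree fixture farm: high seaweed inclusion cuts GWP
by ~24 % but raises abiotic depletion by ~20 % (seaweed production is
energy-intensive — a between-category and an off-/on-farm trade-off); the
adapted cow toilet (CT2) is the only measure improving every category at
once; the full combination gets GWP down ~26 % while still paying an
abiotic-depletion penalty.  The same run in library code:

```python
from dairylca import packaged_fixtures, reference_model, run_scenario

bundle = packaged_fixtures()
model = reference_model("oder_spree", bundle)          # calibrates EFs + backgrounds
result = run_scenario(model, bundle.scenarios()["CM"])
print(result.impacts.to_frame().round(3))              # stage x category table
print(result.demands)                                  # seaweed 49.6 t, 27 toilets,
                                                       # 41,890 L acid, 55.35 t lime
```

## Layout

| module | contents |
| --- | --- |
| `dairylca.farm_system` | farm/herd/crop types, FPCM standardization, excreta N budget, slurry-first fertilization plan |
| `dairylca.emission_inventory` | emission-factor set, per-stage operations, the six-stage inventory builder, EF calibration |
| `dairylca.abatement` | the three measures, their demands/burdens, slot-based scenario composition |
| `dairylca.impact_assessment` | characterization factors, background intensities + calibration, impact tables, IDF allocation |
| `dairylca.reporting` | scenario runs, stage/gas tables, percent changes, trade-off classification, CSV export |
| `dairylca.synthetic_data` | checksummed packaged fixtures, seeded farm sampler, perturbation ensembles |
| `dairylca.cli` | `dairylca run / compare / report / fixtures-export` |

See `docs/methods.md` for the model description, calibration choices and
known limitations.
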