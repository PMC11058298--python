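# Methods

## System and scope

The package models a specialized, confinement dairy farm from cradle to farm
gate and attributes all burdens to 1 kg of fat- and protein-corrected milk
(FPCM).  The herd is static — two categories, mature dairy cows (dry period
included) and heifers up to two years, with no culling or birth dynamics —
and all internal flows are annual and absolute (kg N/yr, m³/yr, kg gas/yr);
division by the milk output happens only at characterization, so the
nitrogen-conservation identities inside the manure chain hold exactly.

Six management stages structure every result: production & transport of
measure-related inputs, feed purchase, forage production, enteric
fermentation, in-house manure handling, and outside slurry storage.

Two fixture farms ship with the package, a large eastern-German operation
(666 cows / 361 heifers / 806 ha, "oder_spree") and a small western-German
one (121 / 134 / 111 ha, "diepholz"), both at an assumed 10,000 kg
FPCM/cow/yr, together with their reference stage-impact and gas-contribution
tables and the measure parameter set.  All fixtures are plain text and
SHA-256-checksummed; a mismatch is a hard error.

## Inventory model

Tier-1 algebra with every constant in the configurable
`EmissionFactorSet`:

* **Enteric CH₄** — head count × per-head factor × optional feed multiplier.
  The default factors (dairy 137.65, heifer 52.43 kg CH₄/head/yr) are the
  unique pair that reproduces both fixture farms' enteric stage impacts
  given their herd compositions; they sit plausibly above the generic
  tier-1 Western-Europe dairy value because the fixture cows are
  high-yielding.
* **Housing NH₃** — excreted N × fraction (default 0.0851 kg NH₃-N/kg N,
  farm-consistent across both fixtures to three digits).  A cow toilet
  multiplies the dairy-cow term only.
* **Outside storage** (crusted tank) — NH₃, direct N₂O per kg stored N,
  CH₄ per kg volatile solids (VS = 0.35 × organic-matter intake), indirect
  N₂O from the volatilized NH₃-N.  A closed container (separated urine)
  emits exactly zero.
* **Field application** — NH₃ and direct N₂O from broadcast/organic
  baselines recalculated through technique multipliers (trailing hose
  −33 % NH₃ / +25 % N₂O; injection −61 % / +19 %), with acidification
  modifiers (−45.7 % NH₃, −21 % N₂O, −18 % NO₃) composing multiplicatively;
  NO₃ leaching as a fixed fraction of applied N; indirect N₂O from
  volatilization (EF 0.010) and leaching (EF 0.011).  Mineral-fertilizer
  NH₃/N₂O factors are validated to sit strictly below the organic ones.
* **Liming** — 0.44 kg CO₂ per kg CaCO₃ (limestone carbon content).
* Ambient temperature is carried as a tag (11 °C); the factors are
  calibrated at that condition, not temperature-resolved.

The chain is evaluated **stage-independently with reference pools**: a
mitigation upstream (toilet cutting housing NH₃) does not enlarge the
downstream pools.  This mirrors the stage-wise inventory convention of the
reference tables (their CT1 column changes the housing stage only), keeps
every stage degree-1 homogeneous in its own driver, and makes the emitted
reactive N a lower bound on the reference chain — the builder asserts that
NH₃-N + N₂O-N + NO₃-N never exceeds the N entering the chain.

## Excreta and fertilization

Per-head defaults: N excretion 141 (dairy) / 29.5 (heifer) kg N/yr — the
pair back-solved consistently from both farms' in-house NH₃ responses to
the cow toilet; urine 30 / 12 L/day at 5.4 kg N/m³; mixed slurry at
3.2 kg N/m³ (midpoint of the 2.9–3.5 range); organic-matter intake 19.13 /
4.71 kg/day, back-solved from the two farms' seaweed demands at the low
inclusion level (24.8 / 4.8 t/yr).

Fertilization is slurry-first under per-crop N-rate caps: legumes take
their fixed allowance plus a fixation credit and never mineral N; grass
production is saturated with slurry; the silage crops receive the residual
organic N and a mineral top-up to cap.  The farms' total mineral use is
expert data that cannot be derived from shared feasibility constants, so a
declared total (53 / 55 kg N/ha) is honored by reserving the corresponding
mineral share on the silage crops; organic N beyond all caps (including an
other-cropland sink, default cap 170 kg N/ha) is reported as surplus rather
than silently dropped.

## Abatement measures

* **Seaweed** — CH₄ multipliers per category and level (low: 0.74 / 0.55;
  high: 0.33 / 0.32); demand = count × inclusion × OM intake × 365; plants
  needed = ceil(demand / 4.38 t/yr).  High inclusion sets the dairy milk
  yield to 8,800 kg.  Because the reference tables keep all non-enteric
  per-kg intensities unchanged under high inclusion, the engine keeps the
  reference FPCM denominator by default; `propagate_milk_penalty=True`
  implements the literal yield-reduction alternative.
* **Cow toilet** — one unit per 25 cows; housing NH₃ ×0.6 on dairy cows.
  The captured stream is the farm's configured share of total herd urine
  (0.29 / 0.23 — per-farm data, since back-deriving them from urine
  physiology is inconsistent across the farms), bounded by half the dairy
  cows' urine.  CT1 remixes the urine downstream (no storage or field
  change); CT2 stores it closed (zero emissions), injects it, scales the
  slurry storage and its mixing-energy background by the remaining N
  fraction, and displaces mineral fertilizer 1:1 up to the available urine
  N — the captured urine N (~14 t/yr on the large farm) is below the
  declared mineral total, so displacement is partial and any cap surplus is
  reported.
* **Acidification** — 1.5 L acid per m³ of spread slurry; counter-liming
  112.5 kg CaCO₃/ha (75 kg per L-per-tonne dose) on the slurry-fertilized
  forage area — the per-hectare reading is the only one compatible with
  the reference forage-GWP responses, where the N₂O saving slightly
  outweighs the lime CO₂; a per-m³ reading would add two orders of
  magnitude of lime.  Yields rise (maize ×1.05, grassland ×1.30) with
  total applied N unchanged.  Acid/lime production burdens are booked into
  the forage-production background (their transport into production &
  transport), matching the reference tables' stage attribution.

Scenarios occupy slots (feed / housing / application), at most one measure
each, so composition is order-invariant by construction and the combined
scenario acidifies only the slurry remaining after urine separation (its
acid demand is strictly below the acidification-only scenario's).

## Characterization and background calibration

CML-style factors: CH₄ 28 and N₂O 265 kg CO₂e/kg, NH₃ 0.35 kg PO₄³⁻e/kg
and 1.60 kg SO₂e/kg, NO₃ 0.10 kg PO₄³⁻e/kg, lime CO₂ 1, fossil energy in
MJ.  The NH₃→AP factor defaults to 1.60 rather than the generic 1.88: it is
the largest value compatible with non-negative background burdens in the
fixture storage stage (whose AP/EP cell ratio is farm-consistent at 1.600).

Upstream burdens are **calibrated background intensities**: for each stage
and category the base is the residual between the reference cell and the
characterized foreground plus explicit activity terms (mineral-N
production, seaweed, toilet hardware, acid, lime, transport).  Calibration
raises if a residual would be meaningfully negative and otherwise clips
rounding-level negatives to zero, reporting them.  The round trip
(calibrate, then characterize the reference) reproduces every reference
cell of both farms to < 0.001.  Backgrounds are fixed across scenarios and
move only through bookkeeping: displaced mineral N, the stored-slurry
fraction, measure input demands.

The two reference surfaces are not mutually consistent at the forage
stage: the gas-resolved table attributes more field NH₃ to forage
production than the stage table's own EP/AP cells admit under any positive
characterization, and on the small farm the storage gas entries overshoot
the storage GWP cell by 0.005.  The stage table is taken as binding — the
calibrated field NH₃ is bounded by the forage AP room and the storage N₂O
factors are shrunk proportionally into the storage GWP room — so the
forward gas table matches the gas-resolved reference in housing and
storage but shows smaller field NH₃/indirect-N₂O entries than printed.
Scenario comparison numbers quoted from the gas-resolved surface are
therefore always computed on the packaged fixture, and the forward engine
is held to the stage table plus structural checks.

The IDF allocation constant set (6.04, ratio 0.02) gives AF_milk = 0.8792;
scenario tables are reported unallocated, allocation being applied only in
the literature-comparison numbers (0.89 / 1.11 kg CO₂e/kg FPCM).

## Reporting and trade-offs

Percent changes are 100 × (scenario − reference)/reference; integers in
summaries, one decimal in forage-stage reports, rounded half away from
zero.  Trade-off classification uses a dead band of 0.5 % of the reference
(configurable) and flags: (1) between categories — one total falls while
another rises; (2) location shift — the off-farm production & transport
stage moves opposite to the on-farm stages within a category; (3)
pollution swapping — within a stage, NH₃ moves opposite to another gas.
On both fixture farms the acidification scenario raises no swapping flag
and the adapted cow toilet raises no between-category flag, in the forward
runs as well as on the fixture tables.

## Synthetic farms and perturbation ensembles

`generate_farm(seed, ranges)` samples uniform, seeded farms that respect
the specialization rule (≥ 0.45 dairy cows/ha) by construction — uniform
ranges are an artifact choice, as the study design contains no sensitivity
analysis to emulate.  `perturb` runs seeded ensembles over the
parameters that most plausibly vary in practice — the seaweed CH₄
effectiveness, the urine-capture share and the acidification NH₃
effectiveness — and reports min/median/max per output.  These generators
exercise the pipeline's scaling behavior; they do not emulate real-farm
heterogeneity in feed composition, soil or management, so passing ensemble
tests demonstrates internal consistency, not external validity.

## Numerical choices and limitations

* All problem sizes are tiny (≤ 10³ head, 7 scenarios); every computation
  is closed-form linear algebra on scalars, deterministic, and runs in
  milliseconds — ensembles of a few members suffice for the monotonicity
  checks.
* Degenerate inputs: an empty farm is valid (zero budgets); zero slurry
  yields mineral-filled caps; zero stored pools yield zero flows;
  characterization requires a positive milk output.
* The engine is not a process-network LCA: feed purchase is a constant
  background, forage yields do not feed back into purchased feed, and the
  acidification CH₄/CO₂ field benefits, sulfur fertilization value,
  hydrogen shifts under seaweed and all economics are out of scope.
* Scenario columns of the reference tables are regression fixtures, not
  forward targets: the forward engine reproduces the reference columns
  exactly and the scenario responses structurally (signs, flag patterns,
  dosing, demand bookkeeping), but individual scenario cells can deviate
  where the reference surfaces embed unstated intermediate steps (e.g. the
  large farm's high-seaweed enteric cell is not reproducible from the
  stated multipliers under any denominator convention; the small farm's
  is).  The toilet-hardware burden is calibrated per unit on the large
  farm's fixture and overstates the small farm's production & transport
  column by ~2 per mille of its GWP.
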