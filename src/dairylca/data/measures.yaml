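# Abatement-measure parameter set: direct reduction effects, input demands
# and upstream burden intensities of the three measures.
seaweed:
  inclusion:                  # share of organic-matter intake
    low:  {dairy_cow: 0.005, heifer: 0.0025}
    high: {dairy_cow: 0.010, heifer: 0.0050}
  ch4_multipliers:            # enteric CH4 relative to conventional feed
    low:  {dairy_cow: 0.74, heifer: 0.55}   # -26 % / -45 %
    high: {dairy_cow: 0.33, heifer: 0.32}   # -67 % / -68 %
  milk_yield_high: 8800       # kg FPCM/head/yr (-12 %) at high inclusion
  plant_capacity_kg_per_day: 12
  transport_distance_km: 1000   # lorry, Sweden -> Germany
  # alternative sourcing by ship from Australia for what-if runs
  transport_distance_km_ship_alternative: 25000
  production_intensity:       # per kg dried seaweed (land-based system)
    GWP: 9.4                  # kg CO2e
    EP: 0.0233                # kg PO4e
    AP: 0.0617                # kg SO2e
    AD: 109.4                 # MJ

cow_toilet:
  cows_per_toilet: 25
  collected_urine_l_per_cow_day: 15   # half of a dairy cow's daily urine
  nh3_reduction: 0.40                 # on the served animals, in-house
  urine_technique: injection
  slurry_technique: trailing_hose
  hardware_intensity_per_toilet:      # steel, rubber, pump, energy per unit-yr
    GWP: 740.0
    EP: 1.727
    AP: 2.713
    AD: 7646.0

acidification:
  acid_dose_l_per_m3: 1.5
  lime_kg_per_l_acid: 75        # counter-liming: 112.5 kg CaCO3 per ha-dose
  acid_density_kg_per_l: 1.84
  nh3_multiplier: 0.543         # -45.7 %
  n2o_multiplier: 0.79          # -21 %
  no3_multiplier: 0.82          # -18 %
  yield_multipliers:
    maize_silage: 1.05
    grass_silage: 1.30
    grass_production: 1.30
    alfalfa_silage: 1.30
  tank_capacity_l: 1000
  transport_distance_km: 300
  acid_intensity_per_kg:  {GWP: 0.09, EP: 0.0002, AP: 0.0065, AD: 8.0}
  lime_intensity_per_kg:  {GWP: 0.05, EP: 0.0001, AP: 0.0012, AD: 1.8}
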