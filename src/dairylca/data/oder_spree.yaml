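# Synthetic specialized dairy farm, Oder-Spree district (Brandenburg).
# Large eastern-German operation: big herd, large fields, poorer (low SQR)
# soils, hence lower forage yields and heavier machinery.
region: oder_spree
milk_production:
  dairy_cows: 666
  heifers: 361
  milk_yield_kg_fpcm: 10000
  annual_milk_kg_fpcm: 6660000
feed_composition:
  forage_pct_dm: 71
  concentrate_pct_dm: 29
farm_land:
  total_ha: 806
crop_plan:
  maize_silage:
    area_ha: 293
    yield_t_fm_per_ha: 34.6
    n_rate_cap_kg_per_ha: 162
  alfalfa_silage:
    area_ha: 72
    yield_t_fm_per_ha: 14.8
    n_rate_cap_kg_per_ha: 40
    n_fixation_kg_per_ha: 40
  grass_silage:
    area_ha: 54
    yield_t_fm_per_ha: 15.9
    n_rate_cap_kg_per_ha: 80
  grass_production:
    area_ha: 73
    yield_t_fm_per_ha: 11.9
    n_rate_cap_kg_per_ha: 80
fertilization:
  total_mineral_kg_n_per_ha: 53
further_characteristics:
  soil_yield_level: low
  machinery_power_kw: 233
  farm_to_field_distance_km: 15
  urine_capture_fraction: 0.29
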