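# Synthetic specialized dairy farm, Diepholz district (Lower Saxony).
# Smaller western-German operation: small herd and fields, medium soils,
# higher forage yields, lighter machinery.
region: diepholz
milk_production:
  dairy_cows: 121
  heifers: 134
  milk_yield_kg_fpcm: 10000
  annual_milk_kg_fpcm: 1210000
feed_composition:
  forage_pct_dm: 58
  concentrate_pct_dm: 42
farm_land:
  total_ha: 111
crop_plan:
  maize_silage:
    area_ha: 43
    yield_t_fm_per_ha: 44.1
    n_rate_cap_kg_per_ha: 170
  grass_silage:
    area_ha: 10
    yield_t_fm_per_ha: 30
    n_rate_cap_kg_per_ha: 170
  grass_production:
    area_ha: 33
    yield_t_fm_per_ha: 14.2
    n_rate_cap_kg_per_ha: 170
fertilization:
  total_mineral_kg_n_per_ha: 55
further_characteristics:
  soil_yield_level: medium
  machinery_power_kw: 83
  farm_to_field_distance_km: 5
  urine_capture_fraction: 0.23
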