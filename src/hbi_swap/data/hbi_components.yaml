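# Default Healthy Beverage Index component standards.
#
# Units: beverage-group components are fluid oz/day; WATER and
# MEETS_FLUID_REQS are % of the sex-specific daily fluid requirement;
# PCT_ENERGY_BEV is % of total energy from beverages.
# max_points sum to 100 by contract. Rationale for each cut-point is in
# docs/methods.md.
- component_id: WATER
  standard_lo: 50.0
  standard_hi: .inf
  zero_point: 0.0
  max_points: 15.0
  mode: proportional
- component_id: COFFEE_TEA_UNSWEETENED
  standard_lo: 0.0
  standard_hi: 32.0
  zero_point: 64.0
  max_points: 5.0
  mode: proportional
- component_id: LOW_FAT_MILK
  standard_lo: 0.0
  standard_hi: 16.0
  zero_point: 32.0
  max_points: 5.0
  mode: proportional
- component_id: DIET
  standard_lo: 0.0
  standard_hi: 32.0
  zero_point: 64.0
  max_points: 5.0
  mode: proportional
- component_id: JUICE_100
  standard_lo: 0.0
  standard_hi: 8.0
  zero_point: 16.0
  max_points: 5.0
  mode: proportional
- component_id: ALCOHOL
  standard_lo: 0.0
  standard_hi: 24.0
  zero_point: 48.0
  max_points: 5.0
  mode: proportional
- component_id: WHOLE_MILK
  standard_lo: 0.0
  standard_hi: 8.0
  zero_point: 24.0
  max_points: 10.0
  mode: proportional
- component_id: SSB
  standard_lo: 0.0
  standard_hi: 4.0
  zero_point: 16.0
  max_points: 20.0
  mode: proportional
- component_id: PCT_ENERGY_BEV
  standard_lo: 0.0
  standard_hi: 10.0
  zero_point: 30.0
  max_points: 20.0
  mode: proportional
- component_id: MEETS_FLUID_REQS
  standard_lo: 100.0
  standard_hi: .inf
  zero_point: 100.0
  max_points: 10.0
  mode: binary
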