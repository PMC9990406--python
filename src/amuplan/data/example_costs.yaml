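# SYNTHETIC illustrative cost table (indicative euro price points, not a
# survey of real equipment prices). One block per measure, fields:
#   implementation_cost  one-off purchase+installation (EUR)
#   lifetime_years       linear depreciation horizon
#   operational_cost     recurring maintenance/materials (EUR per year)
#   scaling              fixed | per_animal | per_round | per_stable
#   scale_rate           EUR per scaling unit
# The one-step-depopulation entry carries the foregone revenue of farming
# fewer broilers per round as an operational cost.
depopulation_one_step:
  implementation_cost: 2500.0
  lifetime_years: 5
  operational_cost: 6500.0
  scaling: fixed
material_supply_measures:
  implementation_cost: 2000.0
  lifetime_years: 4
  operational_cost: 500.0
  scaling: fixed
stable_specific_clothing:
  implementation_cost: 289.74
  lifetime_years: 2
  operational_cost: 0.0
  scaling: per_stable
  scale_rate: 250.0
hygiene_lock:
  implementation_cost: 6000.0
  lifetime_years: 10
  operational_cost: 150.0
  scaling: fixed
water_system_disconnection:
  implementation_cost: 400.0
  lifetime_years: 5
  operational_cost: 120.0
  scaling: per_round
  scale_rate: 15.0
material_storage_per_stable:
  implementation_cost: 300.0
  lifetime_years: 5
  operational_cost: 0.0
  scaling: per_stable
  scale_rate: 40.0
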