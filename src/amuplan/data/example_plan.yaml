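# Worked single-farm example used in the documentation and tests: a farm
# with three screened weaknesses (two-or-more-step depopulation, no
# material-supply preventive measures, no stable-specific clothing), its
# baseline model prediction, and the seven scenario predictions with the
# yearly costs of the full intervention set and of the set without the
# depopulation change. All arithmetic downstream (percent changes,
# euros per TIDDDvet) is recomputed from these numbers, never stored.
original_ti: 146.23
baseline_prediction_ti: 122.53
scenario_predictions_ti: [68.14, 73.90, 86.85, 87.06, 94.18, 105.6, 117.01]
full_set_yearly_cost: 8644.87
no_depopulation_yearly_cost: 1644.87
full_set_prediction_ti: 68.14
no_depopulation_prediction_ti: 94.18
weaknesses:
  - depopulation_one_step
  - material_supply_measures
  - stable_specific_clothing
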