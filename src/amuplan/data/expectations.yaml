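# Expected biological direction of each biosecurity measure on AMU.
# protective: applying the measure is expected to REDUCE usage (negative
#             effect); risky: applying it is expected to RAISE usage;
# unclear: no defensible mechanistic expectation (or suspected reverse
#          causality) -- such measures stay in the model as predictors but
#          are never proposed as interventions.
# Edit freely; keys must match the feature names of your farm table.
hygiene_lock: protective
stable_specific_clothing: protective
material_storage_per_stable: protective
water_system_disconnection: protective
material_supply_measures: protective
depopulation_two_or_more_steps: risky
visitor_check_in: unclear
vaccination_protocol_non_official: unclear
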