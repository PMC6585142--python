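condition,correct_paper,n_paper,correct_mobile,n_mobile
low_birth_weight,43,84,82,86
small,48,84,83,86
very_low_weight_lt1500,70,84,85,86
severe_weight_loss,57,84,83,86
moderate_weight_loss,56,84,83,86
poor_movement,53,84,79,86
convulsion_history,68,84,70,86
poor_feeding,59,84,65,86
severe_chest_indrawing,74,84,68,86
fast_breathing,71,84,73,86
umbilicus_red_or_pus,69,84,61,86
skin_pustules,82,84,80,86
jaundice_soles_or_body,69,84,57,86
eye_infection,82,84,81,86
fever,68,84,83,86
hypothermia,62,84,84,86
feeding_intolerance,63,84,74,86
breastfeeding_problems,46,84,62,86
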