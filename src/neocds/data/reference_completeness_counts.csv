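flag,k_paper,n_paper,k_mobile,n_mobile
full_assessment,20,84,86,86
any_recommendation,34,104,103,103
rr_recorded,47,104,103,103
temp_recorded,62,104,103,103
weight_recorded,101,104,102,103
weight_loss_calculated,99,104,103,103
ga_calculated_if_lmp,6,29,34,34
postnatal_age_calculated,77,104,103,103
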