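# Assessor error model — calibrated configuration.
#
# Per-condition, per-method assessor accuracies calibrated to the published
# per-method correct-classification proportions of the reference field study
# this package emulates (sensitivity and specificity are set equal: the
# published tables report overall correctness, not the split).  These are
# calibration inputs, not ground truth.
#
# Field missingness probabilities for the paper method are the published
# marginal unrecorded rates (1 - recorded proportion).  The mobile method has
# zero missingness by construction: the form engine refuses to advance past
# an unanswered required item.
accuracy:
  low_birth_weight:        {paper: 0.512, mobile: 0.953}
  small:                   {paper: 0.571, mobile: 0.965}
  very_low_weight_lt1500:  {paper: 0.833, mobile: 0.988}
  severe_weight_loss:      {paper: 0.679, mobile: 0.965}
  moderate_weight_loss:    {paper: 0.667, mobile: 0.965}
  poor_movement:           {paper: 0.631, mobile: 0.919}
  convulsion_history:      {paper: 0.810, mobile: 0.814}
  poor_feeding:            {paper: 0.702, mobile: 0.756}
  severe_chest_indrawing:  {paper: 0.881, mobile: 0.791}
  fast_breathing:          {paper: 0.845, mobile: 0.849}
  umbilicus_red_or_pus:    {paper: 0.821, mobile: 0.709}
  skin_pustules:           {paper: 0.976, mobile: 0.930}
  jaundice_soles_or_body:  {paper: 0.821, mobile: 0.663}
  eye_infection:           {paper: 0.976, mobile: 0.942}
  fever:                   {paper: 0.810, mobile: 0.965}
  hypothermia:             {paper: 0.738, mobile: 0.977}
  feeding_intolerance:     {paper: 0.750, mobile: 0.861}
  breastfeeding_problems:  {paper: 0.548, mobile: 0.721}
# standard deviation of the per-assessor random effect on the log-odds of a
# correct call (0 = all assessors identical)
chw_sd: 0.3
# paper-method probability that a recorded field is left blank
missingness:
  breath_count_60s: 0.548
  temperature_value: 0.404
  weight: 0.029
  weight_change_percent: 0.048
  gestational_age_weeks: 0.793
  postnatal_age_days: 0.260
  recommendation: 0.673
  sign: 0.25
# paper-method probability that a condition call is simply never made
# (counts as incorrect against gold); default 0 so the calibrated accuracies
# reproduce the published proportions directly
not_assessed_prob: 0.0
# crossover design
n_chws: 12
block_size: 6
# completion-time model (minutes)
time_mean_mobile: 17.5
time_sd_mobile: 10.8
time_mean_paper: 23.6
time_sd_paper: 11.6
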