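# Newborn assessment form schema (reconstructive).
# Ordered items with skip logic, range constraints, required flags, and
# double entry, covering every field the classifier and the completeness
# audit consume. Weights in grams, foot length in mm, temperature per the
# recorded unit, breath count over 60 seconds.
items:
  - id: infant_id
    prompt: "Infant ID"
    answer_type: text
  - id: sex
    prompt: "Infant sex"
    answer_type: select
    choices: [female, male, unrecorded]
  - id: birth_datetime
    prompt: "Date and time of birth"
    answer_type: datetime
  - id: assessment_datetime
    prompt: "Date and time of this assessment"
    answer_type: datetime
  - id: postnatal_age_days
    prompt: "Postnatal age (auto-calculated)"
    answer_type: integer
    compute: postnatal_age_days
  - id: lmp_known
    prompt: "Is the mother's last menstrual period (LMP) date known?"
    answer_type: select
    choices: ["yes", "no"]
  - id: lmp_date
    prompt: "LMP date"
    answer_type: date
    skip: {item: lmp_known, op: eq, value: "no"}
  - id: gestational_age_weeks
    prompt: "Gestational age in weeks (auto-calculated from LMP)"
    answer_type: decimal
    compute: gestational_age_weeks
    skip: {item: lmp_known, op: eq, value: "no"}
  - id: birth_weight_g
    prompt: "Birth weight (g) — enter twice"
    answer_type: decimal
    range: [201, 8000]
    soft_range: [1000, 5000]
    double_entry: true
  - id: current_weight_g
    prompt: "Current weight (g) — enter twice"
    answer_type: decimal
    range: [201, 8000]
    soft_range: [1000, 5000]
    double_entry: true
  - id: weight_change_percent
    prompt: "Percent weight change since birth (auto-calculated)"
    answer_type: decimal
    compute: weight_change_percent
  - id: foot_length_mm
    prompt: "Foot length (mm)"
    answer_type: decimal
    range: [30, 120]
    soft_range: [55, 95]
  - id: is_small
    prompt: "Small baby (auto-classified from weight / foot length)"
    answer_type: select
    choices: ["yes", "no"]
    compute: is_small
  - id: temperature_unit
    prompt: "Thermometer unit"
    answer_type: select
    choices: [C, F]
  - id: temperature_value
    prompt: "Axillary temperature"
    answer_type: decimal
    range: [25, 113]
    soft_range: [32, 104]
  - id: breath_count_60s
    prompt: "Breaths counted over 60 seconds (use the one-minute timer)"
    answer_type: integer
    range: [0, 200]
    soft_range: [20, 120]
  - id: poor_movement
    prompt: "Unconscious or moves only when stimulated?"
    answer_type: select
    choices: ["yes", "no"]
    tags: [danger_sign]
  - id: convulsion_history
    prompt: "History of convulsions?"
    answer_type: select
    choices: ["yes", "no"]
    tags: [danger_sign]
  - id: poor_feeding
    prompt: "Unable to feed or stopped feeding well?"
    answer_type: select
    choices: ["yes", "no"]
    tags: [danger_sign]
  - id: severe_chest_indrawing
    prompt: "Severe chest in-drawing?"
    answer_type: select
    choices: ["yes", "no"]
    tags: [danger_sign]
  - id: umbilicus_red_or_pus
    prompt: "Umbilicus red or draining pus?"
    answer_type: select
    choices: ["yes", "no"]
    tags: [danger_sign]
  - id: skin_pustules
    prompt: "Skin pustules?"
    answer_type: select
    choices: ["yes", "no"]
    tags: [danger_sign]
  - id: jaundice_soles_or_body
    prompt: "Jaundice on soles or body?"
    answer_type: select
    choices: ["yes", "no"]
    tags: [danger_sign]
  - id: eye_infection
    prompt: "Eye infection?"
    answer_type: select
    choices: ["yes", "no"]
    tags: [danger_sign]
  - id: chokes_on_feeds
    prompt: "Chokes on feeds?"
    answer_type: select
    choices: ["yes", "no"]
    tags: [feeding]
  - id: turns_blue_or_pale_feeding
    prompt: "Turns blue or pale when feeding?"
    answer_type: select
    choices: ["yes", "no"]
    tags: [feeding]
  - id: frequent_vomiting
    prompt: "Vomits frequently?"
    answer_type: select
    choices: ["yes", "no"]
    tags: [feeding]
  - id: distended_or_tender_abdomen
    prompt: "Distended or tender abdomen?"
    answer_type: select
    choices: ["yes", "no"]
    tags: [feeding]
  - id: bloody_stools
    prompt: "Bloody stools?"
    answer_type: select
    choices: ["yes", "no"]
    tags: [feeding]
  - id: wakes_easily_for_feeds
    prompt: "Wakes easily for feeds?"
    answer_type: select
    choices: ["yes", "no"]
    tags: [breastfeeding]
  - id: feeds_10min_per_side
    prompt: "Breastfeeds 10+ minutes per side?"
    answer_type: select
    choices: ["yes", "no"]
    tags: [breastfeeding]
  - id: sleeps_comfortably_between_feeds
    prompt: "Sleeps comfortably between feeds?"
    answer_type: select
    choices: ["yes", "no"]
    tags: [breastfeeding]
  - id: five_plus_wet_diapers
    prompt: "5+ wet diapers per day?"
    answer_type: select
    choices: ["yes", "no"]
    tags: [breastfeeding]
  - id: mothers_breasts_softened
    prompt: "Mother's breasts soften after feeds?"
    answer_type: select
    choices: ["yes", "no"]
    tags: [breastfeeding]
  # small-baby care section: shown only when the infant classifies as small
  - id: kmc_counseled
    prompt: "Kangaroo mother care demonstrated and counseled?"
    answer_type: select
    choices: ["yes", "no"]
    skip: {item: is_small, op: eq, value: "no"}
    tags: [small_baby_care]
  - id: cup_feeding_counseled
    prompt: "Cup feeding demonstrated (if not latching)?"
    answer_type: select
    choices: ["yes", "no"]
    skip: {item: is_small, op: eq, value: "no"}
    tags: [small_baby_care]
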