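# Published model inputs: 3-month VA transition matrices, utilities by VA
# state (time trade-off and standard gamble), 2020-euro unit costs, annual
# resource use, adverse-event rates, and run configuration.
#
# The starting VA distribution and the life table were NOT published; the
# entries below are clearly-labelled synthetic stand-ins (see the
# synthetic module) and must not be mistaken for cohort data.
#
# State order everywhere: >20/40, <=20/40 to >20/80, <=20/80 to >20/200,
# <=20/200 to >20/400, <=20/400.

reference_arm: aflibercept
comparator_arm: dexamethasone

model:
  cycle_length_years: 0.25
  discount_rate_per_year: 0.035
  starting_age_years: 68.1
  horizon_years: null            # null = lifetime horizon
  starting_distribution: synthetic_moderate
  extrapolation: continuous
  utility_method: TTO
  half_cycle_correction: false
  include_indirect_costs: false
  indirect_annual_cost: 0.0
  other_cost_interpretation: category
  seed: 1234

life_table:
  type: synthetic_gompertz       # synthetic stand-in for national tables
  a_per_year: 2.4e-5
  b_per_year_of_age: 0.095
  c_per_year: 0.0
  start_age: 40
  max_age: 100

transition_matrices:
  dexamethasone:
    - [0.9863, 0.0107, 0.0030, 0.0,    0.0]
    - [0.0979, 0.8884, 0.0107, 0.0030, 0.0]
    - [0.0,    0.0979, 0.8884, 0.0107, 0.0030]
    - [0.0,    0.0,    0.0979, 0.8884, 0.0137]
    - [0.0,    0.0,    0.0,    0.0979, 0.9021]
  aflibercept:
    - [0.9199, 0.0542, 0.0259, 0.0,    0.0]
    - [0.0153, 0.9046, 0.0542, 0.0259, 0.0]
    - [0.0,    0.0153, 0.9046, 0.0542, 0.0259]
    - [0.0,    0.0,    0.0153, 0.9046, 0.0801]
    - [0.0,    0.0,    0.0,    0.0153, 0.9847]

utilities:
  TTO:
    - {mean: 0.85, low: 0.75, high: 0.95}
    - {mean: 0.78, low: 0.72, high: 0.84}
    - {mean: 0.78, low: 0.67, high: 0.89}
    - {mean: 0.64, low: 0.53, high: 0.75}
    - {mean: 0.59, low: 0.23, high: 0.95}
  SG:
    - {mean: 0.90, low: 0.83, high: 0.97}
    - {mean: 0.92, low: 0.88, high: 0.96}
    - {mean: 0.84, low: 0.72, high: 0.96}
    - {mean: 0.71, low: 0.58, high: 0.84}
    - {mean: 0.70, low: 0.29, high: 1.11}   # stored as published; samplers clip at 1

drugs:
  aflibercept:
    vial_cost_eur_2020: 588.8
    vial_cost_sd_eur: 139.0
    injections_per_year: 9.8
  dexamethasone:
    vial_cost_eur_2020: 750.92
    vial_cost_sd_eur: 208.0
    injections_per_year: 3.1

cost_items:
  retina_specialist_consultation:
    unit_cost_eur_2020: 112.0
    unit_cost_sd_eur: 24.0
    annual_use_per_year:
      aflibercept:   {mean: 12.0, low: 6.0, high: 18.0}
      dexamethasone: {mean: 8.0,  low: 4.0, high: 12.0}
  fundus_photography:
    unit_cost_eur_2020: 20.0
    unit_cost_sd_eur: 4.0
    annual_use_per_year:
      aflibercept:   {mean: 12.0, low: 6.0, high: 18.0}
      dexamethasone: {mean: 8.0,  low: 4.0, high: 12.0}
  optical_coherence_tomography:
    unit_cost_eur_2020: 149.0
    unit_cost_sd_eur: 30.0
    annual_use_per_year:
      aflibercept:   {mean: 6.0, low: 3.0, high: 9.0}
      dexamethasone: {mean: 4.0, low: 2.0, high: 8.0}
  fluorescein_angiography:
    unit_cost_eur_2020: 42.0
    unit_cost_sd_eur: 8.0
    annual_use_per_year:
      aflibercept:   {mean: 2.0, low: 1.0, high: 3.0}
      dexamethasone: {mean: 2.0, low: 1.0, high: 3.0}

adverse_events:
  endophthalmitis:
    unit_cost_eur_2020: 3156.0
    unit_cost_sd_eur: 631.0
    annual_rate_per_year: {aflibercept: 0.006, dexamethasone: 0.0128}
  lens_damage:
    unit_cost_eur_2020: 1600.0
    unit_cost_sd_eur: 320.0
    annual_rate_per_year: {aflibercept: 0.004, dexamethasone: 0.006}
  retinal_detachment:
    unit_cost_eur_2020: 3702.0
    unit_cost_sd_eur: 740.0
    annual_rate_per_year: {aflibercept: 0.004, dexamethasone: 0.007}

other_annual_costs:
  comorbidity_eur_2020_per_year: 771.0
  non_medical_eur_2020_per_year: 1577.0

care_costs:
  vision_rehabilitation_eur_2020_per_year: 69.0
  vision_enhancing_equipment_eur_2020_per_year: 211.0
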