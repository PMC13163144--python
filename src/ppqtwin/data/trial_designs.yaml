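# Trial-design presets for the two observed piperaquine studies in pregnant
# women (Sudan 2012, Thailand 2011): dosing regimen, venous sampling
# schedules, and the demographic summaries the synthetic fixtures reproduce.
# Day n = 24*n hours after the first dose (Day 7 = 168 h).

regimen:
  dose_times_h: [0.0, 24.0, 48.0]   # once daily for three days

schedules:
  sudan_2012:
    early_h: [0, 1.5, 4, 8, 24, 25.5, 28, 32, 48, 49, 50, 51, 52, 54, 56, 60, 72]
    late_days: [5, 7, 14, 21, 28, 35, 42, 49, 56, 63]
  thai_2011:
    early_h: [0, 0.5, 1.5, 4, 8, 24.5, 25.5, 28, 32, 48.25, 48.5, 49, 50, 51, 52, 54, 56, 60, 72]
    late_days: [5, 7, 14, 21, 28, 35, 42, 49, 56, 63, 77, 84]

demographics:
  sudan:
    n: 12
    schedule: sudan_2012
    fed_state: fasted
    body_weight_kg: {mean: 59.6, range: [50.0, 72.0]}
    age_years: {mean: 24.5, range: [18.0, 33.0]}
    dose_salt_mg_per_kg: {mean: 17.57, range: [16.00, 18.82]}
    trimester2: {n: 5, ga_range_weeks: [15.3, 26.0]}
    trimester3: {n: 7, ga_range_weeks: [26.0, 40.1]}
  thailand:
    n: 24
    schedule: thai_2011
    fed_state: unknown
    body_weight_kg: {mean: 49.2, range: [36.0, 58.0]}
    age_years: {mean: 28.1, range: [18.0, 43.0]}
    dose_salt_mg_per_kg: {mean: 17.91, range: [16.33, 19.51]}
    trimester2: {n: 16, ga_range_weeks: [13.1, 27.4]}
    trimester3: {n: 8, ga_range_weeks: [28.5, 33.4]}

# Ground truth for the synthetic "observed" concentration generator: a
# 3-compartment mammillary disposition model with first-order absorption,
# structurally distinct from the whole-body engine so that recovery tests are
# not self-fulfilling.  Apparent (F-folded) parameters at the reference body
# weight; clearances scale with (BW/ref)^0.75, volumes with BW/ref.  The
# terminal half-life target is the printed cohort median for each site.
observation_truth:
  reference_body_weight: 55.0
  ka: 0.5                 # 1/h
  lag_time: 0.5           # h
  cl_f: 80.0              # L/h
  v1_f: 1800.0            # L
  q2_f: 310.0             # L/h
  v2_f: 17000.0           # L
  q3_f: 95.0              # L/h
  v3_f: 19489.0           # L  (terminal t1/2 = 17.9 days at reference)
  half_life_target_days: {sudan: 17.9, thailand: 17.8}
  iiv_cv: {cl: 0.35, v: 0.30, ka: 0.40}
  residual_cv: 0.15
  lloq_ng_ml: 1.5
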