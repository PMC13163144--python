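# Gestational-age covariate models for a healthy pregnant population.
#
# Each scalar parameter follows
#     value(GA) = baseline + poly[0]*GA + poly[1]*GA**2      (GA in weeks)
# with GA = 0 reproducing the non-pregnant baseline exactly.  `cv` is the
# lognormal between-subject coefficient of variation used by stochastic
# sampling (population CVs are not reported for this population; these
# defaults are documented assumptions, see docs/methods.md).
#
# The quadratic forms and the direction/magnitude of each change follow the
# published longitudinal descriptions of pregnancy physiology (term weight
# gain ~ +15 kg, cardiac output ~ +30%, plasma-volume expansion ~ +1.5 L,
# albumin ~ -25%, alpha-1 acid glycoprotein mildly decreased, GFR ~ +45%,
# hematocrit dilution ~ -5 points).  Coefficients are editable.

scalars:
  body_weight:            # kg
    baseline: 61.1
    poly: [0.2409, 0.0038]
    cv: 0.08
  height:                 # cm (no systematic gestational change)
    baseline: 163.0
    poly: [0.0, 0.0]
    cv: 0.035
  cardiac_output:         # L/h; non-decreasing on 0-42 weeks
    baseline: 301.0
    poly: [4.90, -0.0583]
    cv: 0.10
  hematocrit:             # fraction
    baseline: 0.391
    poly: [-0.0005, -0.000021]
    cv: 0.05
  serum_albumin:          # g/L; monotone non-increasing
    baseline: 45.8
    poly: [-0.1775, -0.00214]
    cv: 0.06
  alpha1_acid_glycoprotein:   # g/L
    baseline: 0.73
    poly: [-0.0025, 0.0]
    cv: 0.15
  glomerular_filtration_rate: # mL/min
    baseline: 114.0
    poly: [3.10, -0.047]
    cv: 0.12

# Baseline organ volumes (L) for the reference non-pregnant woman (sum within
# 10% of baseline body weight at ~1 kg/L).  Smaller organs are lumped into
# "rest"; during gestation the maternal weight gain is allocated to adipose,
# "rest" (uterus, mammary tissue, products of conception) and plasma.
organ_volumes:
  baseline:
    adipose: 18.0
    bone: 7.8
    brain: 1.30
    gut: 1.10
    heart: 0.30
    kidney: 0.28
    liver: 1.40
    lung: 0.95
    muscle: 17.5
    skin: 2.30
    spleen: 0.15
    rest: 5.00
    plasma: 2.40
  pregnancy_gain_allocation:
    adipose: 0.40
    rest: 0.50
    plasma: 0.10
  cv: 0.05          # residual per-organ lognormal CV on top of weight scaling

# Blood-flow fractions of cardiac output.  The lung receives the entire
# cardiac output in series; the fractions below are the parallel systemic
# distribution and sum to 1 ("plasma" is a direct arteriovenous shunt term
# standing for non-tissue flow).  Fractions are held constant with GA and the
# absolute flows scale with the gestational cardiac output.
blood_flow_fractions:
  adipose: 0.085
  bone: 0.05
  brain: 0.12
  gut: 0.145
  heart: 0.045
  kidney: 0.17
  liver: 0.065        # hepatic artery only; portal inflow = gut + spleen
  muscle: 0.12
  skin: 0.05
  spleen: 0.03
  rest: 0.10
  plasma: 0.02
flow_fraction_cv: 0.05
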