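# Methods

This note documents the models, parameters, numerical choices and known
limitations of `ppqtwin`. Everything quantitative stated here is computed by
the test suite or by `scripts/acceptance.py`; nothing is quoted from
external sources as a result of this package.

## Pregnancy physiology model

Maternal physiology is described by quadratic gestational-age (GA)
polynomials around a non-pregnant baseline,
`value(GA) = baseline + a1·GA + a2·GA²` with GA in weeks, for body weight,
height, cardiac output, hematocrit, serum albumin, alpha-1 acid glycoprotein
and glomerular filtration rate. GA = 0 reproduces the baseline exactly. The
coefficients live in `src/ppqtwin/data/physiology_coefficients.yaml` and are
calibrated to the well-described direction and magnitude of gestational
change in healthy women: roughly +15 kg body weight at term, +30% cardiac
output (constrained non-decreasing over 0–42 weeks), −25% albumin
(monotone non-increasing), +45% GFR, ~5-point hematocrit dilution, ~1.5 L
plasma-volume expansion. They are configuration, not code: a user with a
preferred published covariate model can edit the YAML.

Organ volumes cover a fixed 13-compartment set (adipose, bone, brain, gut,
heart, kidney, liver, lung, muscle, skin, spleen, a lumped "rest", plasma).
Baseline volumes sum to within 10% of baseline body weight at ~1 kg/L;
gestational weight gain is allocated 40% adipose / 50% rest (uterus,
mammary tissue, products of conception) / 10% plasma. Blood flows are
fractions of cardiac output (the lung carries the whole cardiac output in
series; a small "plasma" fraction is a direct arteriovenous shunt); the
fractions are GA-constant, so absolute flows scale with the gestational
cardiac output and systemic flows sum to cardiac output exactly.

Between-subject variability is mean-preserving lognormal per parameter.
Population CVs for this pregnancy population are not published; the
defaults (3.5–15% depending on the parameter, see the YAML) are assumptions
chosen at the scale reported for comparable adult populations, and are
re-scalable (`cv_scale`, with 0 reproducing the mean exactly). Organ volumes
co-scale with the sampled body weight plus a 5% per-organ CV; flows are
perturbed by 5% and renormalized to the sampled cardiac output. Covariates
are sampled independently — the correlation structure of the reference
population library (e.g., weight–height) is not public, and this divergence
is deliberate and documented. Sampled hematocrit is clipped to (0.16, 0.54)
to keep degenerate draws physiological.

## Compound model

The piperaquine file (`src/ppqtwin/data/piperaquine_phosphate.yaml`) is pure
configuration. Physicochemistry follows the open piperaquine literature:
lipophilic diprotic base (logP 6.2, pKa 8.6/6.5), very highly protein-bound
(fu = 0.005), blood:plasma ratio 0.9. Two salt-to-base dose conversions are
supported and neither is asserted as the trials' convention: the anhydrous
tetraphosphate mass ratio 535.5/927.5 ≈ 0.5774, and the factor implied by
the published cohort dose summaries, 10.24/17.57 ≈ 0.5828 (the default, so
generated base doses reproduce the printed base-dose means).

Tissue:plasma partition coefficients use the standard tissue-composition
method for a moderate-to-strong base: extracellular/intracellular water with
pH-partitioning, neutral lipid and phospholipid partitioning, and
association with acidic phospholipids calibrated from the blood-cell
partition implied by the blood:plasma ratio. A single scalar (`kp_scalar`)
multiplies all predicted Kp; with the default 3.0 the predicted Vss is
~335 L/kg and the simulated terminal half-life ~31 days — a very large
volume, multi-compartment kinetics and a multi-week half-life, as expected
for piperaquine. A user-supplied Kp table is accepted as an alternative.

Clearance supports two modes. The default is a whole-body apparent oral
clearance (CL/F) of 130 L/h at a 75-kg reference with allometric exponent
0.75, calibrated during development so the virtual pregnant population's
NCA-derived CL/F lands at ~120 L/h — the scale at which a
healthy-population piperaquine model sits, and deliberately above the
synthetic "observed" truth (below), reproducing the known tendency of such
models to overestimate piperaquine clearance. The alternative is hepatic
intrinsic CYP3A4 clearance through the well-stirred liver model (portal
first pass emerges structurally).

## Whole-body engine

The engine is a perfusion-limited whole-body model: venous and arterial
blood pools (split 2:1 from the blood volume implied by plasma volume and
hematocrit), lung in series, eleven parallel tissues with gut and spleen
draining through the liver (portal vein), a first-order absorption depot
with lag emptying into the liver, and elimination either from venous blood
(CL/F mode) or in the liver (intrinsic mode). Internal units are mg, L, h;
output is venous plasma ng/mL.

All kinetics are linear, so the system is a linear time-invariant ODE and
the default integrator propagates each inter-dose segment *exactly* via the
eigendecomposition of the system matrix (with a `scipy.linalg.expm` fallback
if the eigenbasis is ill-conditioned). This is faster than step control,
makes superposition and dose-proportionality hold to machine precision, and
reduces mass-balance error to round-off (the test suite asserts < 0.1%; in
practice ~1e-14). Dose events are state jumps at event time + lag, never
impulse approximations. A conventional stiff route (`method="ode"`,
LSODA with restarts at dose events, rtol 1e-8, atol 1e-10 mg) is kept as an
independent cross-check and is what the tolerance-sensitivity test
exercises. Negative states beyond 1e-9 of the administered dose abort the
simulation rather than being clipped.

A degenerate `one_compartment` structure (whole body as a single well-mixed
volume, all Kp = 1) exists purely to pin the engine against the closed-form
one-compartment oral solution.

## Virtual twins

Per patient: `n_subjects` × `n_trials` virtual individuals (default
10 × 10 = 100, organized on a retained trial/subject grid so either
aggregation reading is possible). Physiology is sampled at exactly the
record's age and GA; the absolute dose is mg/kg × the twin's sampled weight,
converted salt→base, dosed at 0/24/48 h (the trials specify once daily for
three days without clock times). Seeding uses one master seed with a
substream per (patient, trial, subject) via `SeedSequence` spawn keys and a
CRC-32 patient key, so adding patients never perturbs other patients'
draws. Body weight is individualizable (`pin_body_weight=True` rescales the
sampled subject to the observed weight) but off by default — the default
replicates the stochastic-weight behavior whose consequences the assessment
statistics are designed to expose. Twin-set summaries are pointwise mean (or
median) with a 2.5–97.5 percentile band.

## NCA

Linear-up/log-down trapezoid with matching (exponential-down) interpolation
at window boundaries, which makes window additivity exact. Terminal slope:
log-linear regression over the last n ≥ 3 quantifiable points after Tmax
(Tmax excluded), n chosen to maximize adjusted R²; manual point-range
override available. AUC(0–∞) adds C_last/λz; CL/F = dose/AUC(0–∞). LLOQ
rule (configurable): BLQ before Tmax → 0, after Tmax → excluded. Day-7 is
168 h after the first dose (Day n = 24·n h); observed values further than
6 h from a sample are flagged. Boundary-window concentrations at exactly
24/48/72 h are interpolated when not sampled.

## Assessment statistics

As defined in the README: dose-normalized AUC, R_AUC, MFE
(ratio of arithmetic means), PE and RD, and the strict >30 ng/mL Day-7
threshold. The two-fold band is inclusive at 0.5 and 2.0 by default
(configurable to exclusive). The predicted summary entering every
comparison is the mean of the 100 twin profiles (median optional).
Predicted "clearance up to Day 7" is operationalized as NCA CL/F with
extrapolation on each twin profile, averaged. Trimester strata: second =
13–28 weeks, third = >28 weeks; generated records carry an explicit
trimester label (used in preference to the GA-derived one) because the
published cohort table's third-trimester range extends down to 26 weeks
while its row label says 28–40.

## Synthetic trials

Individual-level demographics are not published, only summaries. Records
are synthesized by pinning the printed range endpoints and solving a single
power-transform exponent of uniform draws (a max-entropy-style adjustment)
so the sample mean hits the printed mean exactly; trimester group sizes and
GA ranges are generated per group. The frozen fixture seed (20260921) is
part of the study definition.

The "observed" concentration generator is a 3-compartment mammillary
disposition model with first-order absorption — structurally different from
the whole-body engine so that recovery experiments are not self-fulfilling.
Apparent (F-folded) parameters at a 55-kg reference: CL/F 80 L/h, V1 1800 L,
Q2 310 L/h, V2 17,000 L, Q3 95 L/h, V3 tuned per site so the reference
terminal half-life equals the cohort median (17.9 days Sudan, 17.8 days
Thailand). Clearances scale with weight^0.75, volumes with weight.
Between-subject variability: lognormal, CV 35% on CL, 30% shared across
volumes, 40% on ka; proportional residual error CV 15%; LLOQ 1.5 ng/mL with
censored samples stored as 0. These values emulate the published shape of
piperaquine kinetics in pregnant women (multi-phasic decline, Day-7
concentrations spanning tens of ng/mL, CL/F near 90 L/h).

What the generator does *not* emulate: malaria-disease effects on clearance
(CYP3A4 suppression), fed/fasted differences, dose–weight correlation from
tablet-based dosing, within-subject occasion variability, and any real
correlation structure among demographics. Passing tests therefore
demonstrate that the pipeline's machinery is correct and that its statistics
recover known truths under realistic noise — not that the default compound
file would reproduce any specific clinical dataset.

## Problem sizes and determinism

The shipped analysis runs the full design (36 patients × 100 profiles on
the complete trial sampling schedules) in a few seconds thanks to the exact
propagator. Statistical tests use 50–200 replicates at reduced designs
(e.g., 6 × 6 twins, 8 patients for the null end-to-end experiment), sizes
chosen so Monte-Carlo error is comfortably below the asserted tolerances.
All stochastic tests and scripts are seeded; hypothesis profiles are
derandomized.

## Known limitations

- The gestational polynomial coefficients are plausible calibrations, not a
  fitted reproduction of any specific published covariate model.
- No fetal/placental sub-compartments; no disease physiology; no
  enterohepatic recirculation; no saturable absorption (linearity is
  assumed across the narrow therapeutic dose range, consistent with the
  workflow's own dose-normalization step).
- Both cohorts are modeled as fasted; the Thai cohort's fed status is
  unknown.
- Per-cohort predicted CL/F differences beyond allometric weight scaling are
  not modeled.
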