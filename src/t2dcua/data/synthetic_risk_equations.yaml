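# SYNTHETIC risk-equation fixture.
#
# These are NOT the published UKPDS-82 coefficient values (which are external
# to this package and must be supplied by the user for a faithful
# re-analysis). The equations have the same structural forms the outcomes
# model family uses — Weibull/exponential proportional hazards over diabetes
# duration for complications, Gompertz over attained age for mortality, a
# logistic annual probability for ulcers — with coefficients chosen once so
# that a 1000-patient cohort aged ~60 with HbA1c ~8% yields complication
# incidence and (discounted) life expectancy of realistic magnitude.
# Schema: see t2dcua.risk_engine.load_parameter_set.

metadata:
  label: synthetic-demo
  provenance: "synthetic fixture shipped with t2dcua; not UKPDS 82"

complications:
  chf:
    form: weibull_ph
    time_axis: duration
    shape: 1.3
    intercept: -11.1
    coefficients: {age: 0.030, hba1c: 0.130, bmi: 0.040, hist_mi: 0.60}
  ihd:
    form: exponential_ph
    time_axis: duration
    intercept: -8.4
    coefficients: {age: 0.028, hba1c: 0.120, smoker: 0.30, female: -0.20}
  mi:
    form: weibull_ph
    time_axis: duration
    shape: 1.1
    intercept: -9.3
    coefficients: {age: 0.032, hba1c: 0.130, smoker: 0.40, hist_ihd: 0.60, female: -0.30}
  stroke:
    form: weibull_ph
    time_axis: duration
    shape: 1.2
    intercept: -11.0
    coefficients: {age: 0.050, hba1c: 0.100, smoker: 0.35, hist_mi: 0.30}
  amputation:
    form: exponential_ph
    time_axis: duration
    intercept: -9.5
    coefficients: {hba1c: 0.180, smoker: 0.30, duration: 0.030, hist_ulcer: 0.80}
  renal_failure:
    form: weibull_ph
    time_axis: duration
    shape: 1.4
    intercept: -12.9
    coefficients: {age: 0.030, hba1c: 0.150, bmi: 0.020}
  blindness:
    form: exponential_ph
    time_axis: duration
    intercept: -9.3
    coefficients: {hba1c: 0.150, duration: 0.020, age: 0.010}
  ulcer:
    form: logistic
    time_axis: duration
    intercept: -7.6
    coefficients: {hba1c: 0.180, bmi: 0.030, smoker: 0.30}

mortality:
  all_cause:
    form: gompertz
    time_axis: age
    shape: 0.09
    intercept: -10.45
    coefficients:
      hba1c: 0.050
      smoker: 0.30
      female: -0.15
      hist_mi: 0.60
      hist_stroke: 0.60
      hist_chf: 0.70
      hist_renal_failure: 1.00
      hist_amputation: 0.70
      hist_ihd: 0.30

# Risk-factor drift between cycles (age and diabetes duration always +1/yr).
# Default: HbA1c, BMI and weight held constant (the published trajectory
# equations are external); the treatment-switch step then restores exactly
# the untreated HbA1c in every arm. Drift/mean-reverting rules are available
# via drift_per_year / kappa+target.
riskfactor_paths:
  hba1c: {drift_per_year: 0.0}
  bmi: {drift_per_year: 0.0}
  weight: {drift_per_year: 0.0}
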