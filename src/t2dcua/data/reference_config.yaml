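# Reference run configuration.
# Every numeric default is annotated with its source: published baseline
# cohort table, efficacy meta-analysis table, drug price table, cost/utility
# table, or sensitivity-range table of the underlying cost-utility study.
# Values marked "placeholder" are not published anywhere and must be
# overridden for a faithful re-analysis.

seed: 20220218

cohort:
  n_patients: 1000            # simulated patients per arm
  mean_age: 60.62             # years, baseline cohort table
  prop_female: 0.4076         # 40.76% female
  race_props: {white: 0.627, black: 0.180, other: 0.193}   # "other" includes race-unavailable
  median_duration: 9.99       # years of diabetes
  mean_hba1c: 8.07            # % — the text's simulation-cohort mean; the
                              # baseline table prints 8.2 (range 8.0-8.5); configurable
  hba1c_range: [8.0, 8.5]
  mean_bmi: 31.2              # kg/m^2
  mean_weight: 87.63          # kg
  sd_weight: 9.17             # the only published dispersion
  height: 1.68                # metres
  prop_mi_history: 0.125
  prop_angina_history: 0.076  # recorded as ischaemic-heart-disease history
  prop_smoking: 0.107
  # unpublished SDs default to 0 (homogeneous cohort except weight)
  sd_age: 0.0
  sd_duration: 0.0
  sd_hba1c: 0.0
  sd_bmi: 0.0

# HbA1c mean difference vs placebo with 95% CI (percentage points), and the
# 2020 Chinese bid prices behind the annual acquisition costs.
arms:
  - name: "sc. SEMA"
    hba1c_md: -1.33
    ci_lower: -1.50
    ci_upper: -1.16
    therapy:
      kind: semaglutide_escalation
      price_cny: 1120.00       # per pen (1.34 mg/ml, 1.5 ml)
      usable_mg_per_pen: 2.0   # two 1.0 mg maintenance doses per pen
  - name: "DULA"
    hba1c_md: -0.89
    ci_lower: -1.05
    ci_upper: -0.73
    therapy:
      kind: fixed_box
      price_cny: 298.00        # per box, two 1.5 mg pieces
      doses_per_box: 2
  - name: "e-r EXEN"
    hba1c_md: -0.80
    ci_lower: -0.99
    ci_upper: -0.62
    therapy:
      kind: fixed_box
      price_cny: 2068.86       # per box, four 2 mg single-dose kits
      doses_per_box: 4

# Synthetic fixture: NOT the published UKPDS-82 coefficient values (those are
# external); replace with a faithful parameter file for a real re-analysis.
risk_equations_file: synthetic_risk_equations.yaml

economics:
  discount_rate: 0.05              # 5%/year on costs and utilities
  horizon_years: 40
  fx_cny_per_usd: 6.8974           # 2020
  dosing_weeks_per_year: 48        # reproduces all printed annual costs
  treatment_duration_years: 5      # then switch to basal insulin
  post_switch_annual_cost: 400.0   # $/yr insulin glargine U100 — PLACEHOLDER (unpublished), arm-invariant
  management_annual_cost: 1463.01  # $/yr T2D management in the absence of complications
  initial_utility: 0.876           # no-complication utility
  hba1c_rebound_at_switch: true    # arm effects end at the insulin switch
  complications:                   # $ and utility-decrement magnitudes
    ihd:           {fatal_cost: 0.00,    nonfatal_cost: 6451.66,  event_decrement: 0.090, subsequent_cost: 1151.78,  subsequent_decrement: 0.090}
    mi:            {fatal_cost: 8052.81, nonfatal_cost: 8052.81,  event_decrement: 0.055, subsequent_cost: 496.72,   subsequent_decrement: 0.236}
    chf:           {fatal_cost: 3110.07, nonfatal_cost: 3110.07,  event_decrement: 0.236, subsequent_cost: 1644.48,  subsequent_decrement: 0.236}
    stroke:        {fatal_cost: 2323.34, nonfatal_cost: 3136.05,  event_decrement: 0.164, subsequent_cost: 552.89,   subsequent_decrement: 0.326}
    amputation:    {fatal_cost: 4546.19, nonfatal_cost: 4546.19,  event_decrement: 0.380, subsequent_cost: 4425.28,  subsequent_decrement: 0.380}
    blindness:     {fatal_cost: 0.00,    nonfatal_cost: 2420.92,  event_decrement: 0.157, subsequent_cost: 1790.97,  subsequent_decrement: 0.157}  # fatal cost unreported -> 0
    renal_failure: {fatal_cost: 0.00,    nonfatal_cost: 15055.46, event_decrement: 0.400, subsequent_cost: 15055.46, subsequent_decrement: 0.400}
    ulcer:         {fatal_cost: 0.00,    nonfatal_cost: 2368.13,  event_decrement: 0.059, subsequent_cost: 833.47,   subsequent_decrement: 0.059}  # fatal cost unreported -> 0

threshold:
  gdp_per_capita_cny: 72447.0   # 2020 GDP per capita (= $10,503.52)
  multiplier: 3.0               # lambda = 3x GDP per capita = $31,510.57/QALY
  fx: 6.8974

# One-way sensitivity battery (20 parameters): low/high from the published
# sensitivity-range table. Where a single disutility score is published for a
# complication whose event-year and subsequent-year decrements coincide, both
# are varied together.
sensitivity:
  - {name: "Discount rate",            kind: rate,    paths: [economics.discount_rate], low: 0.03, high: 0.08}
  - {name: "Initial utility",          kind: utility, paths: [economics.initial_utility], low: 0.78, high: 0.92}
  - {name: "Treatment time",           kind: years,   paths: [economics.treatment_duration_years], low: 4, high: 6}
  - {name: "Time horizon",             kind: years,   paths: [economics.horizon_years], low: 30, high: 50}
  - {name: "IHD per year cost",        kind: cost,    paths: [economics.complications.ihd.subsequent_cost], low: 921.43, high: 1382.14}
  - {name: "MI per year cost",         kind: cost,    paths: [economics.complications.mi.subsequent_cost], low: 314.79, high: 678.65}
  - {name: "CHF per year cost",        kind: cost,    paths: [economics.complications.chf.subsequent_cost], low: 1368.42, high: 2871.11}
  - {name: "Stroke per year cost",     kind: cost,    paths: [economics.complications.stroke.subsequent_cost], low: 486.36, high: 903.12}
  - {name: "Blindness per year cost",  kind: cost,    paths: [economics.complications.blindness.subsequent_cost], low: 1560.17, high: 2021.65}
  - {name: "ESRD per year cost",       kind: cost,    paths: [economics.complications.renal_failure.subsequent_cost], low: 14347.15, high: 15890.96}
  - {name: "Amputation per year cost", kind: cost,    paths: [economics.complications.amputation.subsequent_cost], low: 0.00, high: 7862.31}
  - {name: "Ulcer per year cost",      kind: cost,    paths: [economics.complications.ulcer.subsequent_cost], low: 666.77, high: 1000.16}
  - {name: "IHD disutility",           kind: utility, paths: [economics.complications.ihd.subsequent_decrement, economics.complications.ihd.event_decrement], low: 0.081, high: 0.099}
  - {name: "MI disutility",            kind: utility, paths: [economics.complications.mi.subsequent_decrement], low: 0.026, high: 0.446}
  - {name: "CHF disutility",           kind: utility, paths: [economics.complications.chf.subsequent_decrement, economics.complications.chf.event_decrement], low: 0.026, high: 0.446}
  - {name: "Stroke disutility",        kind: utility, paths: [economics.complications.stroke.subsequent_decrement], low: 0.036, high: 0.616}
  - {name: "Blindness disutility",     kind: utility, paths: [economics.complications.blindness.subsequent_decrement, economics.complications.blindness.event_decrement], low: 0.007, high: 0.307}
  - {name: "ESRD disutility",          kind: utility, paths: [economics.complications.renal_failure.subsequent_decrement, economics.complications.renal_failure.event_decrement], low: 0.19, high: 0.61}
  - {name: "Amputation disutility",    kind: utility, paths: [economics.complications.amputation.subsequent_decrement, economics.complications.amputation.event_decrement], low: 0.204, high: 0.496}
  - {name: "Ulcer disutility",         kind: utility, paths: [economics.complications.ulcer.subsequent_decrement, economics.complications.ulcer.event_decrement], low: 0.0531, high: 0.0649}

psa:
  n_iter: 1000                # Monte-Carlo iterations
  resample_kinds: [cost, utility]
  resample_effects: true

pricing:
  tol_icur: 0.01              # $/QALY
  tol_price: 0.01             # $/year
  max_iter: 60
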