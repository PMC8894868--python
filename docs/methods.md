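# Methods

## Model structure and assumptions

The simulation is an individual-level, annual-cycle state-transition model
of type 2 diabetes in the UKPDS Outcomes Model (v2) tradition. A patient
state carries continuous risk factors (age, diabetes duration, HbA1c, BMI,
weight, height), fixed attributes (sex, race, smoking), a per-complication
first-event history, and vital status. Eight complications are modelled —
congestive heart failure, ischaemic heart disease, myocardial infarction,
stroke, amputation, renal failure, blindness, diabetic ulcer — plus
all-cause mortality. Only first events are modelled per complication,
matching a cost/utility catalogue that distinguishes the event year from all
subsequent years; recurrent events are out of scope.

Within a cycle the engine evaluates the complications in a fixed, documented
order (CHF → IHD → MI → stroke → amputation → renal failure → blindness →
ulcer), draws one uniform per equation, then evaluates mortality with the
cycle's new events already present in the covariates, and finally advances
the risk factors. Death terminates the trajectory at that cycle. There is no
half-cycle correction: events and death happen at the end of the year, the
death year counts as a lived life-year, and (by the no-partial-year-utility
convention) contributes zero utility while still incurring its annual costs,
with fatal event costs replacing non-fatal ones.

One uniform is drawn per equation per cycle *whether or not the event can
still fire*. This keeps the random-number streams aligned between treatment
arms (common random numbers): the same patient sees the same uniforms in
every arm, so a drug that lowers every event probability can only remove
events, never add them. Between-arm differences are therefore monotone in
the treatment effect and are not inflated by resampling noise. Per-patient
substreams are spawned from the root seed by patient index
(`SeedSequence(seed, spawn_key=(stream, i))`), so enlarging the cohort never
reshuffles earlier patients.

## Risk equations

Equations are data, not code. Each specifies a family — exponential, Weibull
or Gompertz proportional hazards, or a direct logistic annual probability —
an intercept, a named coefficient map resolved against the patient state,
and for Weibull/Gompertz a shape parameter. The PH families integrate the
hazard over one cycle on the equation's time axis (diabetes duration for
complications, attained age for mortality):

```
exponential  p = 1 − exp(−exp(LP))
Weibull      p = 1 − exp(−exp(LP)·((d+1)^γ − d^γ))
Gompertz     p = 1 − exp(−exp(LP)/γ·(e^{γ(d+1)} − e^{γd}))
```

These closed forms are verified in the test suite against numerical
quadrature of the hazard to < 1e−8. Linear predictors are capped at 700
before exponentiation (probabilities saturate at 1 well before the cap
matters), and the logistic uses the numerically stable sigmoid.

The published UKPDS-82 coefficient values are external and are not
redistributed here. The shipped `synthetic_risk_equations.yaml` is a
synthetic fixture: identical structural forms, coefficient magnitudes chosen
once so that a cohort aged ~60 with HbA1c ~8% shows complication incidence
of a few percent to ~10% over 40 years and discounted life expectancy near
11.7 years. Passing tests under this fixture demonstrate that the machinery
is correct and that the qualitative decision findings follow from the price
and efficacy structure; they do not re-estimate the published absolute
totals, which require the genuine coefficient file.

## Risk-factor trajectories

HbA1c, BMI and weight follow per-cycle deterministic rules
`x' = x + drift + κ(target − x)`, plus an optional one-off step at a
scheduled cycle. The default fixture holds all three constant (the published
trajectory equations are external). The treatment effect is applied to
baseline HbA1c; when therapy switches to basal insulin at the end of the
treatment duration (5 years), a scheduled step of equal magnitude and
opposite sign restores the untreated HbA1c, so all arms share the same
glycaemia afterwards — consistent with the arm-invariant post-switch therapy
assumption. The rebound is configurable (`hba1c_rebound_at_switch`).

## Cohort generator

The generator emulates the published baseline profile: Bernoulli draws for
sex (40.76% female), race (62.7/18.0/19.3% white/black/other), prior MI
(12.5%, recorded as MI history), prior angina (7.6%, recorded as IHD
history) and smoking (10.7%); Normal body weight (87.63 ± 9.17 kg); and
degenerate (all-at-the-mean) age 60.62, duration 9.99, HbA1c 8.07 and BMI
31.2, because no dispersion is published for these — optional SDs can be
configured. The source text and its baseline table disagree on mean HbA1c
(8.07% vs 8.2%); the text's simulation-cohort value 8.07 is the default and
the table's value is one config line away. No covariate correlation is
modelled (none is published). What the generator does *not* emulate:
real-world heterogeneity in age/duration/glycaemia, secular drug-adherence
patterns, or competing non-diabetes morbidity beyond the all-cause mortality
equation — so passing tests say nothing about transportability to a real
cohort.

Treatment effects are the published HbA1c mean differences vs placebo with
95% CIs; probabilistic draws use Normal(MD, SE) with SE = CI width / 3.92
(normal approximation, 2 × 1.96).

## Economic conventions

- **Dosing weeks.** 48 dosing weeks per year. This convention reproduces all
  four published annual acquisition costs exactly: DULA ¥298/box of 2 → 24
  boxes → $1036.91; e-r EXEN ¥2068.86/box of 4 → 12 boxes → $3599.37
  (printed 3599.38, sub-cent rounding); sc. SEMA at ¥560/mg from a 2.0
  mg-usable pen → 43 mg escalation year $3491.17 and 48 mg maintenance year
  $3897.12.
- **Semaglutide pen content.** 2.0 usable mg (two 1.0 mg maintenance doses),
  not the nominal 2.01 mg — only 2.0 reproduces the published costs.
- **Post-switch therapy.** The basal-insulin annual cost is not published.
  The default, $400/year, is a placeholder of plausible magnitude for
  insulin glargine U100 in China in 2020; it is arm-invariant, so it affects
  incremental results only through small survival differences. Override it
  in the config for any substantive analysis.
- **Discounting.** End-of-cycle: cycle *t* is weighted by (1+r)^−t, r = 5%.
- **Utility.** Additive decrements from the 0.876 no-complication utility,
  clamped at 0 if stacked decrements exceed it; the dead score 0.
- **Blank fatal costs.** The published table leaves fatal costs for
  blindness and ulcer blank; they are configured as 0.
- **Table 5 vs Table 4 sub-cent differences** (MI 496.71/496.72, CHF
  1644.49/1644.48, amputation 4425.26/4425.28): the cost/utility table's
  values are the config baselines; the sensitivity table's values are the
  one-way ranges.

The published per-arm therapy-cost subtotals cannot be reconciled exactly
with any combination of the published annual drug costs, a 5-year switch and
5% discounting; the internal OM2 accounting is not recoverable from the
paper. Base-case totals under the synthetic fixture are therefore
directional, as are all simulated comparisons.

## Decision rules

Strict inequalities make the INMB sign and the verdict exactly equivalent:
ICUR = λ classifies as "not more cost-effective" (INMB = 0). Two situations
the published rules do not cover are resolved by standard CEA convention:
ΔQALY = 0 resolves by cost sign alone (cheaper wins, equal cost is
equivalent), and in the (−,−) quadrant A is favoured iff ICUR > λ (the
savings per QALY forgone exceed the threshold). λ is computed in yuan and
then converted (217,341/6.8974 = $31,510.57; converting first gives
31,510.56).

## Sensitivity analysis

One-way analysis reruns the full pipeline at each parameter's low and high
value (everything else at base, same seed), 20 parameters in the reference
battery; the default tornado metric is the INMB of a stated pair, which
remains defined where dominance makes the ICUR undefined. Where the
published battery lists a single "disutility score" for a complication whose
event-year and subsequent-year decrements coincide, both are varied
together. The scenario analysis reruns the pipeline at 10/20/30/40/50-year
horizons.

The PSA resamples, per iteration: complication costs (Gamma, moment-matched
to the mean and SE = range/3.92, with SE = 20% of the mean as the fallback
when no range exists), utility inputs and decrements (Beta, moment-matched),
and the three HbA1c effects (Normal from their CIs). The published analysis
names no distribution families; these are standard CEA practice and are
config-overridable. Patient-level noise is *not* resampled across iterations
(the simulation seed is fixed), so the CE-plane scatter isolates parameter
uncertainty; the PSA seed drives only the parameter draws. Quadrant
fractions are reported via the same verdict classifier as the base case and
partition to 1. Structural parameters (discount rate, horizon, treatment
time) are held at base in the PSA.

## Threshold price search

Bisection on the arm's annual cost over [0, current annual cost], reusing
the base-case trajectories (price does not alter events or QALYs) and
re-running only the cost accumulation. Stopping rules: |ICUR − λ| ≤ $0.01
per QALY, or price bracket ≤ $0.01 (which bounds the iteration count by
⌈log₂(range/0.01)⌉ ≈ 19 for a $3,900 range; max 60). When the bracket rule
fires, the achieved ICUR carries slack of about (discounted drug-years ×
$0.005)/|ΔQALY|. For the dose-escalation drug the escalation-year and
maintenance costs scale by one common factor, and the reported "annual cost"
is the maintenance year; relative to the maintenance cost the published
semaglutide threshold cost $1226.23 is a 68.5% cut, which does not match the
published 57.67% under any published annual-cost basis — both numbers are
surfaced, the discrepancy is documented, not resolved.

## Numerical and reproducibility choices

- Root seed → named substreams: cohort generation (spawn key 0), per-patient
  event draws (1, patient index), PSA parameter sampling (2).
- CSVs are written with fixed float formatting so identical configs and
  seeds produce byte-identical outputs; the run manifest records a SHA-256
  hash of the effective configuration.
- Degenerate inputs: zero-width CIs and zero-variance distributions return
  their mean; zero-cost inputs are excluded from Gamma resampling.

## Problem sizes

The reference configuration uses 1000 patients per arm, a 40-year horizon
and 1000 PSA iterations. The test suite exercises the same code paths at
reduced sizes chosen for quick iteration — 10,000 patients for the
constant-hazard life-expectancy recovery, 1000 × 40 years for the
directional end-to-end checks, 30–300 patients for pipeline mechanics, and
3–10 PSA iterations for reproducibility checks — with statistical
assertions stated in standard errors so they are size-aware.

## Known limitations

- The shipped risk-equation fixture is synthetic; absolute simulated totals
  are not comparable to the published ones until a UKPDS-82-faithful
  parameter file is supplied.
- First events only; no recurrent-event or post-event risk modification
  beyond history flags entering the linear predictors.
- Homogeneous-except-weight default cohort understates between-patient
  variance; published probabilistic intervals are not reproducible.
- Single currency conversion at ¥6.8974/$, no CPI engine, no societal costs.
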