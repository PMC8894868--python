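"""Annual-cycle individual-level simulation of diabetic complications and death.

The engine advances each simulated patient through annual cycles. In every
cycle it evaluates, in a fixed documented order, the annual probability of a
first event for each of the eight modelled complications (congestive heart
failure, ischaemic heart disease, myocardial infarction, stroke, amputation,
renal failure, blindness, diabetic ulcer), draws event occurrences, then
evaluates all-cause mortality with the cycle's events already reflected in
the covariates, and finally advances the continuous risk factors (age,
diabetes duration, HbA1c, BMI, weight) along configured trajectories.

Risk equations are pluggable data: each is a parametric hazard (exponential,
Weibull or Gompertz proportional hazards, or an annual logistic probability)
with a named coefficient map resolved against the patient state. Coefficient
values are supplied through a parameter file; the fixture set shipped with
the package is synthetic (see its metadata and ``docs/methods.md``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, InputError

# Complications in the fixed within-cycle evaluation order. Mortality is
# evaluated after all events so that this cycle's events feed the mortality
# covariates.
COMPLICATIONS: tuple[str, ...] = (
    "chf",
    "ihd",
    "mi",
    "stroke",
    "amputation",
    "renal_failure",
    "blindness",
    "ulcer",
)

#: substream labels for deterministic seeding (root seed -> SeedSequence spawn keys)
STREAM_COHORT = 0
STREAM_EVENTS = 1
STREAM_PSA = 2

_FORMS = ("exponential_ph", "weibull_ph", "logistic", "gompertz")


# ---------------------------------------------------------------------------
# patient state
# ---------------------------------------------------------------------------


@dataclass
class PatientState:
    """One simulated person's risk factors, event history and vital status.

    ``history`` maps each complication to the cycle of its first event
    (0 denotes a pre-baseline event, ``None`` denotes no event yet). An event
    recorded with the current cycle index is "this cycle's" event; anything
    earlier is post-event.
    """

    age: float
    female: bool
    race: str  # {"white", "black", "other"}
    duration: float
    hba1c: float
    bmi: float
    weight: float
    height: float
    smoker: bool
    history: dict[str, Optional[int]] = field(
        default_factory=lambda: {c: None for c in COMPLICATIONS}
    )
    alive: bool = True
    death_cycle: Optional[int] = None

    def __post_init__(self) -> None:
        if self.age < 0:
            raise InputError(f"age must be >= 0, got {self.age}")
        if self.hba1c <= 0:
            raise InputError(f"hba1c must be > 0, got {self.hba1c}")
        for c in COMPLICATIONS:
            self.history.setdefault(c, None)

    def covariates(self) -> dict[str, float]:
        """Flatten the state into the covariate vocabulary used by equations."""
        cov = {
            "age": float(self.age),
            "female": 1.0 if self.female else 0.0,
            "male": 0.0 if self.female else 1.0,
            "black": 1.0 if self.race == "black" else 0.0,
            "other_race": 1.0 if self.race == "other" else 0.0,
            "duration": float(self.duration),
            "hba1c": float(self.hba1c),
            "bmi": float(self.bmi),
            "weight": float(self.weight),
            "height": float(self.height),
            "smoker": 1.0 if self.smoker else 0.0,
        }
        for c in COMPLICATIONS:
            cov[f"hist_{c}"] = 0.0 if self.history.get(c) is None else 1.0
        return cov

    def events_in_cycle(self, cycle: int) -> tuple[str, ...]:
        return tuple(c for c in COMPLICATIONS if self.history.get(c) == cycle)

    def prior_events(self, cycle: int) -> tuple[str, ...]:
        return tuple(
            c
            for c in COMPLICATIONS
            if self.history.get(c) is not None and self.history[c] < cycle
        )

    def clone(self) -> "PatientState":
        return replace(self, history=dict(self.history))


# ---------------------------------------------------------------------------
# risk equations
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RiskEquation:
    """Parametric annual-risk equation for one outcome.

    ``form`` selects the hazard family; the annual probability integrates the
    hazard over one cycle on the equation's time axis (diabetes duration for
    the complication equations, attained age for mortality is the usual
    choice, controlled by ``time_axis``).
    """

    outcome: str
    form: str
    intercept: float
    coefficients: Mapping[str, float] = field(default_factory=dict)
    shape: Optional[float] = None
    time_axis: str = "duration"  # {"duration", "age"}

    def __post_init__(self) -> None:
        if self.form not in _FORMS:
            raise ConfigurationError(
                f"equation {self.outcome!r}: unknown form {self.form!r}; "
                f"expected one of {_FORMS}"
            )
        if self.form in ("weibull_ph", "gompertz"):
            if self.shape is None or self.shape <= 0:
                raise ConfigurationError(
                    f"equation {self.outcome!r}: form {self.form!r} requires shape > 0"
                )
        if self.time_axis not in ("duration", "age"):
            raise ConfigurationError(
                f"equation {self.outcome!r}: time_axis must be 'duration' or 'age'"
            )

    def linear_predictor(self, covariates: Mapping[str, float]) -> float:
        lp = self.intercept
        for name, coef in self.coefficients.items():
            try:
                lp += coef * covariates[name]
            except KeyError:
                raise ConfigurationError(
                    f"equation {self.outcome!r}: missing covariate {name!r}"
                ) from None
        return lp


def annual_event_probability(
    eq: RiskEquation, covariates: Mapping[str, float], duration: float
) -> float:
    """Probability of the event within the next annual cycle.

    ``duration`` is the elapsed time on the equation's time axis at the start
    of the cycle. The proportional-hazards forms integrate the hazard over
    [duration, duration + 1]:

    - exponential: ``1 - exp(-exp(LP))``
    - Weibull:     ``1 - exp(-exp(LP) * ((d+1)^shape - d^shape))``
    - Gompertz:    ``1 - exp(-exp(LP)/shape * (e^{shape*(d+1)} - e^{shape*d}))``
    - logistic:    ``1 / (1 + exp(-LP))`` (direct annual probability)
    """
    if duration < 0:
        raise InputError(f"duration must be >= 0, got {duration}")
    lp = eq.linear_predictor(covariates)
    if eq.form == "logistic":
        # numerically stable sigmoid
        if lp >= 0:
            return 1.0 / (1.0 + math.exp(-lp))
        e = math.exp(lp)
        return e / (1.0 + e)
    haz = math.exp(min(lp, 700.0))  # cap avoids overflow; p saturates at 1 anyway
    if eq.form == "exponential_ph":
        cum = haz
    elif eq.form == "weibull_ph":
        s = float(eq.shape)  # type: ignore[arg-type]
        cum = haz * ((duration + 1.0) ** s - duration**s)
    else:  # gompertz
        s = float(eq.shape)  # type: ignore[arg-type]
        cum = haz / s * (math.exp(s * (duration + 1.0)) - math.exp(s * duration))
    p = 1.0 - math.exp(-min(cum, 700.0))
    return min(max(p, 0.0), 1.0)


# ---------------------------------------------------------------------------
# risk-factor trajectories
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PathRule:
    """Deterministic per-cycle update rule for one continuous risk factor.

    ``x' = x + drift_per_year + kappa * (target - x)``, plus ``step_delta``
    once, at the end of cycle ``step_at_cycle`` (used e.g. to return HbA1c to
    its untreated level when therapy is switched).
    """

    drift_per_year: float = 0.0
    kappa: float = 0.0
    target: Optional[float] = None
    step_at_cycle: Optional[int] = None
    step_delta: float = 0.0

    def apply(self, x: float, cycle: Optional[int] = None) -> float:
        out = x + self.drift_per_year
        if self.kappa != 0.0:
            if self.target is None:
                raise ConfigurationError("PathRule with kappa != 0 requires a target")
            out += self.kappa * (self.target - x)
        if self.step_at_cycle is not None and cycle == self.step_at_cycle:
            out += self.step_delta
        return out


def progress_risk_factors(
    state: PatientState,
    paths: Mapping[str, PathRule],
    cycle: Optional[int] = None,
) -> PatientState:
    """Advance age/duration by one year and update HbA1c/BMI/weight in place
    of the configured drift rules. Deterministic given the state."""
    if not state.alive:
        raise InputError("cannot progress a dead patient")
    new = state.clone()
    new.age = state.age + 1.0
    new.duration = state.duration + 1.0
    for factor in ("hba1c", "bmi", "weight"):
        rule = paths.get(factor)
        if rule is not None:
            setattr(new, factor, rule.apply(getattr(state, factor), cycle))
    return new


# ---------------------------------------------------------------------------
# parameter set
# ---------------------------------------------------------------------------


@dataclass
class ParameterSet:
    """All risk equations plus risk-factor paths: the pluggable model inputs."""

    complications: dict[str, RiskEquation]
    mortality: dict[str, RiskEquation]
    riskfactor_paths: dict[str, PathRule] = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in COMPLICATIONS if c not in self.complications]
        if missing:
            raise ConfigurationError(
                f"parameter set is missing complication equations: {missing}"
            )
        if not self.mortality:
            raise ConfigurationError("parameter set needs at least one mortality equation")

    def with_hba1c_step(self, step_at_cycle: int, step_delta: float) -> "ParameterSet":
        """Copy with an extra one-off HbA1c step (therapy-switch rebound)."""
        paths = dict(self.riskfactor_paths)
        base = paths.get("hba1c", PathRule())
        paths["hba1c"] = replace(base, step_at_cycle=step_at_cycle, step_delta=step_delta)
        return ParameterSet(
            complications=self.complications,
            mortality=self.mortality,
            riskfactor_paths=paths,
            metadata=dict(self.metadata),
        )


def load_parameter_set(source) -> ParameterSet:
    """Build a :class:`ParameterSet` from a parsed mapping (YAML/TOML dialect).

    Schema::

        metadata: {label: ..., provenance: ...}
        complications:
          <name>: {form, intercept, shape?, time_axis?, coefficients: {cov: coef}}
        mortality:
          <name>: {form, intercept, shape?, time_axis?, coefficients: {...}}
        riskfactor_paths:
          <factor>: {drift_per_year?, kappa?, target?}
    """
    if not isinstance(source, Mapping):
        raise ConfigurationError("parameter set source must be a mapping")

    def _eq(name: str, spec: Mapping) -> RiskEquation:
        try:
            return RiskEquation(
                outcome=name,
                form=spec["form"],
                intercept=float(spec["intercept"]),
                coefficients={k: float(v) for k, v in (spec.get("coefficients") or {}).items()},
                shape=None if spec.get("shape") is None else float(spec["shape"]),
                time_axis=spec.get("time_axis", "duration"),
            )
        except KeyError as exc:
            raise ConfigurationError(f"equation {name!r}: missing field {exc}") from None

    comps = {n: _eq(n, s) for n, s in (source.get("complications") or {}).items()}
    mort = {n: _eq(n, s) for n, s in (source.get("mortality") or {}).items()}
    paths = {}
    for factor, spec in (source.get("riskfactor_paths") or {}).items():
        paths[factor] = PathRule(
            drift_per_year=float(spec.get("drift_per_year", 0.0)),
            kappa=float(spec.get("kappa", 0.0)),
            target=None if spec.get("target") is None else float(spec["target"]),
        )
    return ParameterSet(
        complications=comps,
        mortality=mort,
        riskfactor_paths=paths,
        metadata=dict(source.get("metadata") or {}),
    )


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CycleRecord:
    """Post-update snapshot of one annual cycle."""

    cycle: int
    state: PatientState
    events: tuple[str, ...]
    alive: bool


@dataclass
class Trajectory:
    """Per-cycle records of one simulated patient, ending at death or horizon."""

    records: list[CycleRecord]

    def __len__(self) -> int:
        return len(self.records)

    @property
    def life_years(self) -> int:
        # the cycle in which death occurs counts as a lived year (death at
        # end of cycle, annual-cycle model without half-cycle correction)
        return len(self.records)

    @property
    def death_cycle(self) -> Optional[int]:
        if self.records and not self.records[-1].alive:
            return self.records[-1].cycle
        return None

    def discounted_life_years(self, rate: float) -> float:
        return sum((1.0 + rate) ** (-r.cycle) for r in self.records)


def _patient_rng(seed: int, index: int) -> np.random.Generator:
    """Per-patient substream: stable under cohort-size changes."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(STREAM_EVENTS, index)))


def _time_on_axis(eq: RiskEquation, state: PatientState) -> float:
    return state.age if eq.time_axis == "age" else state.duration


def simulate_patient(
    state: PatientState,
    params: ParameterSet,
    horizon: int,
    rng: np.random.Generator,
) -> Trajectory:
    """Simulate one patient for up to ``horizon`` annual cycles.

    Within each cycle the complication equations are evaluated in the fixed
    order of :data:`COMPLICATIONS` (first events only), then mortality with
    this cycle's events already in the covariates, then the risk factors
    advance. One uniform is drawn per equation per cycle regardless of
    whether it can fire, so random-number streams stay aligned across arms
    (common random numbers).
    """
    if horizon < 1:
        raise InputError(f"horizon must be >= 1, got {horizon}")
    st = state.clone()
    records: list[CycleRecord] = []
    for cycle in range(1, horizon + 1):
        cov = st.covariates()
        events: list[str] = []
        for comp in COMPLICATIONS:
            u = rng.random()
            if st.history.get(comp) is not None:
                continue
            eq = params.complications[comp]
            p = annual_event_probability(eq, cov, _time_on_axis(eq, st))
            if u < p:
                st.history[comp] = cycle
                cov[f"hist_{comp}"] = 1.0
                events.append(comp)
        died = False
        for eq in params.mortality.values():
            u = rng.random()
            p = annual_event_probability(eq, cov, _time_on_axis(eq, st))
            if u < p:
                died = True
        if died:
            st.alive = False
            st.death_cycle = cycle
        records.append(CycleRecord(cycle, st.clone(), tuple(events), st.alive))
        if died:
            break
        st = progress_risk_factors(st, params.riskfactor_paths, cycle)
    return Trajectory(records)


def simulate_cohort(
    cohort: Sequence[PatientState],
    params: ParameterSet,
    horizon: int,
    seed: int,
    discount_rate: float = 0.05,
) -> tuple[list[Trajectory], dict[str, float]]:
    """Simulate every patient on an independent, index-keyed substream.

    Returns the trajectories and a summary with mean undiscounted and mean
    discounted life expectancy (both reported; discounting at end of cycle).
    """
    if len(cohort) == 0:
        raise InputError("cohort must be non-empty")
    trajectories = [
        simulate_patient(state, params, horizon, _patient_rng(seed, i))
        for i, state in enumerate(cohort)
    ]
    le = float(np.mean([t.life_years for t in trajectories]))
    le_disc = float(np.mean([t.discounted_life_years(discount_rate) for t in trajectories]))
    return trajectories, {
        "mean_le_undiscounted": le,
        "mean_le_discounted": le_disc,
    }


def trajectories_to_frame(trajectories: Iterable[Trajectory]) -> pd.DataFrame:
    """Long-format export: one row per patient-cycle with event flags."""
    rows = []
    for pid, traj in enumerate(trajectories):
        for rec in traj.records:
            row = {
                "patient": pid,
                "cycle": rec.cycle,
                "alive": rec.alive,
                "age": rec.state.age,
                "hba1c": rec.state.hba1c,
            }
            for c in COMPLICATIONS:
                row[f"event_{c}"] = c in rec.events
                row[f"hist_{c}"] = rec.state.history.get(c) is not None
            rows.append(row)
    return pd.DataFrame(rows)
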