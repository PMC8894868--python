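"""Synthetic baseline cohort and treatment-effect sampling.

Generates the simulated type-2-diabetes cohort from a published baseline
profile (means/proportions of age, sex, race, diabetes duration, HbA1c, BMI,
body weight, prior myocardial infarction, prior angina, smoking) and samples
per-arm HbA1c treatment effects given a mean difference with a 95% CI.

Only body weight carries a published dispersion (SD 9.17 kg); the other
continuous factors default to degenerate (all-patients-at-the-mean) draws,
with optional configured SDs — the profile deliberately does not invent
dispersion that was never stated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .exceptions import InputError
from .risk_engine import COMPLICATIONS, STREAM_COHORT, PatientState

RACES = ("white", "black", "other")

#: 95% CI half-width to SE: CI width / (2 * 1.96)
CI_WIDTH_TO_SE = 3.92


@dataclass(frozen=True)
class BaselineProfile:
    """Baseline characteristics of the simulation cohort."""

    n_patients: int = 1000
    mean_age: float = 60.62
    prop_female: float = 0.4076
    race_props: dict = field(
        default_factory=lambda: {"white": 0.627, "black": 0.180, "other": 0.193}
    )
    median_duration: float = 9.99
    mean_hba1c: float = 8.07
    hba1c_range: tuple[float, float] = (8.0, 8.5)
    mean_bmi: float = 31.2
    mean_weight: float = 87.63
    sd_weight: float = 9.17
    height: float = 1.68
    prop_mi_history: float = 0.125
    prop_angina_history: float = 0.076
    prop_smoking: float = 0.107
    # optional dispersion for factors whose SD is not published (default degenerate)
    sd_age: float = 0.0
    sd_duration: float = 0.0
    sd_hba1c: float = 0.0
    sd_bmi: float = 0.0

    def __post_init__(self) -> None:
        if self.n_patients < 0:
            raise InputError(f"n_patients must be >= 0, got {self.n_patients}")
        for name in ("prop_female", "prop_mi_history", "prop_angina_history", "prop_smoking"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InputError(f"{name} must be in [0, 1], got {v}")
        if set(self.race_props) != set(RACES):
            raise InputError(f"race_props must have keys {RACES}")
        if any(not 0.0 <= p <= 1.0 for p in self.race_props.values()):
            raise InputError("race proportions must be in [0, 1]")
        if abs(sum(self.race_props.values()) - 1.0) > 1e-9:
            raise InputError("race proportions must sum to 1")
        for name in ("sd_weight", "sd_age", "sd_duration", "sd_hba1c", "sd_bmi"):
            if getattr(self, name) < 0:
                raise InputError(f"{name} must be >= 0")


@dataclass(frozen=True)
class EfficacySpec:
    """Treatment effect on HbA1c versus placebo: mean difference and 95% CI
    in percentage points (negative values are reductions)."""

    arm_name: str
    hba1c_md: float
    ci_lower: float
    ci_upper: float

    def __post_init__(self) -> None:
        if not self.ci_lower <= self.hba1c_md <= self.ci_upper:
            raise InputError(
                f"{self.arm_name}: require ci_lower <= hba1c_md <= ci_upper, "
                f"got ({self.ci_lower}, {self.hba1c_md}, {self.ci_upper})"
            )

    @property
    def se(self) -> float:
        return (self.ci_upper - self.ci_lower) / CI_WIDTH_TO_SE


def _continuous(rng: np.random.Generator, n: int, mean: float, sd: float, floor: float) -> np.ndarray:
    if sd == 0.0:
        return np.full(n, mean)
    return np.maximum(rng.normal(mean, sd, size=n), floor)


def generate_cohort(profile: BaselineProfile, seed: int) -> list[PatientState]:
    """Draw ``profile.n_patients`` baseline patient states, deterministically.

    Binary attributes are Bernoulli at the stated proportions; continuous
    factors are Normal at the stated mean/SD (degenerate where no SD is
    configured). Identical seeds yield bitwise-identical cohorts. Prior
    angina is recorded as ischaemic-heart-disease history.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(STREAM_COHORT,)))
    n = profile.n_patients
    female = rng.random(n) < profile.prop_female
    r = rng.random(n)
    cut_white = profile.race_props["white"]
    cut_black = cut_white + profile.race_props["black"]
    race = np.where(r < cut_white, "white", np.where(r < cut_black, "black", "other"))
    age = _continuous(rng, n, profile.mean_age, profile.sd_age, 18.0)
    duration = _continuous(rng, n, profile.median_duration, profile.sd_duration, 0.0)
    hba1c = _continuous(rng, n, profile.mean_hba1c, profile.sd_hba1c, 4.0)
    bmi = _continuous(rng, n, profile.mean_bmi, profile.sd_bmi, 12.0)
    weight = _continuous(rng, n, profile.mean_weight, profile.sd_weight, 30.0)
    mi_hist = rng.random(n) < profile.prop_mi_history
    angina_hist = rng.random(n) < profile.prop_angina_history
    smoker = rng.random(n) < profile.prop_smoking

    cohort = []
    for i in range(n):
        history: dict[str, Optional[int]] = {c: None for c in COMPLICATIONS}
        if mi_hist[i]:
            history["mi"] = 0
        if angina_hist[i]:
            history["ihd"] = 0
        cohort.append(
            PatientState(
                age=float(age[i]),
                female=bool(female[i]),
                race=str(race[i]),
                duration=float(duration[i]),
                hba1c=float(hba1c[i]),
                bmi=float(bmi[i]),
                weight=float(weight[i]),
                height=profile.height,
                smoker=bool(smoker[i]),
                history=history,
            )
        )
    return cohort


def sample_treatment_effect(
    spec: EfficacySpec,
    mode: str,
    rng: Optional[np.random.Generator] = None,
) -> float:
    """HbA1c effect in percentage points: the point estimate, or one draw from
    Normal(MD, SE) with SE = CI width / 3.92."""
    if mode == "point":
        return spec.hba1c_md
    if mode == "probabilistic":
        if spec.se == 0.0:
            return spec.hba1c_md
        if rng is None:
            raise InputError("probabilistic mode requires an rng")
        return float(rng.normal(spec.hba1c_md, spec.se))
    raise InputError(f"unknown mode {mode!r}; expected 'point' or 'probabilistic'")


def apply_effect(state: PatientState, effect: float) -> PatientState:
    """Shift baseline HbA1c by ``effect`` (negative = reduction); all other
    fields unchanged."""
    if not state.alive:
        raise InputError("cannot apply a treatment effect to a dead patient")
    new = state.clone()
    new.hba1c = state.hba1c + effect
    return new


# ---------------------------------------------------------------------------
# CSV round-trip (one row per patient)
# ---------------------------------------------------------------------------

_CSV_COLUMNS = [
    "age", "female", "race", "duration", "hba1c", "bmi", "weight", "height",
    "smoker",
] + [f"hist_{c}" for c in COMPLICATIONS]


def cohort_to_frame(cohort: Sequence[PatientState]) -> pd.DataFrame:
    rows = []
    for s in cohort:
        row = {
            "age": s.age, "female": s.female, "race": s.race,
            "duration": s.duration, "hba1c": s.hba1c, "bmi": s.bmi,
            "weight": s.weight, "height": s.height, "smoker": s.smoker,
        }
        for c in COMPLICATIONS:
            row[f"hist_{c}"] = -1 if s.history.get(c) is None else s.history[c]
        rows.append(row)
    return pd.DataFrame(rows, columns=_CSV_COLUMNS)


def cohort_from_frame(frame: pd.DataFrame) -> list[PatientState]:
    cohort = []
    for _, row in frame.iterrows():
        history = {
            c: (None if int(row[f"hist_{c}"]) < 0 else int(row[f"hist_{c}"]))
            for c in COMPLICATIONS
        }
        cohort.append(
            PatientState(
                age=float(row["age"]), female=bool(row["female"]), race=str(row["race"]),
                duration=float(row["duration"]), hba1c=float(row["hba1c"]),
                bmi=float(row["bmi"]), weight=float(row["weight"]),
                height=float(row["height"]), smoker=bool(row["smoker"]),
                history=history,
            )
        )
    return cohort
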