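"""Costs, utilities and discounted accumulation over simulated trajectories.

Costs are 2020 US dollars converted from Chinese yuan at a fixed exchange
rate (¥6.8974 per $). Drug acquisition follows a 48-dosing-weeks-per-year
convention; subcutaneous semaglutide uses its fixed dose-escalation regimen
(0.25 mg × 4 weeks, 0.5 mg × 4 weeks, then 1.0 mg weekly maintenance) priced
per usable milligram of a 2.0 mg pen. After the treatment duration (5 years
in the base case) every arm switches to the same basal insulin at an
arm-invariant annual cost.

Utilities are additive: a complication subtracts an event-year decrement in
the cycle of the event and a subsequent-year decrement thereafter, from the
no-complication initial utility (0.876), clamped at 0. Death contributes a
life-year for its cycle but zero utility (no partial-year utility).
Discounting is end-of-cycle: cycle t is weighted by (1 + rate)^-t.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .exceptions import InputError
from .risk_engine import PatientState, Trajectory

#: semaglutide dose-escalation schedule: (weeks, mg per weekly dose)
SEMA_ESCALATION = ((4, 0.25), (4, 0.5), (40, 1.0))
SEMA_MAINTENANCE_MG_PER_YEAR = 48.0


# ---------------------------------------------------------------------------
# catalogues
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ComplicationCost:
    """Event-year costs (fatal vs non-fatal) and the running annual cost in
    every subsequent year, all in $."""

    fatal_cost: float
    nonfatal_cost: float
    subsequent_cost: float

    def __post_init__(self) -> None:
        for f in ("fatal_cost", "nonfatal_cost", "subsequent_cost"):
            if getattr(self, f) < 0:
                raise InputError(f"{f} must be >= 0, got {getattr(self, f)}")


@dataclass(frozen=True)
class ComplicationUtility:
    """Utility decrements stored as magnitudes: event-year and subsequent-year."""

    event_decrement: float
    subsequent_decrement: float

    def __post_init__(self) -> None:
        if self.event_decrement < 0 or self.subsequent_decrement < 0:
            raise InputError("utility decrements are stored as non-negative magnitudes")


@dataclass(frozen=True)
class CostSchedule:
    """Therapy, management and complication costs for one treatment arm."""

    therapy_first_year: float
    therapy_maintenance: float
    treatment_duration: int = 5
    post_switch_annual_cost: float = 400.0
    management_annual_cost: float = 1463.01
    complications: Mapping[str, ComplicationCost] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.treatment_duration < 1:
            raise InputError("treatment_duration must be >= 1")
        for f in ("therapy_first_year", "therapy_maintenance",
                  "post_switch_annual_cost", "management_annual_cost"):
            if getattr(self, f) < 0:
                raise InputError(f"{f} must be >= 0")

    def therapy_cost(self, treatment_year: int) -> float:
        """Annual therapy cost in the given treatment year (1-based); the arm
        drug up to the treatment duration, basal insulin afterwards."""
        if treatment_year < 1:
            raise InputError("treatment_year is 1-based")
        if treatment_year == 1:
            return self.therapy_first_year
        if treatment_year <= self.treatment_duration:
            return self.therapy_maintenance
        return self.post_switch_annual_cost


@dataclass(frozen=True)
class UtilityCatalog:
    initial_utility: float = 0.876
    decrements: Mapping[str, ComplicationUtility] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 < self.initial_utility <= 1.0:
            raise InputError("initial_utility must be in (0, 1]")


@dataclass(frozen=True)
class EconomicParams:
    discount_rate: float = 0.05
    horizon: int = 40
    fx_rate: float = 6.8974  # ¥ per $
    dosing_weeks_per_year: int = 48

    def __post_init__(self) -> None:
        if self.discount_rate < 0:
            raise InputError("discount_rate must be >= 0")
        if self.horizon < 1:
            raise InputError("horizon must be >= 1")


# ---------------------------------------------------------------------------
# unit operations
# ---------------------------------------------------------------------------


def annual_acquisition_cost(
    price_per_box: float, doses_per_box: int, dose_weeks: int, fx: float
) -> float:
    """Annual drug cost in $: (box price / doses per box) × dosing weeks / fx."""
    if doses_per_box <= 0:
        raise InputError("doses_per_box must be > 0")
    if price_per_box < 0 or dose_weeks < 0 or fx <= 0:
        raise InputError("price, dose_weeks must be >= 0 and fx > 0")
    return (price_per_box / doses_per_box) * dose_weeks / fx


def semaglutide_escalation_cost(
    price_per_pen: float, mg_per_pen_usable: float, fx: float
) -> tuple[float, float]:
    """($ first year, $ maintenance year) under the dose-escalation regimen.

    Cost per mg = pen price / usable mg. First year uses 4×0.25 + 4×0.5 +
    40×1.0 = 43 mg; a maintenance year uses 48 mg (48 dosing weeks).
    """
    if price_per_pen <= 0 or mg_per_pen_usable <= 0 or fx <= 0:
        raise InputError("all inputs must be > 0")
    per_mg = price_per_pen / mg_per_pen_usable
    first_mg = sum(weeks * mg for weeks, mg in SEMA_ESCALATION)
    first = first_mg * per_mg / fx
    maintenance = SEMA_MAINTENANCE_MG_PER_YEAR * per_mg / fx
    return first, maintenance


def discount_factor(rate: float, t: float) -> float:
    """(1 + rate)^(-t); t in years."""
    if rate < -1.0:
        raise InputError("rate must be >= -1")
    if t < 0:
        raise InputError("t must be >= 0")
    return (1.0 + rate) ** (-t)


def annual_utility(
    state: PatientState, catalog: UtilityCatalog, cycle: int | None = None
) -> float:
    """Utility for one annual cycle: initial utility minus event-year
    decrements for this cycle's events and subsequent-year decrements for
    earlier events, additive and clamped at 0; dead patients score 0.

    ``cycle`` identifies which history entries are "this cycle"; with
    ``None`` every past event counts as subsequent-year.
    """
    if not state.alive:
        return 0.0
    u = catalog.initial_utility
    for comp, year in state.history.items():
        if year is None:
            continue
        dec = catalog.decrements.get(comp)
        if dec is None:
            continue
        if cycle is not None and year == cycle:
            u -= dec.event_decrement
        else:
            u -= dec.subsequent_decrement
    return max(u, 0.0)


def annual_cost(
    state: PatientState,
    events_this_cycle: Sequence[str],
    treatment_year: int,
    schedule: CostSchedule,
) -> dict[str, float]:
    """Undiscounted cost of one cycle, split into therapy / management /
    complication components.

    Event-year complications are charged the fatal cost when the patient dies
    in this cycle, otherwise the non-fatal cost; earlier events are charged
    their subsequent-year cost. A dash-valued (unreported) fatal cost is
    configured as 0.
    """
    # trajectories end at death, so a dead snapshot is always the death cycle
    died_this_cycle = not state.alive
    therapy = schedule.therapy_cost(treatment_year)
    management = schedule.management_annual_cost
    comp_cost = 0.0
    events = set(events_this_cycle)
    for comp in events:
        cc = schedule.complications.get(comp)
        if cc is None:
            continue
        comp_cost += cc.fatal_cost if died_this_cycle else cc.nonfatal_cost
    for comp, year in state.history.items():
        if year is None or comp in events:
            continue
        cc = schedule.complications.get(comp)
        if cc is not None:
            comp_cost += cc.subsequent_cost
    return {
        "therapy": therapy,
        "management": management,
        "complication": comp_cost,
        "total": therapy + management + comp_cost,
    }


# ---------------------------------------------------------------------------
# accumulation
# ---------------------------------------------------------------------------


@dataclass
class ArmAccumulation:
    """Discounted per-patient totals for one arm."""

    qaly: float = 0.0
    ly_discounted: float = 0.0
    ly_undiscounted: float = 0.0
    therapy_cost: float = 0.0
    management_cost: float = 0.0
    complication_cost: float = 0.0

    @property
    def total_cost(self) -> float:
        return self.therapy_cost + self.management_cost + self.complication_cost


def accumulate(
    trajectory: Trajectory,
    schedule: CostSchedule,
    catalog: UtilityCatalog,
    params: EconomicParams,
) -> ArmAccumulation:
    """Discount and sum per-cycle utilities and costs along one trajectory.

    The treatment year equals the cycle index (therapy starts at cycle 1);
    accumulation stops at the economic horizon even if the trajectory is
    longer.
    """
    acc = ArmAccumulation()
    for rec in trajectory.records:
        if rec.cycle > params.horizon:
            break
        df = discount_factor(params.discount_rate, rec.cycle)
        acc.ly_undiscounted += 1.0
        acc.ly_discounted += df
        acc.qaly += df * annual_utility(rec.state, catalog, rec.cycle)
        costs = annual_cost(rec.state, rec.events, rec.cycle, schedule)
        acc.therapy_cost += df * costs["therapy"]
        acc.management_cost += df * costs["management"]
        acc.complication_cost += df * costs["complication"]
    return acc


def mean_accumulation(accs: Iterable[ArmAccumulation]) -> ArmAccumulation:
    accs = list(accs)
    if not accs:
        raise InputError("no accumulations to average")
    n = len(accs)
    return ArmAccumulation(
        qaly=float(np.sum([a.qaly for a in accs])) / n,
        ly_discounted=float(np.sum([a.ly_discounted for a in accs])) / n,
        ly_undiscounted=float(np.sum([a.ly_undiscounted for a in accs])) / n,
        therapy_cost=float(np.sum([a.therapy_cost for a in accs])) / n,
        management_cost=float(np.sum([a.management_cost for a in accs])) / n,
        complication_cost=float(np.sum([a.complication_cost for a in accs])) / n,
    )
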