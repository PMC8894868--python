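"""Drug costs, utilities, discounting and trajectory accumulation."""

import numpy as np
import pytest

from t2dcua import (
    BaselineProfile,
    ComplicationCost,
    ComplicationUtility,
    CostSchedule,
    EconomicParams,
    UtilityCatalog,
    accumulate,
    annual_acquisition_cost,
    annual_cost,
    annual_utility,
    discount_factor,
    generate_cohort,
    semaglutide_escalation_cost,
    simulate_patient,
)
from t2dcua.exceptions import InputError
from t2dcua.risk_engine import CycleRecord, Trajectory
from conftest import zero_hazard_params

FX = 6.8974


def _patient(**kw):
    return generate_cohort(BaselineProfile(n_patients=1, **kw), seed=1)[0]


def _catalog(**decs):
    return UtilityCatalog(
        initial_utility=0.876,
        decrements={k: ComplicationUtility(*v) for k, v in decs.items()},
    )


class TestAcquisitionCosts:
    def test_dulaglutide_annual_cost(self):
        # ¥298/box of 2 doses, 48 dosing weeks
        assert annual_acquisition_cost(298.00, 2, 48, FX) == pytest.approx(1036.91, abs=0.005)

    def test_exenatide_annual_cost(self):
        # printed 3599.38; sub-cent rounding
        assert annual_acquisition_cost(2068.86, 4, 48, FX) == pytest.approx(3599.38, abs=0.01)

    def test_zero_dosing_weeks(self):
        assert annual_acquisition_cost(100.0, 1, 0, FX) == 0.0

    def test_zero_doses_per_box_rejected(self):
        with pytest.raises(InputError):
            annual_acquisition_cost(100.0, 0, 48, FX)

    def test_semaglutide_escalation(self):
        first, maintenance = semaglutide_escalation_cost(1120.0, 2.0, FX)
        assert first == pytest.approx(3491.17, abs=0.005)  # 43 mg escalation year
        assert maintenance == pytest.approx(3897.12, abs=0.005)  # 48 mg per year

    def test_semaglutide_linearity(self):
        f1, m1 = semaglutide_escalation_cost(1120.0, 2.0, FX)
        f2, m2 = semaglutide_escalation_cost(2240.0, 2.0, FX)
        assert (f2, m2) == (pytest.approx(2 * f1), pytest.approx(2 * m1))


class TestDiscounting:
    def test_zero_rate_is_identity(self):
        assert discount_factor(0.0, 17) == 1.0

    @pytest.mark.parametrize("t,expected", [(1, 0.95238), (2, 0.90703)])
    def test_five_percent(self, t, expected):
        assert discount_factor(0.05, t) == pytest.approx(expected, abs=1e-5)

    def test_invalid_inputs(self):
        with pytest.raises(InputError):
            discount_factor(-1.5, 1)
        with pytest.raises(InputError):
            discount_factor(0.05, -1)


class TestAnnualUtility:
    def test_no_complications(self):
        assert annual_utility(_patient(), _catalog()) == pytest.approx(0.876)

    def test_event_year_vs_subsequent(self):
        cat = _catalog(mi=(0.055, 0.236))
        s = _patient()
        s.history["mi"] = 3
        assert annual_utility(s, cat, cycle=3) == pytest.approx(0.821)  # event year
        assert annual_utility(s, cat, cycle=4) == pytest.approx(0.640)  # subsequent

    def test_dead_is_zero(self):
        s = _patient()
        s.alive = False
        assert annual_utility(s, _catalog()) == 0.0

    def test_stacked_decrements_clamp_at_zero(self):
        cat = _catalog(mi=(0.5, 0.5), stroke=(0.5, 0.5))
        s = _patient()
        s.history["mi"] = 1
        s.history["stroke"] = 1
        assert annual_utility(s, cat, cycle=2) == 0.0


class TestAnnualCost:
    def _schedule(self):
        return CostSchedule(
            therapy_first_year=1036.91,
            therapy_maintenance=1036.91,
            treatment_duration=5,
            post_switch_annual_cost=400.0,
            management_annual_cost=1463.01,
            complications={
                "mi": ComplicationCost(8052.81, 8052.81, 496.72),
                "stroke": ComplicationCost(2323.34, 3136.05, 552.89),
            },
        )

    def test_therapy_plus_management(self):
        c = annual_cost(_patient(), [], 2, self._schedule())
        assert c["total"] == pytest.approx(1036.91 + 1463.01)

    def test_switch_to_insulin_after_duration(self):
        c = annual_cost(_patient(), [], 6, self._schedule())
        assert c["therapy"] == pytest.approx(400.0)

    def test_nonfatal_event_cost(self):
        s = _patient()
        s.history["stroke"] = 2
        c = annual_cost(s, ["stroke"], 2, self._schedule())
        assert c["complication"] == pytest.approx(3136.05)

    def test_fatal_event_cost(self):
        s = _patient()
        s.history["stroke"] = 2
        s.alive = False
        s.death_cycle = 2
        c = annual_cost(s, ["stroke"], 2, self._schedule())
        assert c["complication"] == pytest.approx(2323.34)

    def test_subsequent_year_cost(self):
        s = _patient()
        s.history["mi"] = 1
        c = annual_cost(s, [], 3, self._schedule())
        assert c["complication"] == pytest.approx(496.72)

    def test_subtotals_identity(self):
        s = _patient()
        s.history["mi"] = 1
        s.history["stroke"] = 3
        c = annual_cost(s, ["stroke"], 3, self._schedule())
        assert c["total"] == pytest.approx(
            c["therapy"] + c["management"] + c["complication"], abs=1e-9
        )


def _hand_trajectory():
    """Three alive cycles with an MI in cycle 2."""
    records = []
    for cycle in (1, 2, 3):
        s = _patient()
        if cycle >= 2:
            s.history["mi"] = 2
        records.append(CycleRecord(cycle, s, ("mi",) if cycle == 2 else (), True))
    return Trajectory(records)


class TestAccumulate:
    def test_hand_worked_qaly(self):
        """0.876/1.05 + 0.821/1.05^2 + (0.876-0.236)/1.05^3 = 2.1318."""
        catalog = _catalog(mi=(0.055, 0.236))
        schedule = CostSchedule(0.0, 0.0, complications={})
        params = EconomicParams(discount_rate=0.05, horizon=40)
        acc = accumulate(_hand_trajectory(), schedule, catalog, params)
        assert acc.qaly == pytest.approx(2.1318, abs=1e-4)

    def test_zero_discount_no_events(self):
        traj = simulate_patient(_patient(), zero_hazard_params(), 10, np.random.default_rng(0))
        acc = accumulate(
            traj,
            CostSchedule(0.0, 0.0),
            _catalog(),
            EconomicParams(discount_rate=0.0, horizon=40),
        )
        assert acc.qaly == pytest.approx(8.76)  # 10 x 0.876
        assert acc.ly_discounted == acc.ly_undiscounted == 10.0

    def test_death_cycle_counts_life_year_but_no_utility(self):
        s = _patient()
        s.alive = False
        s.death_cycle = 1
        traj = Trajectory([CycleRecord(1, s, (), False)])
        acc = accumulate(
            traj, CostSchedule(0.0, 0.0), _catalog(), EconomicParams(0.0, 40)
        )
        assert acc.ly_undiscounted == 1.0
        assert acc.qaly == 0.0

    def test_subtotals_and_orderings(self, ref_config):
        """therapy+management+complication == total; QALY <= LYd <= LY."""
        from t2dcua import build_cost_schedule, build_economic_params, build_utility_catalog
        from t2dcua import simulate_cohort

        cohort = generate_cohort(BaselineProfile(n_patients=50), seed=21)
        trajs, _ = simulate_cohort(cohort, ref_config.risk_equations, 40, seed=21)
        schedule = build_cost_schedule(ref_config.arms[1], ref_config.economics)
        catalog = build_utility_catalog(ref_config.economics)
        params = build_economic_params(ref_config.economics)
        for t in trajs:
            acc = accumulate(t, schedule, catalog, params)
            assert acc.total_cost == pytest.approx(
                acc.therapy_cost + acc.management_cost + acc.complication_cost, abs=1e-9
            )
            assert acc.qaly <= acc.ly_discounted + 1e-12
            assert acc.ly_discounted <= acc.ly_undiscounted + 1e-12

    def test_closed_form_annuity_when_nothing_happens(self):
        """Zero hazards: cost = (therapy+management) annuity; QALY = u x LYd."""
        rate, horizon, therapy, mgmt = 0.05, 15, 1000.0, 1463.01
        traj = simulate_patient(
            _patient(), zero_hazard_params(), horizon, np.random.default_rng(1)
        )
        schedule = CostSchedule(
            therapy, therapy, treatment_duration=horizon, management_annual_cost=mgmt
        )
        acc = accumulate(traj, schedule, _catalog(), EconomicParams(rate, horizon))
        annuity = sum((1 + rate) ** (-t) for t in range(1, horizon + 1))
        assert acc.total_cost == pytest.approx((therapy + mgmt) * annuity, abs=1e-9)
        assert acc.qaly == pytest.approx(0.876 * annuity, abs=1e-9)

    def test_cost_monotone_in_unit_price(self):
        traj = simulate_patient(_patient(), zero_hazard_params(), 10, np.random.default_rng(2))
        params = EconomicParams(0.05, 40)
        totals = [
            accumulate(traj, CostSchedule(p, p), _catalog(), params).total_cost
            for p in (100.0, 200.0, 400.0)
        ]
        assert totals == sorted(totals)
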