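"""Risk equations and the annual-cycle microsimulation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad

from t2dcua import (
    BaselineProfile,
    ParameterSet,
    PathRule,
    RiskEquation,
    annual_event_probability,
    generate_cohort,
    progress_risk_factors,
    simulate_cohort,
    simulate_patient,
)
from t2dcua.exceptions import ConfigurationError, InputError
from t2dcua.risk_engine import trajectories_to_frame
from conftest import constant_death_params, zero_hazard_params


def _rng(seed=0):
    return np.random.default_rng(seed)


def _patient(**kw):
    return generate_cohort(BaselineProfile(n_patients=1, **kw), seed=1)[0]


class TestAnnualEventProbability:
    def test_exponential_unit_hazard(self):
        eq = RiskEquation("x", "exponential_ph", intercept=0.0)
        assert annual_event_probability(eq, {}, 0.0) == pytest.approx(1 - math.exp(-1), abs=1e-12)

    def test_weibull_shape_one_reduces_to_exponential(self):
        for lp in (-3.0, -1.0, 0.5):
            for d in (0.0, 4.0, 19.0):
                w = RiskEquation("x", "weibull_ph", intercept=lp, shape=1.0)
                e = RiskEquation("x", "exponential_ph", intercept=lp)
                assert annual_event_probability(w, {}, d) == pytest.approx(
                    annual_event_probability(e, {}, d), abs=1e-12
                )

    @pytest.mark.parametrize("shape", [0.5, 1.0, 1.5, 2.3])
    @pytest.mark.parametrize("lp", [-5.0, -3.0, -1.0])
    @pytest.mark.parametrize("duration", [0.0, 2.0, 9.0, 25.0])
    def test_weibull_matches_quadrature(self, shape, lp, duration):
        """Closed-form annual probability vs numerical hazard integration."""
        eq = RiskEquation("x", "weibull_ph", intercept=lp, shape=shape)
        p = annual_event_probability(eq, {}, duration)
        integral, _ = quad(
            lambda t: math.exp(lp) * shape * t ** (shape - 1.0), duration, duration + 1.0
        )
        assert abs(p - (1 - math.exp(-integral))) < 1e-8

    def test_gompertz_matches_quadrature(self):
        shape, lp, age = 0.09, -10.0, 60.0
        eq = RiskEquation("death", "gompertz", intercept=lp, shape=shape, time_axis="age")
        p = annual_event_probability(eq, {}, age)
        integral, _ = quad(lambda t: math.exp(lp) * math.exp(shape * t), age, age + 1.0)
        assert abs(p - (1 - math.exp(-integral))) < 1e-8

    def test_logistic_is_direct_probability(self):
        eq = RiskEquation("x", "logistic", intercept=0.0)
        assert annual_event_probability(eq, {}, 0.0) == pytest.approx(0.5)
        low = RiskEquation("x", "logistic", intercept=-1000.0)
        assert annual_event_probability(low, {}, 0.0) == pytest.approx(0.0)

    def test_missing_covariate_names_it(self):
        eq = RiskEquation("chf", "exponential_ph", intercept=0.0, coefficients={"hba1c": 0.1})
        with pytest.raises(ConfigurationError, match="hba1c"):
            annual_event_probability(eq, {"age": 60.0}, 0.0)

    @given(
        form=st.sampled_from(["exponential_ph", "weibull_ph", "logistic", "gompertz"]),
        lp=st.floats(-30, 10),
        shape=st.floats(0.1, 3.0),
        duration=st.floats(0, 60),
        hba1c=st.floats(4, 14),
        coef=st.floats(0, 0.5),
    )
    @settings(max_examples=200, deadline=None)
    def test_probability_in_unit_interval_and_monotone(
        self, form, lp, shape, duration, hba1c, coef
    ):
        eq = RiskEquation("x", form, intercept=lp, coefficients={"hba1c": coef}, shape=shape)
        p = annual_event_probability(eq, {"hba1c": hba1c}, duration)
        assert 0.0 <= p <= 1.0
        # monotone non-decreasing in a positively weighted covariate
        p_hi = annual_event_probability(eq, {"hba1c": hba1c + 1.0}, duration)
        assert p_hi >= p - 1e-15

    def test_negative_duration_rejected(self):
        eq = RiskEquation("x", "exponential_ph", intercept=0.0)
        with pytest.raises(InputError):
            annual_event_probability(eq, {}, -1.0)


class TestProgressRiskFactors:
    def test_zero_drift_only_ages(self):
        s = _patient()
        out = progress_risk_factors(s, {"hba1c": PathRule()})
        assert out.age == s.age + 1 and out.duration == s.duration + 1
        assert (out.hba1c, out.bmi, out.weight) == (s.hba1c, s.bmi, s.weight)

    def test_linear_drift(self):
        s = _patient(mean_hba1c=6.74)
        out = progress_risk_factors(s, {"hba1c": PathRule(drift_per_year=0.1)})
        assert out.hba1c == pytest.approx(6.84)

    def test_mean_reverting_rule(self):
        s = _patient(mean_hba1c=6.0)
        out = progress_risk_factors(s, {"hba1c": PathRule(kappa=0.5, target=8.0)})
        assert out.hba1c == pytest.approx(7.0)

    def test_scheduled_step(self):
        s = _patient(mean_hba1c=6.74)
        rule = PathRule(step_at_cycle=5, step_delta=1.33)
        assert progress_risk_factors(s, {"hba1c": rule}, cycle=4).hba1c == pytest.approx(6.74)
        assert progress_risk_factors(s, {"hba1c": rule}, cycle=5).hba1c == pytest.approx(8.07)

    def test_dead_patient_rejected(self):
        s = _patient()
        s.alive = False
        with pytest.raises(InputError):
            progress_risk_factors(s, {})


class TestSimulatePatient:
    def test_null_model_survives_horizon(self):
        traj = simulate_patient(_patient(), zero_hazard_params(), horizon=40, rng=_rng())
        assert len(traj) == 40
        assert traj.death_cycle is None
        assert all(rec.events == () for rec in traj.records)

    def test_certain_death_in_first_cycle(self):
        traj = simulate_patient(_patient(), constant_death_params(1.0 - 1e-15), 40, _rng())
        assert len(traj) == 1
        assert traj.death_cycle == 1
        assert traj.life_years == 1  # the death cycle counts as a lived year

    def test_first_events_never_repeat(self):
        params = zero_hazard_params()
        params.complications["mi"] = RiskEquation("mi", "exponential_ph", intercept=5.0)
        traj = simulate_patient(_patient(), params, 10, _rng())
        fired = [rec.cycle for rec in traj.records if "mi" in rec.events]
        assert fired == [1]

    def test_zeroed_complication_never_appears(self, ref_config):
        params = ref_config.risk_equations
        params = ParameterSet(
            complications={
                **params.complications,
                "stroke": RiskEquation("stroke", "exponential_ph", intercept=-1000.0),
            },
            mortality=params.mortality,
            riskfactor_paths=params.riskfactor_paths,
        )
        cohort = generate_cohort(BaselineProfile(n_patients=100), seed=5)
        trajs, _ = simulate_cohort(cohort, params, 40, seed=5)
        assert all("stroke" not in rec.events for t in trajs for rec in t.records)

    def test_horizon_below_one_rejected(self):
        with pytest.raises(InputError):
            simulate_patient(_patient(), zero_hazard_params(), 0, _rng())


class TestSimulateCohort:
    def test_zero_hazard_life_expectancy_exact(self):
        cohort = generate_cohort(BaselineProfile(n_patients=5), seed=2)
        _, summary = simulate_cohort(cohort, zero_hazard_params(), 40, seed=2)
        assert summary["mean_le_undiscounted"] == 40.0

    def test_constant_hazard_life_expectancy_small(self):
        """Closed form Σ (1-q)^(t-1) for q = 0.5, horizon 10, within 3 SE."""
        q, horizon, n = 0.5, 10, 2000
        cohort = generate_cohort(BaselineProfile(n_patients=n), seed=9)
        trajs, summary = simulate_cohort(cohort, constant_death_params(q), horizon, seed=9)
        expected = sum((1 - q) ** (t - 1) for t in range(1, horizon + 1))
        lys = [t.life_years for t in trajs]
        se = np.std(lys, ddof=1) / math.sqrt(n)
        assert abs(summary["mean_le_undiscounted"] - expected) <= 3 * se

    def test_seed_determinism_bitwise(self, ref_config):
        cohort = generate_cohort(BaselineProfile(n_patients=50), seed=4)
        t1, _ = simulate_cohort(cohort, ref_config.risk_equations, 40, seed=4)
        t2, _ = simulate_cohort(cohort, ref_config.risk_equations, 40, seed=4)
        assert trajectories_to_frame(t1).equals(trajectories_to_frame(t2))
        t3, _ = simulate_cohort(cohort, ref_config.risk_equations, 40, seed=5)
        assert not trajectories_to_frame(t1).equals(trajectories_to_frame(t3))

    def test_substreams_stable_under_cohort_growth(self, ref_config):
        """Adding patients must not reshuffle earlier patients' trajectories."""
        small = generate_cohort(BaselineProfile(n_patients=20), seed=6)
        big = small + generate_cohort(BaselineProfile(n_patients=20), seed=7)
        t_small, _ = simulate_cohort(small, ref_config.risk_equations, 20, seed=6)
        t_big, _ = simulate_cohort(big, ref_config.risk_equations, 20, seed=6)
        assert trajectories_to_frame(t_small).equals(
            trajectories_to_frame(t_big[: len(small)])
        )

    def test_empty_cohort_rejected(self):
        with pytest.raises(InputError):
            simulate_cohort([], zero_hazard_params(), 10, seed=1)
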