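import dataclasses

import pytest

from t2dcua import load_reference_config
from t2dcua.risk_engine import COMPLICATIONS, ParameterSet, RiskEquation


def shrink(config, n_patients=None, horizon=None):
    """Copy of a run config with a smaller cohort and/or horizon."""
    import copy

    cfg = copy.deepcopy(config)
    if n_patients is not None:
        cfg.cohort = dataclasses.replace(cfg.cohort, n_patients=n_patients)
    if horizon is not None:
        cfg.economics.horizon_years = horizon
    return cfg


def zero_hazard_params() -> ParameterSet:
    """No complication or death ever fires (null model)."""
    eqs = {
        c: RiskEquation(outcome=c, form="exponential_ph", intercept=-1000.0)
        for c in COMPLICATIONS
    }
    mort = {"all_cause": RiskEquation(outcome="death", form="exponential_ph", intercept=-1000.0)}
    return ParameterSet(complications=eqs, mortality=mort, riskfactor_paths={})


def constant_death_params(q: float) -> ParameterSet:
    """Zero complication hazards; constant annual death probability q."""
    import math

    lp = math.log(-math.log(1.0 - q))  # p = 1 - exp(-exp(lp)) = q
    params = zero_hazard_params()
    params.mortality = {
        "all_cause": RiskEquation(outcome="death", form="exponential_ph", intercept=lp)
    }
    return params


@pytest.fixture(scope="session")
def ref_config():
    return load_reference_config()


@pytest.fixture(scope="session")
def small_config(ref_config):
    """Reference settings on a 100-patient cohort (fast pipeline runs)."""
    return shrink(ref_config, n_patients=100)
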