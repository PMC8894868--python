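"""One-way, scenario and probabilistic sensitivity analysis.

One-way analysis reruns the whole pipeline twice per parameter (at its low
and its high value, everything else at base) and reports the span of a
chosen pairwise metric, sorted for tornado rendering. The scenario analysis
reruns the pipeline at alternative time horizons. The probabilistic analysis
(PSA) jointly resamples inputs — Gamma for costs, Beta for utilities and
decrements, Normal for the HbA1c treatment effects — over full pipeline
evaluations while keeping the patient-level random numbers fixed (common
random numbers), so the scatter on the cost-effectiveness plane reflects
parameter uncertainty only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import CI_WIDTH_TO_SE
from .config import RunConfig, SAParameter, get_path, set_path
from .cua import classify_dominance
from .exceptions import InputError
from .pipeline import BaseCaseResult, run_base_case
from .risk_engine import STREAM_PSA

logger = logging.getLogger("t2dcua")

#: default SE for cost parameters without a published interval
COST_SE_FRACTION_OF_MEAN = 0.2


@dataclass(frozen=True)
class TornadoEntry:
    parameter: str
    output_low: float
    output_high: float
    metric: str

    @property
    def span(self) -> float:
        return abs(self.output_high - self.output_low)


MetricFn = Callable[[BaseCaseResult], float]


def metric_inmb(arm_a: str, arm_b: str) -> tuple[str, MetricFn]:
    label = f"INMB ({arm_a} vs. {arm_b})"
    return label, lambda res: res.comparison(arm_a, arm_b).inmb


def metric_icur(arm_a: str, arm_b: str) -> tuple[str, MetricFn]:
    label = f"ICUR ({arm_a} vs. {arm_b})"

    def fn(res: BaseCaseResult) -> float:
        icur = res.comparison(arm_a, arm_b).icur
        if icur is None:
            raise InputError(f"{label}: undefined (dominance); use the INMB metric")
        return icur

    return label, fn


def one_way_sa(
    config: RunConfig,
    params: Optional[Sequence[SAParameter]] = None,
    metric: Optional[tuple[str, MetricFn]] = None,
    seed: Optional[int] = None,
) -> list[TornadoEntry]:
    """Tornado battery: two pipeline runs per parameter, sorted by span.

    The default metric is the INMB of the first configured arm pair — stable
    even where the ICUR is undefined by dominance.
    """
    params = config.sensitivity if params is None else list(params)
    if metric is None:
        metric = metric_inmb(config.arms[0].name, config.arms[1].name)
    label, fn = metric
    entries = []
    for p in params:
        outputs = []
        for value in (p.low, p.high):
            cfg = config
            for path in p.paths:
                get_path(cfg, path)  # raises ConfigurationError naming the path
                cfg = set_path(cfg, path, value)
            outputs.append(fn(run_base_case(cfg, seed=seed, keep_trajectories=False)))
        entries.append(TornadoEntry(p.name, outputs[0], outputs[1], label))
        logger.info("one-way SA %s: low %.2f high %.2f", p.name, outputs[0], outputs[1])
    entries.sort(key=lambda e: e.span, reverse=True)
    return entries


def tornado_frame(entries: Sequence[TornadoEntry]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "parameter": [e.parameter for e in entries],
            "output_low": [e.output_low for e in entries],
            "output_high": [e.output_high for e in entries],
            "span": [e.span for e in entries],
            "metric": [e.metric for e in entries],
        }
    )


def scenario_horizons(
    config: RunConfig,
    horizons: Sequence[int],
    seed: Optional[int] = None,
) -> pd.DataFrame:
    """ICUR (or "Dominance") for every arm pair at each time horizon."""
    if any(h < 1 for h in horizons):
        raise InputError("horizons must be >= 1")
    rows: dict[str, dict] = {}
    for h in horizons:
        cfg = set_path(config, "economics.horizon_years", int(h))
        res = run_base_case(cfg, seed=seed, keep_trajectories=False)
        for c in res.comparisons:
            key = f"{c.arm_a} vs. {c.arm_b}"
            rows.setdefault(key, {})[f"{h} years"] = (
                "Dominance" if c.icur is None else c.icur
            )
    return pd.DataFrame(rows).T


# ---------------------------------------------------------------------------
# PSA distributions
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Sampler:
    """Moment-matched sampling rule for one uncertain input."""

    name: str
    family: str  # {"gamma", "beta", "normal", "degenerate"}
    mean: float
    se: float
    _dist: object = None

    def sample(self, rng: np.random.Generator) -> float:
        if self.family == "degenerate":
            return self.mean
        return float(self._dist.rvs(random_state=rng))  # type: ignore[attr-defined]


def assign_distribution(
    kind: str,
    mean: float,
    se: Optional[float] = None,
    low: Optional[float] = None,
    high: Optional[float] = None,
    name: str = "",
) -> Sampler:
    """Sampling rule by parameter type.

    Costs get a Gamma moment-matched to (mean, SE), with SE = 20% of the mean
    when no interval is given; utilities and decrements get a moment-matched
    Beta; treatment effects get a Normal. An interval (low, high) is read as
    a 95% CI, SE = width / 3.92. Zero variance degenerates to the mean.
    """
    if se is None:
        if low is not None and high is not None:
            se = (high - low) / CI_WIDTH_TO_SE
        elif kind == "cost":
            se = COST_SE_FRACTION_OF_MEAN * mean
        else:
            raise InputError(f"{name or kind}: se or (low, high) required")
    if se == 0.0:
        return Sampler(name, "degenerate", mean, 0.0)
    if kind == "cost":
        if mean <= 0:
            raise InputError(f"{name or kind}: Gamma requires mean > 0, got {mean}")
        shape = (mean / se) ** 2
        scale = se**2 / mean
        return Sampler(name, "gamma", mean, se, stats.gamma(a=shape, scale=scale))
    if kind == "utility":
        if not 0.0 < mean < 1.0:
            raise InputError(f"{name or kind}: Beta requires mean in (0, 1), got {mean}")
        if se**2 >= mean * (1.0 - mean):
            raise InputError(f"{name or kind}: variance too large for a Beta")
        nu = mean * (1.0 - mean) / se**2 - 1.0
        return Sampler(name, "beta", mean, se, stats.beta(a=mean * nu, b=(1.0 - mean) * nu))
    if kind == "effect":
        return Sampler(name, "normal", mean, se, stats.norm(loc=mean, scale=se))
    raise InputError(f"unknown parameter kind {kind!r}")


# ---------------------------------------------------------------------------
# PSA
# ---------------------------------------------------------------------------


def _psa_samplers(config: RunConfig) -> tuple[list[tuple[SAParameter, Sampler]], dict[str, Sampler]]:
    battery = []
    for p in config.sensitivity:
        if p.kind not in config.psa.resample_kinds:
            continue
        mean = float(get_path(config, p.paths[0]))
        if p.kind == "cost" and mean <= 0:
            continue  # zero-cost inputs stay fixed (Gamma undefined)
        battery.append((p, assign_distribution(p.kind, mean, low=p.low, high=p.high, name=p.name)))
    effects = {}
    if config.psa.resample_effects:
        for arm in config.arms:
            spec = arm.efficacy_spec()
            effects[arm.name] = assign_distribution(
                "effect", spec.hba1c_md, se=spec.se, name=f"effect[{arm.name}]"
            )
    return battery, effects


def run_psa(
    config: RunConfig,
    n_iter: Optional[int] = None,
    seed: Optional[int] = None,
) -> tuple[pd.DataFrame, dict[str, dict[str, float]]]:
    """Monte-Carlo PSA: ``n_iter`` full pipeline evaluations with jointly
    resampled inputs, on a fixed patient-level seed.

    Returns the per-iteration cost-effectiveness records (per-arm QALY/cost
    and pairwise ΔQALY/ΔCost) and, per pair, the fractions of iterations
    falling in each decision category relative to the λ line (fractions sum
    to 1).
    """
    n_iter = config.psa.n_iter if n_iter is None else n_iter
    if n_iter < 1:
        raise InputError("n_iter must be >= 1")
    # ``seed`` drives the parameter resampling only; the patient-level draws
    # stay on the config seed (common random numbers across iterations)
    seed = config.seed if seed is None else seed
    sim_seed = config.seed
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(STREAM_PSA,)))
    battery, effect_samplers = _psa_samplers(config)
    lam = config.threshold.lambda_usd

    rows = []
    for it in range(n_iter):
        cfg = config
        for p, sampler in battery:
            value = sampler.sample(rng)
            if p.kind == "utility":
                value = min(max(value, 0.0), 1.0)
            for path in p.paths:
                cfg = set_path(cfg, path, value)
        effects = {name: s.sample(rng) for name, s in effect_samplers.items()} or None
        res = run_base_case(cfg, seed=sim_seed, effects=effects, keep_trajectories=False)
        row: dict[str, float] = {"iteration": it}
        for r in res.arm_results:
            row[f"qaly[{r.arm}]"] = r.qaly
            row[f"cost[{r.arm}]"] = r.total_cost
        for c in res.comparisons:
            row[f"dqaly[{c.arm_a} vs. {c.arm_b}]"] = c.delta_qaly
            row[f"dcost[{c.arm_a} vs. {c.arm_b}]"] = c.delta_cost
        rows.append(row)
        if (it + 1) % 50 == 0:
            logger.info("PSA iteration %d / %d", it + 1, n_iter)
    samples = pd.DataFrame(rows)

    summary: dict[str, dict[str, float]] = {}
    pair_labels = sorted(
        {col[len("dqaly["):-1] for col in samples.columns if col.startswith("dqaly[")}
    )
    for label in pair_labels:
        dq = samples[f"dqaly[{label}]"].to_numpy()
        dc = samples[f"dcost[{label}]"].to_numpy()
        verdicts = [classify_dominance(q, c, None, lam) for q, c in zip(dq, dc)]
        counts = pd.Series(verdicts).value_counts()
        summary[label] = {v: float(counts.get(v, 0)) / n_iter for v in set(verdicts)}
    return samples, summary
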