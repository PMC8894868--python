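"""End-to-end orchestration: shared cohort → per-arm simulation → economics → CUA.

One root seed governs everything. The same baseline cohort and the same
per-patient random-number substreams are reused across arms (common random
numbers), so between-arm differences reflect the treatment effects and not
resampling noise. The HbA1c treatment effect is applied at baseline and, by
default, reversed when therapy switches to basal insulin at the end of the
treatment duration (all arms then share the same glycaemia, matching the
arm-invariant post-switch therapy assumption).
"""

from __future__ import annotations

import datetime
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional

import pandas as pd

from . import __version__ as _version
from .cohort import apply_effect, generate_cohort, sample_treatment_effect
from .config import (
    RunConfig,
    build_cost_schedule,
    build_economic_params,
    build_utility_catalog,
    config_hash,
)
from .cua import ArmResult, CUAComparison, compare, comparison_table
from .economics import accumulate, mean_accumulation
from .exceptions import InputError
from .risk_engine import Trajectory, simulate_cohort

logger = logging.getLogger("t2dcua")


@dataclass
class BaseCaseResult:
    """Per-arm results, pairwise comparisons, and cached trajectories."""

    arm_results: list[ArmResult]
    comparisons: list[CUAComparison]
    lambda_usd: float
    seed: int
    trajectories: dict[str, list[Trajectory]] = field(default_factory=dict, repr=False)
    runtime_s: float = 0.0

    def arm(self, name: str) -> ArmResult:
        for r in self.arm_results:
            if r.arm == name:
                return r
        raise InputError(f"unknown arm {name!r}")

    def comparison(self, a: str, b: str) -> CUAComparison:
        for c in self.comparisons:
            if c.arm_a == a and c.arm_b == b:
                return c
        raise InputError(f"no comparison {a!r} vs {b!r}")

    def table(self) -> pd.DataFrame:
        pairs = [(c.arm_a, c.arm_b) for c in self.comparisons]
        return comparison_table(self.arm_results, self.lambda_usd, pairs)


def run_arm(
    config: RunConfig,
    arm_name: str,
    effect: float,
    seed: int,
    cohort=None,
    keep_trajectories: bool = True,
) -> tuple[ArmResult, list[Trajectory]]:
    """Simulate one arm: apply the HbA1c effect, run the risk engine on the
    shared substreams, accumulate discounted costs and QALYs."""
    econ = config.economics
    if cohort is None:
        cohort = generate_cohort(config.cohort, seed)
    treated = [apply_effect(s, effect) for s in cohort]
    params = config.risk_equations
    if econ.hba1c_rebound_at_switch and effect != 0.0:
        params = params.with_hba1c_step(econ.treatment_duration_years, -effect)
    trajectories, _ = simulate_cohort(
        treated, params, econ.horizon_years, seed, econ.discount_rate
    )
    schedule = build_cost_schedule(config.arm(arm_name), econ)
    catalog = build_utility_catalog(econ)
    eparams = build_economic_params(econ)
    acc = mean_accumulation(accumulate(t, schedule, catalog, eparams) for t in trajectories)
    result = ArmResult(
        arm=arm_name,
        le=acc.ly_discounted,
        le_undiscounted=acc.ly_undiscounted,
        qaly=acc.qaly,
        total_cost=acc.total_cost,
        therapy_cost=acc.therapy_cost,
        complication_cost=acc.complication_cost,
        management_cost=acc.management_cost,
    )
    return result, (trajectories if keep_trajectories else [])


def run_base_case(
    config: RunConfig,
    seed: Optional[int] = None,
    effects: Optional[Mapping[str, float]] = None,
    keep_trajectories: bool = True,
) -> BaseCaseResult:
    """Run the three-arm base case under common random numbers.

    ``effects`` overrides the per-arm HbA1c effects (used by the PSA); the
    default is each arm's point estimate.
    """
    t0 = time.perf_counter()
    seed = config.seed if seed is None else seed
    cohort = generate_cohort(config.cohort, seed)
    lam = config.threshold.lambda_usd
    arm_results: list[ArmResult] = []
    trajectories: dict[str, list[Trajectory]] = {}
    for arm in config.arms:
        effect = (
            effects[arm.name]
            if effects is not None and arm.name in effects
            else sample_treatment_effect(arm.efficacy_spec(), "point")
        )
        res, trajs = run_arm(config, arm.name, effect, seed, cohort, keep_trajectories)
        arm_results.append(res)
        if keep_trajectories:
            trajectories[arm.name] = trajs
        logger.info(
            "arm %s: effect %+0.2f, LE %.4f, QALY %.4f, cost %.2f",
            arm.name, effect, res.le, res.qaly, res.total_cost,
        )
    names = [a.name for a in config.arms]
    pairs = [(names[i], names[j]) for i in range(len(names)) for j in range(i + 1, len(names))]
    comparisons = [
        compare(next(r for r in arm_results if r.arm == a),
                next(r for r in arm_results if r.arm == b), lam)
        for a, b in pairs
    ]
    runtime = time.perf_counter() - t0
    logger.info("base case: %d arms, seed %d, %.2fs", len(names), seed, runtime)
    return BaseCaseResult(
        arm_results=arm_results,
        comparisons=comparisons,
        lambda_usd=lam,
        seed=seed,
        trajectories=trajectories,
        runtime_s=runtime,
    )


# ---------------------------------------------------------------------------
# manifest / serialization
# ---------------------------------------------------------------------------


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    version: str
    created_utc: str
    outputs: dict[str, str] = field(default_factory=dict)


def build_manifest(config: RunConfig, seed: int, outputs: Mapping[str, str]) -> RunManifest:
    return RunManifest(
        config_hash=config_hash(config),
        seed=seed,
        version=_version,
        created_utc=datetime.datetime.now(datetime.timezone.utc).isoformat(),
        outputs=dict(outputs),
    )


def write_manifest(manifest: RunManifest, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(
            {
                "config_hash": manifest.config_hash,
                "seed": manifest.seed,
                "version": manifest.version,
                "created_utc": manifest.created_utc,
                "outputs": manifest.outputs,
            },
            fh,
            indent=2,
            sort_keys=True,
        )
        fh.write("\n")


def write_base_case_csv(result: BaseCaseResult, path: str | Path) -> None:
    """Table-shaped CSV with stable float formatting (bit-stable re-runs)."""
    result.table().to_csv(path, float_format="%.6f")
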