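"""Threshold pricing: bisection on a drug's annual cost until its ICUR
against the reference arm equals the willingness-to-pay threshold λ.

Price changes leave events and QALYs untouched, so the base-case
trajectories are simulated once and only the cost accumulation is repeated
at each candidate price. The incremental cost is affine in the annual price
(its slope is the discounted, survival-weighted expected years on the drug),
so the bisection result must agree with the closed-form solve
``ΔCost(c*) = λ·ΔQALY``; that identity is the test oracle. For the
dose-escalation drug both the first-year and maintenance costs scale by the
common factor (a price cut applies uniformly), and the reported annual cost
is the maintenance-year cost.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass
from typing import Callable, Optional

from .config import RunConfig, build_cost_schedule, build_economic_params, build_utility_catalog
from .economics import accumulate, mean_accumulation
from .exceptions import InputError
from .pipeline import BaseCaseResult, run_base_case

logger = logging.getLogger("t2dcua")


@dataclass(frozen=True)
class PriceSearchResult:
    arm: str
    reference: str
    threshold_annual_cost: float
    achieved_icur: Optional[float]
    percent_reduction: float
    iterations: int
    converged: bool


def percent_reduction(base_annual: float, threshold_annual: float) -> float:
    """Price reduction in percent: 100 × (1 − threshold/base)."""
    if base_annual <= 0:
        raise InputError("base_annual must be > 0")
    return 100.0 * (1.0 - threshold_annual / base_annual)


def bisect_threshold_cost(
    delta_cost_fn: Callable[[float], float],
    delta_qaly: float,
    lam: float,
    lo: float,
    hi: float,
    tol_icur: float = 0.01,
    tol_price: float = 0.01,
    max_iter: int = 60,
) -> tuple[float, Optional[float], int, bool]:
    """Bisect the annual cost c in [lo, hi] until |ΔCost(c)/ΔQALY − λ| ≤ tol.

    ``delta_cost_fn(c)`` is ΔCost of arm-vs-reference when the arm's annual
    cost is c; it must be non-decreasing in c. Equivalent root statement:
    INMB(c) = ΔQALY·λ − ΔCost(c) = 0. Returns (cost, achieved ICUR,
    iterations, converged).

    - already cost-effective at ``hi`` (INMB ≥ 0): returns ``hi`` at once;
    - not reachable even at ``lo`` (INMB < 0): returns ``lo``, unconverged.
    """
    if not lo < hi:
        raise InputError("require lo < hi")

    def icur_at(c: float) -> Optional[float]:
        return delta_cost_fn(c) / delta_qaly if delta_qaly != 0 else None

    def inmb_at(c: float) -> float:
        return delta_qaly * lam - delta_cost_fn(c)

    if inmb_at(hi) >= 0:
        return hi, icur_at(hi), 0, True
    if inmb_at(lo) < 0:
        return lo, icur_at(lo), 0, False

    iterations = 0
    a, b = lo, hi  # inmb(a) >= 0 > inmb(b)
    mid = 0.5 * (a + b)
    while iterations < max_iter:
        iterations += 1
        mid = 0.5 * (a + b)
        icur_mid = icur_at(mid)
        if icur_mid is not None and abs(icur_mid - lam) <= tol_icur:
            return mid, icur_mid, iterations, True
        if inmb_at(mid) >= 0:
            a = mid
        else:
            b = mid
        if b - a <= tol_price:
            mid = 0.5 * (a + b)
            return mid, icur_at(mid), iterations, True
    return mid, icur_at(mid), iterations, False


def binary_search_price(
    config: RunConfig,
    arm: str,
    reference: str,
    lam: Optional[float] = None,
    lo: float = 0.0,
    hi: Optional[float] = None,
    base_result: Optional[BaseCaseResult] = None,
    seed: Optional[int] = None,
) -> PriceSearchResult:
    """Annual cost of ``arm`` at which its comparison against ``reference``
    reaches λ, with the implied percent price reduction.

    Trajectories come from one base-case run (cached in ``base_result`` if
    provided); each bisection step only re-accumulates the arm's costs with a
    uniformly scaled drug price. The search interval defaults to
    [0, current annual cost].
    """
    lam = config.threshold.lambda_usd if lam is None else lam
    if base_result is None:
        base_result = run_base_case(config, seed=seed, keep_trajectories=True)
    if arm not in base_result.trajectories:
        raise InputError(f"base result lacks trajectories for arm {arm!r}")

    econ = config.economics
    catalog = build_utility_catalog(econ)
    eparams = build_economic_params(econ)
    arm_cfg = config.arm(arm)
    base_schedule = build_cost_schedule(arm_cfg, econ)
    base_annual = base_schedule.therapy_maintenance
    if base_annual <= 0:
        raise InputError(f"arm {arm!r} has zero annual therapy cost; nothing to search")
    hi = base_annual if hi is None else hi

    trajs = base_result.trajectories[arm]
    ref_total = base_result.arm(reference).total_cost
    delta_qaly = base_result.arm(arm).qaly - base_result.arm(reference).qaly

    def delta_cost_fn(annual_cost: float) -> float:
        scale = annual_cost / base_annual
        scaled_arm = dataclasses.replace(
            arm_cfg, therapy=dataclasses.replace(arm_cfg.therapy, price_scale=scale)
        )
        schedule = build_cost_schedule(scaled_arm, econ)
        acc = mean_accumulation(accumulate(t, schedule, catalog, eparams) for t in trajs)
        return acc.total_cost - ref_total

    cost, icur, iterations, converged = bisect_threshold_cost(
        delta_cost_fn,
        delta_qaly,
        lam,
        lo,
        hi,
        tol_icur=config.pricing.tol_icur,
        tol_price=config.pricing.tol_price,
        max_iter=config.pricing.max_iter,
    )
    result = PriceSearchResult(
        arm=arm,
        reference=reference,
        threshold_annual_cost=cost,
        achieved_icur=icur,
        percent_reduction=percent_reduction(base_annual, cost),
        iterations=iterations,
        converged=converged,
    )
    logger.info(
        "price search %s vs %s: annual cost %.2f (%.2f%% reduction), ICUR %s, %d iterations",
        arm, reference, cost, result.percent_reduction,
        "n/a" if icur is None else f"{icur:.2f}", iterations,
    )
    return result


def max_bisection_iterations(lo: float, hi: float, tol_price: float) -> int:
    """Upper bound ⌈log2((hi − lo) / tol)⌉ on the bisection iteration count."""
    if tol_price <= 0 or hi <= lo:
        raise InputError("require hi > lo and tol_price > 0")
    return max(0, math.ceil(math.log2((hi - lo) / tol_price)))
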