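"""Cost-utility decision calculus: λ, ICUR, INMB, absolute NMB, dominance.

The willingness-to-pay threshold λ is a GDP-per-capita multiple computed in
yuan and converted to dollars (3 × ¥72,447 / 6.8974 = $31,510.57/QALY in the
base case). For a pairwise comparison A vs B with ΔQALY = QALY_A − QALY_B and
ΔCost = Cost_A − Cost_B:

- ICUR = ΔCost / ΔQALY, reported only when both deltas share a sign;
- INMB = ΔQALY·λ − ΔCost (positive favours A);
- absolute NMB = QALY·λ − Cost per arm (its ranking orders the strategies);
- dominance: A dominates when it gains QALYs and saves cost; in the
  both-positive quadrant A is cost-effective iff ICUR < λ; in the
  both-negative quadrant A is favoured iff ICUR > λ (savings per QALY
  forgone exceed λ). ΔQALY = 0 ties resolve by cost sign.

absolute_nmb(A) − absolute_nmb(B) == inmb(A, B) holds identically, which
reconciles the two net-benefit indicators.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import pandas as pd

from .exceptions import InputError

# verdict labels for "A vs B"
A_DOMINANT = "A_dominant"
B_DOMINANT = "B_dominant"
A_COST_EFFECTIVE = "A_cost_effective"
A_NOT_COST_EFFECTIVE = "A_not_cost_effective"
EQUIVALENT = "equivalent"

VERDICTS = (A_DOMINANT, B_DOMINANT, A_COST_EFFECTIVE, A_NOT_COST_EFFECTIVE, EQUIVALENT)
#: verdicts under which A is the favoured strategy
FAVOURS_A = (A_DOMINANT, A_COST_EFFECTIVE)


@dataclass(frozen=True)
class ArmResult:
    """Per-arm lifetime outcome: life expectancy, QALYs and cost subtotals ($)."""

    arm: str
    le: float  # discounted life expectancy, years
    qaly: float
    total_cost: float
    therapy_cost: float = 0.0
    complication_cost: float = 0.0
    management_cost: float = 0.0
    le_undiscounted: float = float("nan")

    def __post_init__(self) -> None:
        if self.qaly > self.le + 1e-9:
            raise InputError(f"{self.arm}: QALYs ({self.qaly}) cannot exceed LE ({self.le})")
        if self.total_cost < 0:
            raise InputError(f"{self.arm}: total cost must be >= 0")


@dataclass(frozen=True)
class Threshold:
    """Willingness-to-pay threshold as a GDP-per-capita multiple."""

    gdp_per_capita_cny: float = 72447.0
    multiplier: float = 3.0
    fx: float = 6.8974

    @property
    def lambda_usd(self) -> float:
        return lambda_threshold(self.gdp_per_capita_cny, self.multiplier, self.fx)


@dataclass(frozen=True)
class CUAComparison:
    """Pairwise comparison A vs B."""

    arm_a: str
    arm_b: str
    delta_qaly: float
    delta_cost: float
    icur: Optional[float]  # None where dominance/equivalence short-circuits
    inmb: float
    verdict: str


def lambda_threshold(gdp_cny: float, multiplier: float, fx: float) -> float:
    """λ in $/QALY: GDP per capita (¥) × multiplier / exchange rate."""
    if gdp_cny <= 0 or fx <= 0 or multiplier < 0:
        raise InputError("gdp_cny and fx must be > 0, multiplier >= 0")
    return gdp_cny * multiplier / fx


def icur(a: ArmResult, b: ArmResult) -> Union[float, str]:
    """ΔCost/ΔQALY when both deltas share a (nonzero) sign; otherwise the
    short-circuit verdict (dominance or tie)."""
    dq = a.qaly - b.qaly
    dc = a.total_cost - b.total_cost
    if (dq > 0 and dc > 0) or (dq < 0 and dc < 0):
        return dc / dq
    if dq > 0 or (dq == 0 and dc < 0):
        return A_DOMINANT
    if dq < 0 or (dq == 0 and dc > 0):
        return B_DOMINANT
    return EQUIVALENT


def inmb(a: ArmResult, b: ArmResult, lam: float) -> float:
    """Incremental net monetary benefit ΔQALY·λ − ΔCost; positive favours A."""
    return (a.qaly - b.qaly) * lam - (a.total_cost - b.total_cost)


def absolute_nmb(arm: ArmResult, lam: float) -> float:
    """Absolute net monetary benefit QALY·λ − Cost."""
    return arm.qaly * lam - arm.total_cost


def classify_dominance(
    delta_qaly: float,
    delta_cost: float,
    icur_value: Optional[float],
    lam: float,
) -> str:
    """Verdict for A vs B following the standard quadrant decision table.

    Strict inequalities throughout, so ICUR = λ (INMB = 0) is classified as
    not cost-effective and the equivalence INMB > 0 ⇔ favourable verdict is
    exact in every quadrant.
    """
    if delta_qaly == 0 and delta_cost == 0:
        return EQUIVALENT
    if delta_qaly == 0:
        return A_DOMINANT if delta_cost < 0 else B_DOMINANT
    if delta_qaly > 0 and delta_cost <= 0:
        return A_DOMINANT
    if delta_qaly < 0 and delta_cost >= 0:
        return B_DOMINANT
    if icur_value is None:
        icur_value = delta_cost / delta_qaly
    if delta_qaly > 0:  # (+, +) quadrant
        return A_COST_EFFECTIVE if icur_value < lam else A_NOT_COST_EFFECTIVE
    # (-, -) quadrant: savings per QALY forgone must exceed λ to favour A
    return A_COST_EFFECTIVE if icur_value > lam else A_NOT_COST_EFFECTIVE


def compare(a: ArmResult, b: ArmResult, lam: float) -> CUAComparison:
    """Full pairwise comparison of two simulated arms at threshold λ."""
    dq = a.qaly - b.qaly
    dc = a.total_cost - b.total_cost
    ratio = icur(a, b)
    icur_value = ratio if isinstance(ratio, float) else None
    return CUAComparison(
        arm_a=a.arm,
        arm_b=b.arm,
        delta_qaly=dq,
        delta_cost=dc,
        icur=icur_value,
        inmb=inmb(a, b, lam),
        verdict=classify_dominance(dq, dc, icur_value, lam),
    )


def comparison_table(
    results: Sequence[ArmResult],
    lam: float,
    pairs: Optional[Sequence[tuple[str, str]]] = None,
) -> pd.DataFrame:
    """Base-case table: one column per arm plus one per pairwise comparison,
    with the row vocabulary of the published long-term-outcomes table."""
    by_name = {r.arm: r for r in results}
    if pairs is None:
        names = [r.arm for r in results]
        pairs = [(names[i], names[j]) for i in range(len(names)) for j in range(i + 1, len(names))]
    rows = [
        "LE, years",
        "LE (undiscounted), years",
        "QALYs, QALY",
        "Therapy costs ($)",
        "Cost of complications ($)",
        "Management costs ($)",
        "Total cost ($)",
        "ICUR (QALY)",
        "INMB ($)",
        "Absolute NMB ($)",
        "Verdict",
    ]
    table: dict[str, list] = {}
    for r in results:
        table[r.arm] = [
            r.le, r.le_undiscounted, r.qaly, r.therapy_cost, r.complication_cost,
            r.management_cost, r.total_cost, None, None, absolute_nmb(r, lam), None,
        ]
    for a_name, b_name in pairs:
        cmp_ = compare(by_name[a_name], by_name[b_name], lam)
        a, b = by_name[a_name], by_name[b_name]
        icur_cell = "Dominance" if cmp_.icur is None else cmp_.icur
        table[f"{a_name} vs. {b_name}"] = [
            a.le - b.le,
            a.le_undiscounted - b.le_undiscounted,
            cmp_.delta_qaly,
            a.therapy_cost - b.therapy_cost,
            a.complication_cost - b.complication_cost,
            a.management_cost - b.management_cost,
            cmp_.delta_cost,
            icur_cell,
            cmp_.inmb,
            None,
            cmp_.verdict,
        ]
    return pd.DataFrame(table, index=rows)
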