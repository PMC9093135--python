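"""Cost and QALY accrual over a cohort trace, and incremental statistics.

Utilities weight time alive (utility_pfs while progression-free,
utility_pd after progression; both derived in the source evidence by
dividing a QLQ-C30 score by 126).  Costs follow an explicit schedule —
the published parameter table does not state timing conventions, so every
choice is configurable:

* PD-L1 testing, pretreatment and adverse-event management are one-time
  costs at model entry;
* drug acquisition accrues per cycle while progression-free, capped by a
  treatment-duration stop rule defaulting to the trial's median treatment
  durations (24.9 weeks active arm, 13.1 weeks comparator);
* best-supportive-care costs accrue per cycle while progression-free;
* imaging (one scan every 8 weeks) accrues per cycle in PFS at its
  monthly equivalent;
* the post-progression cost (per patient per month) accrues per cycle in
  PD.

All money is in USD; a converter from CNY at the fixed 6.36 CNY/USD rate
is provided for ingesting new prices.  Discounting is annual (3% US, 5%
China) applied at cycle start.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .exceptions import ConfigurationError, InvalidInputError
from .markov_engine import ModelSpec
from .sensitivity import ParameterSpec

__all__ = [
    "EconInputs",
    "CostItem",
    "CostSchedule",
    "ArmResult",
    "ICERResult",
    "utility_from_qlqc30",
    "cny_to_usd",
    "discount_factor",
    "accrue",
    "icer",
    "net_monetary_benefit",
    "weeks_to_months",
    "default_schedule",
    "TREATMENT_DURATION_MONTHS",
    "IMAGING_INTERVAL_MONTHS",
]

#: fixed published exchange rate, CNY per USD
CNY_PER_USD = 6.36

_UTILITY_FIELDS = ("utility_pfs", "utility_pd")
_COST_FIELDS = (
    "cost_pdl1_test",
    "cost_pretreatment",
    "cost_ae_con",
    "cost_ae_ave",
    "cost_imaging",
    "cost_pd_monthly",
    "cost_drug_monthly",
    "cost_bsc_ave_monthly",
    "cost_bsc_con_monthly",
)


def weeks_to_months(weeks: float) -> float:
    """Weeks → months at 52.18 weeks per 12 months."""
    return weeks * 12.0 / 52.18


#: median treatment durations from the trial, converted to months
TREATMENT_DURATION_MONTHS = {
    "AVE": weeks_to_months(24.9),
    "CON": weeks_to_months(13.1),
}

#: one imaging assessment every 8 weeks
IMAGING_INTERVAL_MONTHS = weeks_to_months(8.0)


@dataclass
class EconInputs:
    """One country × population block of the economic parameter table."""

    utility_pfs: ParameterSpec
    utility_pd: ParameterSpec
    cost_pdl1_test: ParameterSpec
    cost_pretreatment: ParameterSpec
    cost_ae_con: ParameterSpec
    cost_ae_ave: ParameterSpec
    cost_imaging: ParameterSpec
    cost_pd_monthly: ParameterSpec
    cost_drug_monthly: ParameterSpec
    cost_bsc_ave_monthly: ParameterSpec
    cost_bsc_con_monthly: ParameterSpec
    annual_discount_rate: float = 0.03
    wtp: float = 150_000.0
    country: str = "US"
    population: str = "overall"

    def __post_init__(self):
        for f in _UTILITY_FIELDS:
            p = getattr(self, f)
            if not (0 <= p.low and p.base <= 1.0000001):
                raise ConfigurationError(f"{f}: utilities must lie in [0, 1]")
        for f in _COST_FIELDS:
            if getattr(self, f).low < 0:
                raise ConfigurationError(f"{f}: costs must be non-negative")
        if not (0 <= self.annual_discount_rate < 1):
            raise ConfigurationError("discount rate must lie in [0, 1)")

    def parameters(self) -> list[ParameterSpec]:
        """All uncertain parameters, for DSA/PSA."""
        return [getattr(self, f) for f in _UTILITY_FIELDS + _COST_FIELDS]

    def base_values(self) -> dict[str, float]:
        return {p.name: p.base for p in self.parameters()}


@dataclass(frozen=True)
class CostItem:
    """Timing and applicability of one cost parameter.

    ``base`` for a per-cycle item is a per-month rate unless
    ``frequency_months`` is set, in which case it is a per-occurrence cost
    incurred every ``frequency_months`` (accrued at its monthly
    equivalent).
    """

    name: str
    timing: str  # one_time_at_entry | per_cycle
    states: tuple[str, ...] = ("PFS",)
    arms: tuple[str, ...] = ("AVE", "CON")
    stop_rule: str = "none"  # none | while_on_treatment
    frequency_months: float | None = None

    def __post_init__(self):
        if self.timing not in ("one_time_at_entry", "per_cycle"):
            raise ConfigurationError(f"{self.name}: unknown timing {self.timing!r}")
        if self.stop_rule not in ("none", "while_on_treatment"):
            raise ConfigurationError(f"{self.name}: unknown stop rule {self.stop_rule!r}")


@dataclass
class CostSchedule:
    """Complete cost-timing convention: every cost item exactly once."""

    items: tuple[CostItem, ...]
    treatment_stop_months: Mapping[str, float] = field(
        default_factory=lambda: dict(TREATMENT_DURATION_MONTHS)
    )

    def __post_init__(self):
        names = [it.name for it in self.items]
        if len(names) != len(set(names)):
            raise ConfigurationError("duplicate cost items in schedule")

    def validate_against(self, values: Mapping[str, float]) -> None:
        scheduled = {it.name for it in self.items}
        missing = [k for k in values if k.startswith("cost_") and k not in scheduled]
        if missing:
            raise ConfigurationError(f"schedule missing cost items: {missing}")


def default_schedule() -> CostSchedule:
    return CostSchedule(
        items=(
            CostItem("cost_pdl1_test", "one_time_at_entry"),
            CostItem("cost_pretreatment", "one_time_at_entry"),
            CostItem("cost_ae_ave", "one_time_at_entry", arms=("AVE",)),
            CostItem("cost_ae_con", "one_time_at_entry", arms=("CON",)),
            CostItem("cost_drug_monthly", "per_cycle", states=("PFS",), arms=("AVE",),
                     stop_rule="while_on_treatment"),
            CostItem("cost_bsc_ave_monthly", "per_cycle", states=("PFS",), arms=("AVE",)),
            CostItem("cost_bsc_con_monthly", "per_cycle", states=("PFS",), arms=("CON",)),
            CostItem("cost_imaging", "per_cycle", states=("PFS",),
                     frequency_months=IMAGING_INTERVAL_MONTHS),
            CostItem("cost_pd_monthly", "per_cycle", states=("PD",)),
        )
    )


@dataclass(frozen=True)
class ArmResult:
    """Discounted totals for one strategy arm."""

    total_cost: float
    total_qalys: float

    def __post_init__(self):
        if self.total_cost < 0 or self.total_qalys < 0:
            raise InvalidInputError("arm totals must be non-negative")


@dataclass(frozen=True)
class ICERResult:
    """Incremental statistics of the active arm vs the comparator."""

    delta_cost: float
    delta_qalys: float
    icer: float | None
    flag: str = ""  # "" | dominant | dominated | southwest | undefined


def utility_from_qlqc30(score: float) -> float:
    """Utility = QLQ-C30 score / 126; 1 is perfect health, 0 is death."""
    if not (0 <= score <= 126):
        raise InvalidInputError(f"QLQ-C30 score must lie in [0, 126], got {score}")
    return score / 126.0


def cny_to_usd(amount: float, rate: float = CNY_PER_USD) -> float:
    """Convert CNY to USD at ``rate`` CNY per USD (published fix: 6.36)."""
    if rate <= 0:
        raise InvalidInputError("exchange rate must be positive")
    if amount < 0:
        raise InvalidInputError("amount must be non-negative")
    return amount / rate


def discount_factor(annual_rate: float, cycle_index, cycles_per_year: int = 12):
    """(1 + r)^(−cycle/cycles_per_year): present-value factor at cycle start."""
    if annual_rate < 0:
        raise InvalidInputError("discount rate must be >= 0")
    cycle_index = np.asarray(cycle_index, dtype=float)
    out = (1.0 + annual_rate) ** (-cycle_index / cycles_per_year)
    return float(out) if out.ndim == 0 else out


def accrue(
    trace: np.ndarray,
    inputs: EconInputs | Mapping[str, float],
    schedule: CostSchedule,
    spec: ModelSpec,
) -> ArmResult:
    """Discounted cost and QALY totals for one arm over a cohort trace.

    QALYs: Σ_t [occ_PFS(t)·u_PFS + occ_PD(t)·u_PD] · (cycle/12) · df(t).
    Costs: one-time items at entry plus per-cycle items × applicable state
    occupancy × df(t), honouring stop rules.  With the half-cycle
    correction enabled, mid-cycle occupancy (average of the cycle's start
    and end rows) replaces start-of-cycle occupancy.
    """
    values = inputs.base_values() if isinstance(inputs, EconInputs) else dict(inputs)
    rate = (
        inputs.annual_discount_rate
        if isinstance(inputs, EconInputs)
        else values.get("annual_discount_rate", 0.0)
    )
    schedule.validate_against(values)
    h = spec.horizon
    if trace.shape != (h + 1, 3):
        raise InvalidInputError(f"trace shape {trace.shape} != ({h + 1}, 3)")
    dt = spec.cycle_length
    cycles = np.arange(h)
    df = discount_factor(rate, cycles * dt, cycles_per_year=12)
    occ = 0.5 * (trace[:-1] + trace[1:]) if spec.half_cycle_correction else trace[:-1]
    occ_by_state = {"PFS": occ[:, 0], "PD": occ[:, 1]}

    u_pfs = values["utility_pfs"]
    u_pd = values["utility_pd"]
    qalys = float(
        np.sum((occ[:, 0] * u_pfs + occ[:, 1] * u_pd) * (dt / 12.0) * df)
    )

    arm = spec.arm
    cost = 0.0
    start_times = cycles * dt
    for item in schedule.items:
        if arm and item.arms and arm not in item.arms:
            continue
        base = values[item.name]
        if item.timing == "one_time_at_entry":
            cost += base  # df(0) = 1
            continue
        rate_per_month = base / item.frequency_months if item.frequency_months else base
        amount = rate_per_month * dt
        occ_sum = np.zeros(h)
        for s in item.states:
            occ_sum = occ_sum + occ_by_state[s]
        frac = np.ones(h)
        if item.stop_rule == "while_on_treatment":
            stop = schedule.treatment_stop_months.get(arm or "AVE")
            if stop is not None:
                frac = np.clip((stop - start_times) / dt, 0.0, 1.0)
        cost += float(np.sum(amount * occ_sum * frac * df))
    return ArmResult(total_cost=cost, total_qalys=qalys)


def icer(ave: ArmResult, con: ArmResult) -> ICERResult:
    """Incremental cost-effectiveness of the active arm vs the comparator.

    ΔE > 0, ΔC > 0 → the ratio; ΔE > 0, ΔC ≤ 0 → dominant; ΔE < 0,
    ΔC ≥ 0 → dominated; ΔE < 0, ΔC < 0 → ratio with a "southwest" flag
    (less effective but cheaper); ΔE = 0 → undefined, no division.
    """
    dc = ave.total_cost - con.total_cost
    de = ave.total_qalys - con.total_qalys
    if de == 0:
        return ICERResult(dc, de, None, "undefined")
    if de > 0:
        if dc <= 0:
            return ICERResult(dc, de, None, "dominant")
        return ICERResult(dc, de, dc / de, "")
    if dc >= 0:
        return ICERResult(dc, de, None, "dominated")
    return ICERResult(dc, de, dc / de, "southwest")


def net_monetary_benefit(arm: ArmResult, wtp: float) -> float:
    """NMB = WTP × QALYs − cost."""
    if wtp < 0:
        raise InvalidInputError("WTP must be >= 0")
    return wtp * arm.total_qalys - arm.total_cost
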