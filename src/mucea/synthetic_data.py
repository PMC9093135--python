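"""Synthetic trial data with known ground truth.

No patient-level data from the source trial are available, so every
pipeline input is emulated here: two-arm Weibull event times with
independent censoring, the figure-digitization process (sparse,
jittered curve coordinates plus a numbers-at-risk table), and a
Gompertz-shaped life table.  The base-case scenario is calibrated so
each arm/endpoint reproduces the trial's printed median survival times
(active arm OS 21.4 months, PFS 3.7; comparator OS 14.3, PFS 2.0) with
350 subjects per arm; the Weibull shape is set to γ = 1.2 (a mild
increasing hazard — no shape is published, only medians are calibrated)
and censoring to 20%, typical of maintenance-trial follow-up.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import quad
from scipy.optimize import brentq

from .exceptions import InvalidInputError
from .km_ipd import (
    DigitizedCurve,
    IPDRecord,
    RiskTable,
    km_estimator,
    km_step_function,
)
from .lifetable import LifeTable

__all__ = [
    "ArmEndpointTruth",
    "TrialScenario",
    "FixtureBundle",
    "simulate_ipd",
    "digitize_curve",
    "make_life_table_fixture",
    "make_base_case_fixture",
    "BASE_CASE_MEDIANS",
]

#: published median survival times (months) per arm × endpoint
BASE_CASE_MEDIANS = {
    ("AVE", "OS"): 21.4,
    ("CON", "OS"): 14.3,
    ("AVE", "PFS"): 3.7,
    ("CON", "PFS"): 2.0,
}


@dataclass(frozen=True)
class ArmEndpointTruth:
    """Ground-truth Weibull (λ, γ) for one arm × endpoint."""

    arm: str
    endpoint: str
    lambda_scale: float
    gamma_shape: float

    @property
    def median(self) -> float:
        return (np.log(2.0) / self.lambda_scale) ** (1.0 / self.gamma_shape)


@dataclass
class TrialScenario:
    """Everything needed to simulate and digitize one synthetic trial."""

    truths: tuple[ArmEndpointTruth, ...]
    n_per_arm: int = 350
    censor_rate: float = 0.2
    max_follow: float = 42.0  # months
    n_points: int = 60
    jitter: float = 0.005
    n_risk_times: int = 6
    seed: int = 0

    def __post_init__(self):
        if self.n_per_arm < 10:
            raise InvalidInputError("n_per_arm must be >= 10")
        if not (0 <= self.jitter < 0.02):
            raise InvalidInputError("jitter amplitude must be < 0.02")
        if not (0 <= self.censor_rate < 1):
            raise InvalidInputError("censor_rate must lie in [0, 1)")


def _censoring_rate_for(lam: float, gam: float, target: float) -> float:
    """Exponential censoring rate μ with P(C < T) = target (pre-administrative)."""
    if target <= 0:
        return 0.0

    def p_censored(mu):
        # P(C < T) = ∫ μ e^{−μc} S_T(c) dc
        val, _ = quad(lambda c: mu * np.exp(-mu * c) * np.exp(-lam * c**gam), 0, np.inf)
        return val - target

    return brentq(p_censored, 1e-8, 1e3)


def simulate_ipd(
    lam: float,
    gam: float,
    n: int,
    censor_rate: float = 0.0,
    max_follow: float = np.inf,
    seed: int = 0,
    arm: str = "",
    endpoint: str = "",
) -> list[IPDRecord]:
    """Simulate right-censored Weibull event times.

    Event times by inversion, T = (−ln U / λ)^(1/γ); independent
    exponential censoring with its rate tuned so the expected censored
    fraction (before administrative cut-off) equals ``censor_rate``;
    administrative censoring at ``max_follow``.  Reproducible given seed.
    """
    if lam <= 0 or gam <= 0:
        raise InvalidInputError("λ and γ must be positive")
    if not (0 <= censor_rate < 1):
        raise InvalidInputError("censor_rate must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    u = rng.uniform(size=n)
    t_event = (-np.log(u) / lam) ** (1.0 / gam)
    if censor_rate > 0:
        mu = _censoring_rate_for(lam, gam, censor_rate)
        t_cens = rng.exponential(1.0 / mu, size=n)
    else:
        t_cens = np.full(n, np.inf)
    t_cens = np.minimum(t_cens, max_follow)
    obs = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    obs = np.maximum(obs, 1e-9)  # records require strictly positive times
    return [
        IPDRecord(time=float(t), event=int(e), arm=arm, endpoint=endpoint)
        for t, e in zip(obs, event)
    ]


def digitize_curve(
    ipd: list[IPDRecord],
    n_points: int = 50,
    jitter: float = 0.0,
    seed: int = 0,
    n_risk_times: int = 6,
) -> tuple[DigitizedCurve, RiskTable]:
    """Emulate figure digitization of the exact KM curve of ``ipd``.

    Samples the KM step function at ``n_points`` of its step corners (a
    careful digitizer clicks where the curve visibly drops, so sampled
    times sit at event times rather than on an arbitrary grid), adds
    uniform survival jitter of the given amplitude (clipped to [0, 1]),
    and tabulates true numbers at risk at ``n_risk_times`` evenly spaced
    times.  With jitter 0 the sampled values equal the KM estimate
    exactly.
    """
    if n_points < 4:
        raise InvalidInputError("n_points must be >= 4")
    km = km_estimator(ipd)
    S = km_step_function(km)
    t_max = max(r.time for r in ipd)
    corners = km.times[km.times > 0]
    if len(corners) >= n_points - 1:
        pick = np.unique(np.linspace(0, len(corners) - 1, n_points - 1).round().astype(int))
        grid = np.concatenate([[0.0], corners[pick]])
    else:
        grid = np.unique(np.concatenate([[0.0], corners, [t_max]]))
    if grid[-1] < t_max:
        grid = np.append(grid, t_max)
    surv = S(grid).copy()
    if jitter > 0:
        rng = np.random.default_rng(seed)
        surv = surv + rng.uniform(-jitter, jitter, size=len(grid))
    surv = np.clip(surv, 0.0, 1.0)
    surv[0] = 1.0
    curve = DigitizedCurve(
        times=grid, survival=np.minimum.accumulate(surv),
        endpoint=ipd[0].endpoint, arm=ipd[0].arm,
    )
    times = np.array([r.time for r in ipd])
    risk_times = np.linspace(0.0, t_max, n_risk_times, endpoint=False)
    n_at_risk = np.array([(times >= rt).sum() for rt in risk_times])
    return curve, RiskTable(times=risk_times, n_at_risk=n_at_risk)


def make_life_table_fixture(a: float = 5e-5, b: float = 0.09,
                            age_min: int = 40, age_max: int = 110) -> LifeTable:
    """Synthetic Gompertz-shaped life table: qx(age) = min(1, a·e^{b·age})."""
    ages = np.arange(age_min, age_max + 1)
    qx = np.minimum(1.0, a * np.exp(b * ages))
    return LifeTable(ages=ages, qx=qx)


@dataclass
class FixtureBundle:
    """All pipeline inputs generated from one scenario, with ground truth."""

    scenario: TrialScenario
    ipd: dict[tuple[str, str], list[IPDRecord]]
    curves: dict[tuple[str, str], DigitizedCurve]
    risk_tables: dict[tuple[str, str], RiskTable]
    life_table: LifeTable


def make_base_case_fixture(
    seed: int = 0,
    n_per_arm: int = 350,
    gamma_shape: float = 1.2,
    censor_rate: float = 0.2,
    jitter: float = 0.005,
    n_points: int = 60,
    n_risk_times: int = 6,
    max_follow: float = 42.0,
) -> FixtureBundle:
    """Trial-like input bundle calibrated to the printed survival medians.

    λ is solved from each median m as λ = ln 2 / m^γ, so
    median_survival(truth) equals the printed median exactly by
    construction.  Deterministic given ``seed``.
    """
    truths = tuple(
        ArmEndpointTruth(
            arm=arm,
            endpoint=ep,
            lambda_scale=float(np.log(2.0) / m**gamma_shape),
            gamma_shape=gamma_shape,
        )
        for (arm, ep), m in BASE_CASE_MEDIANS.items()
    )
    scenario = TrialScenario(
        truths=truths, n_per_arm=n_per_arm, censor_rate=censor_rate,
        max_follow=max_follow, n_points=n_points, jitter=jitter,
        n_risk_times=n_risk_times, seed=seed,
    )
    ss = np.random.SeedSequence(seed)
    sub = ss.generate_state(2 * len(truths)) % (2**31)
    ipd, curves, risk_tables = {}, {}, {}
    for i, truth in enumerate(truths):
        key = (truth.arm, truth.endpoint)
        ipd[key] = simulate_ipd(
            truth.lambda_scale, truth.gamma_shape, n_per_arm,
            censor_rate=censor_rate, max_follow=max_follow,
            seed=int(sub[2 * i]), arm=truth.arm, endpoint=truth.endpoint,
        )
        curves[key], risk_tables[key] = digitize_curve(
            ipd[key], n_points=n_points, jitter=jitter,
            seed=int(sub[2 * i + 1]), n_risk_times=n_risk_times,
        )
    return FixtureBundle(
        scenario=scenario, ipd=ipd, curves=curves,
        risk_tables=risk_tables, life_table=make_life_table_fixture(),
    )
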