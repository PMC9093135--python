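"""Three-state Markov cohort engine: PFS → PD → death.

The cohort starts entirely progression-free.  Each monthly cycle a
patient in PFS may progress (PD), die of background causes, or stay;
a patient in PD may die or stay; death is absorbing and there is no
PD → PFS backflow.  Transition probabilities vary by cycle: the PFS exit
probability comes from the PFS Weibull's conditional per-cycle
probability, background mortality from the life table at the cohort's
current age, and PD → death from the OS Weibull's conditional
probability floored at background mortality (which curve feeds which
transition is configurable — the evidence under-determines it).

State order everywhere: 0 = PFS, 1 = PD, 2 = death.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import InvalidInputError, ModelConstructionError
from .lifetable import LifeTable, monthly_background_mortality
from .parametric_survival import WeibullFit, transition_probability

__all__ = ["ModelSpec", "STATES", "build_transition_series", "run_cohort", "trace_to_frame"]

STATES = ("PFS", "PD", "death")


@dataclass
class ModelSpec:
    """Structural settings of the cohort model.

    The base case is a 1-month cycle over a 10-year horizon (120 cycles),
    starting age 68 (an assumption — the source trial's cohort age is not
    used directly), expected-value cohort (no microsimulation) and no
    half-cycle correction.

    ``competing_risk`` selects how the PFS exit probability is split:
    ``"subtraction"`` (default) takes p(PFS→PD) = max(0, p_exit − p_bg) so
    total PFS exit equals the PFS curve's conditional probability;
    ``"multiplicative"`` treats progression and background death as
    independent risks applied jointly.
    """

    cycle_length: float = 1.0  # months
    horizon: int = 120  # cycles
    starting_age: float = 68.0
    arm: str = ""
    population: str = "overall"
    country: str = "US"
    half_cycle_correction: bool = False
    competing_risk: str = "subtraction"
    pd_death_floor_background: bool = True

    def __post_init__(self):
        if self.horizon < 1 or self.cycle_length <= 0:
            raise InvalidInputError("horizon >= 1 and cycle_length > 0 required")
        if self.competing_risk not in ("subtraction", "multiplicative"):
            raise InvalidInputError("competing_risk must be 'subtraction' or 'multiplicative'")


def build_transition_series(
    pfs_fit: WeibullFit,
    os_fit: WeibullFit,
    table: LifeTable,
    spec: ModelSpec,
) -> np.ndarray:
    """Per-cycle 3x3 row-stochastic transition matrices, shape (horizon, 3, 3)."""
    h = spec.horizon
    dt = spec.cycle_length
    series = np.zeros((h, 3, 3))
    for t in range(h):
        a, b = t * dt, (t + 1) * dt
        age = spec.starting_age + a / 12.0
        p_bg = monthly_background_mortality(table, age)
        if dt != 1.0:  # rescale the monthly background probability to the cycle
            p_bg = 1.0 - (1.0 - p_bg) ** dt
        p_exit = transition_probability(pfs_fit, a, b)
        if spec.competing_risk == "subtraction":
            p_pfs_death = p_bg
            p_pfs_pd = max(0.0, p_exit - p_bg)
        else:
            p_pfs_death = p_bg
            p_pfs_pd = p_exit * (1.0 - p_bg)
        p_pd_death = transition_probability(os_fit, a, b)
        if spec.pd_death_floor_background:
            p_pd_death = max(p_pd_death, p_bg)

        for name, p in (("PFS→PD", p_pfs_pd), ("PFS→death", p_pfs_death),
                        ("PD→death", p_pd_death)):
            if not (0.0 <= p <= 1.0):
                raise ModelConstructionError(
                    f"cycle {t}: probability {name}={p:g} outside [0, 1]"
                )
        if p_pfs_pd + p_pfs_death > 1.0:
            raise ModelConstructionError(
                f"cycle {t}: PFS exit probabilities sum to {p_pfs_pd + p_pfs_death:g} > 1"
            )
        m = series[t]
        m[0, 1] = p_pfs_pd
        m[0, 2] = p_pfs_death
        m[0, 0] = 1.0 - p_pfs_pd - p_pfs_death
        m[1, 2] = p_pd_death
        m[1, 1] = 1.0 - p_pd_death
        m[2, 2] = 1.0
    _validate_series(series)
    return series


def _validate_series(series: np.ndarray) -> None:
    if series.ndim != 3 or series.shape[1:] != (3, 3):
        raise InvalidInputError("transition series must have shape (horizon, 3, 3)")
    if np.any(series < -1e-12) or np.any(series > 1 + 1e-12):
        raise InvalidInputError("transition probabilities must lie in [0, 1]")
    rowsums = series.sum(axis=2)
    if np.max(np.abs(rowsums - 1.0)) > 1e-12:
        raise InvalidInputError("transition matrix rows must sum to 1")
    if np.any(series[:, 2, :2] != 0) or np.any(series[:, 2, 2] != 1):
        raise InvalidInputError("death must be absorbing")
    if np.any(series[:, 1, 0] != 0):
        raise InvalidInputError("no PD→PFS backflow allowed")


def run_cohort(series: np.ndarray, spec: ModelSpec | None = None) -> np.ndarray:
    """Propagate the cohort: occupancy(t+1) = occupancy(t) @ matrix(t).

    Returns the full trace, shape (horizon+1, 3), starting at (1, 0, 0).
    """
    _validate_series(series)
    if spec is not None and len(series) != spec.horizon:
        raise InvalidInputError(
            f"series length {len(series)} != spec horizon {spec.horizon}"
        )
    h = len(series)
    trace = np.zeros((h + 1, 3))
    trace[0] = (1.0, 0.0, 0.0)
    for t in range(h):
        trace[t + 1] = trace[t] @ series[t]
    return trace


def trace_to_frame(trace: np.ndarray) -> pd.DataFrame:
    """Long-format (cycle, state, value) frame for CSV audit export."""
    h = trace.shape[0]
    return pd.DataFrame(
        {
            "cycle": np.repeat(np.arange(h), 3),
            "state": np.tile(STATES, h),
            "value": trace.ravel(),
        }
    )
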