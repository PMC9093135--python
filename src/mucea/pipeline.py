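"""End-to-end pipeline: curves → IPD → fits → Markov → economics → SA.

`ScenarioModel` packages one country × population scenario.  The cohort
traces depend only on the survival fits, life table and model settings —
not on the economic parameters — so they are computed once and every
DSA/PSA evaluation reuses them; a 1,000-draw PSA is then just 1,000
cheap accrual passes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .economics import (
    ArmResult,
    CostSchedule,
    EconInputs,
    ICERResult,
    accrue,
    default_schedule,
    icer,
    net_monetary_benefit,
)
from .km_ipd import (
    DigitizedCurve,
    IPDRecord,
    RiskTable,
    km_estimator,
    reconstruct_ipd,
    sup_norm,
)
from .lifetable import LifeTable
from .markov_engine import ModelSpec, build_transition_series, run_cohort
from .parametric_survival import WeibullFit, fit_weibull
from .sensitivity import (
    CEACPoint,
    PSAResult,
    TornadoEntry,
    ceac,
    default_wtp_grid,
    one_way_dsa,
    run_psa,
)

__all__ = ["ScenarioModel", "reconstruct_all", "fit_all", "ARMS", "ENDPOINTS"]

logger = logging.getLogger(__name__)

ARMS = ("AVE", "CON")
ENDPOINTS = ("PFS", "OS")


def reconstruct_all(
    curves: Mapping[tuple[str, str], DigitizedCurve],
    risk_tables: Mapping[tuple[str, str], RiskTable] | None,
    total_n: int,
) -> tuple[dict[tuple[str, str], list[IPDRecord]], dict[tuple[str, str], float]]:
    """Reconstruct IPD for every arm × endpoint; return records and fidelity.

    Fidelity is the sup-norm between each input curve and the KM estimate
    of its reconstruction.  Missing risk tables fall back to the
    no-censoring-before-end assumption with a logged warning.
    """
    ipd, fidelity = {}, {}
    for key, curve in curves.items():
        rt = risk_tables.get(key) if risk_tables else None
        if rt is None:
            logger.warning("no risk table for %s: assuming no censoring before end", key)
        ipd[key] = reconstruct_ipd(curve, rt, total_n=total_n)
        fidelity[key] = sup_norm(curve, km_estimator(ipd[key]), at_times=curve.times)
        logger.info("reconstructed %s: n=%d, sup-norm fidelity %.4f",
                    key, len(ipd[key]), fidelity[key])
    return ipd, fidelity


def fit_all(
    ipd: Mapping[tuple[str, str], Sequence[IPDRecord]],
) -> dict[tuple[str, str], WeibullFit]:
    """Weibull MLE per arm × endpoint."""
    fits = {}
    for key, records in ipd.items():
        fits[key] = fit_weibull(list(records))
        logger.info("fit %s: λ=%.5g γ=%.4g (n=%d)", key,
                    fits[key].lambda_scale, fits[key].gamma_shape, fits[key].n_obs)
    return fits


@dataclass
class ScenarioModel:
    """One evaluable cost-effectiveness scenario (country × population)."""

    fits: Mapping[tuple[str, str], WeibullFit]
    life_table: LifeTable
    econ: EconInputs
    model_spec: ModelSpec = field(default_factory=ModelSpec)
    schedule: CostSchedule = field(default_factory=default_schedule)

    def __post_init__(self):
        for arm in ARMS:
            for ep in ENDPOINTS:
                if (arm, ep) not in self.fits:
                    raise KeyError(f"missing Weibull fit for {(arm, ep)}")
        self._traces = {}
        for arm in ARMS:
            spec = self._arm_spec(arm)
            series = build_transition_series(
                self.fits[(arm, "PFS")], self.fits[(arm, "OS")],
                self.life_table, spec,
            )
            self._traces[arm] = run_cohort(series, spec)

    def _arm_spec(self, arm: str) -> ModelSpec:
        import dataclasses

        return dataclasses.replace(
            self.model_spec, arm=arm,
            country=self.econ.country, population=self.econ.population,
        )

    def trace(self, arm: str) -> np.ndarray:
        return self._traces[arm]

    def arm_result(self, arm: str, overrides: Mapping[str, float] | None = None) -> ArmResult:
        values = self.econ.base_values()
        if overrides:
            values.update(overrides)
        values["annual_discount_rate"] = self.econ.annual_discount_rate
        return accrue(self._traces[arm], values, self.schedule, self._arm_spec(arm))

    def evaluate(self, overrides: Mapping[str, float] | None = None) -> ICERResult:
        return icer(self.arm_result("AVE", overrides), self.arm_result("CON", overrides))

    def base_case(self) -> dict:
        """Per-arm totals, increments, ICER, NMB and the WTP verdict."""
        ave = self.arm_result("AVE")
        con = self.arm_result("CON")
        res = icer(ave, con)
        inmb = net_monetary_benefit(ave, self.econ.wtp) - net_monetary_benefit(con, self.econ.wtp)
        return {
            "country": self.econ.country,
            "population": self.econ.population,
            "cost_ave": ave.total_cost,
            "cost_con": con.total_cost,
            "qalys_ave": ave.total_qalys,
            "qalys_con": con.total_qalys,
            "delta_cost": res.delta_cost,
            "delta_qalys": res.delta_qalys,
            "icer": res.icer,
            "flag": res.flag,
            "wtp": self.econ.wtp,
            "incremental_nmb": inmb,
            "cost_effective": bool(inmb > 0),
        }

    def dsa(self) -> list[TornadoEntry]:
        return one_way_dsa(self.evaluate, self.econ.parameters(), wtp=self.econ.wtp)

    def psa(self, n_draws: int = 1000, seed: int = 0) -> PSAResult:
        return run_psa(self.evaluate, self.econ.parameters(), n_draws=n_draws, seed=seed)

    def ceac(self, psa_result: PSAResult, wtp_grid=None) -> list[CEACPoint]:
        if wtp_grid is None:
            wtp_grid = default_wtp_grid()
        return ceac(psa_result, wtp_grid)
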