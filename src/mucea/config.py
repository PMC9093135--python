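"""Default economic configuration: the published input-parameter table.

Four scenario blocks (US/China × overall/PD-L1-positive population) share
utilities and differ in costs, discount rate (3% US, 5% China) and WTP
threshold ($150,000/QALY US; $30,447.09/QALY China).  China prices are
stored in USD as published (already converted at 6.36 CNY/USD).

Ranges are the published ±20% intervals; distribution families are beta
for utilities and gamma for costs.
"""

from __future__ import annotations

import hashlib
from typing import Any

import yaml

from .economics import EconInputs
from .exceptions import ConfigurationError
from .sensitivity import ParameterSpec

__all__ = [
    "SCENARIOS",
    "WTP_THRESHOLDS",
    "DISCOUNT_RATES",
    "default_econ_inputs",
    "default_config",
    "econ_inputs_from_dict",
    "load_config",
    "dump_config",
    "config_hash",
]

SCENARIOS = (
    ("US", "overall"),
    ("US", "PD-L1-positive"),
    ("China", "overall"),
    ("China", "PD-L1-positive"),
)

WTP_THRESHOLDS = {"US": 150_000.0, "China": 30_447.09}
DISCOUNT_RATES = {"US": 0.03, "China": 0.05}

_UTILITIES = {
    "utility_pfs": (0.84, 0.68, 1.00, "beta"),
    "utility_pd": (0.80, 0.64, 0.96, "beta"),
}

# country → shared cost items (base, low, high, dist)
_SHARED_COSTS = {
    "US": {
        "cost_pdl1_test": (431.28, 345.03, 517.54, "gamma"),
        "cost_pretreatment": (6.96, 5.57, 8.35, "gamma"),
        "cost_ae_con": (74.89, 59.91, 89.87, "gamma"),
        "cost_ae_ave": (111.68, 89.34, 134.02, "gamma"),
        "cost_imaging": (1137.67, 910.14, 1365.20, "gamma"),
        "cost_pd_monthly": (2396.70, 1917.36, 2876.04, "gamma"),
    },
    "China": {
        "cost_pdl1_test": (157.23, 125.78, 188.68, "gamma"),
        "cost_pretreatment": (1.57, 1.26, 1.88, "gamma"),
        "cost_ae_con": (29.73, 23.78, 35.68, "gamma"),
        "cost_ae_ave": (51.33, 41.06, 61.60, "gamma"),
        "cost_imaging": (163.96, 131.17, 196.75, "gamma"),
        "cost_pd_monthly": (376.83, 301.46, 452.20, "gamma"),
    },
}

# (country, population) → population-specific items
_POPULATION_COSTS = {
    ("US", "overall"): {
        "cost_drug_monthly": (22_022.59, 17_618.07, 26_427.11, "gamma"),
        "cost_bsc_ave_monthly": (4_324.24, 3_387.39, 5_081.09, "gamma"),
        "cost_bsc_con_monthly": (4_113.40, 3_290.72, 4_936.08, "gamma"),
    },
    ("US", "PD-L1-positive"): {
        "cost_drug_monthly": (14_295.37, 11_436.30, 17_154.44, "gamma"),
        "cost_bsc_ave_monthly": (2_754.38, 2_203.50, 3_305.26, "gamma"),
        "cost_bsc_con_monthly": (3_917.52, 3_134.02, 4_701.02, "gamma"),
    },
    ("China", "overall"): {
        "cost_drug_monthly": (172_637.26, 138_109.81, 207_164.71, "gamma"),
        "cost_bsc_ave_monthly": (2_726.00, 2_180.80, 3_271.20, "gamma"),
        "cost_bsc_con_monthly": (2_642.93, 2_114.34, 3_171.52, "gamma"),
    },
    ("China", "PD-L1-positive"): {
        "cost_drug_monthly": (112_062.00, 89_649.60, 134_474.40, "gamma"),
        "cost_bsc_ave_monthly": (2_754.38, 2_203.50, 3_305.26, "gamma"),
        "cost_bsc_con_monthly": (3_917.52, 3_134.02, 4_701.02, "gamma"),
    },
}


def _specs(block: dict[str, tuple]) -> dict[str, ParameterSpec]:
    return {
        name: ParameterSpec(name, base, low, high, dist)
        for name, (base, low, high, dist) in block.items()
    }


def default_econ_inputs(country: str = "US", population: str = "overall") -> EconInputs:
    """The published parameter block for one country × population scenario."""
    if country not in _SHARED_COSTS:
        raise ConfigurationError(f"unknown country {country!r}")
    if (country, population) not in _POPULATION_COSTS:
        raise ConfigurationError(f"unknown population {population!r}")
    params = _specs(_UTILITIES)
    params.update(_specs(_SHARED_COSTS[country]))
    params.update(_specs(_POPULATION_COSTS[(country, population)]))
    return EconInputs(
        annual_discount_rate=DISCOUNT_RATES[country],
        wtp=WTP_THRESHOLDS[country],
        country=country,
        population=population,
        **params,
    )


def _econ_to_dict(econ: EconInputs) -> dict[str, Any]:
    d: dict[str, Any] = {
        "annual_discount_rate": econ.annual_discount_rate,
        "wtp": econ.wtp,
        "parameters": {
            p.name: {"base": p.base, "low": p.low, "high": p.high, "dist": p.dist}
            for p in econ.parameters()
        },
    }
    return d


def econ_inputs_from_dict(d: dict[str, Any], country: str, population: str) -> EconInputs:
    params = {
        name: ParameterSpec(name, v["base"], v["low"], v["high"], v.get("dist", "fixed"))
        for name, v in d["parameters"].items()
    }
    return EconInputs(
        annual_discount_rate=d.get("annual_discount_rate", DISCOUNT_RATES.get(country, 0.03)),
        wtp=d.get("wtp", WTP_THRESHOLDS.get(country, 150_000.0)),
        country=country,
        population=population,
        **params,
    )


def default_config(starting_age: float = 68.0, horizon: int = 120) -> dict[str, Any]:
    """Full run configuration covering the four scenarios, YAML-serializable."""
    return {
        "model": {
            "cycle_length_months": 1.0,
            "horizon_cycles": horizon,
            "starting_age": starting_age,
            "half_cycle_correction": False,
            "competing_risk": "subtraction",
        },
        "sensitivity": {
            "n_draws": 1000,
            "wtp_grid": {"stop": 300_000.0, "step": 5_000.0},
        },
        "scenarios": {
            f"{c}/{p}": _econ_to_dict(default_econ_inputs(c, p)) for c, p in SCENARIOS
        },
    }


def load_config(path) -> dict[str, Any]:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict) or "scenarios" not in cfg:
        raise ConfigurationError(f"{path}: not a valid run configuration")
    return cfg


def dump_config(cfg: dict[str, Any], path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)


def config_hash(cfg: dict[str, Any]) -> str:
    """Short SHA-256 of the canonical YAML form, for output audit headers."""
    canon = yaml.safe_dump(cfg, sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:12]
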