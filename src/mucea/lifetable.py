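"""Age-dependent background mortality from a life table.

A life table supplies qx, the annual probability of death at integer age
x.  The cohort model needs a per-cycle (monthly) probability; the
conversion assumes a constant hazard within the year, so the monthly
probability p_m satisfies (1 − p_m)^12 = 1 − qx.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import InvalidInputError

__all__ = ["LifeTable", "monthly_background_mortality", "read_life_table_csv"]


@dataclass
class LifeTable:
    """Annual death probabilities qx by integer age.

    Lookups above the last tabulated age return the last qx (open-ended
    terminal age group).
    """

    ages: np.ndarray
    qx: np.ndarray

    def __post_init__(self):
        self.ages = np.asarray(self.ages, dtype=int)
        self.qx = np.asarray(self.qx, dtype=float)
        if self.ages.shape != self.qx.shape or self.ages.ndim != 1 or len(self.ages) == 0:
            raise InvalidInputError("ages and qx must be equal-length 1-D arrays")
        if np.any(np.diff(self.ages) != 1):
            raise InvalidInputError("ages must be contiguous integers")
        if np.any((self.qx < 0) | (self.qx > 1)):
            raise InvalidInputError("qx must lie in [0, 1]")

    def annual_qx(self, age_years: float) -> float:
        """qx at floor(age); ages above the table use the last entry."""
        if age_years < self.ages[0]:
            raise InvalidInputError(
                f"age {age_years} below the table's first age {self.ages[0]}"
            )
        idx = min(int(np.floor(age_years)) - int(self.ages[0]), len(self.qx) - 1)
        return float(self.qx[idx])


def monthly_background_mortality(table: LifeTable, age_years: float) -> float:
    """Monthly death probability consistent with the annual qx.

    1 − (1 − qx)^(1/12), the constant-within-year-hazard conversion.
    """
    q = table.annual_qx(age_years)
    return float(1.0 - (1.0 - q) ** (1.0 / 12.0))


def read_life_table_csv(path) -> LifeTable:
    """Read a life table from CSV with columns ``age, qx``."""
    df = pd.read_csv(path, comment="#")
    if not {"age", "qx"} <= set(df.columns):
        raise InvalidInputError("life table CSV needs columns age, qx")
    df = df.sort_values("age")
    return LifeTable(ages=df["age"].to_numpy(), qx=df["qx"].to_numpy())
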