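"""CSV readers and writers for the pipeline's tabular interfaces.

Formats (all long-form, one row per observation; `#`-prefixed header
comment lines carry the config hash and seed for audit):

* curves:       time_months, survival, arm, endpoint
* risk tables:  time_months, n_at_risk, arm, endpoint
* IPD:          time_months, event, arm, endpoint
* life table:   age, qx
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import InvalidInputError
from .km_ipd import DigitizedCurve, IPDRecord, RiskTable, preprocess_curve
from .lifetable import LifeTable

__all__ = [
    "read_curves_csv",
    "write_curves_csv",
    "read_risk_tables_csv",
    "write_risk_tables_csv",
    "read_ipd_csv",
    "write_ipd_csv",
    "write_life_table_csv",
    "write_csv_with_header",
]

Key = tuple[str, str]  # (arm, endpoint)


def write_csv_with_header(df: pd.DataFrame, path, meta: Mapping[str, object] | None = None):
    """Write a CSV preceded by `# key=value` audit comment lines."""
    path = Path(path)
    with open(path, "w") as fh:
        if meta:
            fh.write("# " + " ".join(f"{k}={v}" for k, v in meta.items()) + "\n")
        df.to_csv(fh, index=False)


def _read(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def read_curves_csv(path, preprocess: bool = True) -> dict[Key, DigitizedCurve]:
    df = _read(path)
    need = {"time_months", "survival", "arm", "endpoint"}
    if not need <= set(df.columns):
        raise InvalidInputError(f"curve CSV needs columns {sorted(need)}")
    out: dict[Key, DigitizedCurve] = {}
    for (arm, ep), grp in df.groupby(["arm", "endpoint"]):
        pts = list(zip(grp["time_months"], grp["survival"]))
        if preprocess:
            out[(arm, ep)] = preprocess_curve(pts, endpoint=ep, arm=arm)
        else:
            grp = grp.sort_values("time_months")
            out[(arm, ep)] = DigitizedCurve(
                times=grp["time_months"].to_numpy(),
                survival=grp["survival"].to_numpy(),
                endpoint=ep, arm=arm,
            )
    return out


def write_curves_csv(curves: Mapping[Key, DigitizedCurve], path, meta=None) -> None:
    rows = [
        {"time_months": t, "survival": s, "arm": arm, "endpoint": ep}
        for (arm, ep), c in curves.items()
        for t, s in zip(c.times, c.survival)
    ]
    write_csv_with_header(pd.DataFrame(rows), path, meta)


def read_risk_tables_csv(path) -> dict[Key, RiskTable]:
    df = _read(path)
    need = {"time_months", "n_at_risk", "arm", "endpoint"}
    if not need <= set(df.columns):
        raise InvalidInputError(f"risk table CSV needs columns {sorted(need)}")
    out: dict[Key, RiskTable] = {}
    for (arm, ep), grp in df.groupby(["arm", "endpoint"]):
        grp = grp.sort_values("time_months")
        out[(arm, ep)] = RiskTable(
            times=grp["time_months"].to_numpy(),
            n_at_risk=grp["n_at_risk"].to_numpy(),
        )
    return out


def write_risk_tables_csv(tables: Mapping[Key, RiskTable], path, meta=None) -> None:
    rows = [
        {"time_months": t, "n_at_risk": n, "arm": arm, "endpoint": ep}
        for (arm, ep), rt in tables.items()
        for t, n in zip(rt.times, rt.n_at_risk)
    ]
    write_csv_with_header(pd.DataFrame(rows), path, meta)


def read_ipd_csv(path) -> dict[Key, list[IPDRecord]]:
    df = _read(path)
    need = {"time_months", "event", "arm", "endpoint"}
    if not need <= set(df.columns):
        raise InvalidInputError(f"IPD CSV needs columns {sorted(need)}")
    out: dict[Key, list[IPDRecord]] = {}
    for (arm, ep), grp in df.groupby(["arm", "endpoint"]):
        out[(arm, ep)] = [
            IPDRecord(time=float(t), event=int(e), arm=arm, endpoint=ep)
            for t, e in zip(grp["time_months"], grp["event"])
        ]
    return out


def write_ipd_csv(ipd: Mapping[Key, Sequence[IPDRecord]], path, meta=None) -> None:
    rows = [
        {"time_months": r.time, "event": r.event, "arm": r.arm, "endpoint": r.endpoint}
        for records in ipd.values()
        for r in records
    ]
    write_csv_with_header(pd.DataFrame(rows), path, meta)


def write_life_table_csv(table: LifeTable, path, meta=None) -> None:
    write_csv_with_header(
        pd.DataFrame({"age": table.ages, "qx": table.qx}), path, meta
    )
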