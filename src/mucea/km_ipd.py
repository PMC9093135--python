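"""Digitized Kaplan-Meier curves and pseudo individual patient data.

Published survival figures are often the only patient-level evidence
available to a decision model.  This module turns digitized curve
coordinates (time, survival probability) plus optional numbers-at-risk
tables into pseudo individual patient data (IPD): one (time, event)
record per subject, chosen so that the product-limit estimate of the
reconstructed records tracks the input curve.  The reconstruction uses
Guyot-style interval balancing — censorings in each inter-risk-table
interval are estimated from the drop in numbers at risk not explained by
events, placed on a uniform grid over the interval, and events are
assigned at curve-drop times — and is fully deterministic given its
inputs.

A product-limit estimator (`km_estimator`) is provided as the round-trip
validation oracle.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from lifelines import KaplanMeierFitter

from .exceptions import InvalidInputError, ReconstructionInfeasibleError

__all__ = [
    "DigitizedCurve",
    "RiskTable",
    "IPDRecord",
    "preprocess_curve",
    "reconstruct_ipd",
    "km_estimator",
    "km_step_function",
    "sup_norm",
    "ipd_to_arrays",
]


@dataclass
class DigitizedCurve:
    """Ordered (time, survival) coordinates for one endpoint and arm.

    Times are in months.  After `preprocess_curve` the points are sorted,
    survival is clamped to [0, 1] and non-increasing, and the curve starts
    at (0, 1).
    """

    times: np.ndarray
    survival: np.ndarray
    endpoint: str = "OS"
    arm: str = ""

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.survival = np.asarray(self.survival, dtype=float)
        if self.times.shape != self.survival.shape or self.times.ndim != 1:
            raise InvalidInputError("times and survival must be 1-D and equal length")

    def validate(self) -> "DigitizedCurve":
        """Check the post-preprocessing invariants; return self."""
        if len(self.times) < 2:
            raise InvalidInputError("curve needs at least 2 points")
        if np.any(np.diff(self.times) <= 0):
            raise InvalidInputError("curve times must be strictly increasing")
        if self.times[0] != 0 or self.survival[0] != 1.0:
            raise InvalidInputError("curve must start at (0, 1); run preprocess_curve")
        if np.any(self.survival < 0) or np.any(self.survival > 1):
            raise InvalidInputError("survival values must lie in [0, 1]")
        if np.any(np.diff(self.survival) > 1e-12):
            raise InvalidInputError("survival must be non-increasing")
        return self


@dataclass
class RiskTable:
    """Numbers at risk at published timepoints (months)."""

    times: np.ndarray
    n_at_risk: np.ndarray

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.n_at_risk = np.asarray(self.n_at_risk, dtype=int)
        if self.times.shape != self.n_at_risk.shape or self.times.ndim != 1:
            raise InvalidInputError("risk table columns must be 1-D and equal length")
        if len(self.times) and np.any(np.diff(self.times) <= 0):
            raise InvalidInputError("risk table times must be strictly increasing")
        if np.any(self.n_at_risk < 0):
            raise InvalidInputError("numbers at risk must be non-negative")
        if len(self.n_at_risk) and np.any(np.diff(self.n_at_risk) > 0):
            raise InvalidInputError("numbers at risk must be non-increasing")


@dataclass(frozen=True)
class IPDRecord:
    """One reconstructed subject: follow-up time (months) and event flag."""

    time: float
    event: int
    arm: str = ""
    endpoint: str = ""

    def __post_init__(self):
        if self.time <= 0:
            raise InvalidInputError("IPD time must be > 0")
        if self.event not in (0, 1):
            raise InvalidInputError("event must be 0 or 1")


def preprocess_curve(
    raw_points: Iterable[tuple[float, float]],
    endpoint: str = "OS",
    arm: str = "",
) -> DigitizedCurve:
    """Clean digitization noise: sort, clamp, de-duplicate, enforce monotonicity.

    Duplicate times are collapsed to the lower survival value; survival is
    clamped to [0, 1] and made non-increasing by a running minimum; (0, 1)
    is prepended when absent.
    """
    pts = sorted((float(t), float(s)) for t, s in raw_points)
    if len(pts) == 0:
        raise InvalidInputError("curve has no points")
    if pts[0][0] < 0:
        raise InvalidInputError("curve times must be >= 0")
    # collapse duplicate times to the minimum survival
    times, surv = [], []
    for t, s in pts:
        if times and t == times[-1]:
            surv[-1] = min(surv[-1], s)
        else:
            times.append(t)
            surv.append(s)
    surv = np.clip(surv, 0.0, 1.0)
    surv = np.minimum.accumulate(surv)
    times = np.asarray(times, dtype=float)
    if times[0] != 0.0:
        times = np.insert(times, 0, 0.0)
        surv = np.insert(surv, 0, 1.0)
    else:
        surv[0] = 1.0
        surv = np.minimum.accumulate(surv)
    if len(times) < 2:
        raise InvalidInputError("curve needs at least 2 points")
    return DigitizedCurve(times=times, survival=surv, endpoint=endpoint, arm=arm)


def _largest_remainder(values: Sequence[float], total: int | None = None) -> np.ndarray:
    """Round non-negative reals to integers preserving the (rounded) sum.

    Ties in the fractional parts are broken toward earlier entries, which
    keeps the procedure deterministic.
    """
    vals = np.clip(np.asarray(values, dtype=float), 0.0, None)
    if total is None:
        total = int(round(vals.sum()))
    floors = np.floor(vals).astype(int)
    remainder = int(total - floors.sum())
    if remainder > 0:
        frac = vals - floors
        order = np.lexsort((np.arange(len(vals)), -frac))
        for i in order[:remainder]:
            floors[i] += 1
    elif remainder < 0:
        frac = vals - floors
        order = np.lexsort((np.arange(len(vals)), frac))
        take = 0
        for i in order:
            if take == -remainder:
                break
            if floors[i] > 0:
                floors[i] -= 1
                take += 1
    return floors


def _censor_grid(a: float, b: float, c: int) -> np.ndarray:
    """Uniform deterministic censoring grid strictly inside (a, b)."""
    if c <= 0:
        return np.empty(0)
    return a + (b - a) * (np.arange(c) + 0.5) / c


def reconstruct_ipd(
    curve: DigitizedCurve,
    risk_table: RiskTable | None = None,
    total_n: int | None = None,
    max_iter: int = 60,
) -> list[IPDRecord]:
    """Reconstruct pseudo-IPD from a digitized curve and optional risk table.

    Within each inter-risk-table interval the number of censorings is the
    drop in numbers at risk not explained by events; censoring times sit on
    a uniform grid over the interval and events at the curve-drop times,
    with non-integer implied event counts resolved by largest-remainder
    rounding.  Without a risk table no censoring is assumed before the last
    observed time and all survivors are censored at the final coordinate.

    Returns exactly ``total_n`` records, deterministically.
    """
    curve.validate()
    times, surv = curve.times, curve.survival
    t_max = float(times[-1])

    if risk_table is not None and len(risk_table.times):
        n0 = int(risk_table.n_at_risk[0])
        if total_n is None:
            total_n = n0
        if n0 > total_n:
            raise InvalidInputError(
                f"risk table starts at {n0} subjects but total_n={total_n}"
            )
        keep = risk_table.times <= t_max + 1e-12
        boundaries = list(np.asarray(risk_table.times)[keep])
        marks: list[int | None] = list(np.asarray(risk_table.n_at_risk)[keep])
        if not boundaries or boundaries[0] != 0.0:
            boundaries.insert(0, 0.0)
            marks.insert(0, n0)
        if boundaries[-1] < t_max:
            boundaries.append(t_max)
            marks.append(None)
        n_entry = n0
    else:
        if total_n is None:
            raise InvalidInputError("total_n required when no risk table is given")
        boundaries = [0.0, t_max]
        marks = [total_n, None]
        n_entry = total_n

    if total_n < 1:
        raise InvalidInputError("total_n must be >= 1")

    events: list[tuple[float, int]] = []
    censors: list[float] = []
    n_cur = n_entry
    s_run = 1.0

    n_intervals = len(boundaries) - 1
    for j in range(n_intervals):
        a, b = boundaries[j], boundaries[j + 1]
        last = j == n_intervals - 1
        target = marks[j + 1]
        if last:
            mask = (times > max(a, 0.0)) & (times <= b + 1e-12)
        else:
            mask = (times > max(a, 0.0)) & (times < b - 1e-12)
        idx = np.nonzero(mask & (times > 0))[0]

        c = 0
        d_int = np.zeros(len(idx), dtype=int)
        for _ in range(max_iter):
            cen = _censor_grid(a, b, c)
            n_r = float(n_cur)
            s = s_run
            ci = 0
            d_real = []
            for k in idx:
                while ci < len(cen) and cen[ci] < times[k]:
                    n_r -= 1.0
                    ci += 1
                if s <= 0 or n_r <= 0:
                    d_real.append(0.0)
                    continue
                d = n_r * (1.0 - surv[k] / s)
                d = min(max(d, 0.0), n_r)
                d_real.append(d)
                if d > 0:
                    s *= 1.0 - d / n_r
                    n_r -= d
            d_int = _largest_remainder(d_real)
            d_sum = int(d_int.sum())
            if target is None:
                break
            capacity = n_cur - int(target)  # events + censorings available
            if d_sum > capacity:
                # small excesses are digitization noise: push the surplus
                # drop past the interval by trimming the latest events;
                # gross excesses mean the inputs are inconsistent
                deficit = d_sum - capacity
                if deficit > max(2, int(np.ceil(0.1 * n_cur))):
                    raise ReconstructionInfeasibleError(j, (a, b))
                for pos in range(len(d_int) - 1, -1, -1):
                    take = min(deficit, d_int[pos])
                    d_int[pos] -= take
                    deficit -= take
                    if deficit == 0:
                        break
                d_sum = int(d_int.sum())
            c_new = n_cur - d_sum - int(target)
            if c_new == c:
                break
            c = c_new
        else:  # no convergence: force consistency with the risk table
            if target is not None:
                c = max(0, n_cur - int(d_int.sum()) - int(target))

        # final integer walk updates the running KM state and emits records
        cen = _censor_grid(a, b, c)
        n_r = n_cur
        s = s_run
        ci = 0
        for pos, k in enumerate(idx):
            while ci < len(cen) and cen[ci] < times[k]:
                n_r -= 1
                ci += 1
            d = int(min(d_int[pos], max(n_r, 0)))
            if d > 0:
                s *= 1.0 - d / n_r
                n_r -= d
                events.append((float(times[k]), d))
        censors.extend(float(tc) for tc in cen)
        n_cur = n_cur - int(d_int.sum()) - c
        s_run = s

    # survivors past the last boundary are censored at the end of follow-up
    censors.extend([t_max] * n_cur)
    # subjects never entering the risk set (total_n > first risk entry) are
    # censored immediately after time zero
    if total_n > n_entry:
        eps = min(t_max, times[times > 0][0]) * 1e-6
        censors.extend([eps] * (total_n - n_entry))

    records = [
        IPDRecord(time=t, event=1, arm=curve.arm, endpoint=curve.endpoint)
        for t, d in events
        for _ in range(d)
    ]
    records.extend(
        IPDRecord(time=t, event=0, arm=curve.arm, endpoint=curve.endpoint)
        for t in censors
    )
    records.sort(key=lambda r: (r.time, -r.event))
    assert len(records) == total_n
    return records


def ipd_to_arrays(ipd: Sequence[IPDRecord]) -> tuple[np.ndarray, np.ndarray]:
    """Split records into (durations, event indicators) arrays."""
    t = np.array([r.time for r in ipd], dtype=float)
    e = np.array([r.event for r in ipd], dtype=int)
    return t, e


def km_estimator(ipd: Sequence[IPDRecord]) -> DigitizedCurve:
    """Product-limit (Kaplan-Meier) estimate of a set of IPD records.

    The step function is sampled at the distinct event times, with S(0)=1
    prepended.  Invariant to record order.
    """
    if len(ipd) == 0:
        raise InvalidInputError("no records")
    t, e = ipd_to_arrays(ipd)
    if np.any(t <= 0):
        raise InvalidInputError("IPD times must be > 0")
    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=e)
    event_times = np.unique(t[e == 1])
    surv = kmf.survival_function_at_times(event_times).to_numpy()
    times = np.concatenate([[0.0], event_times])
    survival = np.concatenate([[1.0], surv])
    return DigitizedCurve(
        times=times,
        survival=survival,
        endpoint=ipd[0].endpoint,
        arm=ipd[0].arm,
    )


def km_step_function(curve: DigitizedCurve):
    """Right-continuous step evaluator S(t) for a (preprocessed) curve."""
    times, surv = curve.times, curve.survival

    def S(t):
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(times, t, side="right") - 1
        idx = np.clip(idx, 0, len(times) - 1)
        return surv[idx]

    return S


def sup_norm(a: DigitizedCurve, b: DigitizedCurve, at_times: np.ndarray | None = None) -> float:
    """Sup-norm distance between two step curves on a common time grid."""
    if at_times is None:
        at_times = np.union1d(a.times, b.times)
    Sa, Sb = km_step_function(a), km_step_function(b)
    return float(np.max(np.abs(Sa(at_times) - Sb(at_times))))
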