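"""Deterministic and probabilistic sensitivity analysis.

One-way DSA re-evaluates the ICER at each parameter's low/high bound with
everything else at base, producing tornado-ordered entries.  PSA samples
parameter vectors — beta distributions for utilities, gamma for costs,
moment-matched to the published base value and range (the range is read
as a 95% interval, SE = range/3.92) — evaluates the model per draw and
summarizes the draws as a cost-effectiveness acceptability curve (CEAC).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np

from .exceptions import ConfigurationError, InvalidInputError

__all__ = [
    "ParameterSpec",
    "TornadoEntry",
    "CEACPoint",
    "PSAResult",
    "moment_match_gamma",
    "moment_match_beta",
    "one_way_dsa",
    "run_psa",
    "ceac",
    "default_wtp_grid",
]

logger = logging.getLogger(__name__)

#: z-width of a 95% interval; the printed (low, high) range spans 2 × 1.96 SEs
_Z95_WIDTH = 2.0 * 1.96


@dataclass(frozen=True)
class ParameterSpec:
    """One uncertain model input: base value, range, distribution family."""

    name: str
    base: float
    low: float
    high: float
    dist: str = "fixed"  # beta | gamma | fixed | uniform

    def __post_init__(self):
        if not (self.low <= self.base <= self.high):
            raise InvalidInputError(
                f"{self.name}: need low <= base <= high, got "
                f"({self.low}, {self.base}, {self.high})"
            )
        if self.dist not in ("beta", "gamma", "fixed", "uniform"):
            raise InvalidInputError(f"{self.name}: unknown distribution {self.dist!r}")
        if self.dist == "beta" and not (0 < self.base < 1):
            raise InvalidInputError(f"{self.name}: beta requires base in (0, 1)")
        if self.dist == "gamma" and self.base < 0:
            raise InvalidInputError(f"{self.name}: gamma requires non-negative base")


@dataclass
class TornadoEntry:
    """ICER at a parameter's bounds; bar width ranks sensitivity."""

    name: str
    icer_low: float | None
    icer_high: float | None
    width: float
    nmb_low: float | None = None
    nmb_high: float | None = None
    flagged: bool = False  # an endpoint was dominant/dominated: width is on the NMB scale


@dataclass(frozen=True)
class CEACPoint:
    wtp: float
    probability: float


@dataclass
class PSAResult:
    """Monte-Carlo draws of (incremental cost, incremental QALYs)."""

    draws: np.ndarray  # shape (n, 2): columns delta_cost, delta_qalys
    seed: int
    n_rejected: int = 0

    @property
    def delta_cost(self) -> np.ndarray:
        return self.draws[:, 0]

    @property
    def delta_qalys(self) -> np.ndarray:
        return self.draws[:, 1]


def moment_match_gamma(mean: float, low: float, high: float) -> tuple[float, float]:
    """Gamma (shape, rate) with the given mean and SE = (high − low)/3.92."""
    if mean <= 0:
        raise ConfigurationError(f"gamma moment match needs mean > 0, got {mean}")
    if high <= low:
        raise ConfigurationError("gamma moment match needs high > low")
    se = (high - low) / _Z95_WIDTH
    shape = mean**2 / se**2
    rate = mean / se**2
    return shape, rate


def moment_match_beta(mean: float, low: float, high: float) -> tuple[float, float]:
    """Beta (alpha, beta) with the given mean and SE = (min(high,1) − low)/3.92.

    Raises `ConfigurationError` when the implied variance is infeasible for
    a beta distribution (SE² >= mean(1 − mean)).
    """
    if not (0 < mean < 1):
        raise ConfigurationError(f"beta moment match needs mean in (0, 1), got {mean}")
    se = (min(high, 1.0) - low) / _Z95_WIDTH
    if se <= 0:
        raise ConfigurationError("beta moment match needs a positive range")
    nu = mean * (1.0 - mean) / se**2 - 1.0
    if nu <= 0:
        raise ConfigurationError(
            f"variance {se**2:g} infeasible for a beta with mean {mean:g}"
        )
    return mean * nu, (1.0 - mean) * nu


def _sample_param(spec: ParameterSpec, rng: np.random.Generator, size: int) -> np.ndarray:
    if spec.dist == "fixed" or spec.low == spec.high:
        return np.full(size, spec.base)
    if spec.dist == "beta":
        a, b = moment_match_beta(spec.base, spec.low, spec.high)
        return rng.beta(a, b, size=size)
    if spec.dist == "gamma":
        shape, rate = moment_match_gamma(spec.base, spec.low, spec.high)
        return rng.gamma(shape, 1.0 / rate, size=size)
    return rng.uniform(spec.low, spec.high, size=size)


def one_way_dsa(
    model: Callable[[Mapping[str, float]], "ICERResult"],
    params: Sequence[ParameterSpec],
    wtp: float | None = None,
) -> list[TornadoEntry]:
    """One-way deterministic sensitivity analysis with tornado ordering.

    ``model`` maps a {name: value} override dict to an ICERResult.  Entries
    are sorted by descending bar width.  When an endpoint yields no finite
    ICER (dominance), the entry is flagged and its width falls back to the
    incremental-NMB scale (requires ``wtp``) rather than a silent NaN.
    """
    entries = []
    for p in params:
        res_lo = model({p.name: p.low})
        res_hi = model({p.name: p.high})
        icer_lo, icer_hi = res_lo.icer, res_hi.icer
        nmb_lo = nmb_hi = None
        if wtp is not None:
            nmb_lo = wtp * res_lo.delta_qalys - res_lo.delta_cost
            nmb_hi = wtp * res_hi.delta_qalys - res_hi.delta_cost
        if icer_lo is not None and icer_hi is not None:
            width = abs(icer_hi - icer_lo)
            flagged = False
        else:
            if wtp is None:
                raise ConfigurationError(
                    f"parameter {p.name}: dominance at an endpoint and no WTP "
                    "given for the NMB fallback"
                )
            width = abs(nmb_hi - nmb_lo)
            flagged = True
            logger.warning("DSA parameter %s hit dominance; width on NMB scale", p.name)
        entries.append(
            TornadoEntry(
                name=p.name, icer_low=icer_lo, icer_high=icer_hi,
                width=width, nmb_low=nmb_lo, nmb_high=nmb_hi, flagged=flagged,
            )
        )
    entries.sort(key=lambda e: (-e.width, e.name))
    return entries


def run_psa(
    model: Callable[[Mapping[str, float]], "ICERResult"],
    params: Sequence[ParameterSpec],
    n_draws: int = 1000,
    seed: int = 0,
    max_rejections: int = 10_000,
) -> PSAResult:
    """Probabilistic sensitivity analysis: ``n_draws`` parameter vectors.

    Each vector is sampled independently from the moment-matched
    distributions (fixed parameters at base), the model is evaluated, and
    (ΔC, ΔE) recorded.  A draw whose parameter vector makes the model
    invalid is rejected and resampled, with a logged count.  Bitwise
    reproducible given ``seed``.
    """
    rng = np.random.default_rng(seed)
    out = np.empty((n_draws, 2))
    n_rejected = 0
    i = 0
    while i < n_draws:
        values = {p.name: float(_sample_param(p, rng, 1)[0]) for p in params}
        try:
            res = model(values)
        except InvalidInputError:
            n_rejected += 1
            if n_rejected > max_rejections:
                raise ConfigurationError("PSA rejected too many draws; check ranges")
            continue
        out[i] = (res.delta_cost, res.delta_qalys)
        i += 1
    if n_rejected:
        logger.warning("PSA rejected and resampled %d invalid draws", n_rejected)
    return PSAResult(draws=out, seed=seed, n_rejected=n_rejected)


def ceac(
    draws: PSAResult | np.ndarray,
    wtp_grid: Sequence[float],
) -> list[CEACPoint]:
    """Cost-effectiveness acceptability curve over a WTP grid.

    Probability at each WTP is the fraction of draws with positive
    incremental net monetary benefit, wtp·ΔE − ΔC > 0; exact ties count as
    not cost-effective.
    """
    arr = draws.draws if isinstance(draws, PSAResult) else np.asarray(draws, float)
    if arr.size == 0:
        raise InvalidInputError("no PSA draws")
    dc, de = arr[:, 0], arr[:, 1]
    return [
        CEACPoint(wtp=float(w), probability=float(np.mean(w * de - dc > 0)))
        for w in wtp_grid
    ]


def default_wtp_grid(
    stop: float = 300_000.0,
    step: float = 5_000.0,
    always_include: Sequence[float] = (150_000.0, 30_447.09),
) -> np.ndarray:
    """0..stop in ``step`` increments, always containing the two decision thresholds."""
    grid = np.arange(0.0, stop + step / 2, step)
    return np.unique(np.concatenate([grid, np.asarray(always_include, float)]))
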