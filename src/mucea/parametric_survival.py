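"""Weibull survival models in the cumulative-hazard parameterization.

The model is H(t) = λ t^γ with scale λ > 0 (units month^-γ) and shape
γ > 0, so S(t) = exp(−λ t^γ).  This is the parameterization whose
conditional per-cycle transition probability is

    P(event in (t, t+1] | alive at t) = 1 − exp[λ t^γ − λ (t+1)^γ],

the quantity the Markov engine consumes.  Note it differs from the
location-scale (accelerated failure time) form used by several survival
packages; `to_aft_params` / `from_aft_params` convert between the two for
cross-checking.

Fitting maximizes the right-censored log-likelihood

    l(λ, γ) = Σ_events [log λ + log γ + (γ−1) log t_i] − Σ_all λ t_i^γ

on (log λ, log γ) with analytic gradients, multi-started from the
exponential (γ = 1) closed-form fit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import minimize

from .exceptions import FitFailureError, InvalidInputError, NonIdentifiableError
from .km_ipd import IPDRecord, ipd_to_arrays

__all__ = [
    "WeibullFit",
    "fit_weibull",
    "survival_at",
    "transition_probability",
    "median_survival",
    "to_aft_params",
    "from_aft_params",
]


@dataclass(frozen=True)
class WeibullFit:
    """Fitted Weibull model: cumulative hazard H(t) = λ t^γ."""

    lambda_scale: float
    gamma_shape: float
    log_likelihood: float = np.nan
    n_obs: int = 0
    n_events: int = 0

    def __post_init__(self):
        if self.lambda_scale <= 0 or self.gamma_shape <= 0:
            raise InvalidInputError("λ and γ must be positive")

    def to_json(self, endpoint: str = "", arm: str = "") -> str:
        return json.dumps(
            {
                "endpoint": endpoint,
                "arm": arm,
                "lambda": self.lambda_scale,
                "gamma": self.gamma_shape,
                "loglik": self.log_likelihood,
                "n": self.n_obs,
            }
        )


def _loglik_and_grad(params: np.ndarray, t: np.ndarray, e: np.ndarray):
    """Log-likelihood and gradient on the (log λ, log γ) scale."""
    lam, gam = np.exp(params)
    logt = np.log(t)
    tg = t**gam
    d = e.sum()
    ll = d * (np.log(lam) + np.log(gam)) + (gam - 1.0) * logt[e == 1].sum() - lam * tg.sum()
    # derivatives wrt log λ and log γ
    g_loglam = d - lam * tg.sum()
    g_loggam = d + gam * logt[e == 1].sum() - lam * gam * (tg * logt).sum()
    return ll, np.array([g_loglam, g_loggam])


def fit_weibull(
    ipd: Sequence[IPDRecord] | tuple[np.ndarray, np.ndarray],
    fix_gamma: float | None = None,
) -> WeibullFit:
    """Maximum-likelihood Weibull fit to right-censored records.

    Accepts either a list of `IPDRecord` or a pre-split ``(times, events)``
    pair.  Requires at least two records and at least one event; raises
    `NonIdentifiableError` otherwise, `FitFailureError` on non-convergence.
    With ``fix_gamma`` the shape is held fixed and λ has the closed form
    λ = (number of events)/Σ t_i^γ (the exponential MLE when γ = 1).
    """
    if isinstance(ipd, tuple):
        t, e = np.asarray(ipd[0], float), np.asarray(ipd[1], int)
    else:
        t, e = ipd_to_arrays(ipd)
    if len(t) < 2:
        raise InvalidInputError("need at least 2 records")
    if np.any(t <= 0):
        raise InvalidInputError("all times must be > 0")
    d = int(e.sum())
    if d == 0:
        raise NonIdentifiableError("no events: Weibull parameters are not identifiable")

    if fix_gamma is not None:
        if fix_gamma <= 0:
            raise InvalidInputError("fix_gamma must be positive")
        lam = d / (t**fix_gamma).sum()
        ll, _ = _loglik_and_grad(np.log([lam, fix_gamma]), t, e)
        return WeibullFit(lambda_scale=float(lam), gamma_shape=float(fix_gamma),
                          log_likelihood=float(ll), n_obs=len(t), n_events=d)

    lam_exp = d / t.sum()  # exponential closed-form MLE
    ll_exp, _ = _loglik_and_grad(np.log([lam_exp, 1.0]), t, e)

    best = None
    for gam0 in (1.0, 0.7, 1.5):
        lam0 = d / (t**gam0).sum()
        res = minimize(
            lambda p: tuple(-v for v in _loglik_and_grad(p, t, e)),
            x0=np.log([lam0, gam0]),
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": 500, "ftol": 1e-14, "gtol": 1e-10},
        )
        if best is None or -res.fun > -best.fun:
            best = res
    # Newton polish with a finite-difference Hessian of the analytic gradient:
    # L-BFGS-B stops at a gradient norm proportional to n; the downstream
    # contract is an absolute norm <= 1e-6
    x = best.x
    for _ in range(40):
        ll, g = _loglik_and_grad(x, t, e)
        if np.linalg.norm(g) <= 1e-8:
            break
        h = 1e-6
        H = np.empty((2, 2))
        for k in range(2):
            xp = x.copy()
            xp[k] += h
            H[:, k] = (_loglik_and_grad(xp, t, e)[1] - g) / h
        try:
            step = np.linalg.solve(H, -g)
        except np.linalg.LinAlgError:
            break
        # damped update: accept whatever shrinks the gradient (near the
        # optimum the likelihood itself only moves at rounding level)
        gnorm = np.linalg.norm(g)
        for damp in (1.0, 0.5, 0.25, 0.1):
            xn = x + damp * step
            if np.linalg.norm(_loglik_and_grad(xn, t, e)[1]) < gnorm:
                x = xn
                break
        else:
            break
    ll = _loglik_and_grad(x, t, e)[0]
    best.x = x
    grad_norm = float(np.linalg.norm(_loglik_and_grad(best.x, t, e)[1]))
    if grad_norm > 1e-6 or ll < ll_exp - 1e-8:
        raise FitFailureError(
            "Weibull MLE did not converge",
            diagnostics={"grad_norm": grad_norm, "loglik": ll, "loglik_exp": ll_exp,
                         "message": best.message},
        )
    lam, gam = np.exp(best.x)
    return WeibullFit(
        lambda_scale=float(lam),
        gamma_shape=float(gam),
        log_likelihood=float(ll),
        n_obs=len(t),
        n_events=d,
    )


def survival_at(fit: WeibullFit, t) -> float | np.ndarray:
    """S(t) = exp(−λ t^γ)."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise InvalidInputError("t must be >= 0")
    out = np.exp(-fit.lambda_scale * t**fit.gamma_shape)
    return float(out) if out.ndim == 0 else out


def transition_probability(fit: WeibullFit, cycle_start: float, cycle_end: float) -> float:
    """Conditional probability of the event in (start, end] given survival to start.

    1 − exp[λ start^γ − λ end^γ]; equals 1 − S(end)/S(start).
    """
    if cycle_start < 0 or cycle_end <= cycle_start:
        raise InvalidInputError("need 0 <= cycle_start < cycle_end")
    lam, gam = fit.lambda_scale, fit.gamma_shape
    return float(1.0 - np.exp(lam * cycle_start**gam - lam * cycle_end**gam))


def median_survival(fit: WeibullFit) -> float:
    """Median of the fitted distribution: (ln 2 / λ)^(1/γ), in months."""
    return float((np.log(2.0) / fit.lambda_scale) ** (1.0 / fit.gamma_shape))


def to_aft_params(fit: WeibullFit) -> tuple[float, float]:
    """Convert to the (scale, shape) of S(t) = exp(−(t/scale)^shape).

    This is the parameterization used by lifelines' WeibullFitter
    (lambda_, rho_): scale = λ^(−1/γ), shape = γ.
    """
    return (fit.lambda_scale ** (-1.0 / fit.gamma_shape), fit.gamma_shape)


def from_aft_params(scale: float, shape: float, **kwargs) -> WeibullFit:
    """Build a fit from the location-scale form S(t) = exp(−(t/scale)^shape)."""
    if scale <= 0 or shape <= 0:
        raise InvalidInputError("scale and shape must be positive")
    return WeibullFit(lambda_scale=scale**-shape, gamma_shape=shape, **kwargs)
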