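"""Population parameters from an l_x/m_x schedule.

* net reproductive rate        R0  = sum_x l_x m_x
* mean generation time         T   = sum_x x l_x m_x / sum_x l_x m_x
* intrinsic rate of increase   r_m : sum_x exp(-r x) l_x m_x = 1
* finite rate of increase      lam = exp(r_m)

Schedules are finite by construction (truncated at the last death), so the
nominally infinite sums are exact finite sums.  The implicit equation for
``r_m`` is solved by bracketed root finding: its left side is strictly
decreasing in ``r`` whenever there is reproduction at some age ``x > 0``,
so the real root is unique and bracketing is globally safe.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq
from scipy.special import logsumexp

from .schedules import Schedule

__all__ = [
    "DemographicParams",
    "UndefinedParameterError",
    "net_reproductive_rate",
    "mean_generation_time",
    "intrinsic_rate",
    "finite_rate",
    "euler_lotka_residual",
    "compute_params",
]

DEFAULT_TOL = 1e-10
_INITIAL_BRACKET = (-2.0, 2.0)
_MAX_BRACKET = 2048.0  # |ln| of any normal double fits well inside this


class UndefinedParameterError(ValueError):
    """The requested parameter is undefined for this schedule (e.g. R0 = 0)."""


@dataclass
class DemographicParams:
    r0: float
    t: float
    rm: float
    lam: float
    solver: dict = field(default_factory=dict)


def net_reproductive_rate(schedule: Schedule) -> float:
    return float(np.sum(schedule.lx * schedule.mx))


def mean_generation_time(schedule: Schedule) -> float:
    prod = schedule.lx * schedule.mx
    r0 = float(prod.sum())
    if r0 <= 0.0:
        raise UndefinedParameterError("mean generation time undefined: R0 = 0")
    return float(np.sum(schedule.ages * prod)) / r0


def euler_lotka_residual(schedule: Schedule, r: float) -> float:
    """``sum_x exp(-r x) l_x m_x - 1`` (zero at the intrinsic rate).

    Evaluated in log space over the positive terms so extreme rates (or
    near-subnormal schedules) cannot produce 0 * inf artifacts; the result
    is capped at a huge finite value instead of overflowing.
    """
    prod = schedule.lx * schedule.mx
    mask = prod > 0
    if not np.any(mask):
        return -1.0
    lse = float(logsumexp(np.log(prod[mask]) - r * schedule.ages[mask]))
    if lse > 700.0:
        return 1e300
    return math.expm1(lse)


def intrinsic_rate(schedule: Schedule, tol: float = DEFAULT_TOL) -> float:
    rm, _ = _solve_intrinsic_rate(schedule, tol)
    return rm


def _solve_intrinsic_rate(schedule: Schedule, tol: float = DEFAULT_TOL) -> tuple[float, dict]:
    prod = schedule.lx * schedule.mx
    r0 = float(prod.sum())
    if r0 <= 0.0:
        raise UndefinedParameterError("intrinsic rate undefined: R0 = 0")
    positive_ages = schedule.ages[prod > 0]
    if len(positive_ages) == 0 or positive_ages.max() == 0:
        raise UndefinedParameterError(
            "intrinsic rate undefined: no reproduction at any age x > 0"
        )

    def f(r: float) -> float:
        return euler_lotka_residual(schedule, r)

    lo, hi = _INITIAL_BRACKET
    f_lo, f_hi = f(lo), f(hi)
    # f decreases in r: need f(lo) > 0 > f(hi).  Expand geometrically if not.
    while f_lo < 0.0 and lo > -_MAX_BRACKET:
        lo *= 2.0
        f_lo = f(lo)
    while f_hi > 0.0 and hi < _MAX_BRACKET:
        hi *= 2.0
        f_hi = f(hi)
    if not (f_lo >= 0.0 >= f_hi):
        raise RuntimeError(
            f"failed to bracket the intrinsic rate in [{-_MAX_BRACKET}, {_MAX_BRACKET}]: "
            f"f({lo})={f_lo:.3g}, f({hi})={f_hi:.3g}"
        )
    root, res = brentq(f, lo, hi, xtol=1e-14, rtol=8.9e-16, full_output=True)
    residual = f(root)
    if abs(residual) > tol:
        raise RuntimeError(
            f"intrinsic-rate solve converged to residual {residual:.3g} > tol {tol:.3g}"
        )
    diagnostics = {
        "bracket": (lo, hi),
        "iterations": res.iterations,
        "residual": residual,
        "tol": tol,
    }
    return float(root), diagnostics


def finite_rate(rm: float) -> float:
    """Per-day multiplication factor ``exp(rm)``."""
    if not math.isfinite(rm):
        raise ValueError(f"intrinsic rate must be finite, got {rm!r}")
    return math.exp(rm)


def compute_params(schedule: Schedule, tol: float = DEFAULT_TOL) -> DemographicParams:
    """All four parameters; raises UndefinedParameterError when R0 = 0."""
    r0 = net_reproductive_rate(schedule)
    t = mean_generation_time(schedule)
    rm, diag = _solve_intrinsic_rate(schedule, tol)
    return DemographicParams(r0=r0, t=t, rm=rm, lam=finite_rate(rm), solver=diag)
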