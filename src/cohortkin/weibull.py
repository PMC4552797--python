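"""Two-parameter Weibull survival model.

The model for an age at death :math:`T` is

.. math::

    f(t) = \\frac{\\beta}{\\alpha}\\left(\\frac{t}{\\alpha}\\right)^{\\beta-1}
           \\exp\\{-(t/\\alpha)^\\beta\\},\\qquad t \\ge 0,

with scale :math:`\\alpha > 0` (the characteristic life: the age by which a
fraction :math:`1 - e^{-1}` of a cohort has died, in the same units as ``t``)
and dimensionless shape :math:`\\beta > 0`.  The shape parameter governs the
hazard kinetics: the hazard :math:`h(t) = (\\beta/\\alpha)(t/\\alpha)^{\\beta-1}`
rises with age when ``beta > 1`` (wear-out), is constant when ``beta == 1``
(the memoryless exponential special case), and declines when ``beta < 1``.
On a log-log plot the hazard is exactly linear in log age with slope
``beta - 1``, which is what makes the shape parameter directly readable from
mortality data.

All densities/probabilities accept scalars or array-likes and broadcast.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy.optimize import brentq
from scipy.special import gammaln

__all__ = [
    "WeibullParams",
    "HazardKinetics",
    "pdf",
    "cdf",
    "survival",
    "hazard",
    "cumulative_hazard",
    "log_hazard_line",
    "mean",
    "variance",
    "sample",
    "params_from_moments",
    "classify_regime",
]

#: |beta - 1| at or below this is classified "constant" in exact arithmetic.
#: Scientific judgement about near-constant hazards should use the SE-based
#: criterion in :func:`classify_regime` instead.
SHAPE_TOLERANCE = 1e-6

#: Two-sided z for the standard-error-based regime classification (99% level).
#: Conservative so a hazard that is statistically indistinguishable from
#: constant is not declared rising/declining on sampling noise.
REGIME_Z = 2.5758293035489004


@dataclass(frozen=True)
class WeibullParams:
    """Scale ``alpha`` (> 0, units of age) and shape ``beta`` (> 0)."""

    alpha: float
    beta: float

    def __post_init__(self) -> None:
        for name in ("alpha", "beta"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise ValueError(
                    f"Weibull {name} must be strictly positive and finite, got {v!r}"
                )


@dataclass(frozen=True)
class HazardKinetics:
    """The log-hazard line ``log h(t) = intercept + slope * log t``.

    ``slope == beta - 1``; the regime is the sign of the slope within
    :data:`SHAPE_TOLERANCE`.
    """

    regime: Literal["increasing", "constant", "decreasing"]
    slope_log_hazard: float
    intercept_log_hazard: float


def _check_nonnegative(t: np.ndarray, what: str = "time") -> np.ndarray:
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError(f"{what} must be nonnegative")
    return t


def pdf(params: WeibullParams, t):
    """Probability density of age at death."""
    t = _check_nonnegative(t)
    a, b = params.alpha, params.beta
    z = t / a
    with np.errstate(divide="ignore", invalid="ignore"):
        # z**(b-1) at z=0: 0 for b>1, 1/a scaling for b==1, diverges for b<1
        out = (b / a) * z ** (b - 1.0) * np.exp(-(z**b))
    if b < 1:
        out = np.where(t == 0, np.inf, out)
    return out if out.ndim else float(out)


def cdf(params: WeibullParams, t):
    """P(T <= t) = 1 - exp{-(t/alpha)^beta}."""
    t = _check_nonnegative(t)
    out = -np.expm1(-((t / params.alpha) ** params.beta))
    return out if out.ndim else float(out)


def survival(params: WeibullParams, t):
    """P(T > t) = exp{-(t/alpha)^beta}; survival(0) == 1."""
    t = _check_nonnegative(t)
    out = np.exp(-((t / params.alpha) ** params.beta))
    return out if out.ndim else float(out)


def hazard(params: WeibullParams, t):
    """Instantaneous death rate (beta/alpha)(t/alpha)^(beta-1).

    Equals pdf/survival wherever survival > 0.  At ``t == 0`` the hazard
    diverges for ``beta < 1``, which is rejected explicitly.
    """
    t = _check_nonnegative(t)
    a, b = params.alpha, params.beta
    if b < 1 and np.any(t == 0):
        raise ValueError("hazard diverges at t=0 when beta < 1")
    with np.errstate(divide="ignore"):
        out = (b / a) * (t / a) ** (b - 1.0)
    return out if out.ndim else float(out)


def cumulative_hazard(params: WeibullParams, t):
    """H(t) = (t/alpha)^beta = -log survival(t)."""
    t = _check_nonnegative(t)
    out = (t / params.alpha) ** params.beta
    return out if out.ndim else float(out)


def log_hazard_line(params: WeibullParams) -> HazardKinetics:
    """Exact line for log hazard against log time.

    slope = beta - 1 and intercept = log beta - beta * log alpha, the unique
    intercept for which intercept + slope*log t == log hazard(t) identically.
    """
    a, b = params.alpha, params.beta
    slope = b - 1.0
    intercept = math.log(b) - b * math.log(a)
    if abs(slope) <= SHAPE_TOLERANCE:
        regime = "constant"
    elif slope > 0:
        regime = "increasing"
    else:
        regime = "decreasing"
    return HazardKinetics(regime, slope, intercept)


def classify_regime(beta: float, se_beta: float | None = None, z: float = REGIME_Z) -> str:
    """Hazard-kinetics regime from a shape estimate.

    Without a standard error this is the exact-arithmetic sign test
    (tolerance :data:`SHAPE_TOLERANCE`).  With one, ``beta`` is called
    "constant" whenever the two-sided ``z``-interval around it covers 1 —
    i.e. the data cannot distinguish the hazard from constant at that level.
    """
    if se_beta is None:
        return log_hazard_line(WeibullParams(1.0, beta)).regime
    if se_beta < 0 or not np.isfinite(se_beta):
        raise ValueError("se_beta must be a finite nonnegative number")
    if abs(beta - 1.0) <= z * se_beta:
        return "constant"
    return "increasing" if beta > 1.0 else "decreasing"


def _gamma(x: float) -> float:
    # log-gamma form: Gamma overflows past x ~ 171 (small beta reaches it fast)
    lg = gammaln(x)
    if lg > 700.0:
        raise OverflowError(
            f"gamma({x:g}) overflows a double; shape parameter too close to zero"
        )
    return math.exp(lg)


def mean(params: WeibullParams) -> float:
    """E[T] = alpha * Gamma(1 + 1/beta)."""
    return params.alpha * _gamma(1.0 + 1.0 / params.beta)


def variance(params: WeibullParams) -> float:
    """Var[T] = alpha^2 * [Gamma(1 + 2/beta) - Gamma(1 + 1/beta)^2]."""
    g1 = _gamma(1.0 + 1.0 / params.beta)
    g2 = _gamma(1.0 + 2.0 / params.beta)
    return params.alpha**2 * (g2 - g1 * g1)


def params_from_moments(mean_: float, variance_: float) -> WeibullParams:
    """Invert the moment equations: the (alpha, beta) with the given mean
    and variance.

    Solves Gamma(1+2/b)/Gamma(1+1/b)^2 - 1 = variance/mean^2 for the shape
    by bisection (the squared coefficient of variation is strictly
    decreasing in the shape), then reads the scale off the mean equation.
    """
    if mean_ <= 0 or variance_ <= 0:
        raise ValueError("mean and variance must be positive")
    target = variance_ / mean_**2

    def cv2(b: float) -> float:
        return math.exp(gammaln(1 + 2 / b) - 2 * gammaln(1 + 1 / b)) - 1.0

    beta = brentq(lambda b: cv2(b) - target, 0.05, 200.0, xtol=1e-12)
    alpha = mean_ / _gamma(1.0 + 1.0 / beta)
    return WeibullParams(alpha, beta)


def sample(params: WeibullParams, n: int, seed) -> np.ndarray:
    """Draw ``n`` ages at death by inverse transform: alpha * (-log U)^(1/beta).

    Deterministic for a given ``seed`` (int or numpy SeedSequence/Generator).
    All draws are strictly positive.
    """
    if n < 1:
        raise ValueError("sample size must be at least 1")
    rng = np.random.default_rng(seed)
    u = rng.random(int(n))
    # keep U strictly inside (0, 1) so every draw is finite and positive
    u[u == 0.0] = np.finfo(float).tiny
    return params.alpha * (-np.log(u)) ** (1.0 / params.beta)
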