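"""Sweep/envelopment probabilities under alternative growth laws.

Four variants of the first-mutant calculus, all built from the same Poisson
arrival recipe (:mod:`rangesweep.poisson`):

* ``boundary_growth`` — proliferation (and mutation) restricted to the
  expanding front; a complete sweep is impossible, so the outcome of
  interest is the first mutant *enveloping* the wildtype front.  Like the
  main model, the result is independent of the mutation rate.
* ``fixed_radius`` — the wildtype fills a static d-ball of radius ``x0``;
  the mutant expands inside it at ``c_m``.  Depends on both ``mu`` and
  ``x0``.
* ``exponential`` — well-mixed exponential growth of wildtype and mutant;
  "sweep" means the mutant fraction reaches a dominance threshold before a
  second surviving mutation arises.
* ``logistic_fixed_N`` — fixed total population ``N0`` with the mutant
  sweeping through it logistically at rate ``r_m - r_wt``; closed form
  ``N0 ** (-mu N0/(r_m - r_wt))``, sensitive to both ``mu`` and ``N0``.

The headline sign pattern: expanding-population models (main model,
boundary growth) are mutation-rate invariant; non-growing models (fixed
radius, fixed N) are monotone decreasing in the mutation rate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import integrate

from ._geometry import UNIT_BALL_VOLUME, integral_wildtype_remaining
from .analytic import MacroParams

__all__ = [
    "AltModelSpec",
    "envelopment_probability",
    "sweep_probability_fixed_radius",
    "sweep_probability_exponential",
    "sweep_probability_logistic_fixed_N",
    "evaluate",
]


@dataclass(frozen=True)
class AltModelSpec:
    """Which alternative model to evaluate, with its parameters."""

    model: str
    params: dict = field(default_factory=dict)
    dominance_threshold: float = 0.5

    def __post_init__(self) -> None:
        if self.model not in {
            "boundary_growth",
            "fixed_radius",
            "exponential",
            "logistic_fixed_N",
        }:
            raise ValueError(f"unknown model {self.model!r}")
        if not 0 < self.dominance_threshold < 1:
            raise ValueError("dominance_threshold must lie in (0, 1)")


def evaluate(spec: AltModelSpec) -> float:
    """Dispatch an :class:`AltModelSpec` to the matching probability."""
    p = spec.params
    if spec.model == "boundary_growth":
        return envelopment_probability(MacroParams(**p))
    if spec.model == "fixed_radius":
        return sweep_probability_fixed_radius(**p)
    if spec.model == "exponential":
        return sweep_probability_exponential(
            **p, dominance_threshold=spec.dominance_threshold
        )
    return sweep_probability_logistic_fixed_N(**p)


# ---------------------------------------------------------------------------
# boundary growth (envelopment)
# ---------------------------------------------------------------------------

def _front_profile_integral(gamma: float, d: int) -> float:
    """J = int_1^{exp(pi/gamma)} u^(d-1) g(phi(u)) du with phi = gamma ln u.

    ``g`` is the remaining-front fraction factor: ``2 pi - 2 phi`` for a
    circle (d = 2) and ``2 pi (1 + cos phi)`` for a sphere (d = 3), before
    the ``R^(d-1)`` scale factor that is pulled outside.
    """
    upper = math.exp(math.pi / gamma)
    if d == 2:
        f = lambda u: u * (2 * math.pi - 2 * gamma * math.log(u))
    else:
        f = lambda u: u**2 * 2 * math.pi * (1 + math.cos(gamma * math.log(u)))
    val, _ = integrate.quad(f, 1.0, upper, limit=200)
    return val


def envelopment_probability(params: MacroParams) -> float:
    """Probability the first front mutant envelops the wildtype front.

    Mutations arise on the (d-1)-dimensional front (unit cell density), so
    the first arrival time is Weibull with shape d; the mutant occupies a
    growing cap whose edge advances at ``c_m`` along the front while being
    advected with the expansion, giving cap half-angle
    ``phi(t) = (c_m/c_wt) ln(t/t0)`` and envelopment at ``phi = pi``.
    The mutation rate cancels exactly, as in the main model.
    """
    d = params.d
    if d == 1:
        raise ValueError(
            "envelopment is undefined in 1D: the front is a pair of points "
            "and a boundary mutant can never surround the opposite one"
        )
    if params.c_m <= params.c_wt:
        return 0.0
    gamma = params.c_m / params.c_wt
    J = _front_profile_integral(gamma, d)
    # surface "population" S_d R^(d-1): s2 = 2 pi R, s3 = 4 pi R^2
    s_d = 2 * math.pi if d == 2 else 4 * math.pi
    # P = (s_d/d) / (s_d/d + J); mu and c_wt powers cancel
    base = s_d / d
    return base / (base + J)


# ---------------------------------------------------------------------------
# fixed wildtype radius
# ---------------------------------------------------------------------------

def sweep_probability_fixed_radius(x0: float, mu: float, c_m: float, d: int = 3) -> float:
    """First-mutant sweep probability in a static wildtype ball of radius x0.

    The mutant origin is uniform in the ball (density ``d y^(d-1)/x0^d``)
    and the mutant consumes the wildtype at speed ``c_m``; the second-mutant
    exposure is ``mu * int (V x0^d - lens(tau)) dtau``, evaluated with the
    same ball-intersection geometry as the main model with ``c_wt = 0``.
    """
    if x0 < 0:
        raise ValueError("x0 must be non-negative")
    if x0 == 0:
        return 1.0
    nodes, weights = np.polynomial.legendre.leggauss(120)
    y = 0.5 * x0 * (nodes + 1.0)
    w = 0.5 * x0 * weights
    exposure = integral_wildtype_remaining(np.full_like(y, x0), y, 0.0, c_m, d)
    dens = d * y ** (d - 1) / x0**d
    return float(np.sum(w * dens * np.exp(-mu * exposure)))


# ---------------------------------------------------------------------------
# well-mixed exponential growth
# ---------------------------------------------------------------------------

def sweep_probability_exponential(
    r_wt: float,
    r_m: float,
    mu: float,
    dominance_threshold: float = 0.5,
) -> float:
    """Probability the first surviving mutant reaches dominance first.

    Wildtype grows as ``exp(r_wt t)`` from one individual; given a first
    surviving mutation at ``t0``, the mutant grows as ``exp(r_m tau)`` and
    reaches fraction ``h`` at
    ``tau* = (ln(h/(1-h)) + r_wt t0)/(r_m - r_wt)``.  The sweep succeeds if
    no second surviving mutation arises in the wildtype during
    ``[t0, t0 + tau*]``.  Substituting the unit-exponential arrival measure
    reduces this to a one-dimensional integral; the result is only weakly
    sensitive to ``mu`` (through ``ln mu`` in ``tau*``).
    """
    if not r_m > r_wt > 0:
        raise ValueError("require r_m > r_wt > 0")
    if not 0 < dominance_threshold < 1:
        raise ValueError("dominance_threshold must lie in (0, 1)")
    if mu <= 0:
        raise ValueError("mu must be positive")
    h = dominance_threshold
    g = r_wt / (r_m - r_wt)
    hfac = (h / (1 - h)) ** g

    def integrand(w: float) -> float:
        # w = Lambda(t0) ~ Exp(1);  A = exp(r_wt t0) = 1 + w r_wt / mu
        A = 1.0 + w * r_wt / mu
        exposure = (mu / r_wt) * A * (hfac * A**g - 1.0)
        return math.exp(-w - exposure)

    val, _ = integrate.quad(integrand, 0.0, 60.0, limit=400)
    return val


# ---------------------------------------------------------------------------
# fixed total size, logistic mutant
# ---------------------------------------------------------------------------

def sweep_probability_logistic_fixed_N(
    N0: float, r_wt: float, r_m: float, mu: float
) -> float:
    """Sweep probability in a fixed-size population of N0 individuals.

    The mutant fraction grows logistically at rate ``a = r_m - r_wt`` from
    one individual; the time-integrated remaining wildtype is exactly
    ``(N0/a) ln N0``, so ``Pr(sweep) = N0 ** (-mu N0 / a)`` — decreasing in
    both the mutation rate and the population size.
    """
    if N0 < 1:
        raise ValueError("N0 must be at least 1")
    if not r_m > r_wt > 0:
        raise ValueError("require r_m > r_wt > 0")
    if mu < 0:
        raise ValueError("mu must be non-negative")
    a = r_m - r_wt
    return float(np.exp(-mu * N0 * math.log(N0) / a))
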