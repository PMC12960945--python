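"""Inhomogeneous-Poisson machinery for mutant arrivals in a growing population.

The number of mutations that arise *and survive genetic drift* during [0, t]
in a population of size ``N(s)`` is Poisson distributed with mean

    lambda(t) = mu * integral_0^t N(s) ds,

where ``mu = rho * mu_tilde`` is the per-capita mutation rate thinned by the
drift-survival probability ``rho``.  Every arrival-time, location and sweep
probability in :mod:`rangesweep.analytic` is built on this intensity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy import integrate
from scipy.stats import poisson as _poisson


@dataclass(frozen=True)
class IntensityIntegral:
    """Expected number of surviving mutations over a time horizon.

    Attributes
    ----------
    lambda_value : float
        Expected number of surviving mutations (dimensionless, >= 0).
    t_max : float
        Time horizon in generations.
    mu : float
        Effective mutation rate per individual per generation.
    """

    lambda_value: float
    t_max: float
    mu: float

    def __post_init__(self) -> None:
        if self.lambda_value < 0:
            raise ValueError("lambda_value must be non-negative")

    def prob_no_mutation(self) -> float:
        """P0 = exp(-lambda): probability that no surviving mutant arises."""
        return float(np.exp(-self.lambda_value))


def effective_mutation_rate(mu_tilde: float, rho: float) -> float:
    """Compound mutation rate mu = rho * mu_tilde.

    Parameters
    ----------
    mu_tilde : float
        Per-capita mutation rate (per individual per generation).
    rho : float
        Probability that a new mutant lineage survives genetic drift.
    """
    if mu_tilde < 0:
        raise ValueError("mu_tilde must be non-negative")
    if not 0 <= rho <= 1:
        raise ValueError("rho must lie in [0, 1]")
    return rho * mu_tilde


def per_division_to_per_capita(mu_per_division: float, division_rate: float) -> float:
    """Convert a per-division mutation probability to a per-capita rate.

    A lineage dividing at rate ``r`` accrues mutation opportunities at rate
    ``r`` per individual, so a per-division probability ``mu_d`` corresponds
    to a per-capita rate ``mu_d * r``.  One generation is the time in which
    an individual with proliferation rate 1 divides once, matching the
    agent-based model's clock.

    .. note::
       Provisional helper: the exact conversion depends on the reproduction
       model (e.g. whether both daughters can mutate); this implements the
       simplest rate-multiplication rule.
    """
    if mu_per_division < 0 or division_rate < 0:
        raise ValueError("rates must be non-negative")
    return mu_per_division * division_rate


def cumulative_intensity(
    population_size: Callable[[float], float],
    mu: float,
    t: float,
    *,
    rtol: float = 1e-8,
) -> IntensityIntegral:
    """lambda(t) = mu * integral_0^t N(s) ds by adaptive quadrature.

    ``population_size`` must be non-negative and finite on [0, t].  Closed
    forms for polynomial ``N`` are available through
    :func:`polynomial_intensity`; this quadrature route is the general path
    and the two agree to high accuracy for polynomial inputs (a tested
    cross-check).
    """
    if t < 0:
        raise ValueError("t must be non-negative")
    if mu < 0:
        raise ValueError("mu must be non-negative")
    if t == 0 or mu == 0:
        return IntensityIntegral(0.0, t, mu)

    def integrand(s: float) -> float:
        val = population_size(s)
        if not np.isfinite(val):
            raise ValueError(f"population size is non-finite at time s={s!r}")
        if val < 0:
            raise ValueError(f"population size is negative at time s={s!r}")
        return val

    # probe endpoints so a non-finite N(s) fails loudly rather than inside quad
    integrand(0.0)
    integrand(t)
    value, _ = integrate.quad(integrand, 0.0, t, epsrel=rtol, limit=200)
    return IntensityIntegral(mu * value, t, mu)


def polynomial_intensity(coeffs: np.ndarray | list, mu: float, t: float) -> IntensityIntegral:
    """Closed-form lambda(t) for N(s) = sum_p coeffs[p] * s^p.

    The antiderivative of ``a s^p`` is ``a t^(p+1)/(p+1)``; coefficients must
    produce a non-negative N on [0, t] (checked at the endpoints only).
    """
    if t < 0:
        raise ValueError("t must be non-negative")
    c = np.asarray(coeffs, dtype=float)
    powers = np.arange(1, c.size + 1)
    lam = mu * float(np.sum(c * t**powers / powers))
    return IntensityIntegral(lam, t, mu)


def prob_k_mutations(lambda_value: float, k: int) -> float:
    """Poisson pmf: probability that exactly k surviving mutations arise.

    ``P_k = exp(-lambda) lambda^k / k!``; in particular ``P_0 = exp(-lambda)``.
    """
    if lambda_value < 0:
        raise ValueError("lambda_value must be non-negative")
    if not float(k).is_integer() or k < 0:
        raise ValueError("k must be a non-negative integer")
    return float(_poisson.pmf(int(k), lambda_value))
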