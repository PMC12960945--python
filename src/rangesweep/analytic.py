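"""Macroscopic constant-speed model of selective sweeps during range expansion.

The wildtype expands as a d-ball whose radius grows at speed ``c_wt`` (in
cell diameters per generation).  Surviving beneficial mutations arise at
effective rate ``mu`` per individual per generation and spread within the
wildtype at speed ``c_m > c_wt``.  From the Poisson arrival machinery
(:mod:`rangesweep.poisson`) follow, in closed form:

* the first-arrival time ``T`` and wildtype radius at arrival ``X``, both
  Weibull with shape ``d + 1`` (scales ``kappa`` and ``theta = c_wt*kappa``);
* the mutant origin distance ``Y`` with conditional density
  ``d y^(d-1)/x^d`` and marginal
  ``(d y^(d-1)/theta^d) Gamma(1/(d+1), (y/theta)^(d+1))``;
* the conditional sweep probability ``exp(-mu * int N_wt(tau) dtau)`` and its
  ``y = 0`` upper bound ``exp(-(x/alpha)^(d+1))``;
* the strikingly simple unconditional bound
  ``Pr(sweep) <= beta^d`` with ``beta = (c_m - c_wt)/c_m``, independent of
  the mutation rate;
* the posterior radius-at-arrival given a sweep, approximately Weibull with
  scale ``beta^(d/(d+1)) * theta``.

Numerical marginalisation follows a fixed trapezoid protocol on theta-scaled
grids (see :func:`methods_grid`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import special

from ._geometry import (
    UNIT_BALL_VOLUME,
    ball_volume,
    integral_wildtype_remaining,
)
from ._geometry import wildtype_remaining as _nwt_geometry

__all__ = [
    "MacroParams",
    "CharacteristicScales",
    "GeometryState",
    "scales",
    "arrival_time_density",
    "radius_density",
    "radius_moments",
    "location_density_conditional",
    "location_density",
    "location_moments",
    "wildtype_remaining",
    "conditional_sweep_prob",
    "sweep_probability",
    "sweep_probability_from_rates",
    "posterior_radius_given_sweep",
    "cancer_speed_estimate",
    "REFINED_1D_Y2_COEFF",
]

#: coefficient in the refined 1D approximation y^2 = 0.28125 x^2
REFINED_1D_Y2_COEFF = 0.28125


@dataclass(frozen=True)
class MacroParams:
    """Parameters of the macroscopic model.

    Attributes
    ----------
    c_wt : float
        Wildtype radial expansion speed (cell diameters / generation).
    c_m : float
        Mutant radial expansion speed within the wildtype (same units).
    mu : float
        Effective mutation rate ``rho * mu_tilde`` (per individual per
        generation).
    d : int
        Spatial dimension, 1, 2 or 3.
    """

    c_wt: float
    c_m: float
    mu: float
    d: int = 3

    def __post_init__(self) -> None:
        if self.c_wt <= 0:
            raise ValueError("c_wt must be positive")
        if self.c_m < self.c_wt:
            raise ValueError("require c_m >= c_wt (c_m == c_wt gives sweep probability 0)")
        if self.mu <= 0:
            raise ValueError("mu must be positive")
        if self.d not in (1, 2, 3):
            raise ValueError("d must be 1, 2 or 3")

    @classmethod
    def from_raw_rates(cls, c_wt: float, c_m: float, mu_tilde: float, rho: float, d: int = 3):
        """Build from the per-capita mutation rate and drift-survival probability."""
        from .poisson import effective_mutation_rate

        return cls(c_wt=c_wt, c_m=c_m, mu=effective_mutation_rate(mu_tilde, rho), d=d)


@dataclass(frozen=True)
class CharacteristicScales:
    """Derived scales of the model.

    kappa: characteristic first-arrival time (generations);
    theta: characteristic arrival radius (cell diameters);
    alpha: characteristic sweep length (cell diameters, +inf if c_m == c_wt);
    beta:  relative speed advantage (c_m - c_wt)/c_m in [0, 1).
    """

    kappa: float
    theta: float
    alpha: float
    beta: float

    @property
    def sweep_possible(self) -> bool:
        return self.beta > 0


def scales(params: MacroParams) -> CharacteristicScales:
    """Characteristic scales kappa, theta, alpha, beta for dimension d.

    ``theta^(d+1) = (d+1) c_wt / (mu V_d)`` with ``V_d`` the unit-ball
    volume (3D: ``theta = (3 c_wt/(pi mu))^(1/4)``), and
    ``alpha^(d+1) = theta^(d+1) beta^d / (1 - beta^d)``, which encodes the
    identity ``alpha^(d+1)/(alpha^(d+1) + theta^(d+1)) = beta^d``.
    """
    d = params.d
    V = UNIT_BALL_VOLUME[d]
    kappa = ((d + 1) / (params.mu * V * params.c_wt**d)) ** (1.0 / (d + 1))
    theta = params.c_wt * kappa
    beta = (params.c_m - params.c_wt) / params.c_m
    if beta > 0:
        alpha = theta * (beta**d / (1.0 - beta**d)) ** (1.0 / (d + 1))
    else:
        alpha = math.inf
    return CharacteristicScales(kappa=kappa, theta=theta, alpha=alpha, beta=beta)


@dataclass(frozen=True)
class GeometryState:
    """Mutant/wildtype geometry for a mutant born at distance y, radius x."""

    x: float
    y: float
    tau1: float
    tau2: float

    @classmethod
    def from_params(cls, x: float, y: float, params: MacroParams) -> "GeometryState":
        if not 0 <= y <= x:
            raise ValueError("require 0 <= y <= x")
        if params.c_m <= params.c_wt:
            return cls(x=x, y=y, tau1=math.inf, tau2=math.inf)
        dc = params.c_m - params.c_wt
        return cls(x=x, y=y, tau1=(x - y) / dc, tau2=(x + y) / dc)


# ---------------------------------------------------------------------------
# distributions of arrival time, radius and location
# ---------------------------------------------------------------------------

def _weibull_pdf(v, shape: float, scale: float):
    v = np.asarray(v, dtype=float)
    if np.any(v < 0):
        raise ValueError("argument must be non-negative")
    z = v / scale
    return (shape / scale) * z ** (shape - 1) * np.exp(-(z**shape))


def arrival_time_density(t, params: MacroParams):
    """Density of the first surviving mutant's arrival time.

    Weibull with shape ``d + 1`` and scale ``kappa``
    (3D: ``f_T(t) = 4 t^3/kappa^4 exp(-(t/kappa)^4)``).
    """
    return _weibull_pdf(t, params.d + 1, scales(params).kappa)


def radius_density(x, params: MacroParams):
    """Density of the wildtype radius X at first-mutant arrival.

    Weibull with shape ``d + 1`` and scale ``theta``; equals
    ``arrival_time_density(x/c_wt)/c_wt`` by the change of variables
    ``x = c_wt t``.
    """
    return _weibull_pdf(x, params.d + 1, scales(params).theta)


def radius_moments(params: MacroParams) -> tuple[float, float]:
    """(mean, variance) of X from the closed-form Weibull moments.

    3D: mean = Gamma(5/4) theta ~ 0.91 theta, variance ~ 0.065 theta^2.
    """
    k = params.d + 1
    theta = scales(params).theta
    g1 = special.gamma(1 + 1 / k)
    g2 = special.gamma(1 + 2 / k)
    return g1 * theta, (g2 - g1**2) * theta**2


def location_density_conditional(y, x: float, d: int):
    """f_Y(y | X = x) = d y^(d-1) / x^d on [0, x] (shell measure)."""
    if x <= 0:
        raise ValueError("x must be positive")
    if d not in (1, 2, 3):
        raise ValueError("d must be 1, 2 or 3")
    y = np.asarray(y, dtype=float)
    dens = d * y ** (d - 1) / x**d
    return np.where((y >= 0) & (y <= x), dens, 0.0)


def location_density(y, params: MacroParams):
    """Marginal density of the mutant origin distance Y.

    ``f_Y(y) = (d y^(d-1)/theta^d) Gamma(1/(d+1), (y/theta)^(d+1))`` with
    the (upper) incomplete gamma function; 3D:
    ``(3y^2/theta^3) Gamma(1/4, y^4/theta^4)``.
    """
    d = params.d
    theta = scales(params).theta
    y = np.asarray(y, dtype=float)
    a = 1.0 / (d + 1)
    z = (np.maximum(y, 0.0) / theta) ** (d + 1)
    upper_gamma = special.gammaincc(a, z) * special.gamma(a)
    dens = d * y ** (d - 1) / theta**d * upper_gamma
    return np.where(y >= 0, dens, 0.0)


def location_moments(params: MacroParams, method: str = "quadrature") -> tuple[float, float]:
    """(mean, variance) of Y.

    ``method='quadrature'`` integrates the marginal density on a fine
    theta-scaled grid; ``method='closed_form'`` uses
    ``E[Y^n] = (d/(d+n)) E[X^n]`` (since Y | X is a scaled beta variable),
    giving 3D values E[Y] ~ 0.68 theta, Var[Y] ~ 0.070 theta^2.
    """
    d = params.d
    theta = scales(params).theta
    if method == "closed_form":
        k = d + 1
        ex1 = special.gamma(1 + 1 / k) * theta
        ex2 = special.gamma(1 + 2 / k) * theta**2
        m1 = d / (d + 1) * ex1
        m2 = d / (d + 2) * ex2
        return m1, m2 - m1**2
    if method != "quadrature":
        raise ValueError(f"unknown method {method!r}")
    y = np.linspace(0.0, 6.0 * theta, 60001)
    f = location_density(y, params)
    m1 = np.trapezoid(y * f, y)
    m2 = np.trapezoid(y**2 * f, y)
    return float(m1), float(m2 - m1**2)


# ---------------------------------------------------------------------------
# sweep probabilities
# ---------------------------------------------------------------------------

def wildtype_remaining(tau, x: float, y: float, params: MacroParams):
    """Remaining wildtype count N_wt(tau) after a mutant born at (x, y).

    Untouched shell volume minus the mutant ball while interior, minus the
    two-ball lens after the mutant breaches the boundary; 0 beyond tau2.
    """
    if not 0 <= y <= x:
        raise ValueError("require 0 <= y <= x")
    return _nwt_geometry(tau, x, y, params.c_wt, params.c_m, params.d)


def conditional_sweep_prob(x, y, params: MacroParams, method: str = "exact"):
    """Pr(sweep | X = x, Y = y).

    ``method='exact'``: ``exp(-mu * int_0^inf N_wt(tau) dtau)`` with the
    piecewise ball/lens geometry integrated in closed form (1D, 3D) or by
    fixed-order quadrature (2D).  ``method='approx'``: the y = 0 upper bound
    ``exp(-(x/alpha)^(d+1))``, which ignores y.
    """
    x = np.asarray(x, dtype=float)
    if params.c_m <= params.c_wt:
        return np.where(x == 0, 1.0, 0.0)
    if method == "approx":
        alpha = scales(params).alpha
        return np.exp(-((x / alpha) ** (params.d + 1)))
    if method != "exact":
        raise ValueError(f"unknown method {method!r}")
    integral = integral_wildtype_remaining(x, y, params.c_wt, params.c_m, params.d)
    return np.exp(-params.mu * integral)


def methods_grid(theta: float, upper: float | None = None) -> np.ndarray:
    """Theta-scaled trapezoid grid: [0.001 theta, 3 theta], step 0.001 theta
    up to 0.5 theta and 0.01 theta beyond.

    Contributions outside these bounds are negligible because f_X is tiny
    near 0 and beyond ~2 theta.
    """
    upper = 3.0 * theta if upper is None else upper
    fine = np.arange(0.001, 0.5 + 1e-12, 0.001)
    coarse = np.arange(0.51, 3.0 + 1e-12, 0.01)
    grid = np.concatenate([fine, coarse]) * theta
    return grid[grid <= upper + 1e-12 * theta]


def _conditional_given_x(x: np.ndarray, params: MacroParams, theta: float) -> np.ndarray:
    """Pr(sweep | X = x) = int f_Y(y|x) Pr(sweep|x, y) dy, trapezoid in y."""
    out = np.empty_like(x)
    for i, xi in enumerate(x):
        ygrid = methods_grid(theta, upper=xi)
        if ygrid.size < 2:
            ygrid = np.linspace(0.001 * theta, xi, 8)
        probs = conditional_sweep_prob(np.full_like(ygrid, xi), ygrid, params, "exact")
        fy = location_density_conditional(ygrid, float(xi), params.d)
        out[i] = np.trapezoid(probs * fy, ygrid)
    return out


def sweep_probability(params: MacroParams, method: str = "closed_form") -> float:
    """Unconditional probability that the first surviving mutant sweeps.

    ``method='closed_form'``: ``beta^d`` (the y = 0 bound marginalised over
    f_X, independent of the mutation rate).  ``method='numeric'``: double
    trapezoid marginalisation of the exact conditional probability over
    f_Y(y|x) and f_X(x) on the theta-scaled protocol grid; always <= beta^d.
    ``method='refined_1d'``: the 1D refinement using y^2 = 0.28125 x^2 in
    place of y = 0.
    """
    sc = scales(params)
    if sc.beta == 0:
        return 0.0
    if method == "closed_form":
        return float(sc.beta**params.d)
    if method == "refined_1d":
        if params.d != 1:
            raise ValueError("the refined approximation is defined in 1D only")
        xgrid = methods_grid(sc.theta)
        y = math.sqrt(REFINED_1D_Y2_COEFF) * xgrid
        cond = conditional_sweep_prob(xgrid, y, params, "exact")
        return float(np.trapezoid(cond * radius_density(xgrid, params), xgrid))
    if method != "numeric":
        raise ValueError(f"unknown method {method!r}")
    xgrid = methods_grid(sc.theta)
    cond_x = _conditional_given_x(xgrid, params, sc.theta)
    return float(np.trapezoid(cond_x * radius_density(xgrid, params), xgrid))


def sweep_probability_from_rates(r_re: float, r_wt: float, r_m: float, d: int) -> float:
    """Sweep probability from proliferation rates via the FKPP speed map.

    With ``c = 2 sqrt(D a)`` for invader growth advantages
    ``a_wt = r_wt - r_re`` and ``a_m = r_m - r_wt`` (the diffusivity D
    cancels), ``beta^d`` becomes ``(1 - sqrt(a_wt/a_m))^d``, clipped to 0
    when ``a_wt >= a_m``.
    """
    if not (r_m > r_wt > r_re):
        raise ValueError("require r_m > r_wt > r_re")
    if d not in (1, 2, 3):
        raise ValueError("d must be 1, 2 or 3")
    ratio = (r_wt - r_re) / (r_m - r_wt)
    if ratio >= 1.0:
        return 0.0
    return float((1.0 - math.sqrt(ratio)) ** d)


def posterior_radius_given_sweep(x, params: MacroParams, method: str = "approx"):
    """Density of the radius X at first-mutant arrival, given a sweep occurred.

    ``method='approx'``: Weibull with shape d + 1 and scale
    ``beta^(d/(d+1)) theta`` (3D: ``(4x^3/(beta^3 theta^4))
    exp(-x^4/(beta^3 theta^4))``).  ``method='numeric'``: Bayes' theorem
    with the exact conditional probability and the numeric normaliser.
    """
    sc = scales(params)
    if sc.beta == 0:
        raise ValueError("conditioning on a sweep requires c_m > c_wt")
    d = params.d
    if method == "approx":
        scale = sc.beta ** (d / (d + 1)) * sc.theta
        return _weibull_pdf(x, d + 1, scale)
    if method != "numeric":
        raise ValueError(f"unknown method {method!r}")
    x = np.atleast_1d(np.asarray(x, dtype=float))
    norm = sweep_probability(params, "numeric")
    cond = _conditional_given_x(x, params, sc.theta)
    out = cond * radius_density(x, params) / norm
    return out if out.shape != (1,) else float(out[0])


def cancer_speed_estimate(
    volume_cm3: float,
    years: float,
    cell_diameter_um: float = 20.0,
    generation_days: float = 4.0,
) -> tuple[float, float]:
    """Radial expansion speed implied by a tumour's final volume and age.

    A tumour of volume V reached over time T has mean radial speed
    ``c_tilde = (3V/(4 pi))^(1/3) / T``, returned in micrometres per day,
    together with ``c = c_tilde * generation_days / cell_diameter_um`` in
    cell diameters per generation.

    Returns
    -------
    (um_per_day, cell_diameters_per_generation)
    """
    if min(volume_cm3, years, cell_diameter_um, generation_days) <= 0:
        raise ValueError("all inputs must be positive")
    radius_cm = (3.0 * volume_cm3 / (4.0 * math.pi)) ** (1.0 / 3.0)
    days = years * 365.25
    c_tilde = radius_cm * 1e4 / days  # um / day
    c = c_tilde * generation_days / cell_diameter_um
    return c_tilde, c


def summary(params: MacroParams) -> dict:
    """Headline quantities: scales, sweep probability and radius moments."""
    sc = scales(params)
    ex, vx = radius_moments(params)
    ey, vy = location_moments(params, "closed_form")
    out = {
        "kappa": sc.kappa,
        "theta": sc.theta,
        "alpha": sc.alpha,
        "beta": sc.beta,
        "sweep_prob_closed_form": sc.beta**params.d,
        "E_X": ex,
        "Var_X": vx,
        "E_Y": ey,
        "Var_Y": vy,
    }
    if sc.beta > 0:
        k = params.d + 1
        out["E_X_given_sweep"] = special.gamma(1 + 1 / k) * sc.beta ** (params.d / k) * sc.theta
    return out
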