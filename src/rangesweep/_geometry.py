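"""Ball-intersection geometry for the expanding wildtype / mutant system.

All functions treat the wildtype as a d-ball of radius ``R(tau) = x + c_wt*tau``
centred at the origin and the mutant as a d-ball of radius ``r(tau) = c_m*tau``
centred at distance ``y`` from the origin (0 <= y <= x).  The mutant stays
inside the wildtype until ``tau1 = (x - y)/(c_m - c_wt)`` and covers it
entirely at ``tau2 = (x + y)/(c_m - c_wt)``; in between, the replaced volume
is the two-ball intersection (lens).

Vectorised over ``x`` and ``y``; ``c_wt = 0`` is allowed (static wildtype).
"""

from __future__ import annotations

import numpy as np

#: volume of the unit d-ball for d = 1, 2, 3
UNIT_BALL_VOLUME = {1: 2.0, 2: np.pi, 3: 4.0 * np.pi / 3.0}

# Gauss-Legendre nodes for the 2D lens-region quadrature (smooth integrand)
_GL_NODES, _GL_WEIGHTS = np.polynomial.legendre.leggauss(80)


def ball_volume(radius, d: int):
    """Volume (length/area/volume) of a d-ball."""
    return UNIT_BALL_VOLUME[d] * np.asarray(radius, dtype=float) ** d


def overlap_volume(R, r, dist, d: int):
    """Intersection volume of two d-balls with radii R, r and centre distance dist.

    Handles disjoint and nested configurations; vectorised.
    """
    R = np.asarray(R, dtype=float)
    r = np.asarray(r, dtype=float)
    dist = np.asarray(dist, dtype=float)
    R, r, dist = np.broadcast_arrays(R, r, dist)

    small = np.minimum(R, r)
    nested = dist <= np.abs(R - r)
    disjoint = dist >= R + r
    lens_mask = ~(nested | disjoint)

    out = np.where(nested, ball_volume(small, d), 0.0)
    if np.any(lens_mask):
        Rl, rl, dl = R[lens_mask], r[lens_mask], dist[lens_mask]
        if d == 1:
            lens = np.minimum(Rl, dl + rl) - np.maximum(-Rl, dl - rl)
        elif d == 2:
            lens = _lens_area_2d(Rl, rl, dl)
        else:
            lens = _lens_volume_3d(Rl, rl, dl)
        out = np.asarray(out)
        out[lens_mask] = lens
    return out if out.shape else float(out)


def _lens_area_2d(R, r, dist):
    # standard circle-circle intersection area
    arg1 = np.clip((dist**2 + R**2 - r**2) / (2 * dist * R), -1.0, 1.0)
    arg2 = np.clip((dist**2 + r**2 - R**2) / (2 * dist * r), -1.0, 1.0)
    tri = (-dist + r + R) * (dist + r - R) * (dist - r + R) * (dist + r + R)
    return (
        R**2 * np.arccos(arg1)
        + r**2 * np.arccos(arg2)
        - 0.5 * np.sqrt(np.maximum(tri, 0.0))
    )


def _lens_volume_3d(R, r, dist):
    # spherical-lens volume of two overlapping spheres
    return (
        np.pi
        * (R + r - dist) ** 2
        * (dist**2 + 2 * dist * r - 3 * r**2 + 2 * dist * R + 6 * r * R - 3 * R**2)
        / (12 * dist)
    )


def breach_times(x, y, c_wt: float, c_m: float):
    """(tau1, tau2): when the mutant reaches, then fully covers, the wildtype."""
    if c_m <= c_wt:
        raise ValueError("breach times are finite only for c_m > c_wt")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    dc = c_m - c_wt
    return (x - y) / dc, (x + y) / dc


def wildtype_remaining(tau, x, y, c_wt: float, c_m: float, d: int):
    """N_wt(tau): wildtype volume not yet replaced by the mutant.

    Piecewise: full shell minus the mutant ball while the mutant is interior,
    minus the two-ball lens after it breaches the boundary, and 0 once the
    mutant has covered the wildtype (tau >= tau2).
    """
    tau = np.asarray(tau, dtype=float)
    if np.any(tau < 0):
        raise ValueError("tau must be non-negative")
    R = x + c_wt * tau
    r = c_m * tau
    total = ball_volume(R, d)
    if c_m <= c_wt:
        # mutant never catches the front; it remains interior forever
        return total - ball_volume(np.minimum(r, R), d)
    _, tau2 = breach_times(x, y, c_wt, c_m)
    out = total - overlap_volume(R, r, np.broadcast_to(y, np.shape(tau)), d)
    return np.where(tau >= tau2, 0.0, out)


def integral_wildtype_remaining(x, y, c_wt: float, c_m: float, d: int):
    """integral_0^inf N_wt(tau) d tau, vectorised over (x, y).

    Closed form in 1D and 3D (the lens volume integrates to a polynomial in
    tau); fixed-order Gauss-Legendre over the lens window in 2D, where the
    lens area involves arccos terms.  Returns +inf when c_m <= c_wt.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x, y = np.broadcast_arrays(x, y)
    if np.any(y > x + 1e-12) or np.any(y < 0):
        raise ValueError("require 0 <= y <= x")
    if c_m <= c_wt:
        return np.full(x.shape, np.inf) if x.shape else np.inf

    a, b = float(c_wt), float(c_m)
    tau1, tau2 = breach_times(x, y, a, b)
    V = UNIT_BALL_VOLUME[d]

    # integral of the untouched wildtype volume over [0, tau2]
    if a > 0:
        growth = V * ((x + a * tau2) ** (d + 1) - x ** (d + 1)) / ((d + 1) * a)
    else:
        growth = V * x**d * tau2
    # mutant ball while interior, [0, tau1]
    interior = V * b**d * tau1 ** (d + 1) / (d + 1)
    lens = _lens_window_integral(x, y, a, b, tau1, tau2, d)
    out = growth - interior - lens
    return out if out.shape else float(out)


def _lens_window_integral(x, y, a, b, tau1, tau2, d: int):
    """integral_{tau1}^{tau2} lens(tau) d tau for each (x, y)."""
    if d == 1:
        # overlap = R - (y - r) = (x - y) + (a + b) tau, linear in tau
        w = tau2 - tau1
        return (x - y) * w + 0.5 * (a + b) * (tau2**2 - tau1**2)
    if d == 3:
        return _lens_window_integral_3d(x, y, a, b, tau1, tau2)
    # d == 2: Gauss-Legendre on [tau1, tau2]; integrand smooth inside
    mid = 0.5 * (tau1 + tau2)
    half = 0.5 * (tau2 - tau1)
    taus = mid[..., None] + half[..., None] * _GL_NODES  # (..., n)
    R = x[..., None] + a * taus
    r = b * taus
    dist = np.broadcast_to(y[..., None], taus.shape)
    # guard y == 0 (empty window, half == 0): area value irrelevant
    safe = np.maximum(dist, 1e-300)
    area = _lens_area_2d(R, r, safe)
    return half * np.einsum("...n,n->...", area, _GL_WEIGHTS)


def _lens_window_integral_3d(x, y, a, b, tau1, tau2):
    # lens(tau) = pi * s(tau)^2 * Q(tau) / (12 y) with
    # s = (x - y) + (a + b) tau and Q quadratic in tau: integrate the
    # resulting quartic polynomial exactly.
    p0, p1 = x - y, a + b
    s0, s1, s2 = p0**2, 2 * p0 * p1, np.full_like(x, p1**2)
    q0 = y**2 + 2 * x * y - 3 * x**2
    q1 = 2 * y * (a + b) + 6 * x * (b - a)
    q2 = np.full_like(x, -3.0 * (a - b) ** 2)

    # polynomial product coefficients c_k of s^2 * Q, k = 0..4
    c0 = s0 * q0
    c1 = s0 * q1 + s1 * q0
    c2 = s0 * q2 + s1 * q1 + s2 * q0
    c3 = s1 * q2 + s2 * q1
    c4 = s2 * q2

    def antideriv(t):
        t2 = t * t
        t3 = t2 * t
        t4 = t3 * t
        t5 = t4 * t
        return c0 * t + c1 * t2 / 2 + c2 * t3 / 3 + c3 * t4 / 4 + c4 * t5 / 5

    ysafe = np.where(y > 0, y, 1.0)
    val = np.pi * (antideriv(tau2) - antideriv(tau1)) / (12 * ysafe)
    return np.where(y > 0, val, 0.0)
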