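"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the adaptive solvers of the package: fixed-step
fourth-order Runge-Kutta on a fine grid for the ODEs, explicit counting
for the survivor function, and textbook formulas evaluated directly.
"""

import numpy as np


def embryo_rk4(p, c, E_0, dt, t_max):
    """Fixed-step RK4 integration of the embryo stage.

    Returns (a_b, L_b, e_b) with the birth instant located by linear
    interpolation of maturity between steps, or None if E_Hb is not
    reached.
    """
    E_m = p.p_Am / p.v
    g = p.E_G / (p.kappa * E_m)
    L_m = p.kappa * p.p_Am / p.p_M

    def rhs(y):
        E, L, E_H = y
        e = E / (L**3 * E_m)
        p_C = E * (p.v / L) * (g + L / L_m) / (e + g)
        return np.array([
            -p_C,
            (p.v / 3.0) * (e - L / L_m) / (e + g),
            (1.0 - p.kappa) * p_C - p.k_J * E_H,
        ])

    y = np.array([E_0, 1e-5 * L_m, 0.0])
    t = 0.0
    while t < t_max:
        k1 = rhs(y)
        if k1[2] <= 0.0:  # maturation stalled: E_Hb unreachable
            return None
        k2 = rhs(y + 0.5 * dt * k1)
        k3 = rhs(y + 0.5 * dt * k2)
        k4 = rhs(y + dt * k3)
        y_new = y + (dt / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        if y_new[2] >= p.E_Hb:
            # linear interpolation to the crossing
            w = (p.E_Hb - y[2]) / (y_new[2] - y[2])
            y_b = y + w * (y_new - y)
            a_b = t + w * dt
            e_b = y_b[0] / (y_b[1] ** 3 * E_m)
            return a_b, y_b[1], e_b
        y = y_new
        t += dt
    return None


def shoot_E0_rk4(p, c, f=1.0, rel_tol=1e-7, dt=None):
    """Bisection on E_0 with the fixed-step embryo integrator."""
    if dt is None:
        dt = 0.01  # d; fine grid
    L_m = p.kappa * p.p_Am / p.p_M
    t_max = 20.0 * L_m / p.v  # embryo growth is bounded by dL/da <= v/3

    def resid(E_0):
        out = embryo_rk4(p, c, E_0, dt, t_max)
        if out is None:
            return -10.0
        return out[2] - f

    lo = hi = p.E_Hb / (1 - p.kappa)
    while resid(hi) < 0:
        lo = hi
        hi *= 2
    while resid(lo) > 0:
        hi = lo
        lo /= 2
    while hi - lo > rel_tol * hi:
        mid = 0.5 * (lo + hi)
        if resid(mid) < 0:
            lo = mid
        else:
            hi = mid
    E_0 = 0.5 * (lo + hi)
    a_b, L_b, e_b = embryo_rk4(p, c, E_0, dt, t_max)
    return E_0, a_b, L_b


def survivor_bruteforce(values, x):
    """Fraction of values strictly exceeding x, by explicit counting."""
    values = [v for v in values if np.isfinite(v)]
    return sum(1 for v in values if v > x) / len(values)


def weibull_mean_life(L_i, h_a, v, f=1.0):
    """Mean life span of a fully-grown individual with s_G = 0.

    S(t) = exp(-h_a f v t^3 / (6 L_i)), whose integral is
    Gamma(4/3) (6 L_i / (h_a f v))^(1/3).
    """
    from math import gamma

    return gamma(4.0 / 3.0) * (6.0 * L_i / (h_a * f * v)) ** (1.0 / 3.0)
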