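"""Standard Dynamic Energy Budget (DEB) model for a single individual.

The standard ("std") DEB model describes an individual by three state
variables: reserve energy ``E`` (J), structural volume expressed as
structural length ``L = V^(1/3)`` (cm), and maturity ``E_H`` (J), the
cumulative energy invested in development.  Assimilated energy enters the
reserve; reserve is mobilized at a rate controlled by the energy
conductance ``v``; a fixed fraction ``kappa`` of the mobilized flux is
allocated to the soma (somatic maintenance first, growth with the rest),
and the remainder to maturity maintenance plus maturation (before puberty)
or reproduction (after puberty).  Feeding scales with squared structural
length, somatic maintenance with cubed length, maturity maintenance with
maturity.  At constant food the growth trajectory reduces to the von
Bertalanffy curve.

Aging follows the Weibull-Gompertz damage model: damage-inducing compounds
(state ``q``) amplify themselves and feed a hazard rate ``h``; survival
``S`` decays accordingly, and mean life span is the integral of ``S``.

All parameters are understood at the reference temperature (20 degC);
:func:`arrhenius_correction` converts rates to other body temperatures.

Units: energies J, lengths cm, times d, temperatures K, weights g.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq, minimize_scalar

__all__ = [
    "DEBParameters",
    "ChemicalConstants",
    "CompoundParameters",
    "StateVector",
    "PowerFluxes",
    "BirthResult",
    "LifeHistory",
    "InvalidParameterError",
    "NonViableError",
    "MaturationStalledError",
    "T_REF",
    "arrhenius_correction",
    "at_temperature",
    "compound_parameters",
    "power_fluxes",
    "initial_reserve_and_birth",
    "integrate_embryo",
    "length_at_age",
    "grow_to_puberty",
    "ultimate_state",
    "wet_weight",
    "von_bertalanffy_rate",
    "max_specific_growth",
    "reproduction_rate",
    "specific_respiration",
    "aging_survival",
    "mean_life_span",
    "supply_stress",
    "precociality",
    "simulate_post_birth",
    "life_history",
]

#: Reference temperature, 20 degC, at which all traits are reported.
T_REF = 293.15

# solver tolerances (relative) used throughout this module
_ODE_RTOL = 1e-10
_SHOOT_RTOL = 1e-8
_SURVIVAL_CUTOFF = 1e-7


class InvalidParameterError(ValueError):
    """A DEB parameter violates its admissibility constraint."""


class NonViableError(RuntimeError):
    """Embryo cannot mature to birth for any initial reserve.

    Attributes
    ----------
    stall_maturity : float
        Maturity level (J) at which maturation stalled for the largest
        initial reserve tried.
    """

    def __init__(self, message: str, stall_maturity: float = float("nan")):
        super().__init__(message)
        self.stall_maturity = stall_maturity


class MaturationStalledError(RuntimeError):
    """Maturity maintenance catches up with allocation before puberty."""

    def __init__(self, message: str, stall_maturity: float = float("nan")):
        super().__init__(message)
        self.stall_maturity = stall_maturity


@dataclass(frozen=True)
class DEBParameters:
    """Primary parameters of the std DEB model for one species.

    Rates are given at the reference temperature (20 degC).
    """

    species_id: str
    taxon: str = ""
    sub_taxon: str = ""
    T_A: float = 8000.0      #: Arrhenius temperature (K)
    p_Am: float = 250.0      #: {p_Am}, surface-specific max assimilation (J/d/cm^2)
    v: float = 0.06          #: energy conductance (cm/d)
    kappa: float = 0.8       #: allocation fraction to soma (-)
    kappa_R: float = 0.95    #: reproduction efficiency (-)
    p_M: float = 20.0        #: [p_M], volume-specific somatic maintenance (J/d/cm^3)
    k_J: float = 0.002       #: maturity maintenance rate coefficient (1/d)
    E_G: float = 7800.0      #: [E_G], volume-specific cost of structure (J/cm^3)
    E_Hb: float = 3.5e3      #: maturity at birth (J)
    E_Hp: float = 9.0e5      #: maturity at puberty (J)
    h_a: float = 1e-9        #: Weibull aging acceleration (1/d^2)
    s_G: float = 1e-4        #: Gompertz stress coefficient (-)
    f: float = 1.0           #: scaled functional response (-), 1 = abundant food

    def __post_init__(self) -> None:
        positive = ("T_A", "p_Am", "v", "p_M", "E_G", "E_Hb", "E_Hp", "h_a")
        for name in positive:
            if not getattr(self, name) > 0:
                raise InvalidParameterError(
                    f"{self.species_id or 'parameters'}: {name} must be > 0, "
                    f"got {getattr(self, name)!r}"
                )
        if not 0 < self.kappa < 1:
            raise InvalidParameterError(
                f"{self.species_id}: kappa must lie in (0, 1), got {self.kappa!r}"
            )
        if not 0 < self.kappa_R <= 1:
            raise InvalidParameterError(
                f"{self.species_id}: kappa_R must lie in (0, 1], got {self.kappa_R!r}"
            )
        if self.k_J < 0:
            raise InvalidParameterError(
                f"{self.species_id}: k_J must be >= 0, got {self.k_J!r}"
            )
        if self.s_G < 0:
            raise InvalidParameterError(
                f"{self.species_id}: s_G must be >= 0, got {self.s_G!r}"
            )
        if not self.E_Hb < self.E_Hp:
            raise InvalidParameterError(
                f"{self.species_id}: require E_Hb < E_Hp, "
                f"got E_Hb={self.E_Hb!r}, E_Hp={self.E_Hp!r}"
            )
        if not 0 < self.f <= 1:
            raise InvalidParameterError(
                f"{self.species_id}: f must lie in (0, 1], got {self.f!r}"
            )


@dataclass(frozen=True)
class ChemicalConstants:
    """Conversion constants between energy, mass and dioxygen.

    Defaults are the generalized-composition values commonly used for
    wet/dry biomass conversion in energy-budget work; all are configurable.
    """

    d_Vw: float = 1.0        #: wet specific density of structure (g/cm^3)
    w_E: float = 23.9        #: molar mass of reserve (g/mol)
    mu_E: float = 5.5e5      #: chemical potential of reserve (J/mol)
    mu_V: float = 5.0e5      #: chemical potential of structure (J/mol)
    d_Vd: float = 0.3        #: dry specific density of structure (g/cm^3)
    w_V: float = 23.9        #: molar mass of structure (g/mol)
    mu_O2: float = 4.48e5    #: oxycaloric coefficient (J per mol O2)
    T_ref: float = T_REF     #: reference temperature (K), 20 degC

    def __post_init__(self) -> None:
        for name in ("d_Vw", "w_E", "mu_E", "mu_V", "d_Vd", "w_V", "mu_O2", "T_ref"):
            if not getattr(self, name) > 0:
                raise InvalidParameterError(f"chemical constant {name} must be > 0")


DEFAULT_CHEM = ChemicalConstants()


@dataclass(frozen=True)
class CompoundParameters:
    """Frequently used combinations of primary parameters."""

    E_m: float      #: [E_m] = {p_Am}/v, maximum reserve capacity (J/cm^3)
    g: float        #: energy investment ratio [E_G]/(kappa [E_m]) (-)
    k_M: float      #: somatic maintenance rate coefficient [p_M]/[E_G] (1/d)
    L_m: float      #: maximum structural length kappa {p_Am}/[p_M] (cm)
    omega: float    #: reserve contribution to wet weight (-)
    kappa_G: float  #: fraction of growth flux fixed in structure (-)


@dataclass(frozen=True)
class StateVector:
    """Instantaneous state of an individual."""

    a: float    #: age (d)
    L: float    #: structural length (cm)
    E: float    #: reserve energy (J)
    E_H: float  #: maturity (J)
    q: float = 0.0  #: aging acceleration (1/d^2)
    h: float = 0.0  #: aging hazard (1/d)
    S: float = 1.0  #: survival probability (-)


@dataclass(frozen=True)
class PowerFluxes:
    """Energy fluxes (J/d) through the individual at one instant."""

    p_A: float  #: assimilation
    p_C: float  #: mobilization
    p_S: float  #: somatic maintenance
    p_J: float  #: maturity maintenance
    p_G: float  #: growth
    p_R: float  #: maturation / reproduction


@dataclass(frozen=True)
class BirthResult:
    """Outcome of the embryo initial-reserve shooting problem."""

    E_0: float  #: initial reserve = energy cost of one egg (J)
    a_b: float  #: age at birth (d)
    L_b: float  #: structural length at birth (cm)
    e_b: float  #: scaled reserve density at birth (-), equals f by closure


@dataclass(frozen=True)
class LifeHistory:
    """Derived life-history traits of one species at constant food."""

    E_0: float
    a_b: float
    L_b: float
    Ww_b: float
    a_p: float
    L_p: float
    Ww_p: float
    L_i: float
    Ww_i: float
    r_B: float
    r_max: float
    R_i: float
    a_m: float
    jO2_spec: float
    s_s: float
    s_Hbp: float
    stalled: bool = False       #: puberty unreachable (a_p, L_p, Ww_p, R_i missing)
    demand_bound: bool = False  #: reproduction clipped at zero


# ----------------------------------------------------------------------
# temperature correction
# ----------------------------------------------------------------------

def arrhenius_correction(T: float, T_A: float, T_ref: float = T_REF) -> float:
    """Arrhenius factor TC = exp(T_A/T_ref - T_A/T).

    Rates are multiplied by TC; times divided by TC.  TC(T_ref) = 1.
    """
    if T <= 0 or T_ref <= 0:
        raise InvalidParameterError("temperatures must be positive (K)")
    return math.exp(T_A / T_ref - T_A / T)


def at_temperature(p: DEBParameters, T: float, T_ref: float = T_REF) -> DEBParameters:
    """Return a parameter set with all rates corrected to body temperature T.

    ``p_Am``, ``v``, ``p_M`` and ``k_J`` scale with TC; the aging
    acceleration ``h_a`` (1/d^2) scales with TC squared.
    """
    TC = arrhenius_correction(T, p.T_A, T_ref)
    return replace(
        p,
        p_Am=p.p_Am * TC,
        v=p.v * TC,
        p_M=p.p_M * TC,
        k_J=p.k_J * TC,
        h_a=p.h_a * TC**2,
    )


# ----------------------------------------------------------------------
# compound parameters and fluxes
# ----------------------------------------------------------------------

def compound_parameters(
    p: DEBParameters, c: ChemicalConstants = DEFAULT_CHEM
) -> CompoundParameters:
    """Compute the compound parameters from a primary parameter set."""
    E_m = p.p_Am / p.v
    g = p.E_G / (p.kappa * E_m)
    k_M = p.p_M / p.E_G
    L_m = p.kappa * p.p_Am / p.p_M
    omega = E_m * c.w_E / (c.d_Vw * c.mu_E)
    kappa_G = c.mu_V * (c.d_Vd / c.w_V) / p.E_G
    if not 0 < kappa_G < 1:
        raise InvalidParameterError(
            f"{p.species_id}: kappa_G = {kappa_G:.4g} outside (0, 1); "
            "check E_G against the chemical constants"
        )
    return CompoundParameters(E_m=E_m, g=g, k_M=k_M, L_m=L_m, omega=omega,
                              kappa_G=kappa_G)


def power_fluxes(
    p: DEBParameters,
    L: float,
    E: float,
    E_H: float,
    f: float | None = None,
    feeding: bool = True,
    c: ChemicalConstants = DEFAULT_CHEM,
) -> PowerFluxes:
    """Instantaneous energy fluxes at state (L, E, E_H).

    ``feeding=False`` switches assimilation off (embryo stage).  The
    kappa-rule guarantees kappa*p_C = p_S + p_G and (1-kappa)*p_C =
    p_J + p_R identically; these identities are exact here by construction
    and are exercised in the test suite.
    """
    f = p.f if f is None else f
    cp = compound_parameters(p, c)
    e = E / (L**3 * cp.E_m)
    p_A = f * p.p_Am * L**2 if feeding else 0.0
    p_C = E * (p.v / L) * (cp.g + L / cp.L_m) / (e + cp.g)
    p_S = p.p_M * L**3
    p_J = p.k_J * E_H
    p_G = p.kappa * p_C - p_S
    p_R = (1.0 - p.kappa) * p_C - p_J
    return PowerFluxes(p_A=p_A, p_C=p_C, p_S=p_S, p_J=p_J, p_G=p_G, p_R=p_R)


# ----------------------------------------------------------------------
# embryo: initial reserve shooting
# ----------------------------------------------------------------------

def _embryo_rhs(t, y, p, cp):
    E, L, E_H = y
    e = E / (L**3 * cp.E_m)
    p_C = E * (p.v / L) * (cp.g + L / cp.L_m) / (e + cp.g)
    dE = -p_C
    dL = (p.v / 3.0) * (e - L / cp.L_m) / (e + cp.g)
    dE_H = (1.0 - p.kappa) * p_C - p.k_J * E_H
    return (dE, dL, dE_H)


def integrate_embryo(
    p: DEBParameters,
    E_0: float,
    c: ChemicalConstants = DEFAULT_CHEM,
    t_max: float | None = None,
):
    """Integrate the embryo stage from an initial reserve candidate.

    The embryo does not feed: reserve only drains (dE/da = -p_C) while
    structure grows and maturity accumulates.  Integration stops when
    maturity first reaches ``E_Hb`` (birth) or when maturation stalls
    ((1-kappa) p_C <= k_J E_H), whichever comes first.

    Returns
    -------
    (status, a_end, L_end, e_end, E_H_end)
        status is "birth", "stall" or "timeout".
    """
    cp = compound_parameters(p, c)
    L0 = 1e-5 * cp.L_m
    if t_max is None:
        # generous horizon: embryo growth is bounded by dL/da <= v/3
        t_max = 500.0 * cp.L_m / p.v

    def birth(t, y, *args):
        return y[2] - p.E_Hb
    birth.terminal = True
    birth.direction = 1

    def stall(t, y, *args):
        E, L, E_H = y
        e = E / (L**3 * cp.E_m)
        p_C = E * (p.v / L) * (cp.g + L / cp.L_m) / (e + cp.g)
        return (1.0 - p.kappa) * p_C - p.k_J * E_H
    stall.terminal = True
    stall.direction = -1

    sol = solve_ivp(
        _embryo_rhs,
        (0.0, t_max),
        (E_0, L0, 0.0),
        args=(p, cp),
        method="LSODA",
        events=(birth, stall),
        rtol=_ODE_RTOL,
        atol=(E_0 * 1e-14, cp.L_m * 1e-14, p.E_Hb * 1e-14),
    )
    if sol.t_events[0].size:
        E, L, E_H = sol.y_events[0][0]
        return "birth", sol.t_events[0][0], L, E / (L**3 * cp.E_m), E_H
    if sol.t_events[1].size:
        E, L, E_H = sol.y_events[1][0]
        return "stall", sol.t_events[1][0], L, E / (L**3 * cp.E_m), E_H
    E, L, E_H = sol.y[:, -1]
    return "timeout", sol.t[-1], L, E / (L**3 * cp.E_m), E_H


def initial_reserve_and_birth(
    p: DEBParameters,
    c: ChemicalConstants = DEFAULT_CHEM,
    f: float | None = None,
) -> BirthResult:
    """Solve the embryo shooting problem for the initial reserve E_0.

    The maternal-effect closure fixes the egg's energy content so that the
    scaled reserve density at birth equals the mother's scaled functional
    response ``f``.  E_0 is located by bracketed bisection on the birth
    residual e(a_b) - f, which is monotone increasing in E_0; candidates
    too small stall before reaching E_Hb and count as negative residuals.

    Raises
    ------
    NonViableError
        If maturation stalls before E_Hb for every bracketed E_0.
    """
    f = p.f if f is None else f
    if not 0 < f <= 1:
        raise InvalidParameterError(f"f must lie in (0, 1], got {f!r}")
    cp = compound_parameters(p, c)

    stall_level = float("nan")

    def residual(E_0):
        nonlocal stall_level
        status, a, L, e, E_H = integrate_embryo(p, E_0, c)
        if status == "birth":
            return e - f
        stall_level = E_H
        return -2.0 - (p.E_Hb - E_H) / p.E_Hb

    # initial guess: energy in structure + reserve + maturity at birth,
    # using the k_J = 0, no-maintenance approximation for L_b
    L_b_guess = (p.kappa * p.E_Hb / ((1.0 - p.kappa) * p.E_G)) ** (1.0 / 3.0)
    E_guess = (
        p.E_G * L_b_guess**3 / p.kappa
        + f * cp.E_m * L_b_guess**3
        + p.E_Hb / (1.0 - p.kappa)
    )

    lo = hi = E_guess
    r = residual(E_guess)
    n_grow = 0
    if r < 0:
        while r < 0:
            n_grow += 1
            if n_grow > 80:
                raise NonViableError(
                    f"{p.species_id}: embryo cannot reach E_Hb = {p.E_Hb:g} J "
                    f"(maturation stalls at E_H = {stall_level:g} J)",
                    stall_maturity=stall_level,
                )
            lo = hi
            hi *= 2.0
            r = residual(hi)
    else:
        while r >= 0:
            n_grow += 1
            if n_grow > 200:
                raise NonViableError(
                    f"{p.species_id}: no lower bracket for E_0 found")
            hi = lo
            lo /= 2.0
            r = residual(lo)

    # bisection to relative tolerance on E_0
    while (hi - lo) > _SHOOT_RTOL * hi:
        mid = 0.5 * (lo + hi)
        if residual(mid) < 0:
            lo = mid
        else:
            hi = mid
    E_0 = 0.5 * (lo + hi)

    status, a_b, L_b, e_b, _ = integrate_embryo(p, E_0, c)
    if status != "birth":
        # land on the birth side of the bracket
        E_0 = hi
        status, a_b, L_b, e_b, _ = integrate_embryo(p, E_0, c)
    if status != "birth" or abs(e_b - f) > 1e-4 * f:
        # bisection converged onto a stall/birth discontinuity: no egg
        # satisfies the maternal closure e(a_b) = f
        raise NonViableError(
            f"{p.species_id}: no initial reserve yields reserve density {f:g} "
            f"at birth (maturation stalls below E_Hb = {p.E_Hb:g} J for "
            f"smaller eggs; e_b = {e_b:g} at the viability boundary)",
            stall_maturity=stall_level,
        )
    return BirthResult(E_0=E_0, a_b=a_b, L_b=L_b, e_b=e_b)


# ----------------------------------------------------------------------
# post-birth growth: von Bertalanffy closed form
# ----------------------------------------------------------------------

def ultimate_state(
    p: DEBParameters, c: ChemicalConstants = DEFAULT_CHEM, f: float | None = None
) -> tuple[float, float]:
    """Ultimate structural length L_i = f L_m and ultimate wet weight."""
    f = p.f if f is None else f
    cp = compound_parameters(p, c)
    L_i = f * cp.L_m
    return L_i, wet_weight(L_i, cp, c, f)


def wet_weight(
    L: float,
    cp: CompoundParameters,
    c: ChemicalConstants = DEFAULT_CHEM,
    e: float = 1.0,
) -> float:
    """Wet weight Ww = d_Vw L^3 (1 + e omega): structure plus reserve.

    The reproduction buffer is excluded by convention.
    """
    return c.d_Vw * L**3 * (1.0 + e * cp.omega)


def von_bertalanffy_rate(
    p: DEBParameters, c: ChemicalConstants = DEFAULT_CHEM, f: float | None = None
) -> float:
    """von Bertalanffy growth rate r_B = k_M / (3 (1 + f/g)) (1/d)."""
    f = p.f if f is None else f
    cp = compound_parameters(p, c)
    return cp.k_M / (3.0 * (1.0 + f / cp.g))


def length_at_age(
    a, a_b: float, L_b: float, L_i: float, r_B: float
):
    """Closed-form von Bertalanffy curve L(a) = L_i - (L_i - L_b) e^{-r_B (a-a_b)}."""
    return L_i - (L_i - L_b) * np.exp(-r_B * (np.asarray(a) - a_b))


def grow_to_puberty(
    p: DEBParameters,
    birth: tuple[float, float],
    f: float | None = None,
    c: ChemicalConstants = DEFAULT_CHEM,
) -> tuple[float, float]:
    """Age and length at puberty under constant food.

    Post-birth reserve density stays at ``f`` (weak homeostasis), so length
    follows the von Bertalanffy closed form and maturity obeys
    dE_H/da = (1-kappa) p_C(L(a)) - k_J E_H with
    p_C = f E_m v L^2 (g + L/L_m)/(f + g).

    Raises
    ------
    MaturationStalledError
        If maturity maintenance absorbs the whole (1-kappa) flux before
        E_Hp is reached (puberty unreachable).
    """
    f = p.f if f is None else f
    a_b, L_b = birth
    cp = compound_parameters(p, c)
    L_i = f * cp.L_m
    r_B = cp.k_M / (3.0 * (1.0 + f / cp.g))

    if p.E_Hp <= p.E_Hb:
        return a_b, L_b

    def mobilization(L):
        return f * cp.E_m * p.v * L**2 * (cp.g + L / cp.L_m) / (f + cp.g)

    def rhs(t, y):
        L = L_i - (L_i - L_b) * math.exp(-r_B * (t - a_b))
        return ((1.0 - p.kappa) * mobilization(L) - p.k_J * y[0],)

    def puberty(t, y):
        return y[0] - p.E_Hp
    puberty.terminal = True
    puberty.direction = 1

    def stall(t, y):
        L = L_i - (L_i - L_b) * math.exp(-r_B * (t - a_b))
        return (1.0 - p.kappa) * mobilization(L) - p.k_J * y[0]
    stall.terminal = True
    stall.direction = -1

    # E_H approaches its ceiling at rate ~ k_J and L its asymptote at r_B
    horizon = a_b + 60.0 * max(1.0 / r_B, 1.0 / p.k_J if p.k_J > 0 else 0.0)
    sol = solve_ivp(
        rhs,
        (a_b, horizon),
        (p.E_Hb,),
        method="LSODA",
        events=(puberty, stall),
        rtol=_ODE_RTOL,
        atol=(p.E_Hp * 1e-14,),
    )
    if sol.t_events[0].size:
        a_p = float(sol.t_events[0][0])
        L_p = L_i - (L_i - L_b) * math.exp(-r_B * (a_p - a_b))
        return a_p, L_p
    level = float(sol.y_events[1][0][0]) if sol.t_events[1].size else float(sol.y[0, -1])
    raise MaturationStalledError(
        f"{p.species_id}: maturation stalls at E_H = {level:g} J < "
        f"E_Hp = {p.E_Hp:g} J; puberty unreachable",
        stall_maturity=level,
    )


def max_specific_growth(
    p: DEBParameters,
    birth: tuple[float, float] | None = None,
    f: float | None = None,
    c: ChemicalConstants = DEFAULT_CHEM,
) -> float:
    """Maximum specific structural growth rate r_max (1/d).

    Located numerically on the von Bertalanffy trajectory as the specific
    volume growth rate 3 (dL/da)/L at the age where the absolute growth
    rate dL^3/da is maximal.  Analytically this age has L = (2/3) L_i and
    r_max = 1.5 r_B; the numerical route keeps the identity testable.
    """
    f = p.f if f is None else f
    cp = compound_parameters(p, c)
    L_i = f * cp.L_m
    r_B = cp.k_M / (3.0 * (1.0 + f / cp.g))
    if birth is None:
        L_b = 1e-3 * L_i
        a_b = 0.0
    else:
        a_b, L_b = birth

    def neg_dV(a):
        L = L_i - (L_i - L_b) * math.exp(-r_B * (a - a_b))
        dL = r_B * (L_i - L)
        return -3.0 * L**2 * dL

    span = 20.0 / r_B
    res = minimize_scalar(neg_dV, bounds=(a_b, a_b + span), method="bounded",
                          options={"xatol": 1e-10 / r_B})
    a_star = res.x
    L = L_i - (L_i - L_b) * math.exp(-r_B * (a_star - a_b))
    dL = r_B * (L_i - L)
    return 3.0 * dL / L


# ----------------------------------------------------------------------
# reproduction, respiration
# ----------------------------------------------------------------------

def reproduction_rate(
    p: DEBParameters,
    E_0: float,
    c: ChemicalConstants = DEFAULT_CHEM,
    f: float | None = None,
) -> tuple[float, bool]:
    """Reproduction rate at ultimate size, R_i (offspring per day).

    R_i = kappa_R ((1-kappa) f E_m v L_i^2 - k_J E_Hp) / E_0, the flux to
    reproduction at ultimate size converted continuously into eggs of
    energy E_0.  A negative numerator means the species is demand-bound at
    ultimate size: R_i = 0 is returned with the flag set.

    Returns
    -------
    (R_i, demand_bound)
    """
    f = p.f if f is None else f
    cp = compound_parameters(p, c)
    L_i = f * cp.L_m
    p_C_i = f * cp.E_m * p.v * L_i**2
    numerator = (1.0 - p.kappa) * p_C_i - p.k_J * p.E_Hp
    if numerator < 0:
        return 0.0, True
    return p.kappa_R * numerator / E_0, False


def specific_respiration(
    p: DEBParameters,
    c: ChemicalConstants = DEFAULT_CHEM,
    f: float | None = None,
    L: float | None = None,
    E_H: float | None = None,
) -> float:
    """Weight-specific O2 consumption (mol O2 / d / g).

    Respiration is the dissipated power converted with a single oxycaloric
    coefficient: p_resp = p_A - kappa_R p_R - kappa_G p_G, i.e. everything
    assimilated that is not fixed in eggs or new structure.  Evaluated at
    ultimate size by default (p_G = 0 there, so p_resp = p_S + p_J +
    (1-kappa_R) p_R).
    """
    f = p.f if f is None else f
    cp = compound_parameters(p, c)
    if L is None:
        L = f * cp.L_m
    if E_H is None:
        E_H = p.E_Hp
    E = f * cp.E_m * L**3
    fluxes = power_fluxes(p, L, E, E_H, f=f, c=c)
    p_resp = fluxes.p_A - p.kappa_R * fluxes.p_R - cp.kappa_G * fluxes.p_G
    jO2 = p_resp / c.mu_O2
    return jO2 / wet_weight(L, cp, c, f)


# ----------------------------------------------------------------------
# aging and life span
# ----------------------------------------------------------------------

def aging_survival(
    p: DEBParameters,
    L0: float,
    f: float | None = None,
    c: ChemicalConstants = DEFAULT_CHEM,
    t_eval: Sequence[float] | None = None,
):
    """Integrate the Weibull-Gompertz aging model from length L0.

    States: aging acceleration q (1/d^2), hazard h (1/d), survival S, and
    the running integral of S.  Length follows the von Bertalanffy closed
    form from L0; reserve density is f throughout.

    dq/dt = (q (L/L_m)^3 s_G + h_a) f (v/L - r) - r q
    dh/dt = q - r h
    dS/dt = -h S            with r = 3 (dL/dt)/L.

    Integration is truncated when S < 1e-7; the neglected tail of the
    survival integral is bounded by S/h at truncation and added.

    Returns
    -------
    (mean_time, t, S) : mean time to death since t=0 (d) and, if
        ``t_eval`` is given, survival sampled there (else event samples).
    """
    f = p.f if f is None else f
    cp = compound_parameters(p, c)
    L_i = f * cp.L_m
    r_B = cp.k_M / (3.0 * (1.0 + f / cp.g))

    def rhs(t, y):
        q, h, S, A = y
        L = L_i - (L_i - L0) * math.exp(-r_B * t)
        r = 3.0 * r_B * (L_i - L) / L
        dq = (q * (L / cp.L_m) ** 3 * p.s_G + p.h_a) * f * (p.v / L - r) - r * q
        dh = q - r * h
        dS = -h * S
        return (dq, dh, dS, S)

    def dead(t, y):
        return y[2] - _SURVIVAL_CUTOFF
    dead.terminal = True
    dead.direction = -1

    # Weibull time scale of the fully-grown limit sets the horizon
    theta = (6.0 * L_i / (p.h_a * f * p.v)) ** (1.0 / 3.0)
    horizon = 30.0 * theta + 10.0 / r_B
    sol = solve_ivp(
        rhs,
        (0.0, horizon),
        (0.0, 0.0, 1.0, 0.0),
        method="LSODA",
        events=(dead,),
        rtol=1e-9,
        atol=(1e-16, 1e-16, 1e-12, 1e-9 * theta),
        t_eval=t_eval,
        dense_output=t_eval is None,
    )
    if sol.t_events[0].size:
        q, h, S, A = sol.y_events[0][0]
    else:
        q, h, S, A = sol.y[:, -1]
    tail = S / h if h > 0 else 0.0
    return float(A + tail), sol.t, sol.y[2]


def mean_life_span(
    p: DEBParameters,
    birth: tuple[float, float],
    f: float | None = None,
    c: ChemicalConstants = DEFAULT_CHEM,
) -> float:
    """Mean age at death a_m = a_b + E[time from birth to death] (d)."""
    a_b, L_b = birth
    mean_post, _, _ = aging_survival(p, L_b, f=f, c=c)
    return a_b + mean_post


# ----------------------------------------------------------------------
# dimensionless life-history indices
# ----------------------------------------------------------------------

def supply_stress(p: DEBParameters, f: float | None = None) -> float:
    """Supply stress s_s = p_J p_S^2 / p_A^3 at ultimate size.

    Maturity maintenance times squared somatic maintenance over cubed
    assimilation; ranges over [0, 4/27] for any parameter set with
    nonnegative reproduction.  The L_i factors cancel:
    s_s = k_J E_Hp [p_M]^2 / (f {p_Am})^3.
    """
    f = p.f if f is None else f
    return p.k_J * p.E_Hp * p.p_M**2 / (f * p.p_Am) ** 3


def precociality(p: DEBParameters) -> float:
    """Precociality coefficient s_Hbp = E_Hb / E_Hp in (0, 1]."""
    if p.E_Hb > p.E_Hp:
        raise InvalidParameterError(
            f"{p.species_id}: E_Hb = {p.E_Hb!r} exceeds E_Hp = {p.E_Hp!r}"
        )
    return p.E_Hb / p.E_Hp


# ----------------------------------------------------------------------
# full post-birth simulation (used for invariant checks and diagnostics)
# ----------------------------------------------------------------------

def simulate_post_birth(
    p: DEBParameters,
    birth: BirthResult,
    t_eval: Sequence[float],
    f: float | None = None,
    c: ChemicalConstants = DEFAULT_CHEM,
):
    """Integrate the full feeding individual (L, E, E_H) from birth.

    Unlike the closed-form route used by the trait pipeline, this solves
    the raw balance equations dE/da = p_A - p_C, dL/da from the growth
    flux, dE_H/da = p_R before puberty (maturity frozen at E_Hp after).
    It exists so weak homeostasis, the kappa-rule conservation identities
    and the von Bertalanffy closed form can be verified against the
    integrated dynamics rather than assumed.

    Returns arrays (t, L, E, E_H).
    """
    f = p.f if f is None else f
    cp = compound_parameters(p, c)

    def rhs(t, y):
        L, E, E_H = y
        e = E / (L**3 * cp.E_m)
        p_A = f * p.p_Am * L**2
        p_C = E * (p.v / L) * (cp.g + L / cp.L_m) / (e + cp.g)
        dL = (p.v / 3.0) * (e - L / cp.L_m) / (e + cp.g)
        dE = p_A - p_C
        dE_H = (1.0 - p.kappa) * p_C - p.k_J * E_H if E_H < p.E_Hp else 0.0
        return (dL, dE, dE_H)

    E_b = f * cp.E_m * birth.L_b**3
    t0 = birth.a_b
    sol = solve_ivp(
        rhs,
        (t0, t_eval[-1]),
        (birth.L_b, E_b, p.E_Hb),
        method="LSODA",
        rtol=_ODE_RTOL,
        atol=(cp.L_m * 1e-14, E_b * 1e-12, p.E_Hp * 1e-14),
        t_eval=t_eval,
    )
    return sol.t, sol.y[0], sol.y[1], sol.y[2]


# ----------------------------------------------------------------------
# one-call life history
# ----------------------------------------------------------------------

def life_history(
    p: DEBParameters,
    c: ChemicalConstants = DEFAULT_CHEM,
    f: float | None = None,
) -> LifeHistory:
    """Full derived life history of one species at constant food.

    Runs the embryo shooting problem, the puberty integration, the aging
    integral and the closed-form traits, and assembles everything into one
    record.  A species whose maturation stalls before puberty is returned
    with ``stalled=True`` and NaN for the puberty-dependent traits, rather
    than raising.
    """
    f = p.f if f is None else f
    cp = compound_parameters(p, c)
    birth = initial_reserve_and_birth(p, c, f)
    L_i, Ww_i = ultimate_state(p, c, f)
    r_B = von_bertalanffy_rate(p, c, f)
    r_max = max_specific_growth(p, (birth.a_b, birth.L_b), f, c)
    a_m = mean_life_span(p, (birth.a_b, birth.L_b), f, c)
    Ww_b = wet_weight(birth.L_b, cp, c, f)
    s_s = supply_stress(p, f)
    s_Hbp = precociality(p)
    jO2 = specific_respiration(p, c, f)

    stalled = False
    demand_bound = False
    try:
        a_p, L_p = grow_to_puberty(p, (birth.a_b, birth.L_b), f, c)
        Ww_p = wet_weight(L_p, cp, c, f)
        R_i, demand_bound = reproduction_rate(p, birth.E_0, c, f)
    except MaturationStalledError:
        stalled = True
        a_p = L_p = Ww_p = R_i = float("nan")

    return LifeHistory(
        E_0=birth.E_0, a_b=birth.a_b, L_b=birth.L_b, Ww_b=Ww_b,
        a_p=a_p, L_p=L_p, Ww_p=Ww_p,
        L_i=L_i, Ww_i=Ww_i,
        r_B=r_B, r_max=r_max, R_i=R_i, a_m=a_m,
        jO2_spec=jO2, s_s=s_s, s_Hbp=s_Hbp,
        stalled=stalled, demand_bound=demand_bound,
    )
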