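"""Single-individual model: compound parameters, embryo shooting, growth,
aging, reproduction, respiration and the dimensionless indices."""

import math
from dataclasses import replace

import numpy as np
import pytest
from scipy.optimize import curve_fit

import debtraits as dt
from debtraits.deb_core import DEFAULT_CHEM, power_fluxes, simulate_post_birth, aging_survival, integrate_embryo

from _oracles import shoot_E0_rk4, weibull_mean_life


def make_params(**kw):
    return dt.DEBParameters(species_id=kw.pop("species_id", "test"), **kw)


# ----------------------------------------------------------------------
# compound parameters and temperature correction
# ----------------------------------------------------------------------

class TestCompoundParameters:
    def test_defining_ratios(self):
        p = make_params(p_Am=500.0, v=0.05, kappa=0.8, p_M=20.0, E_G=7800.0)
        cp = dt.compound_parameters(p)
        assert cp.E_m == pytest.approx(10000.0)
        assert cp.L_m == pytest.approx(20.0)
        assert cp.g == pytest.approx(0.975)
        assert cp.k_M == pytest.approx(20.0 / 7800.0)

    def test_two_Lm_expressions_agree(self, fixture_params):
        for p in fixture_params:
            cp = dt.compound_parameters(p)
            assert cp.L_m == pytest.approx(p.v / (cp.k_M * cp.g), rel=1e-12)
            assert 0 < cp.kappa_G < 1

    def test_invalid_parameter_names_field(self):
        with pytest.raises(dt.InvalidParameterError, match="p_Am"):
            make_params(p_Am=-1.0)
        with pytest.raises(dt.InvalidParameterError, match="kappa"):
            make_params(kappa=1.5)
        with pytest.raises(dt.InvalidParameterError, match="E_Hb"):
            make_params(E_Hb=2e6, E_Hp=1e6)


class TestArrhenius:
    def test_identity_at_reference(self):
        assert dt.arrhenius_correction(dt.T_REF, 8000.0) == pytest.approx(1.0)

    def test_zero_arrhenius_temperature(self):
        assert dt.arrhenius_correction(310.0, 0.0) == pytest.approx(1.0)

    def test_against_direct_evaluation(self):
        expected = math.exp(8000.0 * (1 / 293.15 - 1 / 303.15))
        assert dt.arrhenius_correction(303.15, 8000.0) == pytest.approx(expected)
        assert expected == pytest.approx(2.46, rel=1e-3)

    def test_at_temperature_scales_rates(self):
        p = make_params()
        warm = dt.at_temperature(p, 303.15)
        TC = dt.arrhenius_correction(303.15, p.T_A)
        assert warm.v == pytest.approx(p.v * TC)
        assert warm.h_a == pytest.approx(p.h_a * TC**2)
        same = dt.at_temperature(p, dt.T_REF)
        assert same.p_Am == pytest.approx(p.p_Am)


# ----------------------------------------------------------------------
# embryo shooting
# ----------------------------------------------------------------------

class TestInitialReserve:
    @pytest.mark.parametrize("f", [1.0, 0.7])
    def test_shooting_residual(self, f):
        p = make_params()
        birth = dt.initial_reserve_and_birth(p, f=f)
        assert abs(birth.e_b - f) <= 1e-5 * f
        assert birth.E_0 > 0 and birth.a_b > 0 and birth.L_b > 0

    def test_matches_fixed_step_oracle(self, fixture_params):
        """Adaptive solver vs independent fine-grid RK4 + bisection."""
        p = fixture_params[0]
        birth = dt.initial_reserve_and_birth(p)
        E_0, a_b, L_b = shoot_E0_rk4(p, DEFAULT_CHEM)
        assert birth.E_0 == pytest.approx(E_0, rel=1e-3)
        assert birth.a_b == pytest.approx(a_b, rel=1e-3)
        assert birth.L_b == pytest.approx(L_b, rel=1e-3)

    def test_E0_and_ab_increase_with_EHb(self):
        prev_E0, prev_ab = 0.0, 0.0
        for E_Hb in (1e3, 4e3, 1.6e4):
            p = make_params(E_Hb=E_Hb)
            b = dt.initial_reserve_and_birth(p)
            assert b.E_0 > prev_E0 and b.a_b > prev_ab
            prev_E0, prev_ab = b.E_0, b.a_b

    def test_birth_length_doubles_with_8x_maturity(self):
        """With k_J=0 maturity tracks cumulated structure, so an 8-fold
        E_Hb gives about twice the birth length."""
        p1 = make_params(k_J=1e-12)  # k_J=0 admissible limit
        p8 = replace(p1, E_Hb=8 * p1.E_Hb)
        L1 = dt.initial_reserve_and_birth(p1).L_b
        L8 = dt.initial_reserve_and_birth(p8).L_b
        assert L8 / L1 == pytest.approx(2.0, rel=0.05)

    def test_non_viable_carries_stall_maturity(self):
        p = make_params(k_J=1.0)  # maturity maintenance overwhelms allocation
        with pytest.raises(dt.NonViableError) as err:
            dt.initial_reserve_and_birth(p)
        # stall happens at or below the birth threshold (up to event tol)
        assert err.value.stall_maturity <= p.E_Hb * 1.01


# ----------------------------------------------------------------------
# post-birth growth
# ----------------------------------------------------------------------

class TestGrowth:
    def test_ultimate_state(self):
        p = make_params()
        cp = dt.compound_parameters(p)
        L_i, Ww_i = dt.ultimate_state(p)
        assert L_i == pytest.approx(cp.L_m)
        L_h, _ = dt.ultimate_state(p, f=0.5)
        assert L_h == pytest.approx(0.5 * cp.L_m)
        assert Ww_i == pytest.approx(L_i**3 * (1 + cp.omega))

    def test_vb_rate_closed_form(self):
        # k_M = 0.01/d and g = 1: r_B = k_M/6 at f=1
        p = make_params(E_G=7800.0, p_M=78.0, kappa=0.8, v=0.05,
                        p_Am=0.05 * 7800.0 / 0.8)
        cp = dt.compound_parameters(p)
        assert cp.g == pytest.approx(1.0)
        assert dt.von_bertalanffy_rate(p) == pytest.approx(0.01 / 6.0)
        # f -> 0 limit approaches k_M/3
        assert dt.von_bertalanffy_rate(p, f=1e-9) == pytest.approx(0.01 / 3.0, rel=1e-6)

    def test_trajectory_matches_von_bertalanffy_closed_form(self):
        p = make_params()
        birth = dt.initial_reserve_and_birth(p)
        cp = dt.compound_parameters(p)
        r_B = dt.von_bertalanffy_rate(p)
        t = np.linspace(birth.a_b, birth.a_b + 5 / r_B, 80)
        _, L, E, E_H = simulate_post_birth(p, birth, t)
        L_closed = dt.deb_core.length_at_age(t, birth.a_b, birth.L_b, cp.L_m, r_B)
        assert np.max(np.abs(L - L_closed) / L_closed) < 1e-6

    def test_weak_homeostasis(self):
        """Reserve density stays at f during growth at constant food."""
        p = make_params()
        birth = dt.initial_reserve_and_birth(p)
        cp = dt.compound_parameters(p)
        t = np.linspace(birth.a_b, birth.a_b + 3000, 50)
        _, L, E, _ = simulate_post_birth(p, birth, t)
        e = E / (L**3 * cp.E_m)
        assert np.max(np.abs(e - 1.0)) < 1e-8

    def test_energy_conservation_along_trajectory(self):
        """kappa-rule identities hold at every sampled state."""
        p = make_params()
        birth = dt.initial_reserve_and_birth(p)
        t = np.linspace(birth.a_b, birth.a_b + 4000, 40)
        _, L, E, E_H = simulate_post_birth(p, birth, t)
        for Li, Ei, Hi in zip(L, E, E_H):
            fl = power_fluxes(p, Li, Ei, Hi)
            assert p.kappa * fl.p_C == pytest.approx(fl.p_S + fl.p_G, rel=1e-10)
            assert (1 - p.kappa) * fl.p_C == pytest.approx(fl.p_J + fl.p_R, rel=1e-10)

    def test_vb_fit_recovers_rate(self):
        """Exponential fit of the simulated curve recovers r_B to 1e-4."""
        p = make_params()
        birth = dt.initial_reserve_and_birth(p)
        cp = dt.compound_parameters(p)
        r_B = dt.von_bertalanffy_rate(p)
        t = np.linspace(birth.a_b, birth.a_b + 6 / r_B, 200)
        _, L, _, _ = simulate_post_birth(p, birth, t)

        def vb(a, L_i, r):
            return L_i - (L_i - birth.L_b) * np.exp(-r * (a - birth.a_b))

        (L_i_fit, r_fit), _ = curve_fit(vb, t, L, p0=(cp.L_m * 1.05, r_B * 1.2))
        assert r_fit == pytest.approx(r_B, rel=1e-4)


class TestPuberty:
    def test_degenerate_threshold(self):
        p = make_params(E_Hb=3.5e3, E_Hp=3.5e3 * (1 + 1e-9))
        b = dt.initial_reserve_and_birth(p)
        a_p, L_p = dt.grow_to_puberty(p, (b.a_b, b.L_b))
        assert a_p == pytest.approx(b.a_b, rel=1e-4)
        assert L_p == pytest.approx(b.L_b, rel=1e-4)

    def test_ordering(self, fixture_params):
        for p in fixture_params:
            b = dt.initial_reserve_and_birth(p)
            a_p, L_p = dt.grow_to_puberty(p, (b.a_b, b.L_b))
            L_i, _ = dt.ultimate_state(p)
            assert b.a_b < a_p and b.L_b < L_p < L_i

    def test_stalled_when_demand_exceeds_supply(self):
        # k_J E_Hp above the asymptotic (1-kappa) mobilization at L_i
        p = make_params(E_Hp=3e6)
        cp = dt.compound_parameters(p)
        assert p.k_J * p.E_Hp > (1 - p.kappa) * cp.E_m * p.v * cp.L_m**2
        b = dt.initial_reserve_and_birth(p)
        with pytest.raises(dt.MaturationStalledError):
            dt.grow_to_puberty(p, (b.a_b, b.L_b))
        lh = dt.life_history(p)
        assert lh.stalled and math.isnan(lh.a_p)


class TestMaxSpecificGrowth:
    @pytest.mark.parametrize("f", [1.0, 0.5])
    def test_ratio_is_three_halves(self, fixture_params, f):
        for p in fixture_params:
            r_max = dt.max_specific_growth(p, f=f)
            r_B = dt.von_bertalanffy_rate(p, f=f)
            assert r_max / r_B == pytest.approx(1.5, rel=1e-6)

    def test_argmax_at_two_thirds_ultimate_length(self):
        """dL^3/da peaks where L = (2/3) L_i (maximize L^2 (L_i - L))."""
        p = make_params()
        b = dt.initial_reserve_and_birth(p)
        cp = dt.compound_parameters(p)
        r_B = dt.von_bertalanffy_rate(p)
        r_max = dt.max_specific_growth(p, (b.a_b, b.L_b))
        # r_max = 3 r_B (L_i - L*)/L*  =>  L* = 3 r_B L_i / (r_max + 3 r_B)
        L_star = 3 * r_B * cp.L_m / (r_max + 3 * r_B)
        assert L_star == pytest.approx(2.0 / 3.0 * cp.L_m, rel=1e-8)


# ----------------------------------------------------------------------
# reproduction and respiration
# ----------------------------------------------------------------------

class TestReproduction:
    def test_closed_form_and_linearity_in_kappa_R(self):
        p = make_params()
        cp = dt.compound_parameters(p)
        E_0 = 2.5e4
        R, flag = dt.reproduction_rate(p, E_0)
        expected = p.kappa_R * ((1 - p.kappa) * cp.E_m * p.v * cp.L_m**2
                                - p.k_J * p.E_Hp) / E_0
        assert R == pytest.approx(expected) and not flag
        p2 = replace(p, kappa_R=p.kappa_R / 2)
        R2, _ = dt.reproduction_rate(p2, E_0)
        assert R2 == pytest.approx(R / 2)

    def test_supply_demand_boundary(self):
        p = make_params()
        cp = dt.compound_parameters(p)
        k_J_star = (1 - p.kappa) * cp.E_m * p.v * cp.L_m**2 / p.E_Hp
        at_boundary = replace(p, k_J=k_J_star)
        R, flag = dt.reproduction_rate(at_boundary, 1e4)
        assert R == pytest.approx(0.0, abs=1e-12)
        beyond = replace(p, k_J=k_J_star * 1.01)
        R, flag = dt.reproduction_rate(beyond, 1e4)
        assert R == 0.0 and flag


class TestRespiration:
    def test_no_overhead_when_kappa_R_is_one(self):
        """kappa_R = 1: respiration at ultimate size is maintenance only."""
        p = make_params(kappa_R=1.0)
        cp = dt.compound_parameters(p)
        c = DEFAULT_CHEM
        jO2 = dt.specific_respiration(p)
        L_i, Ww_i = dt.ultimate_state(p)
        p_resp = jO2 * Ww_i * c.mu_O2
        assert p_resp == pytest.approx(p.p_M * L_i**3 + p.k_J * p.E_Hp, rel=1e-12)

    def test_zoom_invariance_when_reserve_negligible(self):
        """Doubling the zoom factor (p_Am, v with it; maturities by their
        exponents at beta_p = 3) leaves specific respiration unchanged."""
        p = make_params()
        z = 2.0
        p2 = replace(p, p_Am=p.p_Am * z, v=p.v * z, E_Hb=p.E_Hb * z**1.7454,
                     E_Hp=p.E_Hp * z**3)
        j1 = dt.specific_respiration(p)
        j2 = dt.specific_respiration(p2)
        assert j2 == pytest.approx(j1, rel=0.01)


# ----------------------------------------------------------------------
# aging
# ----------------------------------------------------------------------

class TestAging:
    def test_weibull_closed_form_fully_grown(self):
        """Starting fully grown with s_G=0 the survival is a Weibull of
        shape 3; the ODE mean matches Gamma(4/3) theta within 0.5%."""
        p = make_params(s_G=0.0)
        cp = dt.compound_parameters(p)
        mean, t, S = aging_survival(p, L0=cp.L_m)
        expected = weibull_mean_life(cp.L_m, p.h_a, p.v)
        assert mean == pytest.approx(expected, rel=5e-3)

    def test_cube_root_scaling_in_h_a(self):
        p = make_params(s_G=0.0)
        cp = dt.compound_parameters(p)
        m1, _, _ = aging_survival(p, L0=cp.L_m)
        m2, _, _ = aging_survival(replace(p, h_a=p.h_a * 1000), L0=cp.L_m)
        assert m2 / m1 == pytest.approx(0.1, rel=5e-3)

    def test_survival_monotone_from_one(self):
        p = make_params()
        b = dt.initial_reserve_and_birth(p)
        _, t, S = aging_survival(p, L0=b.L_b, t_eval=np.linspace(0, 2e4, 200))
        assert S[0] == pytest.approx(1.0, abs=1e-9)
        assert np.all(np.diff(S) <= 1e-12)
        assert np.all((S >= -1e-12) & (S <= 1 + 1e-12))

    def test_life_span_exceeds_puberty_age(self, fixture_table):
        ok = ~(fixture_table.stalled | fixture_table.non_viable)
        sub = fixture_table[ok]
        assert (sub.a_b < sub.a_p).all() and (sub.a_p < sub.a_m).all()


# ----------------------------------------------------------------------
# dimensionless indices
# ----------------------------------------------------------------------

class TestSupplyStress:
    def test_zero_without_maturity_maintenance(self):
        p = make_params(k_J=0.0)
        assert dt.supply_stress(p) == 0.0

    def test_demand_extreme_value(self):
        """At the demand extreme p_J = (1-kappa) p_A the supply stress is
        kappa^2 (1-kappa): 4/27 at kappa = 2/3."""
        p = _demand_extreme_params(kappa=2.0 / 3.0)
        assert dt.supply_stress(p) == pytest.approx(4.0 / 27.0, rel=1e-9)

    def test_grid_search_maximum(self):
        kappas = np.linspace(0.05, 0.95, 1801)
        vals = [dt.supply_stress(_demand_extreme_params(kappa=k)) for k in kappas]
        i = int(np.argmax(vals))
        assert vals[i] == pytest.approx(0.148148, abs=1e-5)
        assert kappas[i] == pytest.approx(2.0 / 3.0, abs=1e-3)

    def test_bounded_when_reproduction_nonnegative(self, default_family_table):
        ok = ~(default_family_table.stalled | default_family_table.non_viable)
        s = default_family_table.loc[ok & (default_family_table.R_i >= 0), "s_s"]
        assert ((s >= 0) & (s <= 4.0 / 27.0 + 1e-12)).all()


def _demand_extreme_params(kappa):
    """Parameter set with maturity maintenance at its reproduction-zero
    ceiling, p_J = (1-kappa) p_A at ultimate size."""
    p = dt.DEBParameters(species_id="extreme", kappa=kappa)
    cp = dt.compound_parameters(p)
    k_J_star = (1 - kappa) * p.p_Am * cp.L_m**2 / p.E_Hp
    return replace(p, k_J=k_J_star)


class TestPrecociality:
    def test_ratio_and_bounds(self, fixture_params):
        for p in fixture_params:
            s = dt.precociality(p)
            assert 0 < s < 1
            assert s == pytest.approx(p.E_Hb / p.E_Hp)

    def test_order_of_magnitude_of_weight_ratio(self, fixture_table):
        """s_Hbp roughly tracks Ww_b/Ww_p at abundant food (diagnostic)."""
        ratio = fixture_table.Ww_b / fixture_table.Ww_p
        fold = ratio / fixture_table.s_Hbp
        assert ((fold > 0.1) & (fold < 10)).all()
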