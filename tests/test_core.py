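"""Unit and property tests for the state dynamics and observable mappings."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from quaildeb import (OrganismState, arrhenius_correct, compute_fluxes,
                      integrate, physical_length, specific_growth_rate,
                      wet_weight)
from quaildeb.core import Fluxes

from conftest import euler_integrate


class TestSpecificGrowthRate:
    def test_breakeven_reserve_gives_zero(self, h1):
        # reserve exactly at maintenance break-even: numerator vanishes
        L = 1.7
        E = h1.p_M * L ** 4 / (h1.kap * h1.v)
        assert specific_growth_rate(E, L, h1) == pytest.approx(0.0, abs=1e-12)

    def test_equilibrium_at_ultimate_length(self, h1):
        # f=1 equilibrium reserve density at L = kap*p_Am/p_M: r = 0 and the
        # physical length matches the ~26 cm ultimate total length
        L = h1.L_inf(1.0)
        E = h1.E_m * L ** 3
        r = specific_growth_rate(E, L, h1)
        assert abs(r) < 1e-10
        assert physical_length(L, h1.del_M) == pytest.approx(26.0, rel=0.02)

    def test_starving_branch_matches_hand_formula(self, h2):
        # below break-even the denominator uses kap_G * E_G and r < 0
        L, frac = 2.0, 0.5
        E = frac * h2.p_M * L ** 4 / (h2.kap * h2.v)
        r = specific_growth_rate(E, L, h2)
        num = E * h2.v / L - h2.p_M * L ** 3 / h2.kap
        den = E + h2.kap_G * h2.E_G * L ** 3 / h2.kap
        assert r < 0
        assert r == pytest.approx(num / den, rel=1e-12)

    def test_inflated_maintenance_can_starve(self, h2):
        # H2 up-regulation raises the effective maintenance and can push an
        # otherwise fed hen over the starvation switch
        L = h2.L_inf(h2.f_mf)
        E = h2.f_mf * h2.E_m * L ** 3
        assert specific_growth_rate(E, L, h2) == pytest.approx(0.0, abs=1e-10)
        assert specific_growth_rate(E, L, h2, p_M_eff=h2.p_M * 1.9) < 0

    @pytest.mark.parametrize("E,L", [(float("nan"), 1.0), (1e5, 0.0),
                                     (float("inf"), 1.0), (-1.0, 1.0)])
    def test_invalid_inputs_raise(self, h1, E, L):
        with pytest.raises(ValueError):
            specific_growth_rate(E, L, h1)


class TestComputeFluxes:
    def _adult(self, p):
        L = p.L_inf(1.0)
        return OrganismState(t=300.0, L=L, E=p.E_m * L ** 3, E_H=p.E_Hp)

    def test_embryo_does_not_assimilate(self, h1):
        st_e = OrganismState(t=1.0, L=0.2, E=5e4, E_H=0.5 * h1.E_Hb)
        fx = compute_fluxes(st_e, 1.0, 0.0, "none", h1)
        assert fx.p_A == 0.0 and fx.p_A_R == 0.0
        assert fx.p_C > 0 and fx.p_S > 0

    def test_h1_h2_coincide_without_upregulation(self, h2):
        st_a = self._adult(h2)
        f1 = compute_fluxes(st_a, h2.f_mf, 0.0, "H1", h2)
        f2 = compute_fluxes(st_a, h2.f_mf, 0.0, "H2", h2)
        assert f1 == f2

    def test_kappa_rule_identity_non_starving(self, h1):
        # kap * p_C = p_S + p_G whenever the soma is not starving
        st_a = OrganismState(t=100.0, L=1.5, E=h1.E_m * 1.5 ** 3, E_H=5e5)
        fx = compute_fluxes(st_a, 1.0, 0.0, "none", h1)
        assert h1.kap * fx.p_C == pytest.approx(fx.p_S + fx.p_G, rel=1e-10)

    def test_h2_upregulated_fluxes(self, h2):
        st_a = self._adult(h2)
        s = 0.8
        base = compute_fluxes(st_a, h2.f_mf, 0.0, "H2", h2)
        up = compute_fluxes(st_a, h2.f_mf, s, "H2", h2)
        assert up.p_A == pytest.approx((1 + s) * base.p_A, rel=1e-12)
        assert up.p_S == pytest.approx((1 + s * h2.f_mf) * base.p_S, rel=1e-12)

    def test_h1_routes_extra_to_reproduction(self, h1):
        st_a = self._adult(h1)
        s = 0.8
        base = compute_fluxes(st_a, h1.f_mf, 0.0, "H1", h1)
        up = compute_fluxes(st_a, h1.f_mf, s, "H1", h1)
        assert up.p_A == pytest.approx(base.p_A, rel=1e-12)
        assert up.p_A_R == pytest.approx(s * h1.f_mf * base.p_A / h1.f_mf, rel=1e-9)

    def test_adult_maintenance_scale_at_reference_temperature(self, h2):
        # p_S = p_M * L^3 exactly; combined maintenance of a full-grown adult
        # is in the several-thousand J/d range at the reference temperature
        st_a = self._adult(h2)
        fx = compute_fluxes(st_a, 1.0, 0.0, "H2", h2, T=h2.T_ref)
        assert fx.p_S == pytest.approx(h2.p_M * st_a.L ** 3, rel=1e-12)
        assert 3000 < fx.p_S + fx.p_J < 10000

    def test_bad_arguments_raise(self, h1):
        st_a = self._adult(h1)
        with pytest.raises(ValueError):
            compute_fluxes(st_a, 1.0, 0.0, "H3", h1)
        with pytest.raises(ValueError):
            compute_fluxes(st_a, -0.1, 0.0, "H1", h1)
        with pytest.raises(ValueError):
            compute_fluxes(st_a, 1.0, -0.5, "H2", h1)


class TestArrhenius:
    def test_identity_at_reference(self, h1):
        assert arrhenius_correct(3.14, h1.T_ref, h1) == pytest.approx(3.14)

    def test_body_temperature_factor(self, h1):
        # independently evaluated: exp(8000/293.15 - 8000/312.05) = 5.22193
        expected = math.exp(8000.0 / 293.15 - 8000.0 / 312.05)
        assert arrhenius_correct(1.0, 312.05, h1) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(5.22193, rel=1e-5)

    @given(st.floats(min_value=275.0, max_value=320.0),
           st.floats(min_value=0.1, max_value=30.0))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_monotone_in_temperature(self, T, dT):
        p = preset_h1()
        assert arrhenius_correct(1.0, T + dT, p) > arrhenius_correct(1.0, T, p)

    def test_k_R_quoted_at_body_temperature(self, h1):
        rt = h1.rates_at(h1.T_b)
        assert rt.k_R == pytest.approx(h1.k_R_rate, rel=1e-12)


def preset_h1():
    from quaildeb import preset
    return preset("H1")


class TestObservables:
    def test_structure_only_weight(self, h1):
        st_o = OrganismState(t=0, L=2.0, E=0.0, E_H=h1.E_Hp)
        assert wet_weight(st_o, h1) == pytest.approx(8.0)

    def test_buffer_term_linearity(self, h1):
        # adding mu_E/w_Ed joules to the buffer adds exactly one gram
        st0 = OrganismState(t=0, L=2.0, E=1e5, E_H=h1.E_Hp, E_R=0.0)
        st1 = OrganismState(t=0, L=2.0, E=1e5, E_H=h1.E_Hp,
                            E_R=h1.mu_E / h1.w_Ed)
        assert wet_weight(st1, h1) - wet_weight(st0, h1) == pytest.approx(1.0)

    def test_physical_length_roundtrip(self, h1):
        assert physical_length(2.641, h1.del_M) == pytest.approx(26.15, rel=1e-3)
        assert physical_length(1.23, 1.0) == 1.23
        assert physical_length(physical_length(1.3, 0.2) * 0.2, 1.0) == pytest.approx(1.3)
        with pytest.raises(ValueError):
            physical_length(1.0, 0.0)


class TestIntegrate:
    def test_matches_euler_oracle(self, h1):
        # juvenile growth over 10 d vs an independent fixed-step integrator
        st0 = OrganismState(t=0.0, L=0.9, E=0.8 * h1.E_m * 0.9 ** 3,
                            E_H=2 * h1.E_Hb)
        tr = integrate(st0, (0.0, 10.0), h1, f=1.0, T=h1.T_b, rtol=1e-9)
        ref = euler_integrate(st0, (0.0, 10.0), h1, f=1.0, hyp="none",
                              T=h1.T_b, h=1e-3)
        assert tr.L[-1] == pytest.approx(ref.L, rel=1e-3)
        assert tr.E[-1] == pytest.approx(ref.E, rel=1e-3)
        assert tr.E_H[-1] == pytest.approx(ref.E_H, rel=1e-3)

    def test_starvation_reserve_then_structure_decline(self, h1):
        L = h1.L_inf(1.0)
        st0 = OrganismState(t=0.0, L=L, E=h1.E_m * L ** 3, E_H=h1.E_Hp)
        tr = integrate(st0, (0.0, 120.0), h1, f=0.0, T=h1.T_b)
        assert np.all(np.diff(tr.E) < 1e-6)          # reserve declines
        assert tr.L[-1] < tr.L[0]                    # shrinking follows

    def test_stage_events_ordered_and_buffer_gated(self, h2):
        from quaildeb import initial_egg_energy, simulate_embryo
        E0 = initial_egg_energy(h2.E_m, h2)
        birth, a_b = simulate_embryo(E0, h2)
        tr = integrate(birth, (a_b, a_b + 400.0), h2, f=h2.f_B, T=h2.T_b)
        assert np.all(np.diff(tr.E_H) >= -1e-6)      # maturity non-decreasing
        crossings = np.sum(np.diff((tr.E_H >= h2.E_Hp).astype(int)) == 1)
        assert crossings == 1                         # puberty crossed once
        assert np.all(tr.E_R[tr.E_H < h2.E_Hp] == 0)  # no buffer before puberty
        assert tr.events["fledging"] <= tr.events["puberty"]

    def test_ultimate_length_closed_form(self, h1):
        f = 0.8
        L_start = 0.6 * f * h1.L_inf(1.0)
        st0 = OrganismState(t=0.0, L=L_start, E=f * h1.E_m * L_start ** 3,
                            E_H=h1.E_Hp)
        tr = integrate(st0, (0.0, 2500.0), h1, f=f, T=h1.T_b)
        assert tr.L[-1] == pytest.approx(h1.L_inf(f), rel=0.002)

    def test_energy_conservation_reserve(self, h1):
        # d/dt E = p_A - p_C along the trajectory, checked globally:
        # the reserve balance closes to within 0.1%
        st0 = OrganismState(t=0.0, L=1.2, E=0.9 * h1.E_m * 1.2 ** 3, E_H=3e5)
        tr = integrate(st0, (0.0, 40.0), h1, f=1.0, T=h1.T_b, rtol=1e-9,
                       dense_step=0.05)
        rt = h1.rates_at(h1.T_b)
        p_net = np.empty_like(tr.t)
        for i in range(tr.t.size):
            fx = compute_fluxes(tr.state_at(i), 1.0, 0.0, "none", h1, rates=rt)
            p_net[i] = fx.p_A - fx.p_C
        gained = np.trapezoid(p_net, tr.t)
        assert gained == pytest.approx(tr.E[-1] - tr.E[0], rel=1e-3)

    def test_solver_error_reports_time(self, h1):
        st0 = OrganismState(t=0.0, L=1e-4, E=100.0, E_H=0.0)
        with pytest.raises(RuntimeError, match="egg too small"):
            integrate(st0, (0.0, 500.0), h1, f=0.0, T=h1.T_b,
                      stop_at_event="birth")
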