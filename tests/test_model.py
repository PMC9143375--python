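"""Closed-form solution and parameter-algebra tests for the SLS model."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from slsfit import (
    CreepProtocol,
    PronyParameters,
    RelaxationProtocol,
    creep_hold_amplitude,
    creep_loading_strain,
    creep_strain_finite,
    creep_strain_infinite,
    make_sls,
    prony_to_sls,
    recover_E2_eta,
    relaxation_hold_amplitude,
    relaxation_loading_stress,
    relaxation_modulus_dimensionless,
    relaxation_stress_finite,
    relaxation_stress_infinite,
    sls_to_prony,
    strain_at_ramp_end,
    stress_at_ramp_end,
)

moduli = st.floats(min_value=1e2, max_value=1e7)
viscosities = st.floats(min_value=1e1, max_value=1e7)
rates = st.floats(min_value=1e-5, max_value=1e3)


def sls_params(draw):
    return make_sls(draw(moduli), draw(moduli), draw(viscosities))


valid_sls = st.builds(make_sls, moduli, moduli, viscosities)


class TestParameterAlgebra:
    @pytest.mark.parametrize(
        "E1,E2,eta,tau_R,tau_C",
        [
            (5000.0, 20000.0, 10000.0, 0.5, 2.5),
            (30000.0, 120000.0, 600000.0, 5.0, 25.0),
            (1.0, 1.0, 1.0, 1.0, 2.0),
        ],
    )
    def test_time_constants(self, E1, E2, eta, tau_R, tau_C):
        p = make_sls(E1, E2, eta)
        assert p.tau_R == pytest.approx(tau_R)
        assert p.tau_C == pytest.approx(tau_C)
        assert p.tau_C > p.tau_R

    @pytest.mark.parametrize("bad", [(0, 1, 1), (1, -1, 1), (1, 1, float("nan")), (1, 1, float("inf"))])
    def test_invalid_parameters_rejected(self, bad):
        with pytest.raises(ValueError):
            make_sls(*bad)

    def test_sls_to_prony_benchmark_values(self):
        q = sls_to_prony(make_sls(30e3, 120e3, 600e3))
        assert q.E == pytest.approx(30e3)
        assert q.g == pytest.approx(0.8)
        assert q.tau_R == pytest.approx(5.0)
        # symmetric arms give g = 1/2; soft benchmark material gives 20/25
        assert sls_to_prony(make_sls(7.0, 7.0, 3.0)).g == pytest.approx(0.5)
        assert sls_to_prony(make_sls(5e3, 20e3, 10e3)).g == pytest.approx(0.8)

    def test_prony_to_sls_benchmark_values(self):
        p = prony_to_sls(PronyParameters(E=30e3, g=0.8, tau_R=5.0))
        assert p.E1 == pytest.approx(30e3)
        assert p.E2 == pytest.approx(120e3)
        assert p.eta == pytest.approx(600e3)
        assert prony_to_sls(PronyParameters(5e3, 0.8, 0.5)).E2 == pytest.approx(20e3)

    def test_prony_vanishing_maxwell_arm(self):
        p = prony_to_sls(PronyParameters(E=1.0, g=1e-9, tau_R=1.0))
        assert p.E2 == pytest.approx(0.0, abs=1e-8)
        assert p.eta == pytest.approx(0.0, abs=1e-8)

    @pytest.mark.parametrize("g", [0.0, 1.0, -0.2, 1.3])
    def test_prony_g_out_of_range(self, g):
        with pytest.raises(ValueError):
            PronyParameters(E=1.0, g=g, tau_R=1.0)

    def test_recover_E2_eta(self):
        E2, eta = recover_E2_eta(5000.0, 2.5, 0.5)
        assert E2 == pytest.approx(20000.0)
        assert eta == pytest.approx(10000.0)
        # tau_C = 2 tau_R <=> E2 = E1
        E2, _ = recover_E2_eta(1234.0, 1.0, 0.5)
        assert E2 == pytest.approx(1234.0)

    def test_recover_E2_eta_ill_posed(self):
        with pytest.raises(ValueError):
            recover_E2_eta(1000.0, 0.5, 0.5)
        with pytest.raises(ValueError):
            recover_E2_eta(1000.0, 0.4, 0.5)

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(valid_sls)
    def test_round_trips(self, p):
        back = prony_to_sls(sls_to_prony(p))
        assert back.E1 == pytest.approx(p.E1, rel=1e-12)
        assert back.E2 == pytest.approx(p.E2, rel=1e-12)
        assert back.eta == pytest.approx(p.eta, rel=1e-12)
        # tau_C - tau_R cancels when E1 >> E2, so the attainable precision
        # scales with the conditioning factor (1 + E1/E2)
        cond = 1e-14 * (2.0 + p.E1 / p.E2)
        E2, eta = recover_E2_eta(p.E1, p.tau_C, p.tau_R)
        assert E2 == pytest.approx(p.E2, rel=cond)
        assert eta == pytest.approx(p.eta, rel=cond)

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(valid_sls)
    def test_tau_ordering(self, p):
        assert p.tau_C > p.tau_R


class TestRelaxationModulus:
    def test_values(self):
        q = PronyParameters(E=1.0, g=0.8, tau_R=2.0)
        assert relaxation_modulus_dimensionless(0.0, q) == pytest.approx(1.0)
        assert relaxation_modulus_dimensionless(1e6, q) == pytest.approx(0.2)
        assert relaxation_modulus_dimensionless(2.0, q) == pytest.approx(
            1 - 0.8 * (1 - math.exp(-1))
        )

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            relaxation_modulus_dimensionless(-0.1, PronyParameters(1.0, 0.5, 1.0))


class TestRelaxationForms:
    def test_loading_stress_example(self, soft_material):
        # E1 r t + E1 r (tauC - tauR)(1 - e^{-t/tauR}) at t = 1 s, r = 0.01/s
        expected = 50.0 + 100.0 * (1 - math.exp(-2.0))
        assert relaxation_loading_stress(1.0, soft_material, 0.01) == pytest.approx(expected)
        assert relaxation_loading_stress(0.0, soft_material, 0.01) == 0.0

    def test_loading_initial_slope_is_instantaneous_modulus(self, soft_material):
        r, h = 0.01, 1e-9
        slope = relaxation_loading_stress(h, soft_material, r) / h
        assert slope == pytest.approx(r * (soft_material.E1 + soft_material.E2), rel=1e-6)

    def test_loading_ramp_window_enforced(self, soft_material):
        with pytest.raises(ValueError):
            relaxation_loading_stress(2.0, soft_material, 0.01, hold_strain=0.01)

    def test_ramp_end_rate_limits(self, soft_material):
        eps0 = 0.01
        fast = RelaxationProtocol(1e12, eps0, 1.0)
        slow = RelaxationProtocol(1e-9, eps0, 1.0)
        assert stress_at_ramp_end(soft_material, fast) == pytest.approx(
            (soft_material.E1 + soft_material.E2) * eps0, rel=1e-6
        )
        assert stress_at_ramp_end(soft_material, slow) == pytest.approx(
            soft_material.E1 * eps0, rel=1e-6
        )

    def test_hold_equilibrium_and_continuity(self, soft_material):
        proto = RelaxationProtocol(0.01, 0.01, 10.0)
        assert relaxation_stress_finite(0.0, soft_material, proto) == pytest.approx(
            stress_at_ramp_end(soft_material, proto), rel=1e-15
        )
        assert relaxation_stress_finite(1e9, soft_material, proto) == pytest.approx(
            soft_material.E1 * 0.01
        )

    def test_infinite_form_values(self, soft_material):
        eps0 = 0.01
        assert relaxation_stress_infinite(0.0, soft_material, eps0) == pytest.approx(250.0)
        assert relaxation_stress_infinite(1e9, soft_material, eps0) == pytest.approx(50.0)
        assert relaxation_stress_infinite(soft_material.tau_R, soft_material, eps0) == pytest.approx(
            (soft_material.E1 + soft_material.E2 / math.e) * eps0
        )

    def test_finite_form_tends_to_infinite_at_extreme_rate(self, soft_material):
        proto = RelaxationProtocol(1e9, 0.01, 10.0)
        t = np.linspace(0, 5, 200)
        fin = relaxation_stress_finite(t, soft_material, proto)
        inf = relaxation_stress_infinite(t, soft_material, 0.01)
        assert np.max(np.abs(fin - inf)) / np.max(np.abs(inf)) < 1e-6
        assert relaxation_hold_amplitude(soft_material, proto) == pytest.approx(
            soft_material.E2 * 0.01, rel=1e-6
        )

    def test_stretch_exponent_validated(self, soft_material):
        proto = RelaxationProtocol(0.01, 0.01, 10.0)
        for bad in (0.0, -0.5, 1.2):
            with pytest.raises(ValueError):
                relaxation_stress_finite(1.0, soft_material, proto, k=bad)


class TestCreepForms:
    def test_loading_strain_lags_quasistatic_line(self, soft_material):
        r = 100.0
        t = np.linspace(0.01, 1.0, 50)
        eps = creep_loading_strain(t, soft_material, r)
        assert np.all(eps < (r / soft_material.E1) * t)
        assert creep_loading_strain(0.0, soft_material, r) == 0.0

    def test_loading_initial_slope_is_instantaneous_compliance(self, soft_material):
        r, h = 100.0, 1e-9
        slope = creep_loading_strain(h, soft_material, r) / h
        assert slope == pytest.approx(r / (soft_material.E1 + soft_material.E2), rel=1e-6)

    def test_ramp_end_rate_limits(self, soft_material):
        sigma0 = 100.0
        fast = CreepProtocol(1e15, sigma0, 1.0)
        slow = CreepProtocol(1e-9, sigma0, 1.0)
        assert strain_at_ramp_end(soft_material, fast) == pytest.approx(
            sigma0 / (soft_material.E1 + soft_material.E2), rel=1e-6
        )
        assert strain_at_ramp_end(soft_material, slow) == pytest.approx(
            sigma0 / soft_material.E1, rel=1e-6
        )

    def test_hold_equilibrium_and_continuity(self, soft_material):
        proto = CreepProtocol(100.0, 100.0, 30.0)
        assert creep_strain_finite(0.0, soft_material, proto) == pytest.approx(
            strain_at_ramp_end(soft_material, proto), rel=1e-15
        )
        assert creep_strain_finite(1e9, soft_material, proto) == pytest.approx(0.02)

    def test_infinite_form_values(self, soft_material):
        sigma0 = 100.0
        assert creep_strain_infinite(0.0, soft_material, sigma0) == pytest.approx(0.004)
        assert creep_strain_infinite(1e9, soft_material, sigma0) == pytest.approx(0.02)
        g = 0.8
        assert creep_strain_infinite(soft_material.tau_C, soft_material, sigma0) == pytest.approx(
            (sigma0 / soft_material.E1) * (1 - g / math.e)
        )

    def test_finite_form_tends_to_infinite_at_extreme_rate(self, soft_material):
        proto = CreepProtocol(1e9, 100.0, 30.0)
        t = np.linspace(0, 20, 200)
        fin = creep_strain_finite(t, soft_material, proto)
        inf = creep_strain_infinite(t, soft_material, 100.0)
        assert np.max(np.abs(fin - inf)) / np.max(np.abs(inf)) < 1e-6
        expected_amp = -100.0 * soft_material.E2 / (
            soft_material.E1 * (soft_material.E1 + soft_material.E2)
        )
        assert creep_hold_amplitude(soft_material, proto) == pytest.approx(expected_amp, rel=1e-6)


class TestPhaseProperties:
    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(valid_sls, rates)
    def test_relaxation_continuity_and_signs(self, p, r):
        proto = RelaxationProtocol(r, 0.01, 5 * p.tau_R)
        assert relaxation_stress_finite(0.0, p, proto) == pytest.approx(
            stress_at_ramp_end(p, proto), rel=1e-12
        )
        assert relaxation_hold_amplitude(p, proto) > 0
        t = np.linspace(0, proto.hold_duration, 64)
        sigma = relaxation_stress_finite(t, p, proto)
        assert np.all(np.diff(sigma) <= 1e-12 * np.max(np.abs(sigma)))

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(valid_sls, rates)
    def test_creep_continuity_and_signs(self, p, r):
        proto = CreepProtocol(r * 1e4, 100.0, 5 * p.tau_C)
        assert creep_strain_finite(0.0, p, proto) == pytest.approx(
            strain_at_ramp_end(p, proto), rel=1e-12
        )
        assert creep_hold_amplitude(p, proto) < 0
        t = np.linspace(0, proto.hold_duration, 64)
        eps = creep_strain_finite(t, p, proto)
        assert np.all(np.diff(eps) >= -1e-12 * np.max(np.abs(eps)))

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(valid_sls, rates, st.floats(min_value=0.2, max_value=1.0))
    def test_equilibria_for_every_stretch_exponent(self, p, r, k):
        rproto = RelaxationProtocol(r, 0.01, 1.0)
        cproto = CreepProtocol(r * 1e4, 100.0, 1.0)
        t_long = 1e8 * max(p.tau_R, p.tau_C)
        assert relaxation_stress_finite(t_long, p, rproto, k=k) == pytest.approx(p.E1 * 0.01)
        assert creep_strain_finite(t_long, p, cproto, k=k) == pytest.approx(100.0 / p.E1)
        assert relaxation_stress_infinite(t_long, p, 0.01) == pytest.approx(p.E1 * 0.01)
        assert creep_strain_infinite(t_long, p, 100.0) == pytest.approx(100.0 / p.E1)
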