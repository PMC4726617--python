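"""Structural model: transit input, ODE solution, derived rate constants."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad

from ugtphen import (ConcentrationProfile, DoseEvent, StructuralParams,
                     k12_midazolam, k23, simulate_profile, transit_input_rate,
                     transit_rate_constant)
from ugtphen.model_core import simulate_amounts_ivp


class TestTransitRateConstant:
    @pytest.mark.parametrize("mtt, nn, expected", [
        (1.04, 1.07, 2.07 / 1.04),   # published estimates
        (1.0, 0.0, 1.0),
        (2.0, 3.0, 2.0),
    ])
    def test_values(self, mtt, nn, expected):
        assert transit_rate_constant(mtt, nn) == pytest.approx(expected, rel=1e-12)

    def test_nonpositive_mtt_rejected(self):
        with pytest.raises(ValueError):
            transit_rate_constant(0.0, 1.0)
        with pytest.raises(ValueError):
            transit_rate_constant(-1.0, 1.0)


class TestTransitInputRate:
    def test_zero_at_t0_for_positive_nn(self):
        assert transit_input_rate(0.0, 400.0, 1.0, 2.0, 1.07) == 0.0

    def test_nn_zero_reduces_to_first_order(self):
        t = np.linspace(0.0, 5.0, 40)
        rate = transit_input_rate(t, 400.0, 1.0, 1.5, 0.0)
        expected = 400.0 * 1.5 * np.exp(-1.5 * t)
        np.testing.assert_allclose(rate, expected, rtol=1e-12)

    def test_mass_balance_integral(self):
        # total drug delivered over [0, 200] h equals dose*F within 0.1%
        total, _ = quad(lambda t: float(transit_input_rate(t, 400.0, 1.0,
                                                           1.99, 1.07)),
                        0.0, 200.0, limit=200)
        assert total == pytest.approx(400.0, rel=1e-3)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            transit_input_rate(-0.1, 400.0, 1.0, 2.0, 1.0)


class TestSimulateProfile:
    def test_zero_dose_gives_zero_concentrations(self, theta):
        times = np.array([0.5, 1.0, 4.0, 24.0])
        p, m = simulate_profile(theta, [DoseEvent(0.0, 0.0)], times)
        assert np.all(p.concentrations == 0.0)
        assert np.all(m.concentrations == 0.0)

    def test_analytic_matches_ode_solver(self, theta, single_dose):
        times = np.array([0.25, 0.5, 1.0, 2.0, 4.0, 8.0, 12.0, 24.0])
        pa, ma = simulate_profile(theta, single_dose, times, method="analytic")
        pi, mi = simulate_profile(theta, single_dose, times, method="ivp",
                                  rtol=1e-10, atol=1e-13)
        np.testing.assert_allclose(pa.concentrations, pi.concentrations,
                                   rtol=1e-7)
        np.testing.assert_allclose(ma.concentrations, mi.concentrations,
                                   rtol=1e-7)

    def test_one_compartment_limit(self, theta, single_dose):
        # vanishing transit chain -> closed-form first-order absorption
        p = theta.replace(nn=0.0, mtt=1e-7)
        t = np.linspace(0.1, 24.0, 60)
        parent, _ = simulate_profile(p, single_dose, t)
        k = p.cl_f / p.v_f
        closed = (400.0 * p.f * p.ka / (p.v_f * (p.ka - k))
                  * (np.exp(-k * t) - np.exp(-p.ka * t)))
        np.testing.assert_allclose(parent.concentrations, closed, rtol=1e-3)

    def test_auc_ratio_identity(self, theta, single_dose):
        # AUC_inf(metabolite)/AUC_inf(parent) == fmet*cl_f/cl_glu
        t = np.linspace(0.0, 300.0, 200001)  # >= 10 half-lives of both
        parent, metab = simulate_profile(theta, single_dose, t)
        ratio = (np.trapezoid(metab.concentrations, t)
                 / np.trapezoid(parent.concentrations, t))
        assert ratio == pytest.approx(theta.fmet * theta.cl_f / theta.cl_glu,
                                      rel=1e-4)

    def test_mass_balance_through_time(self, theta, single_dose):
        # depot + central + cumulative elimination == delivered input, and
        # delivered + in-flight == F * dose
        times = np.array([0.5, 1.0, 2.0, 4.0, 8.0, 16.0, 24.0])
        state = simulate_amounts_ivp(theta, single_dose, times)
        lhs = state["depot"] + state["central"] + state["eliminated"]
        np.testing.assert_allclose(lhs, state["delivered"], rtol=1e-6)
        assert np.all(state["delivered"] <= 400.0 * theta.f + 1e-9)
        assert state["delivered"][-1] == pytest.approx(400.0 * theta.f,
                                                       rel=1e-6)

    def test_pre_dose_time_zero_concentration(self, theta, single_dose):
        p, m = simulate_profile(theta, single_dose, np.array([0.0, 1.0]))
        assert p.concentrations[0] == 0.0
        assert m.concentrations[0] == 0.0

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        cl=st.floats(1.0, 200.0), v=st.floats(5.0, 500.0),
        ka=st.floats(0.1, 20.0), mtt=st.floats(0.05, 8.0),
        nn=st.floats(0.0, 6.0), fmet=st.floats(0.005, 1.0),
        cl_glu=st.floats(0.05, 20.0),
    )
    def test_nonnegativity_property(self, cl, v, ka, mtt, nn, fmet, cl_glu):
        params = StructuralParams(cl_f=cl, v_f=v, ka=ka, mtt=mtt, nn=nn,
                                  fmet=fmet, cl_glu=cl_glu)
        t = np.linspace(0.0, 48.0, 30)
        p, m = simulate_profile(params, [DoseEvent(0.0, 400.0)], t)
        assert np.all(p.concentrations >= 0.0)
        assert np.all(m.concentrations >= 0.0)
        assert np.all(np.isfinite(p.concentrations))
        assert np.all(np.isfinite(m.concentrations))

    def test_multiple_doses_superpose(self, theta):
        t = np.linspace(0.0, 48.0, 97)
        one, _ = simulate_profile(theta, [DoseEvent(0.0, 400.0)], t)
        shifted, _ = simulate_profile(theta, [DoseEvent(12.0, 400.0)], t)
        both, _ = simulate_profile(theta, [DoseEvent(0.0, 400.0),
                                           DoseEvent(12.0, 400.0)], t)
        np.testing.assert_allclose(
            both.concentrations, one.concentrations + shifted.concentrations,
            rtol=1e-10, atol=1e-12)


class TestDerivedConstants:
    def test_k23_published_arithmetic(self, theta):
        # FMET * (CL/F) / (V/F) with the published estimates
        assert k23(theta) == pytest.approx(0.0324 * 41.7 / 157.0, rel=1e-12)
        assert k23(theta) == pytest.approx(0.008606, rel=1e-4)

    def test_k23_edge_values(self, theta):
        assert k23(theta.replace(fmet=1.0, cl_f=50.0, v_f=50.0)) == 1.0

    def test_k12_worked_examples(self):
        assert k12_midazolam(30.0, 100.0) == pytest.approx(0.18)
        assert k12_midazolam(25.0, 25.0) == pytest.approx(0.6)
        assert k12_midazolam(30.0, 200.0) == pytest.approx(
            k12_midazolam(30.0, 100.0) / 2.0)

    def test_k12_domain(self):
        with pytest.raises(ValueError):
            k12_midazolam(0.0, 10.0)
        with pytest.raises(ValueError):
            k12_midazolam(10.0, -1.0)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(scale=st.floats(0.01, 100.0))
    def test_rate_constants_scale_invariant(self, theta, scale):
        # homogeneous of degree 0 in simultaneous clearance+volume scaling
        scaled = theta.replace(cl_f=theta.cl_f * scale, v_f=theta.v_f * scale)
        assert k23(scaled) == pytest.approx(k23(theta), rel=1e-12)
        assert k12_midazolam(30.0 * scale, 100.0 * scale) == pytest.approx(
            k12_midazolam(30.0, 100.0), rel=1e-12)


class TestDomainTypes:
    def test_structural_params_validation(self):
        with pytest.raises(ValueError):
            StructuralParams(cl_f=-1.0, v_f=157.0, ka=4.23, mtt=1.04, nn=1.07)
        with pytest.raises(ValueError):
            StructuralParams(cl_f=41.7, v_f=157.0, ka=4.23, mtt=1.04, nn=-0.1)
        with pytest.raises(ValueError):
            StructuralParams(cl_f=41.7, v_f=157.0, ka=4.23, mtt=1.04, nn=1.0,
                             fmet=1.5)

    def test_profile_validation(self):
        with pytest.raises(ValueError):
            ConcentrationProfile("s", "raltegravir", np.array([1.0, 0.5]),
                                 np.array([1.0, 2.0]))
        with pytest.raises(ValueError):
            ConcentrationProfile("s", "raltegravir", np.array([0.5, 1.0]),
                                 np.array([1.0, -2.0]))
        with pytest.raises(ValueError):
            ConcentrationProfile("s", "nope", np.array([0.5]), np.array([1.0]))

    def test_dose_event_validation(self):
        with pytest.raises(ValueError):
            DoseEvent(-1.0, 400.0)
        with pytest.raises(ValueError):
            DoseEvent(0.0, -400.0)
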