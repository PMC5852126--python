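"""Gating kinetics, membrane currents, vector field and analytic Jacobian."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ihdyn import ModelParameters, State, gating_rates, ionic_currents, rhs, jacobian
from ihdyn.model import steady_state_current, steady_gating, d_steady_state_current_dV
from ihdyn import _kernels

from conftest import random_states


class TestGating:
    @pytest.mark.parametrize("V,attr,expected", [
        (-35.0, "alpha_m", 1.0),        # removable singularity, exact limit
        (-80.0, "H_inf", 0.5),          # Boltzmann midpoint
        (-70.0, "tau_H", 105.0),        # cosh minimum: 200/2 + 5
        (-34.0, "alpha_n", 0.1),        # removable singularity, exact limit
    ])
    def test_exact_values(self, V, attr, expected):
        assert getattr(gating_rates(V), attr) == pytest.approx(expected, abs=1e-12)

    def test_rates_and_steady_states_well_behaved(self):
        g = gating_rates(np.linspace(-120.0, 40.0, 1601))
        for name in ("alpha_m", "beta_m", "alpha_h", "beta_h", "alpha_n", "beta_n"):
            assert np.all(getattr(g, name) >= 0)
        for name in ("m_inf", "h_inf", "n_inf", "H_inf"):
            x = getattr(g, name)
            assert np.all((x >= 0) & (x <= 1))
        assert np.all(g.tau_H >= 5.0)

    def test_continuity_at_singularities(self):
        # the filled limits must join the neighbouring values smoothly
        for V0, attr in [(-35.0, "alpha_m"), (-34.0, "alpha_n")]:
            vals = [getattr(gating_rates(V0 + e), attr) for e in (-1e-7, 0.0, 1e-7)]
            assert abs(vals[1] - 0.5 * (vals[0] + vals[2])) < 1e-8

    def test_nonfinite_voltage_rejected(self):
        with pytest.raises(ValueError):
            gating_rates(np.nan)

    def test_h_activates_under_hyperpolarization(self):
        g = gating_rates(np.array([-120.0, -80.0, -40.0]))
        assert g.H_inf[0] > 0.95 > g.H_inf[1] + 0.4 > g.H_inf[2]


class TestCurrents:
    def test_hand_evaluated_currents(self):
        # independent evaluation of the printed formulas at one state
        s = State(V=-60.0, h=0.5, n=0.3, H=0.2)
        p = ModelParameters(gh=0.05)
        cur = ionic_currents(s, p)
        assert cur["I_Na"] == pytest.approx(-0.298471415152, rel=1e-10)
        assert cur["I_K"] == pytest.approx(2.187, rel=1e-12)
        assert cur["I_h"] == pytest.approx(-0.3, rel=1e-12)
        assert cur["I_L"] == pytest.approx(0.5, rel=1e-12)

    def test_zero_conductance_and_zero_driving_force(self):
        p = ModelParameters(gh=0.0)
        s = State(V=p.EK, h=0.5, n=0.9, H=0.7)
        cur = ionic_currents(s, p)
        assert cur["I_h"] == 0.0
        assert cur["I_K"] == 0.0


class TestRhs:
    def test_gating_flux_points_inward_at_bounds(self):
        p = ModelParameters()
        up = rhs(State(V=-60.0, h=1.0, n=1.0, H=1.0), p)
        lo = rhs(State(V=-60.0, h=0.0, n=0.0, H=0.0), p)
        assert np.all(up[1:] <= 0)
        assert np.all(lo[1:] >= 0)

    def test_equilibrium_is_a_root(self):
        from ihdyn import find_equilibria
        p = ModelParameters(Iapp=0.08, gh=0.02)
        for eq in find_equilibria(p):
            assert np.linalg.norm(rhs(eq.state, p)) < 1e-10

    @given(st.floats(-90, 0), st.floats(0.01, 0.99))
    @settings(max_examples=25, deadline=None)
    def test_external_current_enters_linearly(self, V, h):
        p = ModelParameters()
        s = np.array([V, h, 0.3, 0.4])
        d0, d1 = rhs(s, p, 0.0), rhs(s, p, 1.0)
        assert d1[0] - d0[0] == pytest.approx(1.0 / p.C, rel=1e-12)
        assert np.allclose(d0[1:], d1[1:])


class TestJacobian:
    def test_structure_of_H_row(self, rng):
        p = ModelParameters(Iapp=0.1, gh=0.03)
        for s in random_states(rng, 5):
            J = jacobian(s, p)
            assert J[3, 1] == 0.0 and J[3, 2] == 0.0
            assert J[1, 2] == 0.0 and J[1, 3] == 0.0
            assert J[2, 1] == 0.0 and J[2, 3] == 0.0

    def test_matches_finite_differences(self, rng):
        p = ModelParameters(Iapp=-0.02, gh=0.04)
        step = 1e-6
        worst = 0.0
        for s in random_states(rng, 100):
            J = jacobian(s, p)
            Jfd = np.empty((4, 4))
            for j in range(4):
                e = np.zeros(4)
                e[j] = step
                Jfd[:, j] = (rhs(s + e, p) - rhs(s - e, p)) / (2 * step)
            scale = np.maximum(np.abs(Jfd), 1e-3)
            worst = max(worst, float(np.max(np.abs(J - Jfd) / scale)))
        assert worst < 1e-5

    def test_steady_state_current_derivative(self):
        # analytic dI_ss/dV against central differences
        p = ModelParameters(Iapp=0.0, gh=0.03)
        V = np.linspace(-90.0, -40.0, 101)
        e = 1e-6
        fd = (steady_state_current(V + e, p) - steady_state_current(V - e, p)) / (2 * e)
        assert np.allclose(d_steady_state_current_dV(V, p), fd, rtol=1e-6, atol=1e-9)


class TestKernelConsistency:
    def test_compiled_derivative_matches_reference(self, rng):
        """The njit inner loop duplicates the gating math; pin it to the
        numpy reference implementation."""
        p = ModelParameters(Iapp=0.07, gh=0.025)
        par = p.as_array()
        for s in random_states(rng, 50):
            ref = rhs(s, p, 0.123)
            got = _kernels._deriv(s[0], s[1], s[2], s[3], par, 0.123)
            assert np.allclose(ref, np.array(got), rtol=1e-13, atol=1e-15)

    def test_compiled_stimuli_match_reference(self):
        from ihdyn.stimulus import Constant, SquarePulse, Ramp, Zap, Sine, ZapSpec
        protos = [Constant(0.3), SquarePulse(-0.8, 100.0, 100.0),
                  Ramp(0.01, 50.0), Zap(ZapSpec()), Sine(0.01, 3.0)]
        t = np.linspace(0.0, 900.0, 997)
        for proto in protos:
            ref = proto(t)
            got = np.array([_kernels.stim_value(proto.kind, proto.kernel_params(), tk)
                            for tk in t])
            assert np.allclose(ref, got, atol=1e-14)


def test_parameter_validation():
    with pytest.raises(ValueError):
        ModelParameters(C=0.0)
    with pytest.raises(ValueError):
        ModelParameters(gh=-0.01)
    with pytest.raises(ValueError):
        State(V=-60.0, h=1.2, n=0.1, H=0.1)
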