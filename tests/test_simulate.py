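"""Integration, equilibrium settling, spike detection, damped oscillations."""

import numpy as np
import pytest

from ihdyn import (
    ModelParameters, NoiseSpec, integrate, run_spikes, settle_to_equilibrium,
    detect_spikes, damped_frequency, find_equilibria,
)
from ihdyn.simulate import Trajectory, NoRestingStateError


class TestIntegrate:
    def test_equilibrium_is_invariant(self):
        p = ModelParameters(Iapp=-0.05, gh=0.05)
        x0 = settle_to_equilibrium(p)
        tr = integrate(p, x0=x0, t_end=500.0, record_dt=1.0)
        assert np.abs(tr.V - x0[0]).max() < 1e-6

    def test_deterministic_firing_is_period_one(self):
        # at Iapp = 0.17 the deterministic model fires periodically (CV = 0)
        p = ModelParameters(Iapp=0.17, gh=0.02)
        st, _ = run_spikes(p, x0=np.array([-64.0, 0.8, 0.1, 0.1]), t_end=2000.0)
        isis = st.isis()
        assert len(isis) > 15
        settled = isis[-10:]          # the onset transient decays geometrically
        assert np.ptp(settled) < 2 * 0.001
        assert np.std(settled, ddof=1) / np.mean(settled) < 1e-5

    def test_step_refinement_converges(self):
        p = ModelParameters(Iapp=-0.05, gh=0.03)
        x0 = settle_to_equilibrium(p)
        x0 = x0 + np.array([1.0, 0, 0, 0])
        v_end = {}
        for dt in (0.002, 0.001):
            tr = integrate(p, x0=x0, t_end=100.0, dt=dt, record_dt=0.1)
            v_end[dt] = tr.V[-1]
        assert abs(v_end[0.002] - v_end[0.001]) < 1e-3

    def test_gating_bounds_preserved_under_noise(self):
        p = ModelParameters(Iapp=0.17, gh=0.02)
        tr = integrate(p, x0=np.array([-64.0, 0.8, 0.1, 0.1]), t_end=500.0,
                       noise=NoiseSpec(D=0.6, seed=3), record_dt=0.01)
        for g in (tr.h, tr.n, tr.H):
            assert g.min() >= 0.0 and g.max() <= 1.0

    def test_seeded_runs_are_bit_identical(self):
        p = ModelParameters(Iapp=0.17, gh=0.0)
        kw = dict(x0=np.array([-64.0, 0.8, 0.1, 0.1]), t_end=200.0,
                  noise=NoiseSpec(D=0.2, seed=42), record_dt=0.1)
        a = integrate(p, **kw)
        b = integrate(p, **kw)
        assert np.array_equal(a.V, b.V)
        c = integrate(p, x0=kw["x0"], t_end=200.0,
                      noise=NoiseSpec(D=0.2, seed=43), record_dt=0.1)
        assert not np.array_equal(a.V, c.V)

    def test_record_stride_validation(self):
        p = ModelParameters()
        with pytest.raises(ValueError):
            integrate(p, x0=np.full(4, 0.1), t_end=1.0, dt=0.001, record_dt=0.0015)


class TestSettle:
    def test_agrees_with_equilibrium_scan(self):
        p = ModelParameters(Iapp=-0.05, gh=0.0)
        x0 = settle_to_equilibrium(p)
        stable = [e for e in find_equilibria(p) if e.is_stable]
        assert stable and np.allclose(x0, stable[0].state, atol=1e-8)
        from ihdyn import rhs
        assert np.linalg.norm(rhs(x0, p)) < 1e-9

    def test_firing_only_region_raises(self):
        with pytest.raises(NoRestingStateError):
            settle_to_equilibrium(ModelParameters(Iapp=0.17, gh=0.02))

    def test_focus_resting_state(self):
        p = ModelParameters(Iapp=-0.05, gh=0.05)
        stable = [e for e in find_equilibria(p) if e.is_stable]
        assert stable[0].etype == "stable_focus"


class TestDetectSpikes:
    def test_subthreshold_trace_has_no_spikes(self):
        p = ModelParameters(Iapp=-0.05, gh=0.0)
        tr = integrate(p, t_end=300.0, record_dt=0.1)
        assert len(detect_spikes(tr)) == 0

    def test_single_crossing_single_spike(self):
        t = np.arange(0.0, 50.0, 0.01)
        V = -65.0 + 90.0 * np.exp(-0.5 * (t - 20.0) ** 2)   # one AP-like bump
        tr = Trajectory(t=t, V=V, h=V * 0, n=V * 0, H=V * 0, stim=V * 0, dt=0.01)
        st = detect_spikes(tr)
        assert len(st) == 1
        assert st.spike_times[0] == pytest.approx(20.0, abs=1.5)

    def test_matches_streaming_detection(self):
        p = ModelParameters(Iapp=0.17, gh=0.02)
        x0 = np.array([-64.0, 0.8, 0.1, 0.1])
        tr = integrate(p, x0=x0, t_end=1000.0)        # full-resolution record
        st_a = detect_spikes(tr)
        st_b, _ = run_spikes(p, x0=x0, t_end=1000.0)
        assert len(st_a) == len(st_b)
        assert np.allclose(st_a.spike_times, st_b.spike_times, atol=2e-3)

    def test_threshold_insensitivity(self):
        # APs overshoot far above 0 mV: the count is stable over [-20, 10]
        p = ModelParameters(Iapp=0.17, gh=0.02)
        x0 = np.array([-64.0, 0.8, 0.1, 0.1])
        periods = {}
        for thr in (-20.0, -10.0, 0.0, 10.0):
            st, _ = run_spikes(p, x0=x0, t_end=2000.0, threshold=thr)
            periods[thr] = np.mean(st.isis()[-5:])
        ref = periods[0.0]
        assert all(abs(T - ref) < 2 * 0.001 for T in periods.values())


class TestDampedFrequency:
    def _decay(self, gh):
        p = ModelParameters(Iapp=-0.05, gh=gh)
        eq = [e for e in find_equilibria(p) if e.is_stable][0]
        x0 = eq.state.copy()
        x0[0] += 2.0
        tr = integrate(p, x0=x0, t_end=4000.0, record_dt=0.1)
        return eq, tr

    def test_node_decays_without_oscillation(self):
        eq, tr = self._decay(0.01)
        assert eq.etype == "stable_node"
        assert damped_frequency(tr) is None

    def test_focus_frequency_matches_eigenvalues(self):
        eq, tr = self._decay(0.05)
        assert eq.etype == "stable_focus"
        f = damped_frequency(tr)
        f_eig = np.abs(eq.eigenvalues.imag).max() / (2 * np.pi) * 1000.0
        assert f == pytest.approx(f_eig, rel=0.05)

    def test_synthetic_damped_cosine(self):
        t = np.arange(0.0, 3000.0, 0.1)
        V = -60.0 + 2.0 * np.exp(-t / 400.0) * np.cos(2 * np.pi * 2.5 * t / 1000.0)
        tr = Trajectory(t=t, V=V, h=V * 0, n=V * 0, H=V * 0, stim=V * 0, dt=0.1)
        assert damped_frequency(tr) == pytest.approx(2.5, abs=0.01)
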