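"""Equilibria, eigen-classification, codim-1 detection and limit-cycle
boundaries."""

import numpy as np
import pytest

from ihdyn import (
    ModelParameters, find_equilibria, fold_points_gh, hopf_gh, nf_gh,
    sweep_1d, classify_hopf, locate_cycle_boundary, run_spikes,
    settle_to_equilibrium, jacobian, rhs,
)
from ihdyn.bifurcation import (
    classify_eigenvalues, firing_onset_gh, locate_codim2,
    stable_behavior_partition, _lower_equilibrium,
)
from ihdyn.model import d_steady_state_current_dV


class TestFindEquilibria:
    def test_lower_branch_types_along_gh(self):
        # below / inside / past the focus window of the resting branch
        assert _lower_equilibrium(0.08, 0.01).etype == "stable_node"
        assert _lower_equilibrium(0.08, 0.02).etype == "stable_focus"
        eqs = find_equilibria(ModelParameters(Iapp=0.08, gh=0.03))
        assert not any(e.is_stable for e in eqs)   # past the fold: firing only

    def test_three_branch_structure(self):
        eqs = find_equilibria(ModelParameters(Iapp=0.08, gh=0.02))
        assert [e.etype for e in eqs] == ["stable_focus", "saddle", "unstable_focus"]

    def test_residuals_and_refined_scan_agree(self):
        p = ModelParameters(Iapp=-0.05, gh=0.05)
        eqs = find_equilibria(p)
        fine = find_equilibria(p, n_scan=100001)
        assert len(eqs) == len(fine)
        for a, b in zip(eqs, fine):
            assert abs(a.V - b.V) < 1e-8
            assert np.linalg.norm(rhs(a.state, p)) < 1e-9

    def test_classification_stable_under_fd_jacobian(self, rng):
        # eigen-typing must not depend on the analytic-vs-numeric Jacobian
        for _ in range(40):
            iapp = rng.uniform(-0.3, 0.05)
            gh = rng.uniform(0.0, 0.05)
            p = ModelParameters(Iapp=iapp, gh=gh)
            eq = find_equilibria(p)[0]
            step = 1e-6
            Jfd = np.empty((4, 4))
            for j in range(4):
                e = np.zeros(4)
                e[j] = step
                Jfd[:, j] = (rhs(eq.state + e, p) - rhs(eq.state - e, p)) / (2 * step)
            assert classify_eigenvalues(np.linalg.eigvals(Jfd)) == eq.etype


class TestCodim1Conditions:
    def test_fold_defining_conditions(self):
        for iapp in (0.08, -0.05):
            bp = fold_points_gh(iapp)[0]
            p = ModelParameters(Iapp=iapp, gh=bp.gh)
            # dI_ss/dV = 0 at the fold V, and the Jacobian has a near-zero eigenvalue
            assert abs(d_steady_state_current_dV(bp.V, p)) < 1e-7
            assert np.min(np.abs(bp.eigenvalues)) < 1e-6

    def test_hopf_defining_condition(self):
        bp = hopf_gh(-0.05, (0.055, 0.0623))
        eigs = bp.eigenvalues[np.argsort(-bp.eigenvalues.real)]
        assert abs(eigs[0].real) < 1e-6
        assert abs(eigs[0].imag) > 1e-3

    def test_nf_collision_condition(self):
        bp = nf_gh(0.08, (0.01, 0.02))
        eigs = bp.eigenvalues[np.argsort(-bp.eigenvalues.real)]
        # at the collision the two leading eigenvalues nearly coincide
        assert abs(eigs[0] - eigs[1]) < 1e-3

    def test_sweep_detects_fold_and_nf(self):
        d = sweep_1d(0.08, gh_range=(0.0, 0.03), n_grid=61)
        kinds = {bp.kind for bp in d.points}
        assert "SN" in kinds and "NF" in kinds
        fold = next(bp for bp in d.points if bp.kind == "SN")
        nf = next(bp for bp in d.points if bp.kind == "NF")
        assert nf.gh < fold.gh


class TestCycleBoundaries:
    def test_hopf_is_subcritical_with_bistability(self):
        gh_h = hopf_gh(-0.05, (0.055, 0.0623)).gh
        assert classify_hopf(-0.05, gh_h) == "sub"
        # two attractors just below the Hopf: rest-start stays subthreshold,
        # spike-start keeps firing
        p = ModelParameters(Iapp=-0.05, gh=gh_h - 5e-4)
        x_rest = settle_to_equilibrium(p)
        st, _ = run_spikes(p, x0=x_rest, t_end=3000.0)
        assert len(st) == 0
        st, _ = run_spikes(p, x0=np.array([-55.0, 0.6, 0.2, 0.2]), t_end=3000.0)
        assert len(st) > 5

    def test_cycle_boundary_brackets_validated(self):
        with pytest.raises(ValueError):
            locate_cycle_boundary(-0.05, 0.055, 0.07)

    def test_simulation_consistent_with_firing_border(self):
        # just beyond the firing onset the model spikes from rest-like
        # states; just inside, the resting state is an attractor
        i_bt = 0.0424
        for iapp in (-0.05, 0.0, 0.08):
            onset = firing_onset_gh(iapp, i_bt)
            p_out = ModelParameters(Iapp=iapp, gh=onset + 5e-4)
            assert not any(e.is_stable for e in find_equilibria(p_out)) or \
                len(run_spikes(p_out, x0=np.array([-55.0, 0.6, 0.2, 0.2]),
                               t_end=4000.0)[0]) >= 2
            p_in = ModelParameters(Iapp=iapp, gh=max(onset - 5e-4, 0.0))
            assert any(e.is_stable for e in find_equilibria(p_in))


class TestPartitionAndCodim2:
    def test_four_behaviors_ordered_at_negative_iapp(self):
        gh = np.array([0.01, 0.05, 0.0615, 0.065])
        labels = stable_behavior_partition(np.array([-0.05]), gh, window=6000.0)
        assert list(labels[:, 0]) == ["stable_node", "stable_focus",
                                      "coexistence", "firing"]

    def test_focus_region_labels(self):
        labels = stable_behavior_partition(np.array([0.08]),
                                           np.array([0.01, 0.02]), window=4000.0)
        assert list(labels[:, 0]) == ["stable_node", "stable_focus"]

    def test_bt_point_lies_on_fold_with_double_zero(self):
        bt = locate_codim2("BT")
        fold = fold_points_gh(bt.Iapp)[0]
        assert fold.gh == pytest.approx(bt.gh, abs=1e-6)
        eigs = np.sort(np.abs(bt.eigenvalues))
        assert eigs[0] < 1e-6 and eigs[1] < 1e-3
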