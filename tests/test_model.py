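"""Gating kinetics, currents, right-hand side and Jacobian of the CSC model."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import cscburst as cb
from cscburst.model import ca_balance, state_at_voltage
from cscburst.params import PARAM_FIELDS


class TestGateSteadyState:
    def test_midpoint_is_half(self):
        assert cb.gate_steady_state(-37.0, -37.0, 3.0) == pytest.approx(0.5)

    def test_pre_runup_na_activation_midpoint(self, pre):
        # Na+ activation half-point sits at the tabulated v_m
        assert cb.gate_steady_state(pre.v_m, pre.v_m, pre.s_m) == pytest.approx(0.5)

    def test_limits(self):
        assert cb.gate_steady_state(1e3, -40.0, -4.0) == pytest.approx(0.0, abs=1e-12)
        assert cb.gate_steady_state(1e3, -40.0, 4.0) == pytest.approx(1.0, abs=1e-12)

    def test_zero_slope_rejected(self):
        with pytest.raises(ValueError):
            cb.gate_steady_state(-50.0, -40.0, 0.0)

    @settings(max_examples=50, deadline=None)
    @given(v=st.floats(-80, -10), s=st.floats(1.0, 15),
           dv=st.floats(0.1, 10))
    def test_monotonicity_and_range(self, v, s, dv):
        lo = cb.gate_steady_state(v - dv, v, s)
        hi = cb.gate_steady_state(v + dv, v, s)
        assert 0.0 < lo < hi < 1.0
        # inactivation (negative slope) flips the ordering
        assert cb.gate_steady_state(v - dv, v, -s) > cb.gate_steady_state(v + dv, v, -s)


class TestTimeConstants:
    def test_tau_h_peak_value(self, post):
        # peak at Vc equals y0 + 2A/w
        expected = post.y0 + 2.0 * post.A / post.w
        assert cb.tau_h(post.Vc, post) == pytest.approx(expected)
        assert expected == pytest.approx(14.1, abs=0.05)

    def test_tau_h_symmetric_and_baseline(self, post):
        assert cb.tau_h(post.Vc + 10, post) == pytest.approx(cb.tau_h(post.Vc - 10, post))
        assert cb.tau_h(post.Vc + 1e5, post) == pytest.approx(post.y0, rel=1e-4)

    def test_tau_n_examples(self):
        assert cb.tau_n(-23.0) == pytest.approx(3.0)
        assert cb.tau_n(-1e3) == pytest.approx(6.0)
        assert cb.tau_n(1e3) == pytest.approx(0.0, abs=1e-12)
        V = np.linspace(-100, 20, 50)
        assert np.all(np.diff(cb.tau_n(V)) < 0)


class TestIonicCurrents:
    def test_currents_vanish_at_reversal(self, post):
        y = state_at_voltage(post.E_K, post)
        c = cb.ionic_currents(y, post)
        assert c.I_K == pytest.approx(0.0)
        assert c.I_A == pytest.approx(0.0)
        assert c.I_KCa == pytest.approx(0.0)
        y = state_at_voltage(post.E_Ca, post)
        c = cb.ionic_currents(y, post)
        assert c.I_T == pytest.approx(0.0)
        assert c.I_HVA == pytest.approx(0.0)

    def test_kca_hill_half_activation(self, post):
        # at Ca = k_Ca the fifth-order Hill factor is exactly 1/2
        y = state_at_voltage(-50.0, post, Ca=post.k_Ca)
        c = cb.ionic_currents(y, post)
        expected = post.g_KCa * 0.5 * (-50.0 - post.E_K)
        assert c.I_KCa == pytest.approx(expected)

    def test_only_leak_with_zeroed_gates(self, post):
        y = np.array([post.E_Ca, 0, 0, 0, 0, 0, 0, 0.0])
        c = cb.ionic_currents(y, post)
        assert c.I_Na == c.I_K == c.I_A == c.I_T == c.I_HVA == c.I_KCa == 0.0
        assert c.I_L == pytest.approx(post.g_L * (post.E_Ca - post.E_L))


class TestRhs:
    def test_pure_extrusion_when_ca_currents_off(self, post):
        p = post.replace(g_T=0.0, g_HVA=0.0)
        y = state_at_voltage(-50.0, p, Ca=0.3)
        assert cb.rhs(y, p)[7] < 0.0

    def test_dca_equals_flux_balance_form(self, post):
        y = state_at_voltage(-55.0, post, Ca=0.2)
        c = cb.ionic_currents(y, post)
        expected = -post.eps * (post.alpha * (c.I_T + c.I_HVA) + post.k * 0.2)
        assert cb.rhs(y, post)[7] == pytest.approx(expected)

    def test_non_finite_state_rejected(self, post):
        y = state_at_voltage(-60.0, post)
        y[0] = np.nan
        with pytest.raises(ValueError):
            cb.rhs(y, post)

    def test_finite_difference_of_trajectory_matches_rhs(self, post, tonic_traj):
        # central differences of the integrated V course reproduce dV/dt
        t, states = tonic_traj.times, tonic_traj.states
        sl = slice(20000, 24000)
        dV_fd = np.gradient(states[sl, 0], t[sl])
        dV_rhs = np.array([cb.rhs(y, post)[0] for y in states[sl]])
        err = np.sqrt(np.mean((dV_fd - dV_rhs) ** 2))
        assert err < 0.02 * np.sqrt(np.mean(dV_rhs ** 2))


class TestFastSubsystem:
    def test_matches_full_rhs_components(self, post, tonic_traj):
        y = tonic_traj.states[50000]
        full = cb.rhs(y, post)
        fast = cb.fast_subsystem_rhs(y[[0, 1, 2, 3, 5, 6]], y[4], y[7], post)
        assert np.allclose(fast, full[[0, 1, 2, 3, 5, 6]], rtol=1e-12)

    def test_fast_equilibrium_embeds_into_full_system(self, post):
        eqs = cb.find_fast_equilibria(post, hA=0.05, Ca=0.2)
        assert eqs
        for yf in eqs:
            res = cb.fast_subsystem_rhs(yf, 0.05, 0.2, post)
            assert np.max(np.abs(res)) < 1e-9

    def test_frozen_pair_validated(self, post):
        with pytest.raises(ValueError):
            cb.fast_subsystem_rhs(np.zeros(6), hA=1.5, Ca=0.1, params=post)


class TestJacobian:
    @pytest.mark.parametrize("V", [-80.0, -55.0, -30.0])
    def test_matches_finite_differences(self, post, V):
        y = state_at_voltage(V, post, Ca=0.2, hA=0.1)
        J = cb.jacobian(y, post)
        Jfd = np.zeros((8, 8))
        for j in range(8):
            e = 1e-6 * max(1.0, abs(y[j]))
            yp, ym = y.copy(), y.copy()
            yp[j] += e
            ym[j] -= e
            Jfd[:, j] = (cb.rhs(yp, post) - cb.rhs(ym, post)) / (2 * e)
        assert np.allclose(J, Jfd, rtol=1e-5, atol=1e-8 * np.abs(Jfd).max())

    def test_constant_tau_gate_diagonal(self, post):
        y = state_at_voltage(-60.0, post)
        J = cb.jacobian(y, post)
        assert J[3, 3] == pytest.approx(-1.0 / post.tau_nA)
        assert J[4, 4] == pytest.approx(-1.0 / post.tau_hA)
        assert J[5, 5] == pytest.approx(-1.0 / post.tau_hT)
        assert J[6, 6] == pytest.approx(-1.0 / post.tau_mHVA)

    def test_ca_row_structure(self, post):
        y = state_at_voltage(-60.0, post, Ca=0.3)
        J = cb.jacobian(y, post)
        assert J[7, 7] == pytest.approx(-post.eps * post.k)
        # Ca does not feed back on the Ca currents
        assert J[7, 1] == J[7, 2] == J[7, 3] == J[7, 4] == 0.0

    def test_fast_jacobian_is_submatrix(self, post):
        y = state_at_voltage(-45.0, post, Ca=0.25, hA=0.05)
        J8 = cb.jacobian(y, post)
        J6 = cb.fast_jacobian(y[[0, 1, 2, 3, 5, 6]], 0.05, 0.25, post)
        idx = [0, 1, 2, 3, 5, 6]
        assert np.allclose(J6, J8[np.ix_(idx, idx)])


class TestParameters:
    def test_presets_differ_only_in_runup_symbols(self, pre, post):
        changed = {n for n in PARAM_FIELDS
                   if getattr(pre, n) != getattr(post, n)}
        assert changed == {"v_m", "s_m", "v_h", "v_nA", "v_hA", "s_hA"}

    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            cb.ModelParameters.post_runup().replace(g_Na=-1.0)
        with pytest.raises(ValueError):
            cb.ModelParameters.post_runup().replace(C=0.0)
        with pytest.raises(KeyError):
            cb.ModelParameters.post_runup().replace(g_bogus=1.0)

    def test_json_round_trip(self, post):
        again = cb.ModelParameters.from_json(post.replace(g_HVA=0.3).to_json())
        assert again.g_HVA == 0.3
        assert again == post.replace(g_HVA=0.3)

    def test_ca_balance_zero_at_reversal(self, post):
        assert ca_balance(post.E_Ca, post) == 0.0
        assert ca_balance(-70.0, post) > 0.0
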