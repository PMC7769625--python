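"""Integration protocols, determinism and solver convergence."""
import numpy as np
import pytest

import cscburst as cb
from cscburst.simulate import SolverOptions


def test_leak_only_relaxes_exponentially(post):
    # with every conductance but leak removed the membrane is a linear RC
    # circuit: V relaxes to E_L with time constant C / g_L
    p = post.replace(g_Na=0, g_K=0, g_A=0, g_T=0, g_KCa=0, g_HVA=0)
    y0 = cb.state_at_voltage(-70.0, p)
    traj = cb.integrate(p, initial_state=y0, duration=200.0)
    tau = p.C / p.g_L
    expected = p.E_L + (-70.0 - p.E_L) * np.exp(-traj.times / tau)
    assert np.allclose(traj.V, expected, atol=0.01)


def test_tonic_firing_is_periodic(post, tonic_traj):
    from cscburst.features import analysis_window
    win = analysis_window(tonic_traj)
    st = cb.detect_spikes(win.times, win.V)
    assert st.size > 50
    isi = np.diff(st)
    assert isi.std() / isi.mean() < 0.01


def test_spike_upstrokes_resolved(tonic_traj):
    # consecutive output samples differ by < 2 mV even on the upstroke
    assert np.max(np.abs(np.diff(tonic_traj.V))) < 2.0


def test_deterministic_repeat(post):
    a = cb.integrate(post, duration=500.0)
    b = cb.integrate(post, duration=500.0)
    assert np.array_equal(a.states, b.states)


def test_tolerance_halving_moves_spikes_little(post):
    opts = SolverOptions(rtol=1e-8, atol=1e-10)
    tight = SolverOptions(rtol=5e-9, atol=5e-11)
    a = cb.integrate(post, duration=2000.0, solver_options=opts)
    b = cb.integrate(post, duration=2000.0, solver_options=tight)
    sa = cb.detect_spikes(a.times, a.V)
    sb = cb.detect_spikes(b.times, b.V)
    n = min(sa.size, sb.size)
    assert n > 10
    assert np.max(np.abs(sa[:n] - sb[:n])) < 0.5


class TestEquilibrateAtHold:
    def test_clamped_derivatives_vanish(self, post):
        y = cb.equilibrate_at_hold(post, -70.0)
        dy = cb.rhs(y, post)
        # with V clamped, every gate and Ca derivative is zero
        assert np.allclose(dy[1:], 0.0, atol=1e-12)

    def test_ca_zero_at_calcium_reversal(self, post):
        y = cb.equilibrate_at_hold(post.replace(E_Ca=-50.0), -50.0)
        assert y[7] == 0.0

    def test_out_of_range_hold_rejected(self, post):
        with pytest.raises(ValueError):
            cb.equilibrate_at_hold(post, +10.0)


class TestSynapticConductance:
    def test_peak_at_onset_plus_tau(self):
        assert cb.synaptic_conductance(55.0, peak=2.0, tau=5.0, onset=50.0) \
            == pytest.approx(2.0)

    def test_zero_before_onset(self):
        t = np.linspace(0.0, 49.9, 100)
        assert np.all(cb.synaptic_conductance(t, 2.0, 5.0, 50.0) == 0.0)

    def test_integral_closed_form(self):
        # integral over [onset, inf) equals peak * tau * e
        t = np.linspace(50.0, 50.0 + 400.0, 400001)
        g = cb.synaptic_conductance(t, peak=1.3, tau=4.0, onset=50.0)
        est = np.trapezoid(g, t)
        assert est == pytest.approx(1.3 * 4.0 * np.e, rel=1e-4)

    def test_synaptic_pair_protocol_perturbs_voltage(self, post):
        quiet = post.replace(I_app=-1.0)  # below firing threshold
        base = cb.integrate(quiet, duration=400.0,
                            protocol=cb.StimulusProtocol(kind="constant"))
        pert = cb.integrate(quiet, duration=400.0,
                            protocol=cb.StimulusProtocol(
                                kind="synaptic_pair", g_inh=0.5, g_exc=0.0,
                                t_onset=100.0))
        i = np.searchsorted(base.times, 105.0)
        # inhibition pulls V toward E_inh
        assert pert.V[i] < base.V[i]


def test_step_protocol_changes_current_at_t_step(post):
    p = post.replace(I_app=0.0)
    traj = cb.integrate(p, duration=600.0,
                        protocol=cb.StimulusProtocol(kind="step", I_bias=-2.0,
                                                     I_test=2.0, t_step=300.0))
    st = cb.detect_spikes(traj.times, traj.V)
    # hyperpolarized and silent before the step, spiking after
    assert np.all(st > 300.0)
    assert st.size >= 2


def test_phase_plane_cycle_closes(post, tonic_traj):
    loop = cb.phase_plane_cycle(tonic_traj)
    gap = np.linalg.norm(loop[0] - loop[-1])
    diam = np.max(np.ptp(loop, axis=0))
    assert gap < 0.01 * diam
    area = 0.5 * abs(np.sum(loop[:-1, 0] * loop[1:, 1] - loop[1:, 0] * loop[:-1, 1]))
    assert area > 0.0
    # dV/dt from the vector field matches differencing the V course
    dV_fd = np.gradient(loop[:, 0]) / np.gradient(
        np.linspace(0.0, 1.0, len(loop)))
    assert loop[:, 1].max() > 0 and loop[:, 1].min() < 0


def test_trajectory_window_and_export_roundtrip(tmp_path, post, tonic_traj):
    from cscburst.io import read_trace, write_trace
    sub = tonic_traj.window(1000.0, 2000.0)
    assert sub.times[0] >= 1000.0 and sub.times[-1] <= 2000.0
    path = tmp_path / "trace.tsv"
    write_trace(path, sub)
    back = read_trace(path)
    assert np.allclose(back.states, sub.states, atol=1e-9)
    assert back.params == sub.params
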