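"""Equilibrium continuation, eigenvalue certificates and Floquet analysis."""
import numpy as np
import pytest

import cscburst as cb
from cscburst.bifurcation import _flow_var, find_equilibria
from cscburst.model import _jac, _jac_fast


@pytest.fixture(scope="module")
def gkca_branch(post):
    """Full-system equilibrium branch in g_KCa (square-wave configuration)."""
    p = post.replace(g_HVA=0.249)
    return p, cb.continue_equilibria(p, "g_KCa", (0.1, 30.0))


@pytest.fixture(scope="module")
def zcurve(post):
    """Fast-subsystem equilibrium branch in hA at Ca = 0.25."""
    p = post.replace(g_HVA=0.249)
    return p, cb.continue_fast_equilibria(p, (0.45, 0.0), 0.25)


class TestFindEquilibria:
    def test_residuals_tiny(self, post):
        for y in find_equilibria(post):
            assert np.max(np.abs(cb.rhs(y, post))) < 1e-10

    def test_high_gkca_has_stable_equilibrium(self, post):
        p = post.replace(g_KCa=30.0, g_HVA=0.249)
        eqs = find_equilibria(p)
        assert eqs
        stable = [np.all(np.linalg.eigvals(_jac(y, p.to_vector())).real < 0)
                  for y in eqs]
        assert any(stable)

    def test_closed_form_reduction_consistency(self, post):
        # every root satisfies: gates at steady state, Ca at flux balance
        for y in find_equilibria(post):
            rebuilt = cb.state_at_voltage(y[0], post)
            assert np.allclose(y, rebuilt, atol=1e-12)


class TestContinuation:
    def test_oracle_equivalence(self, gkca_branch):
        # continuation points match the scalar-reduction roots in V
        p, br = gkca_branch
        for i in range(0, len(br.params), 10):
            eqs = find_equilibria(p.replace(g_KCa=float(br.params[i])))
            dv = min(abs(y[0] - br.states[i][0]) for y in eqs)
            assert dv < 1e-8

    def test_stability_flag_matches_eigenvalues(self, gkca_branch):
        _, br = gkca_branch
        assert np.array_equal(br.stable,
                              np.all(br.eigenvalues.real < 0, axis=1))

    def test_two_hopf_events_bracket_unstable_segment(self, gkca_branch):
        _, br = gkca_branch
        hbs = [e for e in br.events if e.kind == "HB"]
        assert len(hbs) == 2
        lo, hi = sorted(e.param for e in hbs)
        mid = (br.params > lo * 1.5) & (br.params < hi * 0.8)
        assert mid.any() and not br.stable[mid].any()

    def test_hopf_certificates(self, gkca_branch):
        _, br = gkca_branch
        for e in br.events:
            ev = e.data["eigenvalues"]
            if e.kind == "HB":
                cplx = ev[ev.imag > 1e-8]
                assert cplx.size >= 1
                assert np.min(np.abs(cplx.real)) < 1e-4
            else:
                real = ev[np.abs(ev.imag) < 1e-8].real
                assert np.min(np.abs(real)) < 1e-4

    def test_locate_hopf_agrees_with_branch_event(self, gkca_branch):
        p, br = gkca_branch
        hb2 = max(e.param for e in br.events if e.kind == "HB")
        located = cb.locate_hopf_in_parameter(p, "g_KCa", (10.0, 30.0))
        assert located == pytest.approx(hb2, rel=0.01)

    def test_forward_backward_symmetry(self, post):
        p = post.replace(g_HVA=0.249)
        fwd = cb.continue_fast_equilibria(p, (0.2, 0.3), 0.25)
        bwd = cb.continue_fast_equilibria(p, (0.3, 0.2), 0.25,
                                          x0=fwd.states[-1])
        assert abs(bwd.params[-1] - fwd.params[0]) < 5e-3
        assert abs(bwd.states[-1][0] - fwd.states[0][0]) < 0.1


class TestZCurve:
    def test_two_folds_and_one_upper_hopf(self, zcurve):
        _, br = zcurve
        kinds = sorted(e.kind for e in br.events)
        assert kinds == ["HB", "SN", "SN"]
        sn = sorted(e.param for e in br.events if e.kind == "SN")
        hb = [e.param for e in br.events if e.kind == "HB"][0]
        assert sn[0] < hb < sn[1]

    def test_lower_branch_stable_middle_saddle(self, zcurve):
        p, _ = zcurve
        for hA in (0.02, 0.04):
            eqs = cb.find_fast_equilibria(p, hA, 0.25)
            assert len(eqs) == 3
            vs = sorted(eqs, key=lambda y: y[0])
            ev_lo = np.linalg.eigvals(_jac_fast(vs[0], p.to_vector(), hA, 0.25))
            ev_mid = np.linalg.eigvals(_jac_fast(vs[1], p.to_vector(), hA, 0.25))
            assert ev_lo.real.max() < 0
            assert (ev_mid.real > 0).any() and (ev_mid.real < 0).any()


class TestSNIC:
    def test_iapp_fold_is_snic_post_runup(self, post):
        br = cb.continue_equilibria(post, "I_app", (-3.0, 1.0))
        sns = [e for e in br.events if e.kind == "SN"]
        assert sns
        fold = max(sns, key=lambda e: e.param)
        res = cb.classify_snic(post, "I_app", fold.param, duration=5000.0)
        assert res["label"] == "SNIC"
        assert res["r_squared"] > 0.99
        # type I excitability: arbitrarily low onset frequencies
        assert res["frequencies_Hz"].min() < 10.0


class TestPeriodicOrbits:
    def test_trivial_multiplier_and_stability(self, post, fast_orbit_seed):
        seed, hA, Ca = fast_orbit_seed
        y0, T = cb.periodic_orbit_from_simulation(post, hA, Ca, seed)
        assert T > 1.0
        _, M = _flow_var(post.to_vector(), y0, T, hA, Ca)
        mults = np.linalg.eigvals(M)
        trivial = mults[np.argmin(np.abs(mults - 1.0))]
        assert abs(trivial - 1.0) < 1e-4
        nontrivial = np.delete(mults, np.argmin(np.abs(mults - 1.0)))
        # the orbit was found by forward simulation, hence stable
        assert np.all(np.abs(nontrivial) < 1.0 + 1e-6)

    def test_short_continuation_keeps_certificates(self, post, fast_orbit_seed):
        seed, hA, Ca = fast_orbit_seed
        y0, T = cb.periodic_orbit_from_simulation(post, hA, Ca, seed)
        br = cb.continue_periodic_orbit(post, Ca, y0, T, hA, direction=+1.0,
                                        max_points=12)
        assert len(br.params) >= 5
        for m in br.multipliers:
            trivial = m[np.argmin(np.abs(m - 1.0))]
            assert abs(trivial - 1.0) < 1e-4


class TestRegimeSweep:
    def test_uniform_tonic_block(self, post):
        grid1 = np.array([0.9, 1.0, 1.1])
        grid2 = np.array([0.07, 0.08])
        rmap = cb.regime_sweep(post, ("g_KCa", grid1), ("g_HVA", grid2),
                               duration=6000.0)
        assert set(rmap.labels.ravel()) == {"T"}

    def test_grid_size_guard(self, post):
        with pytest.raises(ValueError):
            cb.regime_sweep(post, ("g_KCa", np.zeros(300)),
                            ("g_HVA", np.zeros(300)))
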