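"""Critical manifold, two-parameter bifurcation sets and burst overlays."""
import numpy as np
import pytest

import cscburst as cb
from cscburst.slowfast import _roots_and_stability


@pytest.fixture(scope="module")
def sw_params(post):
    return post.replace(g_HVA=0.235)


@pytest.fixture(scope="module")
def sw_manifold(sw_params):
    return cb.compute_critical_manifold(
        sw_params, hA_grid=np.linspace(0.0, 0.08, 33),
        Ca_grid=np.linspace(0.15, 0.35, 9), n_v=601)


@pytest.fixture(scope="module")
def sw_overlay(sw_params, sw_manifold):
    traj = cb.integrate(sw_params, duration=20000.0)
    return cb.overlay_burst(traj, sw_manifold, sw_manifold.folds)


class TestCriticalManifold:
    def test_root_count_one_or_three(self, sw_manifold):
        counts = {sw_manifold.V_sheets[j, i].size
                  for j in range(sw_manifold.Ca_grid.size)
                  for i in range(sw_manifold.hA_grid.size)}
        assert counts <= {1, 3}
        assert 3 in counts

    def test_sheet_stability(self, sw_manifold):
        # wherever three sheets exist: lower stable, middle unstable
        for j in range(sw_manifold.Ca_grid.size):
            for i in range(sw_manifold.hA_grid.size):
                roots = sw_manifold.V_sheets[j, i]
                if roots.size == 3:
                    order = np.argsort(roots)
                    mre = sw_manifold.max_re[j, i][order]
                    assert mre[0] < 0
                    assert mre[1] > 0

    def test_fold_curves_present_and_ordered(self, sw_manifold):
        assert sw_manifold.folds["SN1"].size > 0
        assert sw_manifold.folds["SN2"].size > 0
        # at matching Ca the lower-sheet fold sits at smaller hA
        sn1 = sw_manifold.folds["SN1"]
        sn2 = sw_manifold.folds["SN2"]
        ca_common = set(np.round(sn1[:, 1], 6)) & set(np.round(sn2[:, 1], 6))
        assert ca_common
        for ca in list(ca_common)[:3]:
            h1 = sn1[np.isclose(sn1[:, 1], ca), 0].min()
            h2 = sn2[np.isclose(sn2[:, 1], ca), 0].max()
            assert h1 < h2

    def test_slice_matches_continuation(self, sw_params):
        # manifold roots agree with the pseudo-arclength Z-curve in V
        br = cb.continue_fast_equilibria(sw_params, (0.3, 0.0), 0.25)
        pvec = sw_params.to_vector()
        for i in range(0, len(br.params), 200):
            hA = float(br.params[i])
            if not 0.0 <= hA <= 1.0:
                continue
            roots, _ = _roots_and_stability(sw_params, pvec, hA, 0.25,
                                            (-120.0, 20.0), 1401)
            assert np.min(np.abs(roots - br.states[i][0])) < 1e-6


class TestBifurcationSet2D:
    def test_sn_and_hb_loci_track_across_ca(self, sw_params):
        curves = cb.bifurcation_set_2d(sw_params,
                                       np.linspace(0.18, 0.30, 5),
                                       hA_max=0.12, n_v=801)
        # the upper fold and the Hopf persist across the whole Ca range;
        # the lower fold terminates at a cusp at higher Ca
        assert curves["SN2"].shape[0] == 5
        assert {round(q, 3) for q in curves["HB"][:, 1]} \
            == {0.18, 0.21, 0.24, 0.27, 0.3}
        assert curves["SN1"].shape[0] >= 3
        # near-parallel copies: the loci drift monotonically with Ca
        assert np.all(np.diff(curves["SN2"][:, 0]) < 0)
        hb_min = [curves["HB"][curves["HB"][:, 1] == ca, 0].min()
                  for ca in sorted(set(curves["HB"][:, 1]))]
        assert np.all(np.diff(hb_min) < 0)


class TestOverlay:
    def test_phases_alternate_and_spikes_in_active(self, sw_overlay):
        ph = sw_overlay.phase
        changes = np.sum(ph[1:] != ph[:-1])
        assert changes >= 6
        st = cb.detect_spikes(sw_overlay.times, sw_overlay.V)
        for ts in st:
            k = np.searchsorted(sw_overlay.times, ts)
            assert ph[min(k, ph.size - 1)] == "active"

    def test_ca_rises_in_active_falls_in_silent(self, sw_overlay):
        runs = []
        cur, start = sw_overlay.phase[0], 0
        for k in range(1, sw_overlay.phase.size):
            if sw_overlay.phase[k] != cur:
                runs.append((cur, start, k))
                cur, start = sw_overlay.phase[k], k
        interior = runs[1:-1]
        assert interior
        for ph, a, b in interior:
            net = sw_overlay.Ca[b - 1] - sw_overlay.Ca[a]
            if ph == "active":
                assert net > 0
            else:
                assert net < 0

    def test_burst_initiation_at_sn1_crossing(self, sw_overlay):
        # every silent->active transition is preceded by an SN1 fold
        # crossing a fold-ghost transit (<~100 ms) earlier
        onsets = [sw_overlay.times[k] for k in range(1, sw_overlay.phase.size)
                  if sw_overlay.phase[k] == "active"
                  and sw_overlay.phase[k - 1] == "silent"]
        sn1_t = np.array([c["t"] for c in sw_overlay.crossings
                          if c["curve"] == "SN1"])
        assert onsets and sn1_t.size
        for t_on in onsets[1:-1]:
            before = sn1_t[sn1_t <= t_on]
            assert before.size and t_on - before.max() < 100.0

    def test_silent_phase_tracks_lower_sheet(self, sw_overlay):
        assert sw_overlay.silent_sheet_agreement >= 0.8

    def test_non_bursting_trajectory_rejected(self, post, tonic_traj,
                                              sw_manifold):
        with pytest.raises(ValueError):
            cb.overlay_burst(tonic_traj, sw_manifold, {})


class TestPseudoPlateauDissection:
    def test_isola_absent_near_lower_fold(self, post, fast_orbit_seed):
        # in the pseudo-plateau configuration the isolated spiking family
        # near the lower fold is missing: the frozen fast subsystem relaxes
        # to an equilibrium from a mid-spike state
        p = post.replace(g_K=12.0, g_KCa=7.0, g_HVA=0.22)
        # pick a node inside the three-sheet wedge of this configuration
        hA, Ca = 0.01, 0.2
        assert len(cb.find_fast_equilibria(p, hA, Ca)) == 3
        seed, _, _ = fast_orbit_seed
        with pytest.raises((ValueError, RuntimeError)):
            cb.periodic_orbit_from_simulation(p, hA, Ca, seed)
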