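"""Slow-fast dissection: critical manifold, bifurcation sets and burst overlays.

The two slowest variables of the model, the A-type inactivation gate ``hA``
and the cytosolic Ca2+ concentration, are treated as parameters of the
6-variable fast subsystem.  The surface of fast-subsystem equilibria over
the (hA, Ca) plane — the critical manifold — is Z-shaped in hA: a stable
lower sheet (the silent phase), a saddle middle sheet and an upper sheet
whose stability is lost at a Hopf curve.  Square-wave bursts jump to the
spiking branch at the lower fold (SN1) and fall back near the homoclinic
termination of the fast-subsystem orbits; pseudo-plateau bursts spiral
along the upper sheet past the Hopf curve (slow passage) and leave at SN2.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .bifurcation import (BranchEvent, continue_periodic_orbit,
                          find_fast_equilibria,
                          periodic_orbit_from_simulation, _current_balance)
from .features import DetectorSettings, analysis_window, detect_spikes, segment_bursts
from .model import FAST_INDICES, _jac_fast, state_at_voltage
from .params import ModelParameters
from .simulate import Trajectory

__all__ = ["CriticalManifold", "BurstOverlay", "compute_critical_manifold",
           "bifurcation_set_2d", "overlay_burst", "fast_homoclinic_scan",
           "square_wave_homoclinic_scan", "find_isolated_orbit"]

log = logging.getLogger(__name__)


@dataclass
class CriticalManifold:
    hA_grid: np.ndarray
    Ca_grid: np.ndarray
    #: object array (nCa, nhA) of 1-D arrays of equilibrium V values
    V_sheets: np.ndarray
    #: object array of matching max-real-part arrays (stability certificates)
    max_re: np.ndarray
    #: fold loci: dict sheet-name -> (n, 2) array of (hA, Ca)
    folds: dict[str, np.ndarray] = field(default_factory=dict)
    #: Hopf locus on the upper sheet, (n, 2) array of (hA, Ca)
    hopf: np.ndarray | None = None

    def roots_at(self, iCa: int, ihA: int) -> np.ndarray:
        return self.V_sheets[iCa, ihA]


@dataclass
class BurstOverlay:
    times: np.ndarray
    hA: np.ndarray
    Ca: np.ndarray
    V: np.ndarray
    phase: np.ndarray          # 'active' | 'silent'
    crossings: list[dict] = field(default_factory=list)
    silent_sheet_agreement: float = np.nan


def _roots_and_stability(params, pvec, hA, Ca, v_range, n_grid):
    Vs = np.linspace(*v_range, n_grid)
    fs = np.array([_current_balance(V, pvec, params, hA=hA, Ca=Ca) for V in Vs])
    roots = []
    for i in range(n_grid - 1):
        if fs[i] * fs[i + 1] < 0:
            roots.append(brentq(_current_balance, Vs[i], Vs[i + 1],
                                args=(pvec, params, hA, Ca), xtol=1e-12))
    mres = []
    for V in roots:
        yf = state_at_voltage(V, params, Ca=Ca, hA=hA)[list(FAST_INDICES)]
        ev = np.linalg.eigvals(_jac_fast(yf, pvec, hA, Ca))
        mres.append(ev.real.max())
    return np.array(roots), np.array(mres)


def compute_critical_manifold(params: ModelParameters,
                              hA_grid: np.ndarray | None = None,
                              Ca_grid: np.ndarray | None = None,
                              v_range=(-120.0, 20.0),
                              n_v: int = 1401) -> CriticalManifold:
    """Fast-subsystem equilibrium surface over an (hA, Ca) grid.

    Per node, all roots of the scalar voltage balance are found by dense
    bracketing; stability comes from the 6x6 Jacobian.  Fold curves are the
    loci where the root count changes between adjacent hA nodes; the Hopf
    locus is found by bisection of the upper sheet's leading complex pair.
    """
    if hA_grid is None:
        hA_grid = np.linspace(0.0, 1.0, 201)
    if Ca_grid is None:
        Ca_grid = np.linspace(0.0, 0.8, 81)
    hA_grid = np.asarray(hA_grid, float)
    Ca_grid = np.asarray(Ca_grid, float)
    pvec = params.to_vector()
    nC, nH = Ca_grid.size, hA_grid.size
    V_sheets = np.empty((nC, nH), dtype=object)
    max_re = np.empty((nC, nH), dtype=object)
    for j, Ca in enumerate(Ca_grid):
        for i, hA in enumerate(hA_grid):
            r, m = _roots_and_stability(params, pvec, hA, Ca, v_range, n_v)
            V_sheets[j, i] = r
            max_re[j, i] = m

    # fold curves: root-count change refined by bisection in hA
    def count(hA, Ca):
        r, _ = _roots_and_stability(params, pvec, hA, Ca, v_range, n_v)
        return r.size

    sn1_pts, sn2_pts = [], []
    for j, Ca in enumerate(Ca_grid):
        counts = np.array([V_sheets[j, i].size for i in range(nH)])
        for i in range(nH - 1):
            if counts[i] != counts[i + 1]:
                a, b = hA_grid[i], hA_grid[i + 1]
                ca_, cb_ = counts[i], counts[i + 1]
                for _ in range(30):
                    m = 0.5 * (a + b)
                    cm = count(m, Ca)
                    if cm == ca_:
                        a = m
                    else:
                        b = m
                hA_f = 0.5 * (a + b)
                # classify which fold by the V of the merging pair
                r, _ = _roots_and_stability(params, pvec,
                                            a if ca_ > cb_ else b, Ca,
                                            v_range, n_v)
                if r.size >= 3:
                    merging_low = True if counts[i] < counts[i + 1] else None
                # lower fold (SN1) merges the two lowest roots
                pair_v = np.sort(r)[:2].mean() if r.size >= 2 else np.nan
                all_mid = np.median(r) if r.size else np.nan
                if pair_v <= all_mid:
                    sn1_pts.append((hA_f, Ca))
                else:
                    sn2_pts.append((hA_f, Ca))

    # distinguish folds more robustly: SN1 = smaller hA? Not in general.
    # Use the V level of the disappearing pair computed above.
    folds = {}
    if sn1_pts or sn2_pts:
        pts = np.array(sn1_pts + sn2_pts)
        # re-split by per-Ca ordering: for each Ca the lower-hA fold is SN2
        # (upper knee) or SN1 depending on orientation; classify by V of the
        # middle/lower sheet merge instead: recompute per point.
        sn_lo, sn_hi = [], []
        for hA_f, Ca in pts:
            r, _ = _roots_and_stability(params, pvec, hA_f - 1e-4, Ca, v_range, n_v)
            r2, _ = _roots_and_stability(params, pvec, hA_f + 1e-4, Ca, v_range, n_v)
            rich = r if r.size > r2.size else r2
            if rich.size < 3:
                continue
            rich = np.sort(rich)
            # which adjacent pair is closest to merging?
            d_low = rich[1] - rich[0]
            d_hi = rich[2] - rich[1]
            (sn_lo if d_low < d_hi else sn_hi).append((hA_f, Ca))
        folds["SN1"] = np.array(sorted(sn_lo, key=lambda q: q[1])) if sn_lo else np.empty((0, 2))
        folds["SN2"] = np.array(sorted(sn_hi, key=lambda q: q[1])) if sn_hi else np.empty((0, 2))

    # Hopf locus on the upper sheet
    def upper_pair_re(hA, Ca):
        r, _ = _roots_and_stability(params, pvec, hA, Ca, v_range, n_v)
        if r.size == 0:
            return np.nan
        V = np.max(r)
        yf = state_at_voltage(V, params, Ca=Ca, hA=hA)[list(FAST_INDICES)]
        ev = np.linalg.eigvals(_jac_fast(yf, pvec, hA, Ca))
        cplx = ev[ev.imag > 1e-9]
        return cplx.real.max() if cplx.size else np.nan

    hopf_pts = []
    for j, Ca in enumerate(Ca_grid):
        vals = np.array([upper_pair_re(hA, Ca) for hA in hA_grid])
        for i in range(nH - 1):
            a, b = vals[i], vals[i + 1]
            if np.isnan(a) or np.isnan(b) or a * b >= 0:
                continue
            lo, hi = hA_grid[i], hA_grid[i + 1]
            fa = a
            for _ in range(30):
                m = 0.5 * (lo + hi)
                fm = upper_pair_re(m, Ca)
                if np.isnan(fm):
                    break
                if fa * fm <= 0:
                    hi = m
                else:
                    lo, fa = m, fm
            hopf_pts.append((0.5 * (lo + hi), Ca))
    hopf = np.array(sorted(hopf_pts, key=lambda q: q[1])) if hopf_pts else None
    return CriticalManifold(hA_grid, Ca_grid, V_sheets, max_re, folds, hopf)


def fast_homoclinic_scan(params: ModelParameters, Ca: float,
                         seed_state: np.ndarray | None = None,
                         hA_hint: float | None = None,
                         hb_hint: float | None = None,
                         max_points: int = 300) -> list[BranchEvent]:
    """All homoclinic-approach events of the fast subsystem at fixed Ca.

    Two orbit families are traced: (i) the isolated family of stable
    orbits near the lower fold, found by relaxation from ``seed_state`` and
    continued in both directions — its two ends terminate homoclinically
    (one beyond a period-doubling); and (ii) the family emanating from the
    subcritical Hopf on the upper sheet of the Z-curve, seeded from the
    linearization and continued until its homoclinic termination.  Returns
    the list of HC_approach events (with SNP/PD events interleaved).
    """
    events: list[BranchEvent] = []

    # family (i): isolated stable orbits near the lower fold
    if seed_state is not None and hA_hint is not None:
        try:
            y0, T = periodic_orbit_from_simulation(params, hA_hint, Ca, seed_state)
            for direction in (+1.0, -1.0):
                br = continue_periodic_orbit(params, Ca, y0, T, hA_hint,
                                             direction=direction,
                                             max_points=max_points)
                events.extend(br.events)
        except (ValueError, RuntimeError) as err:
            log.warning("isolated family tracing failed: %s", err)

    # family (ii): subcritical Hopf family on the upper sheet
    if hb_hint is not None:
        try:
            y0, T, hA_start = _seed_orbit_near_hopf(params, Ca, hb_hint)
            for direction in (-1.0, +1.0):
                br = continue_periodic_orbit(params, Ca, y0, T, hA_start,
                                             direction=direction,
                                             max_points=max_points)
                hcs = [e for e in br.events if e.kind == "HC_approach"]
                events.extend(br.events)
                if hcs:
                    break
        except (ValueError, RuntimeError) as err:
            log.warning("Hopf family tracing failed: %s", err)
    return events


def find_isolated_orbit(params: ModelParameters, Ca: float = 0.25):
    """Locate the isolated stable fast-subsystem orbit near the lower fold.

    Tries several mid-burst seed states of the full system and several hA
    values around the lower fold; returns ``(y0, T, hA)`` of the refined
    orbit.  Raises if no oscillating attractor is found (e.g. in the
    pseudo-plateau configuration, where the family is absent).
    """
    from .bifurcation import continue_fast_equilibria
    from .pipeline import burst_trajectory
    from .simulate import fast_state_from_full

    zbr = continue_fast_equilibria(params, (0.45, 0.0), Ca)
    sn = sorted(e.param for e in zbr.events if e.kind == "SN")
    if not sn:
        raise ValueError("no folds on the fast-subsystem equilibrium branch")
    traj = burst_trajectory(params)
    win = analysis_window(traj)
    st = detect_spikes(win.times, win.V)
    for k in (0, 2, 5):
        idx = len(st) // 2 + k
        if idx >= len(st):
            continue
        seed = fast_state_from_full(
            win.states[int(np.searchsorted(win.times, st[idx]))])
        for frac in (0.75, 1.0, 1.25, 0.5):
            try:
                y0, T = periodic_orbit_from_simulation(params, frac * sn[0],
                                                       Ca, seed)
                return y0, T, frac * sn[0]
            except (ValueError, RuntimeError):
                continue
    raise ValueError("no isolated fast-subsystem orbit found near the fold")


def square_wave_homoclinic_scan(params: ModelParameters, Ca: float = 0.25,
                                max_points: int = 300) -> dict:
    """End-to-end homoclinic census of the fast subsystem at fixed Ca.

    Computes the Z-curve (SN1, SN2, HB), seeds the isolated orbit family
    from a mid-burst state of the full system and the Hopf family from the
    upper-branch linearization, and traces all of them to their
    terminations.  Returns a dict with the Z-curve events and the periodic
    orbit events; in the square-wave configuration three distinct
    homoclinic approaches are found (one terminating the Hopf family, two
    terminating the isolated family).
    """
    from .bifurcation import continue_fast_equilibria
    from .pipeline import burst_trajectory
    from .simulate import fast_state_from_full

    zbr = continue_fast_equilibria(params, (0.45, 0.0), Ca)
    sn = sorted(e.param for e in zbr.events if e.kind == "SN")
    hb = [e.param for e in zbr.events if e.kind == "HB"]
    if not sn:
        raise ValueError("no folds on the fast-subsystem equilibrium branch")

    traj = burst_trajectory(params)
    win = analysis_window(traj)
    st = detect_spikes(win.times, win.V)
    seeds = []
    for k in (0, 2, 5):
        idx = len(st) // 2 + k
        if idx < len(st):
            i_mid = int(np.searchsorted(win.times, st[idx]))
            seeds.append(fast_state_from_full(win.states[i_mid]))

    events: list[BranchEvent] = []
    for seed in seeds:
        for frac in (0.75, 1.0, 1.25, 0.5):
            try:
                evs = fast_homoclinic_scan(params, Ca, seed_state=seed,
                                           hA_hint=frac * sn[0],
                                           hb_hint=hb[0] if hb else None,
                                           max_points=max_points)
            except (ValueError, RuntimeError):
                continue
            if sum(e.kind == "HC_approach" for e in evs) >= 3:
                events = evs
                break
            if len(evs) > len(events):
                events = evs
        else:
            continue
        break
    return {"z_events": zbr.events, "orbit_events": events,
            "n_homoclinic": sum(e.kind == "HC_approach" for e in events)}


def _seed_orbit_near_hopf(params: ModelParameters, Ca: float, hA_hb: float,
                          offsets=(2e-3, 4e-3, 1e-3),
                          amps=(2.0, 1.0, 3.0, 0.5)):
    """Small-amplitude periodic-orbit guess near a fast-subsystem Hopf.

    The guess is the upper-sheet equilibrium displaced along the real part
    of the critical eigenvector with period 2*pi/omega; it is polished by
    the shooting Newton iteration and accepted only if it remains a genuine
    orbit (does not collapse back onto the equilibrium).
    """
    from .bifurcation import _shoot_newton
    pvec = params.to_vector()
    for offset in offsets:
        for sign in (-1.0, +1.0):
            hA = hA_hb + sign * offset
            if not 0.0 <= hA <= 1.0:
                continue
            eqs = find_fast_equilibria(params, hA, Ca)
            if not eqs:
                continue
            yf = eqs[int(np.argmax([e[0] for e in eqs]))]
            J = _jac_fast(yf, pvec, hA, Ca)
            ev, vec = np.linalg.eig(J)
            icplx = np.where(ev.imag > 1e-9)[0]
            if icplx.size == 0:
                continue
            i = icplx[np.argmax(ev.real[icplx])]
            omega = ev.imag[i]
            v = vec[:, i].real
            v = v / np.linalg.norm(v)
            for amp in amps:
                y0, T, ok = _shoot_newton(pvec, yf + amp * v,
                                          2 * np.pi / omega, hA, Ca)
                if ok and T > 0 and np.linalg.norm(y0 - yf) > 0.3 * amp:
                    return y0, T, hA
    raise RuntimeError("could not seed an orbit near the Hopf point")


def bifurcation_set_2d(params: ModelParameters, Ca_grid: np.ndarray,
                       hA_max: float = 0.3, n_v: int = 1401,
                       include_orbits: bool = False,
                       seed_state: np.ndarray | None = None) -> dict[str, np.ndarray]:
    """Loci of fast-subsystem bifurcations in the (hA, Ca) plane.

    For each Ca the SN folds and the upper-sheet Hopf are located by
    bisection; with ``include_orbits`` the orbit families are continued as
    well and their SNP/PD/HC_approach events appended.  Returns a dict of
    curve label -> (n, 2) array of (hA, Ca) points (nearest-neighbour
    ordered in Ca).
    """
    man = compute_critical_manifold(params,
                                    hA_grid=np.linspace(0.0, hA_max, 61),
                                    Ca_grid=Ca_grid, n_v=n_v)
    curves: dict[str, list] = {"SN1": [], "SN2": [], "HB": []}
    for name in ("SN1", "SN2"):
        if name in man.folds:
            curves[name] = [tuple(q) for q in man.folds[name]]
    if man.hopf is not None:
        curves["HB"] = [tuple(q) for q in man.hopf]

    if include_orbits and seed_state is not None:
        for label in ("SNP", "PD", "HC"):
            curves.setdefault(label, [])
        for Ca in Ca_grid:
            sn1 = [q for q in curves["SN1"] if abs(q[1] - Ca) < 1e-12]
            hb = [q for q in curves["HB"] if abs(q[1] - Ca) < 1e-12]
            evs = fast_homoclinic_scan(
                params, Ca, seed_state=seed_state,
                hA_hint=sn1[0][0] if sn1 else None,
                hb_hint=hb[0][0] if hb else None)
            for e in evs:
                key = "HC" if e.kind == "HC_approach" else e.kind
                curves[key].append((e.param, Ca))

    return {k: np.array(sorted(v, key=lambda q: q[1])) if v else np.empty((0, 2))
            for k, v in curves.items()}


def overlay_burst(traj: Trajectory, manifold: CriticalManifold,
                  curves: dict[str, np.ndarray] | None = None,
                  settings: DetectorSettings | None = None) -> BurstOverlay:
    """Project a bursting trajectory onto the slow (hA, Ca) plane.

    Labels every sample active/silent (active spans are bursts padded to
    the surrounding sub-threshold crossings), records where the slow path
    crosses the fold curves, and measures how closely the silent phase
    tracks the lower stable sheet of the critical manifold.
    """
    s = settings or DetectorSettings()
    win = analysis_window(traj)
    t, V = win.times, win.V
    hA = win.column("hA")
    Ca = win.column("Ca")
    st = detect_spikes(t, V, s.threshold, s.min_separation)
    bursts = segment_bursts(st, s.gap_factor)
    if len(bursts) < 2:
        raise ValueError("overlay requires a bursting trajectory")

    phase = np.full(t.size, "silent", dtype="U6")
    level = s.plateau_level
    for b in bursts:
        i0 = np.searchsorted(t, b[0])
        i1 = np.searchsorted(t, b[-1])
        lo = i0
        while lo > 0 and V[lo - 1] > level:
            lo -= 1
        hi = i1
        while hi < V.size - 1 and V[hi + 1] > level:
            hi += 1
        phase[lo:hi + 1] = "active"

    crossings = []
    if curves:
        for name, pts in curves.items():
            if pts.size == 0:
                continue
            for k in range(t.size - 1):
                # crossing when hA passes the curve's hA at the nearest Ca
                ca_mid = 0.5 * (Ca[k] + Ca[k + 1])
                idx = np.argmin(np.abs(pts[:, 1] - ca_mid))
                hA_c = pts[idx, 0]
                if (hA[k] - hA_c) * (hA[k + 1] - hA_c) < 0:
                    crossings.append({"curve": name, "t": float(t[k]),
                                      "hA": float(hA_c), "Ca": float(ca_mid),
                                      "phase_after": str(phase[min(k + 1, t.size - 1)])})

    # silent-phase proximity to the lower stable sheet, evaluated with an
    # exact per-sample root solve (grid lookup would alias the sheet slope)
    sil = phase == "silent"
    agree = np.nan
    if sil.any():
        pvec = win.params.to_vector()
        good = 0
        tot = 0
        for k in np.where(sil)[0][::40]:
            roots, mres = _roots_and_stability(win.params, pvec, hA[k], Ca[k],
                                               (-120.0, 20.0), 701)
            stab = roots[mres < 0]
            # only samples where a lower (hyperpolarized) stable sheet
            # exists count: past the fold the silent trajectory is in
            # transit and has no sheet to track
            if stab.size == 0 or stab.min() > -45.0:
                continue
            tot += 1
            if np.abs(stab.min() - V[k]) < 2.0:
                good += 1
        agree = good / tot if tot else np.nan
    return BurstOverlay(t, hA, Ca, V, phase, crossings, agree)
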