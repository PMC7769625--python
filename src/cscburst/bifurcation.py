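"""Numerical continuation and bifurcation detection for the CSC model.

Equilibria of the full system are found through a closed-form reduction
(every gate at its steady state and Ca at flux balance leave a single scalar
current-balance equation in V) and continued in any model parameter by
pseudo-arclength continuation with Newton correction.  Saddle-node events
are certified by a real eigenvalue crossing zero, Hopf events by a complex
pair crossing the imaginary axis.

Periodic orbits of the frozen-(hA, Ca) fast subsystem are continued by
single shooting with the period as an unknown and an anchoring phase
condition; the monodromy matrix is computed by integrating the variational
equations, giving Floquet multipliers at every accepted point.  Saddle-node
(SNP) and period-doubling (PD) bifurcations of orbits are flagged from the
multipliers; homoclinic terminations are reported as *approach* events when
the period blows up while the orbit collides with a saddle equilibrium.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy.integrate import solve_ivp
from scipy.optimize import brentq
from scipy.stats import linregress

from .features import DetectorSettings, classify_regime, detect_spikes, analysis_window
from .model import (FAST_INDICES, _jac, _jac_fast, _rhs, _rhs_fast,
                    state_at_voltage)
from .params import PARAM_FIELDS, ModelParameters
from .simulate import SolverOptions, StimulusProtocol, Trajectory, integrate

__all__ = [
    "EquilibriumBranch", "PeriodicOrbitBranch", "RegimeMap",
    "find_equilibria", "find_fast_equilibria",
    "continue_equilibria", "continue_fast_equilibria",
    "locate_hopf_in_parameter", "classify_snic",
    "periodic_orbit_from_simulation", "continue_periodic_orbit",
    "regime_sweep",
]

log = logging.getLogger(__name__)

_EIG_ZERO = 1e-9  # eigenvalues below this modulus count as zero for SN tests


# ---------------------------------------------------------------------------
# branch containers
# ---------------------------------------------------------------------------

@dataclass
class BranchEvent:
    kind: str              # SN | HB | SNP | PD | HC_approach
    param: float
    state: np.ndarray
    data: dict = field(default_factory=dict)


@dataclass
class EquilibriumBranch:
    param_name: str
    params: np.ndarray            # (n,)
    states: np.ndarray            # (n, dim)
    eigenvalues: np.ndarray       # (n, dim) complex
    stable: np.ndarray            # (n,) bool
    events: list[BranchEvent] = field(default_factory=list)

    @property
    def l2_norm(self) -> np.ndarray:
        return np.sqrt(np.sum(self.states ** 2, axis=1))


@dataclass
class PeriodicOrbitBranch:
    param_name: str
    params: np.ndarray            # (n,)
    orbits: list[np.ndarray]      # per point: (m, dim) samples over one period
    periods: np.ndarray           # (n,)
    multipliers: np.ndarray       # (n, dim) complex Floquet multipliers
    stable: np.ndarray            # (n,) bool
    events: list[BranchEvent] = field(default_factory=list)

    @property
    def l2_norm(self) -> np.ndarray:
        out = np.empty(len(self.orbits))
        for i, orb in enumerate(self.orbits):
            out[i] = np.sqrt(np.mean(np.sum(orb ** 2, axis=1)))
        return out


@dataclass
class RegimeMap:
    axis1_name: str
    axis1: np.ndarray
    axis2_name: str
    axis2: np.ndarray
    labels: np.ndarray            # (n2, n1) unicode
    spike_counts: np.ndarray      # (n2, n1) float (nan where not applicable)
    provenance: np.ndarray        # (n2, n1) unicode: inherited | default | failed
    bistable: np.ndarray | None = None


# ---------------------------------------------------------------------------
# equilibria via the scalar reduction
# ---------------------------------------------------------------------------

def _current_balance(V: float, pvec: np.ndarray, params: ModelParameters,
                     hA: float | None = None, Ca: float | None = None) -> float:
    y = state_at_voltage(V, params, Ca=Ca, hA=hA)
    return _rhs(0.0, y, pvec)[0]


def find_equilibria(params: ModelParameters, v_range=(-120.0, 20.0),
                    n_grid: int = 2801) -> list[np.ndarray]:
    """All equilibria of the full system.

    Gates are set to their steady states and Ca to its flux-balance value,
    reducing the fixed-point problem to a scalar current balance in V that
    is bracketed on a dense grid and polished by Brent's method.
    """
    pvec = params.to_vector()
    Vs = np.linspace(*v_range, n_grid)
    fs = np.array([_current_balance(V, pvec, params) for V in Vs])
    roots = []
    for i in range(n_grid - 1):
        if fs[i] == 0.0:
            roots.append(Vs[i])
        elif fs[i] * fs[i + 1] < 0:
            roots.append(brentq(_current_balance, Vs[i], Vs[i + 1],
                                args=(pvec, params), xtol=1e-13))
    return [state_at_voltage(V, params) for V in roots]


def find_fast_equilibria(params: ModelParameters, hA: float, Ca: float,
                         v_range=(-120.0, 20.0), n_grid: int = 2801) -> list[np.ndarray]:
    """All equilibria of the frozen-(hA, Ca) fast subsystem (6-state vectors)."""
    pvec = params.to_vector()
    Vs = np.linspace(*v_range, n_grid)
    fs = np.array([_current_balance(V, pvec, params, hA=hA, Ca=Ca) for V in Vs])
    roots = []
    for i in range(n_grid - 1):
        if fs[i] * fs[i + 1] < 0:
            roots.append(brentq(_current_balance, Vs[i], Vs[i + 1],
                                args=(pvec, params, hA, Ca), xtol=1e-13))
    out = []
    for V in roots:
        y = state_at_voltage(V, params, Ca=Ca, hA=hA)
        out.append(y[list(FAST_INDICES)])
    return out


# ---------------------------------------------------------------------------
# pseudo-arclength continuation of equilibria
# ---------------------------------------------------------------------------

def _param_index(name: str) -> int:
    try:
        return PARAM_FIELDS.index(name)
    except ValueError:
        raise KeyError(f"unknown parameter symbol {name!r}") from None


class _FullSystem:
    """F(x, lam) = rhs with one parameter slot replaced by lam."""

    dim = 8

    def __init__(self, params: ModelParameters, pname: str):
        self.pvec = params.to_vector()
        self.ip = _param_index(pname)

    def _pv(self, lam):
        pv = self.pvec.copy()
        pv[self.ip] = lam
        return pv

    def F(self, x, lam):
        return _rhs(0.0, x, self._pv(lam))

    def J(self, x, lam):
        return _jac(x, self._pv(lam))

    def dF_dlam(self, x, lam, h=1e-7):
        s = max(abs(lam), 1.0) * h
        return (self.F(x, lam + s) - self.F(x, lam - s)) / (2 * s)


class _FastSystem:
    """Fast subsystem with lam = hA (Ca fixed) or lam = Ca (hA fixed)."""

    dim = 6

    def __init__(self, params: ModelParameters, vary: str, hA: float, Ca: float):
        assert vary in ("hA", "Ca")
        self.pvec = params.to_vector()
        self.vary = vary
        self.hA, self.Ca = hA, Ca

    def _hc(self, lam):
        return (lam, self.Ca) if self.vary == "hA" else (self.hA, lam)

    def F(self, x, lam):
        hA, Ca = self._hc(lam)
        return _rhs_fast(0.0, x, self.pvec, hA, Ca)

    def J(self, x, lam):
        hA, Ca = self._hc(lam)
        return _jac_fast(x, self.pvec, hA, Ca)

    def dF_dlam(self, x, lam, h=1e-7):
        s = max(abs(lam), 1e-2) * h
        return (self.F(x, lam + s) - self.F(x, lam - s)) / (2 * s)


def _newton_bordered(sys, x, lam, tangent, x_pred, lam_pred, tol=1e-11,
                     max_iter=12):
    """Solve F(x, lam)=0 plus the pseudo-arclength constraint."""
    n = sys.dim
    for _ in range(max_iter):
        F = sys.F(x, lam)
        g = tangent[:n] @ (x - x_pred) + tangent[n] * (lam - lam_pred)
        res = np.linalg.norm(F) + abs(g)
        if res < tol:
            return x, lam, True
        A = np.zeros((n + 1, n + 1))
        A[:n, :n] = sys.J(x, lam)
        A[:n, n] = sys.dF_dlam(x, lam)
        A[n, :n] = tangent[:n]
        A[n, n] = tangent[n]
        rhs_vec = np.concatenate([-F, [-g]])
        try:
            delta = np.linalg.solve(A, rhs_vec)
        except np.linalg.LinAlgError:
            return x, lam, False
        x = x + delta[:n]
        lam = lam + delta[n]
    return x, lam, False


def _branch_tangent(sys, x, lam, prev_tangent=None):
    n = sys.dim
    A = np.zeros((n + 1, n + 1))
    A[:n, :n] = sys.J(x, lam)
    A[:n, n] = sys.dF_dlam(x, lam)
    if prev_tangent is None:
        A[n, :] = 0.0
        A[n, n] = 1.0
    else:
        A[n, :] = prev_tangent
    b = np.zeros(n + 1)
    b[n] = 1.0
    try:
        t = np.linalg.solve(A, b)
    except np.linalg.LinAlgError:
        t = np.zeros(n + 1)
        t[n] = 1.0
    t /= np.linalg.norm(t)
    if prev_tangent is not None and t @ prev_tangent < 0:
        t = -t
    return t


def _continue_core(sys, x0, lam0, lam_range, step0, max_step, min_step,
                   max_points, param_scale):
    """Pseudo-arclength predictor-corrector; returns lists of (x, lam)."""
    lam_lo, lam_hi = min(lam_range), max(lam_range)
    # polish start point
    t0 = np.zeros(sys.dim + 1)
    t0[sys.dim] = 1.0
    x, lam, ok = _newton_bordered(sys, x0.copy(), lam0, t0, x0, lam0)
    if not ok:
        x, lam = x0.copy(), lam0
    pts_x, pts_lam = [x.copy()], [lam]
    tangent = _branch_tangent(sys, x, lam)
    # head toward the interior of the range
    if (lam <= lam_lo + 1e-12 and tangent[sys.dim] < 0) or \
       (lam >= lam_hi - 1e-12 and tangent[sys.dim] > 0):
        tangent = -tangent
    h = step0 * param_scale
    while len(pts_x) < max_points:
        x_pred = x + h * tangent[:sys.dim]
        lam_pred = lam + h * tangent[sys.dim]
        xn, lamn, ok = _newton_bordered(sys, x_pred.copy(), lam_pred, tangent,
                                        x_pred, lam_pred)
        if not ok:
            h *= 0.5
            if h < min_step * param_scale:
                log.warning("continuation step collapsed at %s = %.6g",
                            "param", lam)
                break
            continue
        x, lam = xn, lamn
        pts_x.append(x.copy())
        pts_lam.append(lam)
        tangent = _branch_tangent(sys, x, lam, tangent)
        h = min(h * 1.3, max_step * param_scale)
        if lam < lam_lo - 1e-9 or lam > lam_hi + 1e-9:
            break
    return pts_x, pts_lam


def _certify_events(sys, pts_x, pts_lam):
    """Scan a branch for SN (real eigenvalue through 0) and HB (complex pair
    through the imaginary axis), refining by bisection in arclength."""
    events = []

    def eig(x, lam):
        return np.linalg.eigvals(sys.J(x, lam))

    def sn_indicator(x, lam):
        # determinant sign change: robust against small constant eigenvalues
        # (e.g. the Ca relaxation rate) masking the fold eigenvalue
        return np.linalg.det(sys.J(x, lam))

    def hb_indicator(x, lam):
        ev = eig(x, lam)
        cplx = ev[ev.imag > 1e-8]
        if cplx.size == 0:
            return np.nan
        return cplx.real[np.argmax(cplx.real)]

    for kind, indicator in (("SN", sn_indicator), ("HB", hb_indicator)):
        vals = np.array([indicator(x, lam) for x, lam in zip(pts_x, pts_lam)])
        for i in range(len(vals) - 1):
            a, b = vals[i], vals[i + 1]
            if np.isnan(a) or np.isnan(b) or a * b >= 0:
                continue
            # bisect along the secant between the two branch points
            xa, la = pts_x[i].copy(), pts_lam[i]
            xb, lb = pts_x[i + 1].copy(), pts_lam[i + 1]
            fa = a
            for _ in range(40):
                xm_pred = 0.5 * (xa + xb)
                lm_pred = 0.5 * (la + lb)
                tang = np.zeros(sys.dim + 1)
                dx = xb - xa
                dl = lb - la
                nrm = np.sqrt(dx @ dx + dl * dl)
                if nrm < 1e-14:
                    break
                tang[:sys.dim] = dx / nrm
                tang[sys.dim] = dl / nrm
                xm, lm, ok = _newton_bordered(sys, xm_pred.copy(), lm_pred,
                                              tang, xm_pred, lm_pred)
                if not ok:
                    break
                fm = indicator(xm, lm)
                if np.isnan(fm):
                    break
                if fa * fm <= 0:
                    xb, lb = xm, lm
                else:
                    xa, la, fa = xm, lm, fm
                if abs(lb - la) < 1e-10 and np.linalg.norm(xb - xa) < 1e-10:
                    break
            x_ev = 0.5 * (xa + xb)
            lam_ev = 0.5 * (la + lb)
            ev = eig(x_ev, lam_ev)
            # certification: discard indicator jumps that are not true
            # crossings (e.g. a real pair merging into a complex pair)
            if kind == "SN":
                real = ev[np.abs(ev.imag) < 1e-8].real
                if real.size == 0 or np.min(np.abs(real)) > 1e-4:
                    continue
            else:
                cplx = ev[ev.imag > 1e-8]
                if cplx.size == 0 or np.min(np.abs(cplx.real)) > 1e-4:
                    continue
            events.append(BranchEvent(kind, float(lam_ev), x_ev,
                                      {"eigenvalues": ev}))
    events.sort(key=lambda e: e.param)
    return events


def _assemble_eq_branch(sys, pname, pts_x, pts_lam) -> EquilibriumBranch:
    states = np.array(pts_x)
    lams = np.array(pts_lam)
    eigs = np.array([np.linalg.eigvals(sys.J(x, lam))
                     for x, lam in zip(pts_x, pts_lam)])
    stable = np.all(eigs.real < 0, axis=1)
    events = _certify_events(sys, pts_x, pts_lam)
    return EquilibriumBranch(pname, lams, states, eigs, stable, events)


def continue_equilibria(params: ModelParameters, param_name: str,
                        param_range: tuple[float, float],
                        x0: np.ndarray | None = None,
                        step0: float = 1e-3, max_step: float = 5e-2,
                        min_step: float = 1e-6,
                        max_points: int = 4000) -> EquilibriumBranch:
    """Continue full-system equilibria in one parameter.

    Starts from an equilibrium at the lower end of ``param_range`` (found
    by :func:`find_equilibria` when ``x0`` is not given) and follows the
    branch by pseudo-arclength continuation, certifying SN and HB events
    from the eigenvalue spectrum.
    """
    sys = _FullSystem(params, param_name)
    lam0 = param_range[0]
    if x0 is None:
        eqs = find_equilibria(params.replace(**{param_name: lam0}))
        if not eqs:
            raise ValueError(f"no equilibrium at {param_name} = {lam0}")
        x0 = eqs[0]
    scale = abs(param_range[1] - param_range[0])
    pts_x, pts_lam = _continue_core(sys, np.asarray(x0, float), lam0,
                                    param_range, step0, max_step, min_step,
                                    max_points, scale)
    return _assemble_eq_branch(sys, param_name, pts_x, pts_lam)


def continue_fast_equilibria(params: ModelParameters, hA_range: tuple[float, float],
                             Ca: float, x0: np.ndarray | None = None,
                             step0: float = 1e-3, max_step: float = 5e-2,
                             min_step: float = 1e-7,
                             max_points: int = 6000) -> EquilibriumBranch:
    """Continue fast-subsystem equilibria in hA at fixed Ca (the Z-curve)."""
    sys = _FastSystem(params, "hA", hA_range[0], Ca)
    lam0 = hA_range[0]
    if x0 is None:
        eqs = find_fast_equilibria(params, lam0, Ca)
        if not eqs:
            raise ValueError(f"no fast equilibrium at hA = {lam0}")
        x0 = eqs[0]
    scale = abs(hA_range[1] - hA_range[0])
    pts_x, pts_lam = _continue_core(sys, np.asarray(x0, float), lam0,
                                    hA_range, step0, max_step, min_step,
                                    max_points, scale)
    return _assemble_eq_branch(sys, "hA", pts_x, pts_lam)


def locate_hopf_in_parameter(params: ModelParameters, param_name: str,
                             bracket: tuple[float, float],
                             xtol: float = 1e-3) -> float:
    """Bisect for a Hopf bifurcation of the full-system equilibrium.

    The indicator is the largest real part over complex eigenvalue pairs of
    the equilibrium tracked by continuity in V across the bracket; a sign
    change is required.
    """
    def spectrum(lam):
        p = params.replace(**{param_name: lam})
        eqs = find_equilibria(p)
        if not eqs:
            return None
        return [np.linalg.eigvals(_jac(y, p.to_vector())) for y in eqs]

    def indicator(lam):
        evs = spectrum(lam)
        if evs is None:
            return np.nan
        return max(ev.real.max() for ev in evs)

    a, b = bracket
    fa, fb = indicator(a), indicator(b)
    if np.isnan(fa) or np.isnan(fb) or fa * fb > 0:
        raise ValueError("bracket does not straddle a stability change")
    while b - a > xtol:
        m = 0.5 * (a + b)
        fm = indicator(m)
        if np.isnan(fm):
            raise ValueError("lost the equilibrium during bisection")
        if fa * fm <= 0:
            b, fb = m, fm
        else:
            a, fa = m, fm
    lam_hb = 0.5 * (a + b)
    # certify that the crossing is carried by a complex pair
    evs = spectrum(lam_hb)
    leading = max((ev[np.argmax(ev.real)] for ev in evs),
                  key=lambda z: z.real)
    if abs(leading.imag) < 1e-8:
        raise ValueError("stability change is not a Hopf (real eigenvalue)")
    return lam_hb


# ---------------------------------------------------------------------------
# SNIC classification
# ---------------------------------------------------------------------------

def classify_snic(params: ModelParameters, param_name: str, fold_param: float,
                  side: float = 1.0, rel_offsets=None,
                  duration: float = 6000.0) -> dict:
    """Test a saddle-node event for the SNIC (type I excitability) signature.

    Simulates at parameter values just beyond the fold and fits
    ``1/f^2 = a * (lam - lam_fold) ** -1`` i.e. checks that the firing
    frequency scales as ``sqrt(lam - lam_fold)``: a linear fit of ``1/f^2``
    against ``1/(lam - lam_fold)`` over ~a decade must give R^2 > 0.99.
    Returns a dict with the label and fit diagnostics.
    """
    if rel_offsets is None:
        rel_offsets = np.array([0.02, 0.04, 0.08, 0.15, 0.3])
    scale = max(abs(fold_param), 1.0)
    freqs, dists = [], []
    for ro in rel_offsets:
        lam = fold_param + side * ro * scale
        p = params.replace(**{param_name: lam})
        traj = integrate(p, duration=duration)
        win = analysis_window(traj)
        st = detect_spikes(win.times, win.V)
        if st.size < 4:
            continue
        isi = np.diff(st)
        freqs.append(1000.0 / isi.mean())
        dists.append(abs(lam - fold_param))
    if len(freqs) < 3:
        return {"label": "non-SNIC", "reason": "too few spiking points",
                "r_squared": np.nan}
    x = 1.0 / np.asarray(dists)
    y = 1.0 / np.asarray(freqs) ** 2
    fit = linregress(x, y)
    r2 = fit.rvalue ** 2
    label = "SNIC" if (r2 > 0.99 and fit.slope > 0) else "non-SNIC"
    return {"label": label, "r_squared": float(r2), "slope": float(fit.slope),
            "frequencies_Hz": np.asarray(freqs), "distances": np.asarray(dists)}


# ---------------------------------------------------------------------------
# periodic orbits of the fast subsystem (single shooting)
# ---------------------------------------------------------------------------

@njit(cache=True)
def _rhs_fast_var(t, z, p, hA, Ca):
    """Fast subsystem plus variational equations (6 + 36 components)."""
    y = z[:6]
    dy = _rhs_fast(t, y, p, hA, Ca)
    J = _jac_fast(y, p, hA, Ca)
    Phi = z[6:].reshape(6, 6)
    dPhi = J @ Phi
    out = np.empty(42)
    out[:6] = dy
    out[6:] = dPhi.ravel()
    return out


def _flow(pvec, yf0, T, hA, Ca, rtol=1e-10, atol=1e-12):
    sol = solve_ivp(_rhs_fast, (0.0, T), yf0, method="LSODA",
                    rtol=rtol, atol=atol, args=(pvec, hA, Ca),
                    dense_output=False)
    if not sol.success:
        raise RuntimeError("flow integration failed")
    return sol.y[:, -1]


def _flow_var(pvec, yf0, T, hA, Ca, rtol=1e-9, atol=1e-11):
    z0 = np.concatenate([yf0, np.eye(6).ravel()])
    sol = solve_ivp(_rhs_fast_var, (0.0, T), z0, method="LSODA",
                    rtol=rtol, atol=atol, args=(pvec, hA, Ca))
    if not sol.success:
        raise RuntimeError("variational integration failed")
    zT = sol.y[:, -1]
    return zT[:6], zT[6:].reshape(6, 6)


def periodic_orbit_from_simulation(params: ModelParameters, hA: float, Ca: float,
                                   seed_state: np.ndarray, settle: float = 1500.0,
                                   threshold: float = -20.0):
    """Locate a stable fast-subsystem periodic orbit by relaxation.

    Integrates from ``seed_state`` until transients decay, extracts one
    period between two upward threshold crossings and polishes it with the
    shooting Newton iteration.  Returns ``(y0, T)``.
    """
    from .simulate import integrate_fast
    t, ys = integrate_fast(params, seed_state, hA, Ca, settle)
    V = ys[:, 0]
    half = t > t[-1] * 0.6
    if np.ptp(V[half]) < 10.0:
        raise ValueError("fast subsystem does not oscillate at this (hA, Ca)")
    up = np.where((V[:-1] < threshold) & (V[1:] >= threshold) & half[1:])[0]
    if up.size < 3:
        raise ValueError("could not isolate a period")
    i0, i1 = up[-2] + 1, up[-1] + 1
    y0 = ys[i0].copy()
    T = float(t[i1] - t[i0])
    pvec = params.to_vector()
    y0, T, ok = _shoot_newton(pvec, y0, T, hA, Ca)
    if not ok:
        raise RuntimeError("shooting refinement failed on the seed orbit")
    return y0, T


def _shoot_newton(pvec, y0, T, hA, Ca, phase_ref=None, tol=3e-7, max_iter=15):
    """Newton for the periodic BVP at fixed hA: unknowns (y0, T)."""
    if phase_ref is None:
        phase_ref = _rhs_fast(0.0, y0, pvec, hA, Ca)
    y_anchor = y0.copy()
    for _ in range(max_iter):
        yT, M = _flow_var(pvec, y0, T, hA, Ca)
        F = yT - y0
        g = phase_ref @ (y0 - y_anchor)
        if np.linalg.norm(F) + abs(g) < tol:
            return y0, T, True
        fT = _rhs_fast(0.0, yT, pvec, hA, Ca)
        A = np.zeros((7, 7))
        A[:6, :6] = M - np.eye(6)
        A[:6, 6] = fT
        A[6, :6] = phase_ref
        b = np.concatenate([-F, [-g]])
        try:
            d = np.linalg.solve(A, b)
        except np.linalg.LinAlgError:
            return y0, T, False
        y0 = y0 + d[:6]
        T = T + d[6]
        if T <= 0 or not np.isfinite(T):
            return y0, T, False
    return y0, T, False


def _po_corrector(pvec, u, tangent, u_pred, Ca, scale, tol=5e-7, max_iter=12):
    """Newton for shooting + pseudo-arclength; u = (y0[6], T, hA).

    ``tangent`` lives in the coordinates scaled by ``scale`` (so that mV,
    ms and hA steps are commensurate); the arclength constraint is
    ``tangent . ((u - u_pred) / scale)``.
    """
    u = u.copy()
    for _ in range(max_iter):
        y0, T, hA = u[:6], u[6], u[7]
        if T <= 0 or not (0.0 <= hA <= 1.0) or not np.all(np.isfinite(u)):
            return u, False
        yT, M = _flow_var(pvec, y0, T, hA, Ca)
        f0 = _rhs_fast(0.0, y0, pvec, hA, Ca)
        F = yT - y0
        g_phase = f0 @ (y0 - u_pred[:6])
        g_arc = tangent @ ((u - u_pred) / scale)
        if np.linalg.norm(F) + abs(g_phase) + abs(g_arc) < tol:
            return u, True
        fT = _rhs_fast(0.0, yT, pvec, hA, Ca)
        # dF/dhA by finite difference
        h = 1e-7
        yT2 = _flow(pvec, y0, T, hA + h, Ca)
        dF_dhA = (yT2 - yT) / h
        A = np.zeros((8, 8))
        A[:6, :6] = M - np.eye(6)
        A[:6, 6] = fT
        A[:6, 7] = dF_dhA
        A[6, :6] = f0
        A[7, :] = tangent / scale
        b = np.concatenate([-F, [-g_phase], [-g_arc]])
        try:
            d = np.linalg.solve(A, b)
        except np.linalg.LinAlgError:
            return u, False
        u = u + d
    return u, False


def _orbit_samples(pvec, y0, T, hA, Ca, n=200):
    ts = np.linspace(0.0, T, n)
    sol = solve_ivp(_rhs_fast, (0.0, T), y0, method="LSODA", t_eval=ts,
                    rtol=1e-9, atol=1e-11, args=(pvec, hA, Ca))
    return sol.y.T


def _hc_check(params, pvec, Ca, u_last, orbit, T_ref, saddle_tol):
    """Homoclinic-approach test at a branch end.

    The orbit family is declared to terminate homoclinically when the last
    computable orbit passes within ``saddle_tol`` (state-space norm, the V
    component dominates and is in mV) of a saddle equilibrium while its
    period has grown above ``T_ref`` (the smallest period seen along the
    branch).  Near a homoclinic the monodromy grows like
    exp(lambda_u * T), which is what stalls the shooting corrector, so the
    check runs at step collapse as well as at outright period blow-up.
    """
    T, hA = u_last[6], u_last[7]
    if T <= 1.05 * T_ref:
        return None
    mind = np.inf
    for s in find_fast_equilibria(params, hA, Ca):
        ev = np.linalg.eigvals(_jac_fast(s, pvec, hA, Ca))
        if (ev.real > 0).any() and (ev.real < 0).any():
            mind = min(mind, float(np.min(np.linalg.norm(orbit - s, axis=1))))
    if mind < saddle_tol or not np.isfinite(saddle_tol):
        return BranchEvent("HC_approach", float(hA), u_last[:6].copy(),
                           {"period": float(T),
                            "min_saddle_distance_mV": mind})
    return None


def _nontrivial_multipliers(mults):
    """Drop the Floquet multiplier closest to +1 (the trivial one)."""
    i = np.argmin(np.abs(mults - 1.0))
    return np.delete(mults, i), mults[i]


def continue_periodic_orbit(params: ModelParameters, Ca: float,
                            seed_y0: np.ndarray, seed_T: float, hA0: float,
                            direction: float = 1.0,
                            hA_range: tuple[float, float] = (0.0, 1.0),
                            step0: float = 0.05, max_step: float = 0.4,
                            min_step: float = 1e-7, max_points: int = 400,
                            period_blowup: float = 10.0,
                            saddle_tol: float = 2.0,
                            hA_scale: float = 2e-3,
                            n_orbit_samples: int = 150) -> PeriodicOrbitBranch:
    """Continue a fast-subsystem periodic orbit in hA at fixed Ca.

    ``direction`` sets the initial sense of the branch (+1 toward larger
    hA).  The branch terminates when it leaves ``hA_range``, the step
    collapses (shooting divergence), or the period exceeds ``period_blowup``
    times the seed period — the latter is recorded as a homoclinic-approach
    (``HC_approach``) event if the orbit passes within ``saddle_tol`` mV of
    a saddle equilibrium.
    """
    pvec = params.to_vector()
    u = np.concatenate([seed_y0, [seed_T, hA0]])
    # scaling that makes voltage (mV), gates, period (ms) and hA steps
    # commensurate in the arclength metric
    scale = np.array([25.0, 0.3, 0.3, 0.3, 0.3, 0.3, max(seed_T, 1.0), hA_scale])
    pts_u, orbits, mult_list = [], [], []

    def accept(u):
        y0, T, hA = u[:6], u[6], u[7]
        _, M = _flow_var(pvec, y0, T, hA, Ca)
        mults = np.linalg.eigvals(M)
        pts_u.append(u.copy())
        orbits.append(_orbit_samples(pvec, y0, T, hA, Ca, n_orbit_samples))
        mult_list.append(mults)
        return mults

    accept(u)
    tangent = np.zeros(8)
    tangent[7] = direction
    h = step0
    hc_event = None
    while len(pts_u) < max_points:
        u_pred = pts_u[-1] + h * tangent * scale
        un, ok = _po_corrector(pvec, u_pred, tangent, u_pred, Ca, scale)
        if not ok:
            h *= 0.5
            if h < min_step:
                log.info("PO continuation: step collapse at hA=%.6g", pts_u[-1][7])
                hc_event = _hc_check(params, pvec, Ca, pts_u[-1], orbits[-1],
                                     min(q[6] for q in pts_u), saddle_tol)
                break
            continue
        # secant tangent (in scaled coordinates)
        new_tan = (un - pts_u[-1]) / scale
        nrm = np.linalg.norm(new_tan)
        if nrm < 1e-8:
            # converged back onto the previous point: no progress
            h *= 0.5
            if h < min_step:
                log.info("PO continuation: stagnation at hA=%.6g", pts_u[-1][7])
                hc_event = _hc_check(params, pvec, Ca, pts_u[-1], orbits[-1],
                                     min(q[6] for q in pts_u), saddle_tol)
                break
            continue
        if nrm > 0:
            new_tan /= nrm
            if new_tan @ tangent < 0:
                new_tan = -new_tan
            tangent = new_tan
        accept(un)
        h = min(h * 1.4, max_step)
        T = un[6]
        hA = un[7]
        if not (hA_range[0] <= hA <= hA_range[1]):
            break
        if T > period_blowup * seed_T:
            hc_event = _hc_check(params, pvec, Ca, un, orbits[-1],
                                 min(q[6] for q in pts_u[:-1]), np.inf)
            break

    lams = np.array([u[7] for u in pts_u])
    periods = np.array([u[6] for u in pts_u])
    states0 = [u[:6] for u in pts_u]
    mults = np.array(mult_list)
    stable = np.empty(len(pts_u), bool)
    events: list[BranchEvent] = []
    prev_snp = prev_pd = None
    for i, m in enumerate(mults):
        nt, triv = _nontrivial_multipliers(m)
        stable[i] = np.all(np.abs(nt) < 1.0 + 1e-6)
        # SNP: a real nontrivial multiplier crossing +1
        real_nt = nt[np.abs(nt.imag) < 1e-6].real
        snp_ind = (real_nt - 1.0)[np.argmin(np.abs(real_nt - 1.0))] if real_nt.size else np.nan
        pd_ind = (real_nt + 1.0)[np.argmin(np.abs(real_nt + 1.0))] if real_nt.size else np.nan
        if prev_snp is not None and np.isfinite(snp_ind) and prev_snp * snp_ind < 0:
            events.append(BranchEvent("SNP", float(lams[i]), states0[i].copy(),
                                      {"multipliers": m}))
        if prev_pd is not None and np.isfinite(pd_ind) and prev_pd * pd_ind < 0:
            events.append(BranchEvent("PD", float(lams[i]), states0[i].copy(),
                                      {"multipliers": m}))
        prev_snp, prev_pd = snp_ind, pd_ind
    if hc_event is not None:
        events.append(hc_event)
    return PeriodicOrbitBranch("hA", lams, orbits, periods, mults, stable, events)


# ---------------------------------------------------------------------------
# brute-force regime sweeps
# ---------------------------------------------------------------------------

def regime_sweep(params: ModelParameters,
                 axis1: tuple[str, np.ndarray],
                 axis2: tuple[str, np.ndarray],
                 duration: float = 20000.0,
                 settings: DetectorSettings | None = None,
                 solver_options: SolverOptions | None = None,
                 second_pass: bool = False,
                 default_state: np.ndarray | None = None) -> RegimeMap:
    """Two-parameter regime classification on a grid.

    Cells are visited in serpentine order along ``axis1`` with the initial
    condition inherited from the previous cell's final state, which lets the
    sweep track bursting attractors through bistable windows.  With
    ``second_pass=True`` every cell is re-run from ``default_state`` and
    cells whose label differs between passes are flagged bistable.
    """
    name1, grid1 = axis1
    name2, grid2 = axis2
    grid1 = np.asarray(grid1, float)
    grid2 = np.asarray(grid2, float)
    if grid1.size * grid2.size > 200 * 200:
        raise ValueError("grid too large; keep sweeps at desk scale (<= 200x200)")
    s = settings or DetectorSettings()
    opts = solver_options or SolverOptions(rtol=1e-8, atol=1e-10)
    if default_state is None:
        default_state = state_at_voltage(-70.0, params)

    labels = np.full((grid2.size, grid1.size), "", dtype="U6")
    counts = np.full((grid2.size, grid1.size), np.nan)
    prov = np.full((grid2.size, grid1.size), "inherited", dtype="U9")

    def run_cell(p, y0):
        traj = integrate(p, initial_state=y0, duration=duration,
                         solver_options=opts)
        label = classify_regime(traj, s)
        cnt = np.nan
        if label in ("SW", "PB", "CB", "T"):
            try:
                spb = spikes_per_burst(traj, s)
                cnt = float(spb) if np.isscalar(spb) or isinstance(spb, int) \
                    else float(np.median(spb))
            except ValueError:
                cnt = np.nan
        return label, cnt, traj.final_state()

    from .features import spikes_per_burst  # local import to avoid cycle

    y_carry = default_state.copy()
    for j, v2 in enumerate(grid2):
        order = range(grid1.size) if j % 2 == 0 else range(grid1.size - 1, -1, -1)
        for i in order:
            p = params.replace(**{name1: float(grid1[i]), name2: float(v2)})
            try:
                label, cnt, y_final = run_cell(p, y_carry)
                # bistability probing: a quiescent outcome from the
                # inherited state may have missed a coexisting bursting
                # attractor -- retry once from the default probe state
                if label in ("ESS", "Q"):
                    label2, cnt2, y_final2 = run_cell(p, default_state.copy())
                    if label2 not in ("ESS", "Q"):
                        label, cnt, y_final = label2, cnt2, y_final2
                        prov[j, i] = "default"
                y_carry = y_final
            except (RuntimeError, ValueError):
                labels[j, i] = "failed"
                prov[j, i] = "failed"
                y_carry = default_state.copy()
                continue
            labels[j, i] = label
            counts[j, i] = cnt

    bistable = None
    if second_pass:
        bistable = np.zeros_like(counts, dtype=bool)
        for j, v2 in enumerate(grid2):
            for i, v1 in enumerate(grid1):
                p = params.replace(**{name1: float(v1), name2: float(v2)})
                try:
                    label2, _, _ = run_cell(p, default_state.copy())
                except (RuntimeError, ValueError):
                    continue
                if labels[j, i] not in ("", "failed") and label2 != labels[j, i]:
                    bistable[j, i] = True
                    prov[j, i] = "bistable"
    return RegimeMap(name1, grid1, name2, grid2, labels, counts, prov, bistable)
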