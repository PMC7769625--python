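"""Time integration of the CSC model under electrophysiological stimulation protocols.

Integration uses SciPy's LSODA (stiff-capable, adaptive) with tight default
tolerances (rtol 1e-8, atol 1e-10) and dense equispaced output (0.025 ms) so
that action-potential upstrokes are resolved sample-to-sample.  Identical
inputs give bit-identical trajectories.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from numba import njit
from scipy.integrate import solve_ivp

from .model import FAST_INDICES, STATE_FIELDS, _rhs, _rhs_fast, state_at_voltage
from .params import ModelParameters

__all__ = [
    "StimulusProtocol", "Trajectory", "SolverOptions",
    "integrate", "integrate_fast", "equilibrate_at_hold", "synaptic_conductance",
    "DEFAULT_DT",
]

#: Default output sampling interval (ms); resolves AP upstrokes to < 2 mV per sample.
DEFAULT_DT = 0.025


@dataclass(frozen=True)
class SolverOptions:
    rtol: float = 1e-8
    atol: float = 1e-10
    dt: float = DEFAULT_DT
    max_step: float = np.inf
    method: str = "LSODA"


@dataclass(frozen=True)
class StimulusProtocol:
    """Stimulation protocol.

    kinds
    -----
    constant
        Steady applied current ``I_bias`` (uA/cm^2) for the whole run.
    step
        ``I_bias`` until ``t_step``, then ``I_test``.
    hold_release
        Initialize at the conditional steady state of the system clamped at
        ``V_hold`` (gates at steady state, Ca at flux balance), then release
        at t = 0 with ``I_bias`` applied.  This trades voltage-clamp realism
        for a deterministic initial condition.
    synaptic_pair
        One inhibitory alpha-conductance input at ``t_onset`` followed by an
        excitatory one ``lag`` ms later.
    """

    kind: Literal["constant", "step", "hold_release", "synaptic_pair"] = "constant"
    I_bias: float = 0.0
    I_test: float = 0.0
    t_step: float = 0.0
    V_hold: float = -70.0
    g_inh: float = 0.0
    g_exc: float = 0.0
    E_inh: float = -80.0
    E_exc: float = 0.0
    tau_inh: float = 5.0
    tau_exc: float = 1.0
    t_onset: float = 50.0
    lag: float = 5.0

    def __post_init__(self) -> None:
        if self.kind not in ("constant", "step", "hold_release", "synaptic_pair"):
            raise ValueError(f"unknown protocol kind {self.kind!r}")
        if self.g_inh < 0 or self.g_exc < 0:
            raise ValueError("peak synaptic conductances must be >= 0")
        if self.kind == "hold_release" and not (-120.0 <= self.V_hold <= 0.0):
            raise ValueError("V_hold outside physiological range [-120, 0] mV")


@dataclass
class Trajectory:
    """Dense solution of the full system.

    ``states`` has shape (n_samples, 8) with columns ordered as
    :data:`cscburst.model.STATE_FIELDS`.
    """

    times: np.ndarray
    states: np.ndarray
    params: ModelParameters
    protocol: StimulusProtocol
    solver: SolverOptions = field(default_factory=SolverOptions)

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.states)):
            raise ValueError("trajectory contains non-finite states")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    @property
    def t(self) -> np.ndarray:
        return self.times

    @property
    def V(self) -> np.ndarray:
        return self.states[:, 0]

    def column(self, name: str) -> np.ndarray:
        return self.states[:, STATE_FIELDS.index(name)]

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0])

    def final_state(self) -> np.ndarray:
        return self.states[-1].copy()

    def window(self, t0: float, t1: float | None = None) -> "Trajectory":
        """Sub-trajectory with t in [t0, t1]."""
        t1 = self.times[-1] if t1 is None else t1
        m = (self.times >= t0) & (self.times <= t1)
        return Trajectory(self.times[m], self.states[m], self.params,
                          self.protocol, self.solver)


def synaptic_conductance(t, peak: float, tau: float, onset: float):
    """Alpha-function synaptic conductance.

    ``g(t) = peak * ((t - onset)/tau) * exp(1 - (t - onset)/tau)`` for
    ``t >= onset`` and 0 before; the maximum equals ``peak`` at
    ``t = onset + tau`` and the integral over [onset, inf) is
    ``peak * tau * e``.
    """
    if tau <= 0:
        raise ValueError("synaptic time constant must be > 0")
    t = np.asarray(t, dtype=float)
    x = (t - onset) / tau
    out = np.where(x > 0, peak * x * np.exp(1.0 - x), 0.0)
    return out if out.ndim else float(out)


@njit(cache=True)
def _rhs_syn(t, y, p, g_inh, tau_inh, E_inh, on_inh,
             g_exc, tau_exc, E_exc, on_exc):
    dy = _rhs(t, y, p)
    V = y[0]
    I_syn = 0.0
    xi = (t - on_inh) / tau_inh
    if xi > 0.0:
        I_syn += g_inh * xi * np.exp(1.0 - xi) * (V - E_inh)
    xe = (t - on_exc) / tau_exc
    if xe > 0.0:
        I_syn += g_exc * xe * np.exp(1.0 - xe) * (V - E_exc)
    dy[0] -= I_syn / p[0]
    return dy


def equilibrate_at_hold(params: ModelParameters, V_hold: float) -> np.ndarray:
    """State of the cell conditioned on a holding potential.

    Every stored gate sits at its steady state for ``V_hold`` and Ca at its
    flux-balance value (floored at zero).  Under the clamped dynamics all
    gate and Ca derivatives vanish by construction.
    """
    if not (-120.0 <= V_hold <= 0.0):
        raise ValueError("V_hold outside physiological range [-120, 0] mV")
    return state_at_voltage(V_hold, params)


def _solve(fun, args, t0, t1, y0, opts: SolverOptions, dense_t=None):
    if dense_t is None:
        n = max(2, int(round((t1 - t0) / opts.dt)))
        dense_t = t0 + opts.dt * np.arange(n + 1)
        dense_t = dense_t[dense_t <= t1 + 1e-12]
    sol = solve_ivp(fun, (t0, t1), y0, method=opts.method, t_eval=dense_t,
                    rtol=opts.rtol, atol=opts.atol, max_step=opts.max_step,
                    args=args)
    if not sol.success:
        raise RuntimeError(f"integration failed near t = {sol.t[-1]:.3f} ms: {sol.message}")
    if not np.all(np.isfinite(sol.y)):
        bad = np.where(~np.isfinite(sol.y).all(axis=0))[0]
        raise RuntimeError(f"non-finite state at t = {sol.t[bad[0]]:.3f} ms")
    return sol


def integrate(params: ModelParameters,
              initial_state: np.ndarray | None = None,
              duration: float = 2000.0,
              protocol: StimulusProtocol | None = None,
              solver_options: SolverOptions | None = None) -> Trajectory:
    """Integrate the full system for ``duration`` ms under a protocol.

    ``initial_state`` defaults to the conditional steady state at -70 mV
    (or at ``V_hold`` for hold-release protocols).
    """
    if duration <= 0:
        raise ValueError("duration must be > 0")
    protocol = protocol or StimulusProtocol()
    opts = solver_options or SolverOptions()

    if protocol.kind == "hold_release":
        y0 = equilibrate_at_hold(params, protocol.V_hold)
    elif initial_state is None:
        y0 = state_at_voltage(-70.0, params)
    else:
        y0 = np.asarray(initial_state, dtype=float).copy()
        if y0.shape != (8,) or not np.all(np.isfinite(y0)):
            raise ValueError("initial_state must be 8 finite components")
    if protocol.kind == "hold_release" and initial_state is not None:
        y0 = np.asarray(initial_state, dtype=float).copy()

    pvec = params.to_vector()

    if protocol.kind in ("constant", "hold_release"):
        pvec[1] = params.I_app + protocol.I_bias
        sol = _solve(_rhs, (pvec,), 0.0, duration, y0, opts)
        times, states = sol.t, sol.y.T
    elif protocol.kind == "step":
        ts = min(max(protocol.t_step, 0.0), duration)
        chunks_t, chunks_y = [], []
        if ts > 0:
            pv = pvec.copy()
            pv[1] = params.I_app + protocol.I_bias
            sol = _solve(_rhs, (pv,), 0.0, ts, y0, opts)
            chunks_t.append(sol.t)
            chunks_y.append(sol.y.T)
            y0 = sol.y[:, -1].copy()
        if ts < duration:
            pv = pvec.copy()
            pv[1] = params.I_app + protocol.I_test
            sol = _solve(_rhs, (pv,), ts, duration, y0, opts)
            chunks_t.append(sol.t)
            chunks_y.append(sol.y.T)
        times = np.concatenate(chunks_t)
        states = np.concatenate(chunks_y)
        keep = np.concatenate([[True], np.diff(times) > 0])
        times, states = times[keep], states[keep]
    elif protocol.kind == "synaptic_pair":
        pvec[1] = params.I_app + protocol.I_bias
        args = (pvec, protocol.g_inh, protocol.tau_inh, protocol.E_inh,
                protocol.t_onset, protocol.g_exc, protocol.tau_exc,
                protocol.E_exc, protocol.t_onset + protocol.lag)
        sol = _solve(_rhs_syn, args, 0.0, duration, y0, opts)
        times, states = sol.t, sol.y.T
    else:  # pragma: no cover
        raise ValueError(protocol.kind)

    return Trajectory(times, states, params, protocol, opts)


def integrate_fast(params: ModelParameters, fast_state: np.ndarray,
                   hA: float, Ca: float, duration: float,
                   solver_options: SolverOptions | None = None):
    """Integrate the frozen-(hA, Ca) fast subsystem; returns (t, states)."""
    opts = solver_options or SolverOptions()
    y0 = np.asarray(fast_state, dtype=float)
    if y0.shape != (6,):
        raise ValueError("fast state must have 6 components")
    sol = _solve(_rhs_fast, (params.to_vector(), hA, Ca), 0.0, duration, y0, opts)
    return sol.t, sol.y.T


def fast_state_from_full(state: np.ndarray) -> np.ndarray:
    """Project a full 8-state onto the 6 fast-subsystem components."""
    state = np.asarray(state, dtype=float)
    return state[list(FAST_INDICES)].copy()
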