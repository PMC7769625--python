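"""Right-hand side, ionic currents, gating kinetics and Jacobians of the CSC model.

State vector ordering (8 components)::

    y = (V, h, n, nA, hA, hT, mHVA, Ca)

``V`` is the membrane potential (mV), ``Ca`` the cytosolic Ca2+
concentration (uM) and the rest are first-order gating fractions.  The Na+
activation gate ``m`` and the T-type activation gate ``mT`` are fast and are
evaluated at their voltage-dependent steady states; they are never stored.

The *fast subsystem* used for slow-fast dissection freezes the two slowest
variables, ``hA`` and ``Ca``, as parameters, leaving the 6 components::

    yf = (V, h, n, nA, hT, mHVA)

All hot kernels are numba-compiled and operate on the packed parameter
vector produced by :meth:`cscburst.params.ModelParameters.to_vector`.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .params import ModelParameters

__all__ = [
    "STATE_FIELDS", "FAST_INDICES", "CurrentBreakdown",
    "gate_steady_state", "tau_h", "tau_n",
    "ionic_currents", "rhs", "fast_subsystem_rhs",
    "jacobian", "fast_jacobian", "state_at_voltage", "ca_balance",
]

STATE_FIELDS: tuple[str, ...] = ("V", "h", "n", "nA", "hA", "hT", "mHVA", "Ca")
#: Indices of the fast-subsystem components within the full state.
FAST_INDICES: tuple[int, ...] = (0, 1, 2, 3, 5, 6)

# Parameter-vector slot indices (see params.PARAM_FIELDS).
_C, _IAPP = 0, 1
_GNA, _GK, _GL, _GA, _GT, _GKCA, _GHVA = 2, 3, 4, 5, 6, 7, 8
_ENA, _EK, _EL, _ECA = 9, 10, 11, 12
_VM, _SM, _VH, _SH = 13, 14, 15, 16
_VN, _SN = 17, 18
_VNA, _SNA, _TNA = 19, 20, 21
_VHA, _SHA, _THA = 22, 23, 24
_VMT, _SMT, _VHT, _SHT, _THT = 25, 26, 27, 28, 29
_VMHVA, _SMHVA, _TMHVA = 30, 31, 32
_Y0, _A, _W, _VC = 33, 34, 35, 36
_KCA, _ALPHA, _K, _EPS = 37, 38, 39, 40


# ---------------------------------------------------------------------------
# gating kinetics
# ---------------------------------------------------------------------------

@njit(cache=True, inline="always")
def _sigmoid(V, v, s):
    return 1.0 / (1.0 + np.exp(-(V - v) / s))


@njit(cache=True, inline="always")
def _tau_h(V, y0, A, w, Vc):
    # Peaked (Lorentzian-type) voltage dependence of Na+ inactivation,
    # maximal at Vc with peak value y0 + 2A/w, relaxing to y0 far from Vc.
    return y0 + 2.0 * A * w / (4.0 * np.pi * (V - Vc) ** 2 + w * w)


@njit(cache=True, inline="always")
def _tau_n(V):
    return 6.0 / (1.0 + np.exp((V + 23.0) / 15.0))


def gate_steady_state(V, v_x: float, s_x: float):
    """Steady-state (in)activation ``1 / (1 + exp(-(V - v_x)/s_x))``.

    Monotone increasing in ``V`` for ``s_x > 0`` (activation), decreasing
    for ``s_x < 0`` (inactivation).  ``V`` may be scalar or array.
    """
    if s_x == 0.0:
        raise ValueError("sigmoid slope s_x must be nonzero")
    V = np.asarray(V, dtype=float)
    out = 1.0 / (1.0 + np.exp(-(V - v_x) / s_x))
    return out if out.ndim else float(out)


def tau_h(V, params: ModelParameters):
    """Voltage-dependent Na+ inactivation time constant (ms).

    A peaked profile centred at ``Vc`` with baseline ``y0``::

        tau_h(V) = y0 + 2*A*w / (4*pi*(V - Vc)^2 + w^2)

    The peak value is ``y0 + 2*A/w`` (about 14.1 ms with the default
    constants) and the profile is symmetric about ``Vc``.
    """
    V = np.asarray(V, dtype=float)
    out = params.y0 + 2.0 * params.A * params.w / (
        4.0 * np.pi * (V - params.Vc) ** 2 + params.w ** 2)
    return out if out.ndim else float(out)


def tau_n(V):
    """Voltage-dependent delayed-rectifier activation time constant (ms)."""
    V = np.asarray(V, dtype=float)
    out = 6.0 / (1.0 + np.exp((V + 23.0) / 15.0))
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# currents and right-hand sides
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CurrentBreakdown:
    """Instantaneous ionic current densities (uA/cm^2), outward positive."""

    I_Na: float
    I_K: float
    I_L: float
    I_A: float
    I_T: float
    I_HVA: float
    I_KCa: float

    def total(self) -> float:
        return (self.I_Na + self.I_K + self.I_L + self.I_A
                + self.I_T + self.I_HVA + self.I_KCa)


@njit(cache=True)
def _currents(y, p):
    V, h, n, nA, hA, hT, mHVA, Ca = y[0], y[1], y[2], y[3], y[4], y[5], y[6], y[7]
    minf = _sigmoid(V, p[_VM], p[_SM])
    mTinf = _sigmoid(V, p[_VMT], p[_SMT])
    I_Na = p[_GNA] * minf ** 3 * h * (V - p[_ENA])
    I_K = p[_GK] * n ** 4 * (V - p[_EK])
    I_L = p[_GL] * (V - p[_EL])
    I_A = p[_GA] * nA * hA * (V - p[_EK])
    I_T = p[_GT] * mTinf * hT * (V - p[_ECA])
    I_HVA = p[_GHVA] * mHVA * (V - p[_ECA])
    c5 = Ca ** 5
    I_KCa = p[_GKCA] * (c5 / (p[_KCA] ** 5 + c5)) * (V - p[_EK])
    return I_Na, I_K, I_L, I_A, I_T, I_HVA, I_KCa


@njit(cache=True)
def _rhs(t, y, p):
    V, h, n, nA, hA, hT, mHVA, Ca = y[0], y[1], y[2], y[3], y[4], y[5], y[6], y[7]
    I_Na, I_K, I_L, I_A, I_T, I_HVA, I_KCa = _currents(y, p)
    out = np.empty(8)
    out[0] = (p[_IAPP] - I_Na - I_K - I_L - I_A - I_T - I_KCa - I_HVA) / p[_C]
    out[1] = (_sigmoid(V, p[_VH], p[_SH]) - h) / _tau_h(V, p[_Y0], p[_A], p[_W], p[_VC])
    out[2] = (_sigmoid(V, p[_VN], p[_SN]) - n) / _tau_n(V)
    out[3] = (_sigmoid(V, p[_VNA], p[_SNA]) - nA) / p[_TNA]
    out[4] = (_sigmoid(V, p[_VHA], p[_SHA]) - hA) / p[_THA]
    out[5] = (_sigmoid(V, p[_VHT], p[_SHT]) - hT) / p[_THT]
    out[6] = (_sigmoid(V, p[_VMHVA], p[_SMHVA]) - mHVA) / p[_TMHVA]
    out[7] = -p[_EPS] * (p[_ALPHA] * (I_T + I_HVA) + p[_K] * Ca)
    return out


@njit(cache=True)
def _rhs_fast(t, yf, p, hA, Ca):
    y = np.empty(8)
    y[0], y[1], y[2], y[3] = yf[0], yf[1], yf[2], yf[3]
    y[4] = hA
    y[5], y[6] = yf[4], yf[5]
    y[7] = Ca
    full = _rhs(t, y, p)
    out = np.empty(6)
    out[0], out[1], out[2], out[3] = full[0], full[1], full[2], full[3]
    out[4], out[5] = full[5], full[6]
    return out


@njit(cache=True)
def _jac(y, p):
    """Analytic 8x8 Jacobian of ``_rhs`` with respect to the state."""
    V, h, n, nA, hA, hT, mHVA, Ca = y[0], y[1], y[2], y[3], y[4], y[5], y[6], y[7]
    C = p[_C]
    m = _sigmoid(V, p[_VM], p[_SM])
    mT = _sigmoid(V, p[_VMT], p[_SMT])
    dm = m * (1.0 - m) / p[_SM]
    dmT = mT * (1.0 - mT) / p[_SMT]
    c5 = Ca ** 5
    kc5 = p[_KCA] ** 5
    hill = c5 / (kc5 + c5)
    dhill = 5.0 * kc5 * Ca ** 4 / (kc5 + c5) ** 2

    J = np.zeros((8, 8))
    # dVdot/d(state)
    dI_dV = (p[_GNA] * h * (3.0 * m * m * dm * (V - p[_ENA]) + m ** 3)
             + p[_GK] * n ** 4
             + p[_GL]
             + p[_GA] * nA * hA
             + p[_GT] * hT * (dmT * (V - p[_ECA]) + mT)
             + p[_GHVA] * mHVA
             + p[_GKCA] * hill)
    J[0, 0] = -dI_dV / C
    J[0, 1] = -p[_GNA] * m ** 3 * (V - p[_ENA]) / C
    J[0, 2] = -4.0 * p[_GK] * n ** 3 * (V - p[_EK]) / C
    J[0, 3] = -p[_GA] * hA * (V - p[_EK]) / C
    J[0, 4] = -p[_GA] * nA * (V - p[_EK]) / C
    J[0, 5] = -p[_GT] * mT * (V - p[_ECA]) / C
    J[0, 6] = -p[_GHVA] * (V - p[_ECA]) / C
    J[0, 7] = -p[_GKCA] * dhill * (V - p[_EK]) / C

    # h gate (voltage-dependent tau)
    hinf = _sigmoid(V, p[_VH], p[_SH])
    dhinf = hinf * (1.0 - hinf) / p[_SH]
    th = _tau_h(V, p[_Y0], p[_A], p[_W], p[_VC])
    den = 4.0 * np.pi * (V - p[_VC]) ** 2 + p[_W] ** 2
    dth = -2.0 * p[_A] * p[_W] * 8.0 * np.pi * (V - p[_VC]) / (den * den)
    J[1, 0] = dhinf / th - (hinf - h) * dth / (th * th)
    J[1, 1] = -1.0 / th

    # n gate (voltage-dependent tau)
    ninf = _sigmoid(V, p[_VN], p[_SN])
    dninf = ninf * (1.0 - ninf) / p[_SN]
    tn = _tau_n(V)
    sig = 1.0 / (1.0 + np.exp((V + 23.0) / 15.0))
    dtn = -6.0 * sig * (1.0 - sig) / 15.0
    J[2, 0] = dninf / tn - (ninf - n) * dtn / (tn * tn)
    J[2, 2] = -1.0 / tn

    # constant-tau gates
    for row, vx, sx, tx in ((3, p[_VNA], p[_SNA], p[_TNA]),
                            (4, p[_VHA], p[_SHA], p[_THA]),
                            (5, p[_VHT], p[_SHT], p[_THT]),
                            (6, p[_VMHVA], p[_SMHVA], p[_TMHVA])):
        xinf = _sigmoid(V, vx, sx)
        J[row, 0] = xinf * (1.0 - xinf) / sx / tx
        J[row, row] = -1.0 / tx

    # Ca balance
    ea = p[_EPS] * p[_ALPHA]
    J[7, 0] = -ea * (p[_GT] * hT * (dmT * (V - p[_ECA]) + mT)
                     + p[_GHVA] * mHVA)
    J[7, 5] = -ea * p[_GT] * mT * (V - p[_ECA])
    J[7, 6] = -ea * p[_GHVA] * (V - p[_ECA])
    J[7, 7] = -p[_EPS] * p[_K]
    return J


@njit(cache=True)
def _jac_fast(yf, p, hA, Ca):
    """Analytic 6x6 Jacobian of the frozen-(hA, Ca) fast subsystem."""
    y = np.empty(8)
    y[0], y[1], y[2], y[3] = yf[0], yf[1], yf[2], yf[3]
    y[4] = hA
    y[5], y[6] = yf[4], yf[5]
    y[7] = Ca
    J8 = _jac(y, p)
    J = np.empty((6, 6))
    idx = (0, 1, 2, 3, 5, 6)
    for a in range(6):
        for b in range(6):
            J[a, b] = J8[idx[a], idx[b]]
    return J


# ---------------------------------------------------------------------------
# python-facing wrappers
# ---------------------------------------------------------------------------

def _check_state(state: np.ndarray) -> np.ndarray:
    state = np.asarray(state, dtype=float)
    if state.shape != (8,):
        raise ValueError("state must have 8 components (V, h, n, nA, hA, hT, mHVA, Ca)")
    if not np.all(np.isfinite(state)):
        raise ValueError("state contains non-finite entries")
    return state


def ionic_currents(state: np.ndarray, params: ModelParameters) -> CurrentBreakdown:
    """Evaluate the seven ionic current densities at a state."""
    state = _check_state(state)
    vals = _currents(state, params.to_vector())
    return CurrentBreakdown(*(float(v) for v in vals))


def rhs(state: np.ndarray, params: ModelParameters, t: float = 0.0) -> np.ndarray:
    """Time derivative of the full 8-variable system."""
    state = _check_state(state)
    return _rhs(t, state, params.to_vector())


def fast_subsystem_rhs(fast_state: np.ndarray, hA: float, Ca: float,
                       params: ModelParameters, t: float = 0.0) -> np.ndarray:
    """Time derivative of the 6-variable fast subsystem with (hA, Ca) frozen."""
    fast_state = np.asarray(fast_state, dtype=float)
    if fast_state.shape != (6,):
        raise ValueError("fast state must have 6 components (V, h, n, nA, hT, mHVA)")
    if not (0.0 <= hA <= 1.0):
        raise ValueError("frozen hA must lie in [0, 1]")
    if Ca < 0.0:
        raise ValueError("frozen Ca must be >= 0")
    return _rhs_fast(t, fast_state, params.to_vector(), hA, Ca)


def jacobian(state: np.ndarray, params: ModelParameters) -> np.ndarray:
    """Analytic 8x8 Jacobian of the full system at a state."""
    state = _check_state(state)
    return _jac(state, params.to_vector())


def fast_jacobian(fast_state: np.ndarray, hA: float, Ca: float,
                  params: ModelParameters) -> np.ndarray:
    """Analytic 6x6 Jacobian of the fast subsystem at a state."""
    fast_state = np.asarray(fast_state, dtype=float)
    return _jac_fast(fast_state, params.to_vector(), hA, Ca)


def ca_balance(V: float, params: ModelParameters) -> float:
    """Ca2+ concentration at which influx and extrusion balance at fixed V.

    With the T-type and HVA gates at their steady states,
    ``Ca* = -alpha * (I_T + I_HVA) / k``; floored at zero (Ca currents are
    inward below E_Ca, so Ca* is normally positive).
    """
    hT = gate_steady_state(V, params.v_hT, params.s_hT)
    mT = gate_steady_state(V, params.v_mT, params.s_mT)
    mHVA = gate_steady_state(V, params.v_mHVA, params.s_mHVA)
    I_T = params.g_T * mT * hT * (V - params.E_Ca)
    I_HVA = params.g_HVA * mHVA * (V - params.E_Ca)
    return max(0.0, -params.alpha * (I_T + I_HVA) / params.k)


def state_at_voltage(V: float, params: ModelParameters,
                     Ca: float | None = None, hA: float | None = None) -> np.ndarray:
    """Full state with every stored gate at its steady state for voltage V.

    ``Ca`` defaults to the flux-balance value :func:`ca_balance`; ``hA``
    defaults to its steady state.  Useful as the conditional steady state of
    a voltage-clamped cell and as the gates-at-steady-state reduction used
    for equilibrium searches.
    """
    p = params
    y = np.empty(8)
    y[0] = V
    y[1] = gate_steady_state(V, p.v_h, p.s_h)
    y[2] = gate_steady_state(V, p.v_n, p.s_n)
    y[3] = gate_steady_state(V, p.v_nA, p.s_nA)
    y[4] = gate_steady_state(V, p.v_hA, p.s_hA) if hA is None else hA
    y[5] = gate_steady_state(V, p.v_hT, p.s_hT)
    y[6] = gate_steady_state(V, p.v_mHVA, p.s_mHVA)
    y[7] = ca_balance(V, p) if Ca is None else Ca
    return y
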