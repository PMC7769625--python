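"""Spike detection, burst segmentation, ISI maps and regime classification.

A *spike* is a local maximum of V above a threshold reached through an
upward crossing.  Bursts are groups of spikes separated by inter-spike gaps
exceeding ``gap_factor`` times the median ISI.  The dynamical regime of a
trajectory is classified into:

========  ==========================================================
``T``     tonic firing (periodic spiking, single gap class)
``SW``    square-wave bursting (repeating multi-spike bursts, full-
          amplitude spikes, no supra-threshold spike-free plateau)
``PB``    pseudo-plateau bursting (damped spikes decaying into a
          depolarized spike-free plateau before repolarization)
``CB``    chaotic bursting (non-repeating spikes-per-burst sequence)
``ESS``   elevated steady state / depolarization block (rest on the
          depolarized branch, above ``ess_level``)
``Q``     quiescent hyperpolarized rest
========  ==========================================================
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .model import _rhs
from .simulate import Trajectory

__all__ = [
    "BurstFeatures", "DetectorSettings",
    "detect_spikes", "segment_bursts", "spikes_per_burst",
    "isi_return_map", "first_spike_latency", "classify_regime",
    "phase_plane_cycle", "extract_features", "analysis_window",
]

log = logging.getLogger(__name__)

REGIMES = ("T", "SW", "PB", "CB", "ESS", "Q")


@dataclass(frozen=True)
class DetectorSettings:
    """Spike/burst detector configuration.

    ``threshold`` (mV) is the minimum peak height of a spike;
    ``min_separation`` (ms) suppresses double-counting on noisy upstrokes;
    ``gap_factor`` multiplies the median ISI to split bursts;
    ``plateau_drop`` (mV) sets the plateau level ``threshold - plateau_drop``
    used both for active-phase padding and pseudo-plateau detection;
    ``plateau_min`` (ms) is the shortest supra-level spike-free segment that
    counts as a plateau; ``ess_level`` (mV) separates depolarization-block
    rest (ESS) from hyperpolarized quiescence (Q).
    """

    threshold: float = -20.0
    min_separation: float = 2.0
    gap_factor: float = 3.0
    plateau_drop: float = 15.0
    plateau_min: float = 20.0
    ess_level: float = -65.0

    @property
    def plateau_level(self) -> float:
        return self.threshold - self.plateau_drop


@dataclass
class BurstFeatures:
    """Summary of the spike/burst structure of a voltage trace."""

    spike_times: np.ndarray
    burst_segments: list[tuple[float, float]]
    burst_spikes: list[np.ndarray]
    spikes_per_burst: np.ndarray
    active_durations: np.ndarray
    silent_durations: np.ndarray
    isi_pairs: np.ndarray
    isi_dispersion: float
    regime: str
    mean_rate: float
    window: tuple[float, float] = (0.0, 0.0)
    extras: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# detection and segmentation
# ---------------------------------------------------------------------------

def detect_spikes(t: np.ndarray, V: np.ndarray, threshold: float = -20.0,
                  min_separation: float = 2.0) -> np.ndarray:
    """Spike times: local maxima of V above ``threshold``.

    A candidate is an interior sample that is >= its left neighbour and
    > its right neighbour and above threshold; candidates closer than
    ``min_separation`` ms to the previously accepted spike are discarded.
    """
    t = np.asarray(t, dtype=float)
    V = np.asarray(V, dtype=float)
    if t.size < 3:
        warnings.warn("trace too short for spike detection", stacklevel=2)
        return np.empty(0)
    mid = V[1:-1]
    cand = np.where((mid > threshold) & (mid >= V[:-2]) & (mid > V[2:]))[0] + 1
    out: list[float] = []
    for i in cand:
        if not out or t[i] - out[-1] >= min_separation:
            out.append(t[i])
    return np.asarray(out)


def segment_bursts(spike_times: np.ndarray, gap_factor: float = 3.0) -> list[np.ndarray]:
    """Group spike times into bursts.

    An inter-spike gap greater than ``gap_factor`` times the median ISI
    starts a new burst.  With fewer than two spikes, or when no gap exceeds
    the cut (a single gap class), the whole train is one burst.
    """
    st = np.asarray(spike_times, dtype=float)
    if st.size == 0:
        return []
    if st.size == 1:
        return [st.copy()]
    isi = np.diff(st)
    cut = gap_factor * np.median(isi)
    splits = np.where(isi > cut)[0]
    bounds = np.concatenate([[0], splits + 1, [st.size]])
    return [st[a:b].copy() for a, b in zip(bounds[:-1], bounds[1:])]


def isi_return_map(spike_times: np.ndarray) -> tuple[np.ndarray, float]:
    """Consecutive-ISI pairs and a diagonal-dispersion statistic.

    Returns ``(pairs, dispersion)`` where ``pairs[i] = (ISI_i, ISI_{i+1})``
    and ``dispersion`` is the RMS perpendicular distance of the points from
    the identity diagonal normalized by the mean ISI.  A perfectly periodic
    train has dispersion 0.
    """
    st = np.asarray(spike_times, dtype=float)
    if st.size < 3:
        raise ValueError("need at least 3 spikes for an ISI return map")
    isi = np.diff(st)
    pairs = np.column_stack([isi[:-1], isi[1:]])
    d = np.abs(pairs[:, 1] - pairs[:, 0]) / np.sqrt(2.0)
    dispersion = float(np.sqrt(np.mean(d ** 2)) / np.mean(isi))
    return pairs, dispersion


def analysis_window(traj: Trajectory, transient_frac: float = 0.25,
                    min_transient: float = 500.0) -> Trajectory:
    """Post-transient analysis window.

    Discards the first ``max(transient_frac * duration, min_transient)`` ms,
    then keeps the last 80% of the remainder.
    """
    t0 = traj.times[0]
    cut = t0 + max(transient_frac * traj.duration, min_transient)
    if cut <= t0:
        return traj
    cut = min(cut, traj.times[0] + 0.9 * traj.duration)
    after = traj.window(cut)
    start = after.times[0] + 0.2 * after.duration
    return traj.window(start)


# ---------------------------------------------------------------------------
# per-trajectory features
# ---------------------------------------------------------------------------

def _active_spans(t, V, bursts, level):
    """Pad each burst to the surrounding crossings of ``level``."""
    spans = []
    for b in bursts:
        i0 = np.searchsorted(t, b[0])
        i1 = np.searchsorted(t, b[-1])
        lo = i0
        while lo > 0 and V[lo - 1] > level:
            lo -= 1
        hi = i1
        while hi < V.size - 1 and V[hi + 1] > level:
            hi += 1
        spans.append((t[lo], t[hi]))
    # merge overlaps (possible for tight bursts)
    merged = [spans[0]]
    for a, b in spans[1:]:
        if a <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(b, merged[-1][1]))
        else:
            merged.append((a, b))
    return merged


def spikes_per_burst(traj_or_spikes, settings: DetectorSettings | None = None,
                     min_bursts: int = 5):
    """Steady-state spikes-per-burst count of a bursting trajectory.

    If the last ``min(3, n)`` complete bursts agree, the common integer is
    returned; otherwise the whole per-burst count sequence is returned
    (signalling non-periodicity).  Raises if no bursting is detected.
    """
    s = settings or DetectorSettings()
    if isinstance(traj_or_spikes, Trajectory):
        win = analysis_window(traj_or_spikes)
        st = detect_spikes(win.times, win.V, s.threshold, s.min_separation)
    else:
        st = np.asarray(traj_or_spikes, dtype=float)
    bursts = segment_bursts(st, s.gap_factor)
    if len(bursts) < 2:
        raise ValueError("no bursting detected")
    # drop possibly-truncated first and last bursts when enough are present
    if len(bursts) > min_bursts:
        bursts = bursts[1:-1]
    counts = np.array([len(b) for b in bursts])
    tail = counts[-3:]
    if len(tail) >= 3 and np.all(tail == tail[0]):
        return int(tail[0])
    return counts


def first_spike_latency(traj: Trajectory,
                        settings: DetectorSettings | None = None) -> float:
    """Delay from stimulus onset to the first spike (ms); inf if none."""
    s = settings or DetectorSettings()
    if traj.protocol.kind == "step":
        onset = traj.protocol.t_step
    elif traj.protocol.kind == "hold_release":
        onset = traj.times[0]
    else:
        raise ValueError("latency requires a hold_release or step protocol")
    st = detect_spikes(traj.times, traj.V, s.threshold, s.min_separation)
    st = st[st >= onset]
    return float(st[0] - onset) if st.size else np.inf


def phase_plane_cycle(traj: Trajectory,
                      settings: DetectorSettings | None = None,
                      closure_tol: float = 0.01):
    """One steady-state action-potential cycle in the (V, dV/dt) plane.

    The cycle is delimited by two consecutive upward crossings of the spike
    threshold in the late part of the trajectory.  ``dV/dt`` is evaluated
    from the vector field, not by differencing.  Raises if the loop fails to
    close to within ``closure_tol`` of its diameter.
    """
    s = settings or DetectorSettings()
    win = analysis_window(traj)
    V = win.V
    up = np.where((V[:-1] < s.threshold) & (V[1:] >= s.threshold))[0]
    if up.size < 2:
        raise ValueError("no periodic spiking found for phase-plane extraction")
    i0, i1 = up[-2] + 1, up[-1] + 1
    seg = win.states[i0:i1 + 1]
    pvec = win.params.to_vector()
    dV = np.array([_rhs(0.0, y, pvec)[0] for y in seg])
    loop = np.column_stack([seg[:, 0], dV])
    diam = np.max(np.ptp(loop, axis=0))
    gap = np.linalg.norm(loop[0] - loop[-1])
    if gap > closure_tol * diam:
        raise ValueError(f"cycle does not close: gap {gap:.3g} vs diameter {diam:.3g}")
    return loop


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

def _longest_run_above(t, V, t_from, t_to, level):
    """Length (ms) of the longest contiguous segment with V >= level in
    the open interval (t_from, t_to)."""
    m = (t > t_from) & (t < t_to)
    if not m.any():
        return 0.0
    above = V[m] >= level
    if not above.any():
        return 0.0
    dt = np.diff(t[m]).mean() if m.sum() > 1 else 0.0
    best = cur = 0
    for a in above:
        cur = cur + 1 if a else 0
        best = max(best, cur)
    return best * dt


def _has_plateau(t, V, t_spike, t_next, level, min_len, refractory=2.0):
    """Spike-free depolarized plateau: after a spike, a contiguous run with
    V >= level lasting >= min_len ms before the next spike (or trace end)."""
    return _longest_run_above(t, V, t_spike + refractory, t_next - refractory,
                              level) >= min_len


def _amplitudes_decay(t, V, burst, tol=2.0):
    """Spike peaks within the burst do not grow (tolerance in mV)."""
    if len(burst) < 2:
        return True
    peaks = np.array([V[np.argmin(np.abs(t - ts))] for ts in burst])
    return peaks[-1] <= peaks[0] + tol


def _counts_periodic(counts: np.ndarray, max_period: int = 4) -> bool:
    for per in range(1, max_period + 1):
        if len(counts) >= 2 * per and np.all(counts[per:] == counts[:-per]):
            return True
    return False


def classify_regime(traj: Trajectory,
                    settings: DetectorSettings | None = None, **window_kw) -> str:
    """Classify the post-transient dynamical regime of a trajectory."""
    feats = extract_features(traj, settings, **window_kw)
    return feats.regime


def extract_features(traj: Trajectory,
                     settings: DetectorSettings | None = None,
                     transient_frac: float = 0.25,
                     min_transient: float = 500.0) -> BurstFeatures:
    """Full spike/burst feature extraction plus regime label.

    ``transient_frac``/``min_transient`` control the discarded transient;
    pass zeros for externally recorded steady-state traces.
    """
    s = settings or DetectorSettings()
    win = analysis_window(traj, transient_frac, min_transient)
    t, V = win.times, win.V
    st = detect_spikes(t, V, s.threshold, s.min_separation)
    span = float(t[-1] - t[0])
    mean_rate = 1000.0 * st.size / span if span > 0 else 0.0

    def _mk(regime, bursts=None, pairs=None, disp=np.nan, extras=None):
        bursts = bursts or []
        segs = [(b[0], b[-1]) for b in bursts]
        counts = np.array([len(b) for b in bursts], dtype=int)
        if bursts:
            spans = _active_spans(t, V, bursts, s.plateau_level)
            edges = [t[0]] + [x for sp in spans for x in sp] + [t[-1]]
            diffs = np.diff(edges)
            active = np.array(diffs[1::2])
            silent = np.array([d for d in diffs[0::2] if d > 0])
        else:
            active = np.empty(0)
            silent = np.array([span])
        return BurstFeatures(st, segs, bursts, counts, active, silent,
                             pairs if pairs is not None else np.empty((0, 2)),
                             disp, regime, mean_rate, (t[0], t[-1]),
                             extras or {})

    # quiescent cases: no spikes and a settling (or settled) voltage
    if st.size < 3:
        q3 = V[(t > t[0] + 0.5 * span) & (t <= t[0] + 0.75 * span)]
        q4 = V[t > t[0] + 0.75 * span]
        settled = np.ptp(q4) < 5.0 or np.ptp(q4) < 0.9 * np.ptp(q3)
        if not settled:
            raise ValueError("insufficient window: trace neither spiking nor settled")
        Vs = float(np.median(q4))
        return _mk("ESS" if Vs > s.ess_level else "Q", extras={"V_rest": Vs})

    pairs, disp = isi_return_map(st)
    bursts = segment_bursts(st, s.gap_factor)

    if len(bursts) == 1:
        # single gap class: slow firing with a plateau after each spike is
        # pseudo-plateau bursting with one full-height spike per cycle
        nxt = np.append(st[1:], t[-1])
        plateaus = [_has_plateau(t, V, a, b, s.plateau_level, s.plateau_min)
                    for a, b in zip(st, nxt)]
        if np.mean(plateaus) > 0.5:
            return _mk("PB", [np.array([ts]) for ts in st], pairs, disp)
        isi = np.diff(st)
        cv = isi.std() / isi.mean()
        return _mk("T" if cv < 0.05 else "CB", bursts, pairs, disp,
                   {"isi_cv": float(cv)})

    # interior bursts only (edge bursts may be truncated by the window)
    interior = bursts[1:-1] if len(bursts) > 3 else bursts
    icounts = np.array([len(b) for b in interior])

    next_start = [bursts[k + 1][0] for k, b in enumerate(bursts[:-1])]
    if len(bursts) > 3:
        next_start = next_start[1:]
    else:
        next_start = next_start + [t[-1]]
    next_start = next_start[:len(interior)]
    plateaus = [_has_plateau(t, V, b[-1], nx, s.plateau_level, s.plateau_min)
                for b, nx in zip(interior, next_start)]
    decays = [_amplitudes_decay(t, V, b) for b in interior]

    if np.mean(plateaus) > 0.5 and np.mean(decays) > 0.5:
        return _mk("PB", bursts, pairs, disp)
    if not _counts_periodic(icounts):
        return _mk("CB", bursts, pairs, disp)
    if np.all(icounts == 1):
        # periodic single-spike "bursts" are slow tonic firing
        return _mk("T", bursts, pairs, disp)
    return _mk("SW", bursts, pairs, disp)
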