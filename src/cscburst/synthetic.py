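"""Surrogate voltage traces with known ground truth.

Two generators emulate whole-cell voltage recordings: parametric burst
trains built from Gaussian spike bumps on a hyperpolarized baseline (with an
optional pseudo-plateau morphology of decaying spikes into a depolarized
shoulder), and model trajectories corrupted with additive Gaussian
measurement noise on V.  Both are deterministic given a seed, and both
return the construction's spike times and burst boundaries so the detector
stack can be validated against exact ground truth.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .params import ModelParameters
from .simulate import (DEFAULT_DT, SolverOptions, StimulusProtocol,
                       Trajectory, integrate)

__all__ = ["SurrogateSpec", "SurrogateTrace", "generate_surrogate_trace",
           "generate_noisy_model_trace"]


@dataclass(frozen=True)
class SurrogateSpec:
    """Construction recipe for a surrogate burst train.

    ``spikes_per_burst`` lists the spike count of each burst;
    ``intra_burst_isi`` and ``inter_burst_gap`` (ms) set the timing
    (the gap must exceed 3x the ISI so the default segmenter is able to
    recover the construction); spikes are Gaussian bumps of the given
    amplitude (mV above baseline) and width (ms, standard deviation).
    With ``plateau=True`` spike amplitudes decay geometrically within each
    burst and a depolarized plateau of ``plateau_duration`` ms trails the
    last spike (pseudo-plateau morphology).
    """

    spikes_per_burst: tuple[int, ...] = (5, 5, 5)
    intra_burst_isi: float = 20.0
    inter_burst_gap: float = 400.0
    amplitude: float = 60.0
    width: float = 1.0
    baseline: float = -65.0
    plateau: bool = False
    plateau_duration: float = 150.0
    plateau_level: float = -32.0
    decay: float = 0.82
    #: damped spikes never drop below this peak voltage, so the rendered
    #: spike count stays recoverable by a detector thresholded at -20 mV
    min_spike_peak: float = -14.0
    noise_sd: float = 0.0
    seed: int = 0
    dt: float = DEFAULT_DT
    pad: float = 200.0

    def __post_init__(self) -> None:
        if self.inter_burst_gap <= 3.0 * self.intra_burst_isi:
            raise ValueError("inter_burst_gap must exceed 3x intra_burst_isi")
        if any(n < 1 for n in self.spikes_per_burst):
            raise ValueError("each burst needs at least one spike")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class SurrogateTrace:
    times: np.ndarray
    V: np.ndarray
    spike_times: np.ndarray
    burst_bounds: list[tuple[float, float]]
    spec: SurrogateSpec


def generate_surrogate_trace(spec: SurrogateSpec) -> SurrogateTrace:
    """Render the surrogate described by ``spec``.

    Deterministic for a given ``spec.seed``.  Ground-truth spike times are
    the Gaussian bump centres; burst bounds span first to last spike of
    each burst (plus the plateau, when present).
    """
    spike_times: list[float] = []
    bounds: list[tuple[float, float]] = []
    plateaus: list[tuple[float, float]] = []
    t_cursor = spec.pad
    for n in spec.spikes_per_burst:
        start = t_cursor
        for k in range(n):
            spike_times.append(t_cursor)
            if k < n - 1:
                t_cursor += spec.intra_burst_isi
        end = t_cursor
        if spec.plateau:
            plateaus.append((t_cursor + 3.0 * spec.width, spec.plateau_duration))
            end = t_cursor + 3.0 * spec.width + spec.plateau_duration
        bounds.append((start, end))
        t_cursor = end + spec.inter_burst_gap

    total = t_cursor + spec.pad
    t = np.arange(0.0, total, spec.dt)
    V = np.full(t.size, spec.baseline)
    for j, ts in enumerate(spike_times):
        amp = spec.amplitude
        if spec.plateau:
            # position within its burst sets the decay power
            for (a, b), n in zip(bounds, spec.spikes_per_burst):
                if a - 1e-9 <= ts <= b + 1e-9:
                    k = int(round((ts - a) / spec.intra_burst_isi))
                    amp = max(spec.amplitude * spec.decay ** k,
                              spec.min_spike_peak - spec.baseline)
                    break
        V += amp * np.exp(-0.5 * ((t - ts) / spec.width) ** 2)
    for start, dur in plateaus:
        ramp = np.clip((t - start) / 2.0, 0.0, 1.0) * np.clip((start + dur - t) / 10.0, 0.0, 1.0)
        V += (spec.plateau_level - spec.baseline) * np.clip(ramp, 0.0, 1.0)

    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        V = V + rng.normal(0.0, spec.noise_sd, size=V.size)
    return SurrogateTrace(t, V, np.asarray(spike_times), bounds, spec)


def generate_noisy_model_trace(params: ModelParameters,
                               protocol: StimulusProtocol | None = None,
                               noise_sd: float = 1.0, seed: int = 0,
                               duration: float = 10000.0,
                               initial_state: np.ndarray | None = None,
                               solver_options: SolverOptions | None = None) -> Trajectory:
    """Model trajectory with additive Gaussian measurement noise on V only.

    The underlying simulation is exactly :func:`cscburst.simulate.integrate`
    (noise is applied post hoc, emulating recording noise rather than
    channel noise); ``noise_sd = 0`` returns the clean trajectory.
    """
    traj = integrate(params, initial_state=initial_state, duration=duration,
                     protocol=protocol, solver_options=solver_options)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        noisy = traj.states.copy()
        noisy[:, 0] += rng.normal(0.0, noise_sd, size=noisy.shape[0])
        traj = Trajectory(traj.times, noisy, traj.params, traj.protocol,
                          traj.solver)
    return traj
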