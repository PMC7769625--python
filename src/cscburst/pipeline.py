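"""Configuration-driven analysis pipeline and named canonical runs.

A :class:`RunConfig` bundles a parameter preset with overrides, a protocol,
solver and analysis settings, and a list of stages; :func:`run_pipeline`
executes the stages in dependency order and writes self-describing text
artifacts.  :data:`FIGURE_CONFIGS` ships named configurations for the
canonical demonstrations of each firing regime and analysis.
"""
from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io as cio
from .bifurcation import continue_equilibria, regime_sweep
from .features import DetectorSettings, classify_regime, extract_features, spikes_per_burst
from .model import state_at_voltage
from .params import PARAM_FIELDS, ModelParameters
from .simulate import SolverOptions, StimulusProtocol, Trajectory, integrate

__all__ = ["RunConfig", "run_pipeline", "FIGURE_CONFIGS", "classify_parameter_set",
           "probe_states", "burst_trajectory"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    preset: str = "post_runup"
    overrides: dict = field(default_factory=dict)
    protocol: dict = field(default_factory=dict)
    solver: dict = field(default_factory=dict)
    analysis: dict = field(default_factory=dict)
    sweep: dict = field(default_factory=dict)
    continuation: dict = field(default_factory=dict)
    stages: tuple[str, ...] = ("simulate", "classify")
    duration: float = 20000.0
    seed: int = 0

    def __post_init__(self) -> None:
        unknown = set(self.overrides) - set(PARAM_FIELDS)
        if unknown:
            raise KeyError(f"unknown parameter symbol(s) in overrides: {sorted(unknown)}")

    def build_params(self) -> ModelParameters:
        return ModelParameters.preset(self.preset).replace(**self.overrides)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, default=list)


# ---------------------------------------------------------------------------
# attractor probing
# ---------------------------------------------------------------------------

def probe_states(params: ModelParameters) -> list[np.ndarray]:
    """Standard battery of initial conditions for attractor probing.

    Bursting orbits in this model are isolas that often coexist with a
    stable rest state, so a single initial condition can miss them.  The
    battery covers a cold hyperpolarized start, a deeply hyperpolarized
    start, and a start with the slow variables (hA, Ca) pre-loaded to
    mid-burst values.
    """
    return [
        state_at_voltage(-70.0, params),
        state_at_voltage(-85.0, params),
        state_at_voltage(-70.0, params, hA=0.3, Ca=0.3),
    ]


_PRECEDENCE = ("CB", "SW", "PB", "T", "ESS", "Q")


def classify_parameter_set(params: ModelParameters, duration: float = 25000.0,
                           settings: DetectorSettings | None = None,
                           solver_options: SolverOptions | None = None,
                           return_trajectory: bool = False):
    """Regime label of a parameter set under the probe battery.

    Each probe state is integrated and classified; the most dynamically
    complex label found wins (CB > SW > PB > T > ESS > Q), mirroring how
    sweeps with inherited initial conditions report the bursting attractor
    wherever one exists.
    """
    best = None
    best_traj = None
    for y0 in probe_states(params):
        traj = integrate(params, initial_state=y0, duration=duration,
                         solver_options=solver_options)
        try:
            label = classify_regime(traj, settings)
        except ValueError:
            continue
        if best is None or _PRECEDENCE.index(label) < _PRECEDENCE.index(best):
            best, best_traj = label, traj
        if best == _PRECEDENCE[0]:
            break
    if best is None:
        raise ValueError("no probe produced a classifiable trajectory")
    return (best, best_traj) if return_trajectory else best


def burst_trajectory(params: ModelParameters, duration: float = 25000.0,
                     settings: DetectorSettings | None = None,
                     solver_options: SolverOptions | None = None) -> Trajectory:
    """First probe trajectory that exhibits bursting (SW/PB/CB)."""
    for y0 in probe_states(params):
        traj = integrate(params, initial_state=y0, duration=duration,
                         solver_options=solver_options)
        try:
            label = classify_regime(traj, settings)
        except ValueError:
            continue
        if label in ("SW", "PB", "CB"):
            return traj
    raise ValueError("no bursting attractor found from the probe battery")


# ---------------------------------------------------------------------------
# named canonical configurations
# ---------------------------------------------------------------------------

FIGURE_CONFIGS: dict[str, RunConfig] = {
    # tonic firing, both runup variants
    "fig1": RunConfig(preset="post_runup", duration=5000.0,
                      stages=("simulate", "classify")),
    "fig1_pre": RunConfig(preset="pre_runup", duration=5000.0,
                          stages=("simulate", "classify")),
    # excitability protocol showcase (hold-release latency)
    "fig2": RunConfig(preset="post_runup", duration=3000.0,
                      protocol={"kind": "hold_release", "V_hold": -80.0},
                      stages=("simulate",)),
    # square-wave bursting time courses
    "fig4a": RunConfig(overrides={"g_HVA": 0.26, "g_A": 6.0}, duration=25000.0),
    "fig4b": RunConfig(overrides={"g_HVA": 0.235}, duration=25000.0),
    # spike counts on the 14- and 10-spike isolas
    "fig6_counts": RunConfig(overrides={"g_HVA": 0.232}, duration=30000.0,
                             analysis={"compare": [0.232, 0.253]},
                             stages=("simulate", "classify")),
    # regime map in the (g_KCa, g_A) plane; g_KCa descending so the
    # serpentine inherits bursting states into the many-spike region
    "fig9_map": RunConfig(overrides={"g_HVA": 0.249},
                          sweep={"axis1": ["g_KCa", [2.0, 1.7, 1.4, 1.1, 0.8, 0.5,
                                                     0.35, 0.27, 0.21, 0.15]],
                                 "axis2": ["g_A", [10.2, 12.2, 14.2]]},
                          stages=("sweep",)),
    # fast-subsystem slice and two-parameter bifurcation set
    "fig10_slice": RunConfig(overrides={"g_HVA": 0.249},
                             analysis={"Ca": 0.25}, stages=("slowfast",)),
    "fig12_curves": RunConfig(overrides={"g_HVA": 0.249},
                              analysis={"Ca_grid": [0.1, 0.45, 8]},
                              stages=("slowfast",)),
    # pseudo-plateau and chaotic bursting
    "fig13": RunConfig(overrides={"g_K": 12.0, "g_KCa": 7.0, "g_HVA": 0.22},
                       duration=25000.0),
    "fig14": RunConfig(overrides={"g_KCa": 3.0, "g_HVA": 0.215},
                       duration=50000.0),
    "fig15_map": RunConfig(overrides={"g_A": 10.2},
                           sweep={"axis1": ["g_KCa", [0.5, 1.5, 3.0, 5.0, 7.0]],
                                  "axis2": ["g_HVA", [0.1, 0.21, 0.3, 0.5, 1.0]]},
                           stages=("sweep",)),
    "fig15b": RunConfig(overrides={"g_HVA": 0.77}, duration=25000.0),
}


# ---------------------------------------------------------------------------
# pipeline driver
# ---------------------------------------------------------------------------

def run_pipeline(config: RunConfig, outdir=None) -> dict:
    """Execute the configured stages; returns the artifact bundle.

    Outputs are written under ``outdir`` when given; every file carries the
    resolved configuration.  A stage failure marks the bundle partial and
    skips downstream stages.
    """
    params = config.build_params()
    outdir = Path(outdir) if outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "config.json").write_text(config.to_json())
    bundle: dict = {"config": config, "partial": False}
    meta = {"preset": config.preset, "overrides": config.overrides,
            "seed": config.seed}

    solver = SolverOptions(**config.solver) if config.solver else SolverOptions()
    settings = DetectorSettings(**{k: v for k, v in config.analysis.items()
                                   if k in DetectorSettings.__dataclass_fields__})

    for stage in config.stages:
        try:
            if stage == "simulate":
                protocol = StimulusProtocol(**config.protocol) if config.protocol \
                    else StimulusProtocol()
                traj = integrate(params, duration=config.duration,
                                 protocol=protocol, solver_options=solver)
                bundle["trajectory"] = traj
                if outdir:
                    cio.write_trace(outdir / "trace.tsv", traj, meta)
            elif stage == "classify":
                compare = config.analysis.get("compare")
                if compare:
                    report = {}
                    for val in compare:
                        p = params.replace(g_HVA=float(val))
                        traj = burst_trajectory(p, duration=config.duration,
                                                solver_options=solver)
                        report[val] = spikes_per_burst(traj, settings)
                    bundle["spikes_per_burst"] = report
                else:
                    traj = bundle.get("trajectory")
                    if traj is None:
                        traj = integrate(params, duration=config.duration,
                                         solver_options=solver)
                    feats = extract_features(traj, settings)
                    bundle["features"] = feats
                    bundle["regime"] = feats.regime
                if outdir:
                    rep = {k: (v.tolist() if isinstance(v, np.ndarray) else v)
                           for k, v in bundle.items()
                           if k in ("regime", "spikes_per_burst")}
                    (outdir / "classify.json").write_text(
                        json.dumps(rep, indent=2, default=str))
            elif stage == "sweep":
                def _grid(ax):
                    if len(ax) == 2 and np.iterable(ax[1]):
                        return ax[0], np.asarray(ax[1], float)
                    return ax[0], np.linspace(ax[1], ax[2], int(ax[3]))
                rmap = regime_sweep(
                    params, _grid(config.sweep["axis1"]),
                    _grid(config.sweep["axis2"]),
                    duration=config.duration, settings=settings,
                    solver_options=solver,
                    default_state=state_at_voltage(-70.0, params, hA=0.3,
                                                   Ca=0.3))
                bundle["regime_map"] = rmap
                if outdir:
                    cio.write_regime_map(outdir / "regime_map.tsv", rmap, meta)
            elif stage == "continue_eq":
                c = config.continuation
                branch = continue_equilibria(params, c["param"],
                                             tuple(c["range"]))
                bundle["branch"] = branch
                if outdir:
                    cio.write_branch_table(outdir / "branch.tsv", branch, meta)
            elif stage == "slowfast":
                from .slowfast import compute_critical_manifold
                Ca = config.analysis.get("Ca", 0.25)
                man = compute_critical_manifold(
                    params, hA_grid=np.linspace(0.0, 0.12, 41),
                    Ca_grid=np.array([Ca]), n_v=801)
                bundle["manifold"] = man
            else:
                raise ValueError(f"unknown stage {stage!r}")
        except Exception as err:  # noqa: BLE001 - stage isolation is the contract
            log.error("stage %s failed: %s", stage, err)
            bundle["partial"] = True
            bundle.setdefault("errors", {})[stage] = str(err)
            break
    return bundle
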