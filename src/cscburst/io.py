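"""Plain-text input/output for trajectories, branches and regime maps.

All tables are tab-delimited text with a ``#``-prefixed header block that
records units and the generating configuration, so every artifact is
self-describing and diffable.
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .model import STATE_FIELDS
from .params import ModelParameters
from .simulate import SolverOptions, StimulusProtocol, Trajectory

__all__ = ["write_trace", "read_trace", "write_branch_table", "write_regime_map",
           "read_two_column"]

_TRACE_COLUMNS = "t_ms V_mV h n nA hA hT mHVA Ca_uM"


def write_trace(path, traj: Trajectory, meta: dict | None = None) -> None:
    """Write a trajectory as delimited text (columns: t, 8 state variables)."""
    path = Path(path)
    header = [
        f"columns: {_TRACE_COLUMNS}",
        f"params: {json.dumps(traj.params.to_dict())}",
        f"protocol: {json.dumps(vars(traj.protocol) if not hasattr(traj.protocol, '__dataclass_fields__') else {k: getattr(traj.protocol, k) for k in traj.protocol.__dataclass_fields__})}",
        f"solver: {json.dumps({k: getattr(traj.solver, k) for k in traj.solver.__dataclass_fields__}, default=str)}",
    ]
    if meta:
        header.append(f"meta: {json.dumps(meta)}")
    data = np.column_stack([traj.times, traj.states])
    np.savetxt(path, data, fmt="%.10g", delimiter="\t",
               header="\n".join(header))


def read_trace(path) -> Trajectory:
    """Read a trace written by :func:`write_trace` (or bare two-column t, V)."""
    path = Path(path)
    params = ModelParameters.post_runup()
    protocol = StimulusProtocol()
    solver = SolverOptions()
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line.lstrip("# ").strip()
            if body.startswith("params:"):
                params = ModelParameters(**json.loads(body[len("params:"):]))
            elif body.startswith("protocol:"):
                protocol = StimulusProtocol(**json.loads(body[len("protocol:"):]))
    data = np.loadtxt(path)
    if data.ndim == 1:
        data = data[None, :]
    if data.shape[1] == 9:
        return Trajectory(data[:, 0], data[:, 1:], params, protocol, solver)
    if data.shape[1] == 2:
        # bare (t, V) recording: embed V with gate columns zeroed
        states = np.zeros((data.shape[0], 8))
        states[:, 0] = data[:, 1]
        return Trajectory(data[:, 0], states, params, protocol, solver)
    raise ValueError(f"unexpected column count {data.shape[1]} in {path}")


def write_branch_table(path, branch, meta: dict | None = None) -> None:
    """Write an equilibrium or periodic-orbit branch as delimited text."""
    path = Path(path)
    is_eq = hasattr(branch, "states")
    header = [f"branch parameter: {branch.param_name}"]
    if meta:
        header.append(f"meta: {json.dumps(meta)}")
    rows = []
    if is_eq:
        header.append("columns: param " + " ".join(STATE_FIELDS[:branch.states.shape[1]])
                      + " l2_norm max_re stable")
        l2 = branch.l2_norm
        for i in range(len(branch.params)):
            rows.append([branch.params[i], *branch.states[i], l2[i],
                         branch.eigenvalues[i].real.max(), int(branch.stable[i])])
    else:
        header.append("columns: param period l2_norm max_abs_nontrivial_multiplier stable")
        l2 = branch.l2_norm
        for i in range(len(branch.params)):
            m = branch.multipliers[i]
            nt = np.delete(m, np.argmin(np.abs(m - 1.0)))
            rows.append([branch.params[i], branch.periods[i], l2[i],
                         np.abs(nt).max() if nt.size else np.nan,
                         int(branch.stable[i])])
    for e in branch.events:
        header.append(f"event: {e.kind} at param={e.param:.8g}")
    np.savetxt(path, np.asarray(rows, dtype=float), fmt="%.10g",
               delimiter="\t", header="\n".join(header))


def write_regime_map(path, rmap, meta: dict | None = None) -> None:
    """Write a regime map as one row per grid cell."""
    path = Path(path)
    header = [
        f"axes: {rmap.axis1_name} {rmap.axis2_name}",
        "columns: axis1 axis2 label spikes_per_burst provenance",
    ]
    if meta:
        header.append(f"meta: {json.dumps(meta)}")
    with open(path, "w") as fh:
        for line in header:
            fh.write(f"# {line}\n")
        for j, v2 in enumerate(rmap.axis2):
            for i, v1 in enumerate(rmap.axis1):
                fh.write(f"{v1:.8g}\t{v2:.8g}\t{rmap.labels[j, i]}\t"
                         f"{rmap.spike_counts[j, i]:.6g}\t{rmap.provenance[j, i]}\n")


def read_two_column(path):
    """Read a bare (t, V) text recording; returns (t, V) arrays."""
    data = np.loadtxt(path)
    if data.ndim != 2 or data.shape[1] < 2:
        raise ValueError("expected two-column t, V text")
    return data[:, 0], data[:, 1]
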