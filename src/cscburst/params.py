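"""Model parameters for the cerebellar stellate cell (CSC) conductance-based model.

The model is a Hodgkin-Huxley-type description of a spontaneously active
cerebellar stellate cell, extended with a high-voltage-activated (HVA) Ca2+
current, a Ca2+-activated K+ current gated by a fifth-order Hill function of
cytosolic Ca2+, and a flux-balance equation for the cytosolic Ca2+
concentration.  Two gating-parameter variants are shipped: ``pre_runup``
(immediately after establishing the whole-cell configuration) and
``post_runup`` (after the temporal increase in excitability that develops
over ~25 min of whole-cell recording).
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

__all__ = ["ModelParameters", "PARAM_FIELDS", "PARAM_UNITS"]

#: Ordered names of the scalar parameter slots in the packed vector handed to
#: the compiled kernels.  The order is load-bearing; do not reorder.
PARAM_FIELDS: tuple[str, ...] = (
    "C", "I_app",
    "g_Na", "g_K", "g_L", "g_A", "g_T", "g_KCa", "g_HVA",
    "E_Na", "E_K", "E_L", "E_Ca",
    "v_m", "s_m", "v_h", "s_h",
    "v_n", "s_n",
    "v_nA", "s_nA", "tau_nA",
    "v_hA", "s_hA", "tau_hA",
    "v_mT", "s_mT", "v_hT", "s_hT", "tau_hT",
    "v_mHVA", "s_mHVA", "tau_mHVA",
    "y0", "A", "w", "Vc",
    "k_Ca", "alpha", "k", "eps",
)

PARAM_UNITS: dict[str, str] = {
    "C": "uF/cm^2", "I_app": "uA/cm^2",
    "g_Na": "uS/cm^2", "g_K": "uS/cm^2", "g_L": "uS/cm^2", "g_A": "uS/cm^2",
    "g_T": "uS/cm^2", "g_KCa": "uS/cm^2", "g_HVA": "uS/cm^2",
    "E_Na": "mV", "E_K": "mV", "E_L": "mV", "E_Ca": "mV",
    "v_m": "mV", "s_m": "mV", "v_h": "mV", "s_h": "mV",
    "v_n": "mV", "s_n": "mV",
    "v_nA": "mV", "s_nA": "mV", "tau_nA": "ms",
    "v_hA": "mV", "s_hA": "mV", "tau_hA": "ms",
    "v_mT": "mV", "s_mT": "mV", "v_hT": "mV", "s_hT": "mV", "tau_hT": "ms",
    "v_mHVA": "mV", "s_mHVA": "mV", "tau_mHVA": "ms",
    "y0": "ms", "A": "ms.mV", "w": "mV", "Vc": "mV",
    "k_Ca": "uM", "alpha": "uM.cm^2/uA/ms", "k": "1/ms", "eps": "",
}

# Values that do not change during runup.
_COMMON = dict(
    C=1.50148, I_app=0.0,
    g_Na=3.4, g_K=20.25, g_L=0.07407, g_A=12.2, g_T=0.45045,
    g_KCa=1.0, g_HVA=0.08,
    E_Na=55.0, E_K=-80.0, E_L=-38.0, E_Ca=22.0,
    v_n=-26.0, s_n=6.0,
    s_nA=13.2, tau_nA=5.0,
    tau_hA=10.0,
    v_mT=-54.0, s_mT=3.0, v_hT=-74.0, s_hT=-3.75, tau_hT=15.0,
    v_mHVA=-25.0, s_mHVA=8.0, tau_mHVA=4.0,
    y0=0.1, A=322.0, w=46.0, Vc=-74.0,
    k_Ca=0.45, alpha=0.018, k=0.1, eps=0.015,
)

# Gating parameters that shift during runup: (pre, post) pairs.
_RUNUP = dict(
    v_m=(-37.0, -45.2), s_m=(3.0, 2.3),
    v_h=(-40.0, -51.5), s_h=(-4.0, -4.0),
    v_nA=(-27.0, -41.0),
    v_hA=(-82.0, -95.0), s_hA=(-6.5, -9.2),
)


@dataclass(frozen=True)
class ModelParameters:
    """Complete parameter set of the CSC model.

    Construct via :meth:`pre_runup` or :meth:`post_runup` and adjust with
    :meth:`replace`, e.g. ``ModelParameters.post_runup().replace(g_HVA=0.232)``.

    Conductances are in uS/cm^2, potentials in mV, time constants in ms,
    Ca2+ concentration parameters in uM.  ``eps`` is the dimensionless
    time-scale factor of the Ca2+ balance equation and ``alpha`` converts
    Ca2+ current density to a concentration flux.
    """

    C: float
    I_app: float
    g_Na: float
    g_K: float
    g_L: float
    g_A: float
    g_T: float
    g_KCa: float
    g_HVA: float
    E_Na: float
    E_K: float
    E_L: float
    E_Ca: float
    v_m: float
    s_m: float
    v_h: float
    s_h: float
    v_n: float
    s_n: float
    v_nA: float
    s_nA: float
    tau_nA: float
    v_hA: float
    s_hA: float
    tau_hA: float
    v_mT: float
    s_mT: float
    v_hT: float
    s_hT: float
    tau_hT: float
    v_mHVA: float
    s_mHVA: float
    tau_mHVA: float
    y0: float
    A: float
    w: float
    Vc: float
    k_Ca: float
    alpha: float
    k: float
    eps: float
    runup: str = field(default="post", compare=False)

    def __post_init__(self) -> None:
        for name in ("g_Na", "g_K", "g_L", "g_A", "g_T", "g_KCa", "g_HVA"):
            if getattr(self, name) < 0:
                raise ValueError(f"conductance {name} must be >= 0")
        if self.C <= 0:
            raise ValueError("membrane capacitance C must be > 0")
        if self.k_Ca <= 0:
            raise ValueError("K(Ca) half-activation k_Ca must be > 0")
        if self.eps <= 0:
            raise ValueError("time-scale factor eps must be > 0")
        for name in PARAM_FIELDS:
            if name.startswith("s_") and getattr(self, name) == 0.0:
                raise ValueError(f"sigmoid slope {name} must be nonzero")

    # -- construction -----------------------------------------------------
    @classmethod
    def _variant(cls, which: str) -> "ModelParameters":
        sel = 0 if which == "pre" else 1
        vals = dict(_COMMON)
        vals.update({k: v[sel] for k, v in _RUNUP.items()})
        return cls(runup=which, **vals)

    @classmethod
    def pre_runup(cls) -> "ModelParameters":
        """Parameter set at t = 0 min after patch clamping."""
        return cls._variant("pre")

    @classmethod
    def post_runup(cls) -> "ModelParameters":
        """Parameter set at t = 25 min after patch clamping (default preset)."""
        return cls._variant("post")

    @classmethod
    def preset(cls, name: str) -> "ModelParameters":
        if name in ("pre", "pre_runup"):
            return cls.pre_runup()
        if name in ("post", "post_runup"):
            return cls.post_runup()
        raise KeyError(f"unknown preset {name!r}; use 'pre_runup' or 'post_runup'")

    def replace(self, **overrides: float) -> "ModelParameters":
        """Return a copy with the given symbols overridden."""
        unknown = set(overrides) - set(PARAM_FIELDS) - {"runup"}
        if unknown:
            raise KeyError(f"unknown parameter symbol(s): {sorted(unknown)}")
        return dataclasses.replace(self, **overrides)

    # -- packing ----------------------------------------------------------
    def to_vector(self) -> np.ndarray:
        """Pack into the flat float64 vector consumed by the compiled kernels."""
        return np.array([getattr(self, n) for n in PARAM_FIELDS], dtype=np.float64)

    @classmethod
    def from_vector(cls, vec: np.ndarray, runup: str = "post") -> "ModelParameters":
        vec = np.asarray(vec, dtype=float)
        if vec.shape != (len(PARAM_FIELDS),):
            raise ValueError(f"expected vector of length {len(PARAM_FIELDS)}")
        return cls(runup=runup, **dict(zip(PARAM_FIELDS, vec.tolist())))

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        d = {n: getattr(self, n) for n in PARAM_FIELDS}
        d["runup"] = self.runup
        return d

    def to_json(self) -> str:
        d = {n: {"value": getattr(self, n), "unit": PARAM_UNITS[n]}
             for n in PARAM_FIELDS}
        d["runup"] = self.runup
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "ModelParameters":
        raw = json.loads(text)
        runup = raw.pop("runup", "post")
        vals = {k: (v["value"] if isinstance(v, dict) else float(v))
                for k, v in raw.items()}
        return cls(runup=runup, **vals)

    def __iter__(self) -> Iterator[tuple[str, float]]:
        for n in PARAM_FIELDS:
            yield n, getattr(self, n)
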