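"""Hodgkin-Huxley-style membrane mechanisms, loaded from a declarative file.

Channel kinetics live in ``data/channels.yml`` so that every rate constant,
reversal potential and maximal conductance is auditable data rather than
code.  Each fibre region (dendrite ... node/PN/JN/IN) binds exactly one
:class:`MechanismSet`.  Myelinated regions are passive; nodes of Ranvier
carry the active axonal channels (fast Na, persistent Na, slow K) and the
front-end regions carry retinal-ganglion-cell channels (Na, delayed
rectifier, A-type K).

Gating variables are advanced with the implicit (backward Euler) update

    x(t+dt) = (x(t) + dt*alpha(V)) / (1 + dt*(alpha(V) + beta(V)))

which keeps states inside [0, 1] for any dt as long as both rates are
non-negative.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from importlib import resources
from functools import lru_cache

import numpy as np
import yaml
from scipy.optimize import brentq

__all__ = [
    "RateLaw",
    "Gate",
    "Channel",
    "MechanismSet",
    "DoubleCableElement",
    "load_channel_library",
    "default_bindings",
    "double_cable_params",
    "ionic_current",
    "update_gates_backward_euler",
    "steady_states",
    "resting_potential",
    "scale_conductance",
]


@dataclass(frozen=True)
class RateLaw:
    """One voltage-dependent transition rate (1/ms)."""

    form: str  # linoid | exp | sigmoid
    a: float
    vh: float
    k: float

    def __call__(self, v: np.ndarray | float) -> np.ndarray:
        v = np.asarray(v, dtype=float)
        x = v - self.vh
        if self.form == "linoid":
            # a*x / (1 - exp(-x/k)); removable singularity at x = 0
            arg = np.clip(-x / self.k, -500, 500)
            den = 1.0 - np.exp(arg)
            small = np.abs(x) < 1e-7
            out = np.where(small, self.a * self.k, self.a * x / np.where(small, 1.0, den))
        elif self.form == "exp":
            out = self.a * np.exp(np.clip(x / self.k, -500, 500))
        elif self.form == "sigmoid":
            out = self.a / (1.0 + np.exp(np.clip(-x / self.k, -500, 500)))
        else:
            raise ValueError(f"unknown rate form {self.form!r}")
        if np.any(~np.isfinite(out)) or np.any(out < 0):
            raise FloatingPointError(
                f"rate {self.form}(a={self.a}, vh={self.vh}, k={self.k}) "
                "produced a negative or non-finite value"
            )
        return out


@dataclass(frozen=True)
class Gate:
    name: str
    power: int
    alpha: RateLaw
    beta: RateLaw

    def steady_state(self, v) -> np.ndarray:
        a, b = self.alpha(v), self.beta(v)
        return a / (a + b)

    def time_constant_ms(self, v) -> np.ndarray:
        return 1.0 / (self.alpha(v) + self.beta(v))


@dataclass(frozen=True)
class Channel:
    name: str
    erev_mv: float
    gates: tuple[Gate, ...]

    def open_fraction(self, states: dict[str, np.ndarray]) -> np.ndarray:
        out = 1.0
        for g in self.gates:
            out = out * states[g.name] ** g.power
        return out


@dataclass
class MechanismSet:
    """Membrane mechanisms for one fibre region."""

    region: str
    cm_uf_cm2: float
    g_leak_s_cm2: float
    e_leak_mv: float
    channels: dict[str, float] = field(default_factory=dict)  # name -> gbar S/cm2
    library: dict[str, Channel] = field(default_factory=dict)

    def channel(self, name: str) -> Channel:
        return self.library[name]

    def gate_list(self) -> list[tuple[str, Gate]]:
        return [(cname, g) for cname in self.channels
                for g in self.library[cname].gates]


@dataclass(frozen=True)
class DoubleCableElement:
    """Myelin sheath + periaxonal pathway parameters for one region."""

    mycm_per_lamella: float  # uF/cm2 per lamella membrane
    mygm_per_lamella: float  # S/cm2 per lamella membrane
    rho_axial_ohm_cm: float  # axoplasm and periaxonal axial resistivity
    periaxonal_width_um: dict[str, float]

    def myelin_cm(self, lamellae: int) -> float:
        """Effective sheath capacitance: 2 membranes per wrap, in series."""
        return self.mycm_per_lamella / (2 * lamellae)

    def myelin_gm(self, lamellae: int) -> float:
        return self.mygm_per_lamella / (2 * lamellae)


@lru_cache(maxsize=1)
def _raw_library() -> dict:
    text = resources.files("finblock.data").joinpath("channels.yml").read_text()
    return yaml.safe_load(text)


def load_channel_library() -> dict[str, Channel]:
    raw = _raw_library()
    lib = {}
    for cname, cdef in raw["channels"].items():
        gates = tuple(
            Gate(
                name=gname,
                power=int(gdef["power"]),
                alpha=RateLaw(**gdef["alpha"]),
                beta=RateLaw(**gdef["beta"]),
            )
            for gname, gdef in cdef["gates"].items()
        )
        lib[cname] = Channel(cname, float(cdef["erev"]), gates)
    return lib


def default_bindings() -> dict[str, MechanismSet]:
    """Region tag -> mechanism set, from the declarative parameter file."""
    raw = _raw_library()
    lib = load_channel_library()
    out = {}
    for region, mdef in raw["mechanisms"].items():
        chans = dict(mdef.get("channels") or {})
        for cname in chans:
            if cname not in lib:
                raise KeyError(f"mechanism {region!r} references unknown "
                               f"channel {cname!r}")
        out[region] = MechanismSet(
            region=region,
            cm_uf_cm2=float(mdef["cm"]),
            g_leak_s_cm2=float(mdef["g_leak"]),
            e_leak_mv=float(mdef["e_leak"]),
            channels={k: float(v) for k, v in chans.items()},
            library=lib,
        )
    return out


def double_cable_params() -> DoubleCableElement:
    raw = _raw_library()["double_cable"]
    return DoubleCableElement(
        mycm_per_lamella=float(raw["mycm_per_lamella"]),
        mygm_per_lamella=float(raw["mygm_per_lamella"]),
        rho_axial_ohm_cm=float(raw["rho_axial_ohm_cm"]),
        periaxonal_width_um={k: float(v) for k, v in
                             raw["periaxonal_width_um"].items()},
    )


# ---------------------------------------------------------------------------
# Point evaluation (reference path used by tests and initialisation)
# ---------------------------------------------------------------------------


def ionic_current(mech: MechanismSet, v_mv: float | np.ndarray,
                  states: dict[str, np.ndarray] | None = None) -> np.ndarray:
    """Total ionic current density (mA/cm2), leak included.

    ``states`` maps gate name -> state; omitted states default to their
    steady-state value at ``v_mv``.
    """
    v = np.asarray(v_mv, dtype=float)
    i = mech.g_leak_s_cm2 * (v - mech.e_leak_mv)
    for cname, gbar in mech.channels.items():
        chan = mech.channel(cname)
        s = {}
        for g in chan.gates:
            if states is not None and g.name in states:
                s[g.name] = np.asarray(states[g.name])
                if np.any((s[g.name] < 0) | (s[g.name] > 1)):
                    raise ValueError(f"gate {g.name!r} state outside [0, 1]")
            else:
                s[g.name] = g.steady_state(v)
        i = i + gbar * chan.open_fraction(s) * (v - chan.erev_mv)
    return i  # S/cm2 * mV = mA/cm2


def update_gates_backward_euler(gates: dict[str, Gate] | list[Gate],
                                states: dict[str, np.ndarray],
                                v_mv: np.ndarray | float,
                                dt_ms: float = 0.01) -> dict[str, np.ndarray]:
    """Implicit gate update; naturally bounded in [0, 1] for alpha, beta >= 0."""
    if dt_ms <= 0:
        raise ValueError("dt must be > 0")
    glist = gates.values() if isinstance(gates, dict) else gates
    out = dict(states)
    for g in glist:
        a, b = g.alpha(v_mv), g.beta(v_mv)
        out[g.name] = (np.asarray(states[g.name]) + dt_ms * a) / (1.0 + dt_ms * (a + b))
    return out


def steady_states(mech: MechanismSet, v_mv: float) -> dict[str, float]:
    out = {}
    for cname in mech.channels:
        for g in mech.channel(cname).gates:
            out[g.name] = float(g.steady_state(v_mv))
    return out


def resting_potential(mech: MechanismSet, lo: float = -95.0,
                      hi: float = -40.0) -> float:
    """Settled resting potential: root of the steady-state I-V curve."""
    f = lambda v: float(ionic_current(mech, v))
    a, b = lo, hi
    if f(a) * f(b) > 0:
        vs = np.linspace(lo, hi, 200)
        iv = np.array([f(v) for v in vs])
        sign = np.sign(iv)
        flips = np.nonzero(np.diff(sign))[0]
        if len(flips) == 0:
            raise ValueError(f"no resting point in [{lo}, {hi}] for "
                             f"{mech.region!r}")
        a, b = vs[flips[0]], vs[flips[0] + 1]
    return float(brentq(f, a, b, xtol=1e-9))


def scale_conductance(bindings: dict[str, MechanismSet], region: str,
                      channel: str, factor: float) -> dict[str, MechanismSet]:
    """Return bindings with one maximal conductance scaled; all else shared.

    ``channel='leak'`` scales the leak conductance.  Unknown region or
    channel names raise.
    """
    if region not in bindings:
        raise KeyError(f"unknown region {region!r}; have {sorted(bindings)}")
    if factor < 0:
        raise ValueError("factor must be >= 0")
    out = dict(bindings)
    mech = copy.copy(bindings[region])
    if channel == "leak":
        mech.g_leak_s_cm2 = mech.g_leak_s_cm2 * factor
    else:
        if channel not in mech.channels:
            raise KeyError(
                f"region {region!r} has no channel {channel!r}; "
                f"have {sorted(mech.channels)}"
            )
        mech.channels = dict(mech.channels)
        mech.channels[channel] = mech.channels[channel] * factor
    out[region] = mech
    return out
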