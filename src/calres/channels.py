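"""Voltage-gated ion channel models.

Every channel is described as a set of gating variables, each a pair of
voltage-dependent curves (steady-state activation and time constant), plus a
current law: ohmic with a fixed reversal potential, or the Goldman–Hodgkin–Katz
(GHK) constant-field flux for Ca²⁺, which at physiological concentration
asymmetry ([Ca]_o ≈ 2 mM vs [Ca]_i ≈ 100 nM) is far from the linear
Nernst-reversal regime.

Gate curves are stored as named parameter sets in a YAML registry
(``calres/data/channels.yaml``); swapping a published kinetic scheme for
another is a config edit, not a code change.  Each gate carries modifier hooks
used by the parameter sweeps: an additive V₁/₂ shift, a multiplicative time
constant scale, and an additive time constant offset.

Units: voltages mV, times ms, temperatures °C, conductance densities S/cm²,
current densities mA/cm², concentrations mM.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources

import numpy as np
import yaml

FARADAY = 96485.33212  # C/mol
GAS_CONSTANT = 8.31446261815324  # J/(mol K)

# time-constant functional forms (see _base_tau)
TAU_CONST = 0
TAU_BELL = 1
TAU_SIGMOID = 2
TAU_PIECEWISE = 3

_TAU_FORMS = {"const": TAU_CONST, "bell": TAU_BELL,
              "sigmoid": TAU_SIGMOID, "piecewise": TAU_PIECEWISE}


def _base_tau(form: int, p, v):
    """Evaluate a registry time-constant curve (ms) at voltage v (mV).

    Forms:
      const:     p0
      bell:      p0 + p1 / (exp((v-p2)/p3) + exp(-(v-p4)/p5))
      sigmoid:   p0 + p1 / (1 + exp((v-p2)/p3))
      piecewise: exp((v+p1)/p2) for v < p0, else p3 + exp(-(v+p4)/p5)
    """
    v = np.asarray(v, dtype=float)
    if form == TAU_CONST:
        return np.broadcast_to(np.asarray(p[0], dtype=float), v.shape).copy() if v.ndim else float(p[0])
    if form == TAU_BELL:
        return p[0] + p[1] / (np.exp((v - p[2]) / p[3]) + np.exp(-(v - p[4]) / p[5]))
    if form == TAU_SIGMOID:
        return p[0] + p[1] / (1.0 + np.exp((v - p[2]) / p[3]))
    if form == TAU_PIECEWISE:
        lo = np.exp((v + p[1]) / p[2])
        hi = p[3] + np.exp(-(v + p[4]) / p[5])
        return np.where(v < p[0], lo, hi) if v.ndim else (lo if v < p[0] else hi)
    raise ValueError(f"unknown tau form {form}")


@dataclass
class GateSpec:
    """One Hodgkin–Huxley gating variable.

    ``steady_state`` is a Boltzmann curve 1/(1+exp((vhalf - v)/k)); a negative
    slope factor ``k`` describes inactivation / hyperpolarization-activated
    gates.  ``v_half_shift`` translates both curves (the τ curve is treated as
    V₁/₂-anchored): shifted(V) = unshifted(V - shift).
    """

    name: str
    role: str  # "act" | "inact"
    vhalf: float
    k: float
    exponent: int = 1
    tau_form: int = TAU_CONST
    tau_params: tuple = (1.0, 0.0, 0.0, 1.0, 0.0, 1.0)
    v_half_shift: float = 0.0
    tau_scale: float = 1.0
    tau_offset: float = 0.0
    q10: float = 3.0
    ref_temp: float = 34.0

    def steady_state(self, v):
        veff = np.asarray(v, dtype=float) - self.v_half_shift
        z = np.clip((self.vhalf - veff) / self.k, -60.0, 60.0)
        out = 1.0 / (1.0 + np.exp(z))
        return float(out) if np.ndim(v) == 0 else out

    def time_constant(self, v, temperature: float = 34.0):
        if self.tau_scale <= 0:
            raise ValueError("tau_scale must be positive")
        veff = np.asarray(v, dtype=float) - self.v_half_shift
        corr = self.q10 ** ((temperature - self.ref_temp) / 10.0)
        tau = self.tau_scale * _base_tau(self.tau_form, self.tau_params, veff) / corr
        tau = tau + self.tau_offset
        return float(tau) if np.ndim(v) == 0 else tau


def gate_steady_state(gate: GateSpec, v) -> float:
    """Steady-state open fraction of a gate at membrane voltage v (mV)."""
    return gate.steady_state(v)


def gate_time_constant(gate: GateSpec, v, temperature: float = 34.0) -> float:
    """Gate time constant (ms) at voltage v, q10-corrected to ``temperature``."""
    return gate.time_constant(v, temperature)


@dataclass
class GHKEnv:
    """Calcium milieu for the GHK flux: concentrations in mM, temperature °C."""

    ca_out: float = 2.0
    ca_in: float = 1e-4  # 100 nM resting
    temperature: float = 34.0
    valence: int = 2

    def __post_init__(self):
        if self.ca_out <= 0 or self.ca_in <= 0:
            raise ValueError("concentrations must be positive")

    @property
    def kT_over_zF_mV(self) -> float:
        """RT/(zF) in mV — the voltage scale of the constant-field expression."""
        T = self.temperature + 273.15
        return 1e3 * GAS_CONSTANT * T / (self.valence * FARADAY)


def ghk_current_density(v, env: GHKEnv, permeability: float):
    """Standard GHK flux for a divalent ion, in mA/cm².

    I = P z²F²V/(RT) · ([Ca]_i − [Ca]_o e^{−zFV/RT}) / (1 − e^{−zFV/RT})
    with P in cm/s and concentrations converted to mol/cm³.  The removable
    singularity at V = 0 is evaluated through expm1 and its analytic limit
    P·z·F·([Ca]_i − [Ca]_o).
    """
    if permeability < 0:
        raise ValueError("permeability must be non-negative")
    v = np.asarray(v, dtype=float)
    z = env.valence
    ci = env.ca_in * 1e-6   # mM -> mol/cm^3
    co = env.ca_out * 1e-6
    x = v / env.kT_over_zF_mV  # = zFV/RT, dimensionless
    with np.errstate(invalid="ignore", divide="ignore"):
        em = np.expm1(-x)  # e^{-x} - 1
        frac = (ci - co * (1.0 + em)) / np.where(x != 0.0, -em, 1.0)
    # I (A/cm^2) = P zF x * frac for x != 0; the x -> 0 limit is P zF (ci - co)
    cur = permeability * z * FARADAY * np.where(x != 0.0, x * frac, ci - co)
    out = 1e3 * cur  # A/cm^2 -> mA/cm^2
    return float(out) if np.ndim(v) == 0 else out


def ghk_driving_force(v, env: GHKEnv):
    """GHK 'driving force' in mV: the factor D(V) such that I = ḡ·gates·D(V).

    This is the conductance-units convention common in compartmental
    simulators: a density quoted in S/cm² multiplies D(V) (mV) to give mA/cm².
    Proportional to :func:`ghk_current_density`; the constant relating the two
    is z²F²[Ca]_o/(RT) (see tests).
    """
    v = np.asarray(v, dtype=float)
    f = env.kT_over_zF_mV
    x = v / f
    with np.errstate(invalid="ignore", divide="ignore"):
        ep = np.expm1(x)
        efun = np.where(x != 0.0, x / np.where(x != 0.0, ep, 1.0), 1.0)
    ratio = env.ca_in / env.ca_out
    out = -f * (1.0 - ratio * np.exp(x)) * efun
    return float(out) if np.ndim(v) == 0 else out


@dataclass
class ChannelSpec:
    """A whole channel: gates with exponents, current law, density.

    ``density`` is a conductance per area in S/cm² for ohmic channels.  For the
    GHK channel the printed literature values (μS/cm²) are used verbatim in the
    driving-force convention of :func:`ghk_driving_force` (conversion constant
    fixed at 1), matching common simulator practice.
    """

    name: str
    gates: list[GateSpec] = field(default_factory=list)
    current_law: str = "ohmic"  # "ohmic" | "ghk"
    erev: float = 0.0
    density: float = 0.0
    valence: int = 2

    def with_modifiers(self, mods: dict | None) -> "ChannelSpec":
        """Return a copy with per-gate modifier hooks applied.

        ``mods`` maps gate role ("act"/"inact") to a dict with any of
        ``v_shift``, ``tau_scale``, ``tau_offset``.
        """
        if not mods:
            return self
        gates = []
        for g in self.gates:
            m = mods.get(g.role, {})
            gates.append(replace(
                g,
                v_half_shift=g.v_half_shift + m.get("v_shift", 0.0),
                tau_scale=g.tau_scale * m.get("tau_scale", 1.0),
                tau_offset=g.tau_offset + m.get("tau_offset", 0.0),
            ))
        return replace(self, gates=gates)


def channel_current(chan: ChannelSpec, v, gate_states, env: GHKEnv | None = None):
    """Current density (mA/cm²) of a channel at voltage v with given gate states."""
    if len(gate_states) != len(chan.gates):
        raise ValueError(
            f"{chan.name}: expected {len(chan.gates)} gate states, got {len(gate_states)}")
    open_frac = 1.0
    for g, s in zip(chan.gates, gate_states):
        s = np.asarray(s, dtype=float)
        if np.any(s < 0) or np.any(s > 1):
            raise ValueError("gate states must lie in [0, 1]")
        open_frac = open_frac * s ** g.exponent
    if chan.current_law == "ohmic":
        return chan.density * open_frac * (np.asarray(v, dtype=float) - chan.erev)
    if chan.current_law == "ghk":
        env = env or GHKEnv()
        return chan.density * open_frac * ghk_driving_force(v, env)
    raise ValueError(f"unknown current law {chan.current_law!r}")


def load_registry(path=None) -> dict[str, ChannelSpec]:
    """Load the channel registry (YAML) into ChannelSpec objects.

    With no path, the packaged default registry is used.
    """
    if path is None:
        text = resources.files("calres").joinpath("data/channels.yaml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    raw = yaml.safe_load(text)
    out: dict[str, ChannelSpec] = {}
    for name, spec in raw.items():
        gates = []
        for g in spec.get("gates", []):
            gates.append(GateSpec(
                name=g["name"],
                role=g.get("role", "act"),
                vhalf=float(g["vhalf"]),
                k=float(g["k"]),
                exponent=int(g.get("exponent", 1)),
                tau_form=_TAU_FORMS[g.get("tau_form", "const")],
                tau_params=tuple(float(x) for x in g.get("tau_params", [1.0])) + (0.0,) * 6,
                q10=float(g.get("q10", spec.get("q10", 3.0))),
                ref_temp=float(g.get("ref_temp", spec.get("ref_temp", 34.0))),
            ))
            gates[-1].tau_params = gates[-1].tau_params[:6]
        out[name] = ChannelSpec(
            name=name,
            gates=gates,
            current_law=spec.get("current", "ohmic"),
            erev=float(spec.get("erev", 0.0)),
            density=float(spec.get("density", 0.0)),
            valence=int(spec.get("valence", 2)),
        )
    return out


_default_registry_cache: dict[str, ChannelSpec] | None = None


def default_registry() -> dict[str, ChannelSpec]:
    """The packaged registry, loaded once per process (copies are cheap)."""
    global _default_registry_cache
    if _default_registry_cache is None:
        _default_registry_cache = load_registry()
    return {k: replace(v, gates=[replace(g) for g in v.gates])
            for k, v in _default_registry_cache.items()}
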