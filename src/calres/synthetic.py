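"""Synthetic inputs: everything the pipeline needs with no downloads.

* :func:`make_trunk` — a soma plus tapered apical-trunk morphology emulating
  the somato-apical trunk of a reconstructed CA1 pyramidal cell (~425 μm to
  the terminal end), in the same representation the SWC reader produces.
* :class:`RLCFixture` — a phenomenological resonant circuit (parallel RC with
  an inductive branch) whose impedance has a closed form; the analysis-module
  oracle.
* :func:`sweep_grid` — the documented deterministic parameter grids for every
  sweep (conductances and time constants: 9 log-spaced multiplicative factors
  0.25×–4×; V₁/₂ shifts: ±15 mV in 2.5 mV steps).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .morphology import Morphology, Section
from .stimulus import ChirpStimulus
from .traces import TraceSet


@dataclass(frozen=True)
class SyntheticTrunkSpec:
    trunk_length_um: float = 425.0
    soma_length_um: float = 20.0
    soma_diam_um: float = 20.0
    proximal_diam_um: float = 2.5
    distal_diam_um: float = 1.0
    n_sections: int = 10
    basal_length_um: float = 0.0   # 0 disables the basal equivalent cylinder
    basal_diam_um: float = 2.0
    axon_length_um: float = 0.0    # 0 disables the axon stub
    axon_diam_um: float = 1.0
    jitter_sd: float = 0.0         # relative diameter jitter (off by default)
    seed: int | None = None

    def __post_init__(self):
        if (self.trunk_length_um <= 0 or self.proximal_diam_um <= 0
                or self.distal_diam_um <= 0 or self.n_sections < 1
                or self.distal_diam_um > self.proximal_diam_um):
            raise ValueError("non-physical trunk spec")


def make_trunk(spec: SyntheticTrunkSpec | None = None) -> Morphology:
    """Deterministic soma + linearly tapered apical trunk (optional basal
    cylinder and axon stub), with the trunk's terminal end at
    ``trunk_length_um`` path distance from the soma."""
    spec = spec or SyntheticTrunkSpec()
    rng = np.random.default_rng(spec.seed)
    L, d0 = spec.soma_length_um, spec.soma_diam_um
    soma = Section(points=np.array([[-L / 2, 0, 0, d0], [L / 2, 0, 0, d0]]),
                   stype="soma", parent=-1)
    sections = [soma]
    n = spec.n_sections
    edges = np.linspace(0.0, spec.trunk_length_um, n + 1)
    diams = np.interp(edges, [0.0, spec.trunk_length_um],
                      [spec.proximal_diam_um, spec.distal_diam_um])
    if spec.jitter_sd > 0:
        jitter = 1.0 + spec.jitter_sd * rng.standard_normal(n + 1)
        diams = diams * np.clip(jitter, 0.5, 1.5)
        diams = np.minimum.accumulate(diams)  # keep monotone non-increasing
    x0 = L / 2  # trunk grows along +x from the soma end
    parent = 0
    for i in range(n):
        pts = np.array([[x0 + edges[i], 0, 0, diams[i]],
                        [x0 + edges[i + 1], 0, 0, diams[i + 1]]])
        sections.append(Section(points=pts, stype="apical", parent=parent))
        parent = len(sections) - 1
    if spec.basal_length_um > 0:
        pts = np.array([[-x0, 0, 0, spec.basal_diam_um],
                        [-x0 - spec.basal_length_um, 0, 0, spec.basal_diam_um]])
        sections.append(Section(points=pts, stype="basal", parent=0))
    if spec.axon_length_um > 0:
        pts = np.array([[-x0, 0, 0, spec.axon_diam_um],
                        [-x0, -spec.axon_length_um, 0, spec.axon_diam_um]])
        sections.append(Section(points=pts, stype="axon", parent=0))
    return Morphology(sections=sections, identifier="synthetic-trunk")


@dataclass(frozen=True)
class RLCFixture:
    """Parallel RC in parallel with a series RL branch (SI units).

    Z(ω) = 1 / (1/R + iωC + 1/(R_L + iωL)); with the inductive branch active
    the magnitude has a unique interior maximum.  Defaults put the closed-form
    peak near 6 Hz at neuron-like impedance scales.
    """

    r_ohm: float = 100e6
    c_farad: float = 150e-12
    l_henry: float = 4.0e6
    rl_ohm: float = 60e6
    inductive: bool = True

    def impedance(self, freq_hz) -> np.ndarray:
        w = 2 * np.pi * np.asarray(freq_hz, dtype=float)
        y = 1.0 / self.r_ohm + 1j * w * self.c_farad
        if self.inductive:
            y = y + 1.0 / (self.rl_ohm + 1j * w * self.l_henry)
        return 1.0 / y

    def magnitude_mohm(self, freq_hz) -> np.ndarray:
        return np.abs(self.impedance(freq_hz)) / 1e6

    def peak_frequency(self, f_min=0.5, f_max=15.0) -> float:
        """Closed-form argmax of |Z| on a fine grid (oracle)."""
        f = np.linspace(f_min, f_max, 20001)
        return float(f[np.argmax(self.magnitude_mohm(f))])


def make_rlc_trace(fixture: RLCFixture | None = None,
                   stim: ChirpStimulus | None = None,
                   dt_ms: float = 1.0, post_pad_s: float = 0.5) -> TraceSet:
    """Integrate the linear circuit driven by the chirp; the chirp-FFT
    impedance of the returned trace must match the closed form."""
    fixture = fixture or RLCFixture()
    stim = stim or ChirpStimulus()
    total_ms = (stim.delay_s + stim.duration_s + post_pad_s) * 1e3
    n = int(round(total_ms / dt_ms))
    t_s = np.arange(n) * dt_ms * 1e-3
    i_pa = stim.current(t_s)
    if fixture.inductive:
        # states: [v, i_L];  C v' = i - v/R - i_L;  L i_L' = v - R_L i_L
        a = np.array([[-1.0 / (fixture.r_ohm * fixture.c_farad), -1.0 / fixture.c_farad],
                      [1.0 / fixture.l_henry, -fixture.rl_ohm / fixture.l_henry]])
        b = np.array([[1.0 / fixture.c_farad], [0.0]])
        c = np.array([[1.0, 0.0]])
    else:
        a = np.array([[-1.0 / (fixture.r_ohm * fixture.c_farad)]])
        b = np.array([[1.0 / fixture.c_farad]])
        c = np.array([[1.0]])
    sys = signal.StateSpace(a, b, c, np.zeros((1, 1)))
    _, v, _ = signal.lsim(sys, i_pa * 1e-12, t_s)
    return TraceSet(time_ms=t_s * 1e3, current_pA=i_pa, sites=["rlc"],
                    v_mV=v[None, :] * 1e3, ca_nM=None,
                    meta={"fixture": "rlc", "stim": {"f_end": stim.f_end}})


SWEEP_KINDS = ("gcat", "tau_act", "tau_inact", "v12_act_cat", "v12_inact_cat",
               "gh", "v12_h", "tau_h", "gka", "v12_act_ka", "v12_inact_ka",
               "tau_act_ka", "tau_inact_ka", "ca_decay_tau", "rm", "cm")

_FACTORS = tuple(float(f) for f in np.geomspace(0.25, 4.0, 9))
_SHIFTS = tuple(float(s) for s in np.arange(-15.0, 15.0 + 1e-9, 2.5))

# kind -> (target, mechanism); mechanism decides how experiments apply the value
_KIND_TABLE = {
    "gcat": ("CaT", "density_factor"),
    "tau_act": (("CaT", "act"), "tau_scale"),
    "tau_inact": (("CaT", "inact"), "tau_scale"),
    "v12_act_cat": (("CaT", "act"), "v_shift"),
    "v12_inact_cat": (("CaT", "inact"), "v_shift"),
    "gh": ("h", "density_factor"),
    "v12_h": (("h", "act"), "v_shift"),
    "tau_h": (("h", "act"), "tau_scale"),
    "gka": ("KA_prox", "density_factor"),
    "v12_act_ka": (("KA_prox", "act"), "v_shift"),
    "v12_inact_ka": (("KA_prox", "inact"), "v_shift"),
    "tau_act_ka": (("KA_prox", "act"), "tau_scale"),
    "tau_inact_ka": (("KA_prox", "inact"), "tau_scale"),
    "ca_decay_tau": ("ca_decay_tau", "pool_factor"),
    "rm": ("rm", "passive_factor"),
    "cm": ("cm", "passive_factor"),
}


def sweep_grid(kind: str, factors=None, shifts=None) -> list[dict]:
    """Deterministic parameter grid for one sweep.

    Each entry is a dict with the sweep ``kind``, the swept ``value`` (a
    multiplicative factor or a V₁/₂ shift in mV), the ``target`` it applies
    to and the ``mechanism``; the unmodified default point (factor 1 / shift 0)
    is always a member.
    """
    if kind not in _KIND_TABLE:
        raise ValueError(f"unknown sweep kind {kind!r}")
    target, mech = _KIND_TABLE[kind]
    values = list(shifts or _SHIFTS) if mech == "v_shift" \
        else list(factors or _FACTORS)
    return [{"kind": kind, "value": float(v), "target": target, "mechanism": mech}
            for v in values]
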