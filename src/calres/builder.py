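"""Construction of compartmental models.

Two entry points:

* :func:`build_single_compartment` — the single-cylinder model (L = d = 60 μm,
  R_m = 11 kΩ·cm², C_m = 1 μF/cm², R_a = 100 Ω·cm; passive input resistance
  97 MΩ using the lateral cylinder surface) with a configurable channel set;
* :func:`discretize` — the gradient-endowed multi-compartment model: each
  section is split into an odd number of equal compartments by the d_λ rule
  (every compartment shorter than 0.1·λ_100, the AC space constant at 100 Hz),
  and per-compartment passive values, channel densities and V₁/₂ overrides are
  evaluated from the somato-apical gradients at the compartment midpoint path
  distance.

Basal and axonal compartments take somatic R_m/R_a and somatic channel
densities; K_A is distributed on basal dendrites via the same linear gradient;
the axon carries Na/K_DR only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .channels import ChannelSpec, default_registry
from .gradients import (CAT_GRADIENT, H_GRADIENT, KA_GRADIENT, RA_GRADIENT,
                        RM_GRADIENT, LinearConductanceGradient, PassiveGradient,
                        SigmoidConductanceGradient, h_vhalf_at, ka_model_at)
from .morphology import Morphology

STYPE_CODE = {"soma": 0, "axon": 1, "basal": 2, "apical": 3}


def lambda_100(diameter_um: float, ra_ohm_cm: float, cm_uf_cm2: float,
               freq_hz: float = 100.0) -> float:
    """AC length constant (μm) at ``freq_hz``: λ_f = ½·sqrt(d/(π f R_a C_m))."""
    if diameter_um <= 0 or ra_ohm_cm <= 0 or cm_uf_cm2 <= 0 or freq_hz <= 0:
        raise ValueError("lambda_100 arguments must be positive")
    d_cm = diameter_um * 1e-4
    cm_f = cm_uf_cm2 * 1e-6
    lam_cm = 0.5 * math.sqrt(d_cm / (math.pi * freq_hz * ra_ohm_cm * cm_f))
    return lam_cm * 1e4


def d_lambda_nseg(length_um: float, lam_um: float, d_lambda: float = 0.1) -> int:
    """Odd compartment count by the standard d_λ convention."""
    return int((length_um / (d_lambda * lam_um) + 0.9) / 2.0) * 2 + 1


@dataclass
class GradientSet:
    """All distance-dependent rules plus uniform defaults for one model build."""

    rm: PassiveGradient = RM_GRADIENT          # kΩ·cm²
    ra: PassiveGradient = RA_GRADIENT          # Ω·cm
    ka: LinearConductanceGradient = KA_GRADIENT
    h: SigmoidConductanceGradient = H_GRADIENT
    cat: SigmoidConductanceGradient = CAT_GRADIENT
    na_density: float = 16.0e-3                # S/cm², uniform
    kdr_density: float = 10.0e-3               # S/cm², uniform
    cm: float = 1.0                            # μF/cm²
    e_pas: float = -65.0                       # mV
    d_lambda: float = 0.1


CHANNEL_ORDER = ("Na", "KDR", "KA_prox", "KA_dist", "h", "CaT")


@dataclass
class CompartmentalModel:
    """Discretized cable model: per-compartment arrays plus channel registry.

    ``parent`` uses compartment indices with parent[i] < i (soma root = 0);
    ``path_dist_um`` is the midpoint path distance from the soma boundary.
    ``vhalf_shift`` maps (channel, gate name) -> per-compartment additive V₁/₂
    override (used for the apical h-channel activation gradient).
    """

    parent: np.ndarray
    length_um: np.ndarray
    diam_um: np.ndarray
    path_dist_um: np.ndarray
    stype: np.ndarray                 # codes per STYPE_CODE
    cm: np.ndarray                    # μF/cm²
    rm: np.ndarray                    # kΩ·cm²
    ra: np.ndarray                    # Ω·cm
    e_pas: np.ndarray                 # mV
    dens: dict[str, np.ndarray]       # S/cm² per channel
    vhalf_shift: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)
    registry: dict[str, ChannelSpec] = field(default_factory=default_registry)

    def __post_init__(self):
        n = self.n
        for name, arr in self.dens.items():
            if np.any(arr < 0):
                raise ValueError(f"negative density for {name}")
        if np.any(self.rm <= 0) or np.any(self.ra <= 0) or np.any(self.cm <= 0):
            raise ValueError("passive values must be positive")
        if np.any(self.length_um <= 0) or np.any(self.diam_um <= 0):
            raise ValueError("geometry must be positive")
        if n > 1 and np.any(self.parent[1:] >= np.arange(1, n)):
            raise ValueError("parents must precede children")

    @property
    def n(self) -> int:
        return len(self.length_um)

    @property
    def area_cm2(self) -> np.ndarray:
        """Lateral cylinder surface per compartment (no end caps)."""
        return np.pi * (self.diam_um * 1e-4) * (self.length_um * 1e-4)

    @property
    def g_pas(self) -> np.ndarray:
        """Leak conductance density, S/cm² (R_m in kΩ·cm²)."""
        return 1.0 / (self.rm * 1e3)

    def axial_conductance(self) -> np.ndarray:
        """Coupling conductance (S) between compartment i and its parent."""
        half_r = (self.ra * (self.length_um * 1e-4 / 2.0)
                  / (np.pi * (self.diam_um * 1e-4 / 2.0) ** 2))  # Ω, center to end
        g = np.zeros(self.n)
        for i in range(1, self.n):
            g[i] = 1.0 / (half_r[i] + half_r[self.parent[i]])
        return g

    def index_at(self, distance_um: float, stype: str = "apical") -> int:
        """Compartment whose midpoint is nearest to ``distance_um`` on ``stype``
        (the soma counts as distance 0)."""
        codes = [STYPE_CODE[stype], STYPE_CODE["soma"]]
        mask = np.isin(self.stype, codes)
        idx = np.flatnonzero(mask)
        if len(idx) == 0:
            raise ValueError(f"no {stype} compartments")
        dmax = self.path_dist_um[idx].max() + 0.5 * self.length_um[idx[-1]]
        if distance_um > dmax + 1e-9:
            raise ValueError(f"site {distance_um} μm beyond {stype} extent {dmax:.1f} μm")
        return int(idx[np.argmin(np.abs(self.path_dist_um[idx] - distance_um))])

    def check_d_lambda(self, d_lambda: float = 0.1) -> bool:
        lam = np.array([lambda_100(d, r, c)
                        for d, r, c in zip(self.diam_um, self.ra, self.cm)])
        return bool(np.all(self.length_um < d_lambda * lam + 1e-9))


def build_single_compartment(channels: dict[str, float] | None = None,
                             length_um: float = 60.0, diam_um: float = 60.0,
                             rm_kohm_cm2: float = 11.0, cm_uf_cm2: float = 1.0,
                             ra_ohm_cm: float = 100.0, e_pas_mv: float = -65.0,
                             registry: dict[str, ChannelSpec] | None = None,
                             ) -> CompartmentalModel:
    """Single-cylinder model with an explicit channel set (name -> S/cm²)."""
    registry = registry or default_registry()
    channels = channels or {}
    unknown = set(channels) - set(registry)
    if unknown:
        raise ValueError(f"unknown channels {sorted(unknown)}")
    dens = {name: np.array([float(channels.get(name, 0.0))]) for name in registry}
    return CompartmentalModel(
        parent=np.array([-1], dtype=np.int64),
        length_um=np.array([length_um]),
        diam_um=np.array([diam_um]),
        path_dist_um=np.array([0.0]),
        stype=np.array([STYPE_CODE["soma"]], dtype=np.int64),
        cm=np.array([cm_uf_cm2]),
        rm=np.array([rm_kohm_cm2]),
        ra=np.array([ra_ohm_cm]),
        e_pas=np.array([e_pas_mv]),
        dens=dens,
        registry=registry,
    )


def discretize(morph: Morphology, gradients: GradientSet | None = None,
               registry: dict[str, ChannelSpec] | None = None,
               d_lambda: float | None = None) -> CompartmentalModel:
    """Split a morphology into compartments by the d_λ rule and evaluate the
    gradients at each compartment's midpoint path distance."""
    grads = gradients or GradientSet()
    registry = registry or default_registry()
    dl = grads.d_lambda if d_lambda is None else d_lambda

    parent, length, diam, pdist, stype = [], [], [], [], []
    cm_l, rm_l, ra_l, epas_l = [], [], [], []
    dens = {name: [] for name in registry}
    h_shift = []

    last_comp_of_sec: dict[int, int] = {}
    for si, sec in enumerate(morph.sections):
        L = sec.length
        start_dist = 0.0 if sec.stype == "soma" else morph.path_distance_to_start(si)
        mid_sec = start_dist + L / 2.0
        is_soma = sec.stype == "soma"
        # gradient-evaluated Ra at the section midpoint feeds the d_λ rule
        ra_mid = grads.ra.value_at(mid_sec if sec.stype == "apical" else 0.0)
        lam = lambda_100(float(np.mean(sec.points[:, 3])), ra_mid, grads.cm)
        nseg = d_lambda_nseg(L, lam, dl)
        # the odd-count convention can leave a compartment marginally above
        # the d_λ bound once the local (tapered) diameter and gradient R_a are
        # used; bump until every compartment satisfies it with its own values
        while True:
            seg_len = L / nseg
            ok = True
            for j in range(nseg):
                mid_arc = (j + 0.5) * seg_len
                x = 0.0 if is_soma else start_dist + mid_arc
                ra_j = grads.ra.value_at(x) if sec.stype == "apical" \
                    else grads.ra.value_at(0.0)
                if seg_len >= dl * lambda_100(float(sec.diam_at(mid_arc)),
                                              ra_j, grads.cm):
                    ok = False
                    break
            if ok:
                break
            nseg += 2
        for j in range(nseg):
            mid_arc = (j + 0.5) * seg_len
            x = 0.0 if is_soma else start_dist + mid_arc
            if si == 0:
                par = -1 if j == 0 else len(length) - 1
            else:
                par = last_comp_of_sec[sec.parent] if j == 0 else len(length) - 1
            parent.append(par)
            length.append(seg_len)
            diam.append(float(sec.diam_at(mid_arc)))
            pdist.append(x)
            stype.append(STYPE_CODE[sec.stype])
            cm_l.append(grads.cm)
            epas_l.append(grads.e_pas)
            apical = sec.stype == "apical"
            rm_l.append(grads.rm.value_at(x) if apical else grads.rm.value_at(0.0))
            ra_l.append(grads.ra.value_at(x) if apical else grads.ra.value_at(0.0))
            for name in registry:
                dens[name].append(0.0)
            if sec.stype in ("soma", "apical", "basal"):
                dens["Na"][-1] = grads.na_density
                dens["KDR"][-1] = grads.kdr_density
                if apical:
                    dens[ka_model_at(x)][-1] = grads.ka.value_at(x)
                    dens["h"][-1] = grads.h.value_at(x)
                    dens["CaT"][-1] = grads.cat.value_at(x)
                elif sec.stype == "basal":
                    # somatic densities, K_A distributed along basal path too
                    dens[ka_model_at(x)][-1] = grads.ka.value_at(x)
                    dens["h"][-1] = grads.h.value_at(0.0)
                    dens["CaT"][-1] = grads.cat.value_at(0.0)
                else:
                    dens["KA_prox"][-1] = grads.ka.value_at(0.0)
                    dens["h"][-1] = grads.h.value_at(0.0)
                    dens["CaT"][-1] = grads.cat.value_at(0.0)
            else:  # axon
                dens["Na"][-1] = grads.na_density
                dens["KDR"][-1] = grads.kdr_density
            h_shift.append(h_vhalf_at(x) - (-82.0) if apical else 0.0)
        last_comp_of_sec[si] = len(length) - 1

    model = CompartmentalModel(
        parent=np.array(parent, dtype=np.int64),
        length_um=np.array(length),
        diam_um=np.array(diam),
        path_dist_um=np.array(pdist),
        stype=np.array(stype, dtype=np.int64),
        cm=np.array(cm_l),
        rm=np.array(rm_l),
        ra=np.array(ra_l),
        e_pas=np.array(epas_l),
        dens={k: np.array(v) for k, v in dens.items()},
        vhalf_shift={("h", "l"): np.array(h_shift)},
        registry=registry,
    )
    return model
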