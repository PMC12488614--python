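"""Cable-equation integrator.

The membrane equation per compartment (voltages mV, time ms, densities in
S/cm² and mA/cm²) is advanced with a semi-implicit scheme, unconditionally
stable on the cable tree at the default 25 μs step:

* implicit (backward-Euler) voltage solve, with the instantaneous ohmic
  channel conductances on the diagonal and the tree system solved by Hines
  elimination (parents precede children, O(n) per step);
* analytic exponential update of every gating variable toward its
  voltage-dependent steady state;
* the GHK Ca_T current entering the right-hand side explicitly at the current
  voltage (its density is orders of magnitude below C_m/dt, so this does not
  limit stability);
* a single intracellular calcium pool per compartment,
  d[Ca]/dt = −i_CaT/(2F·depth) − ([Ca]−[Ca]_rest)/τ_decay,
  also updated with the analytic exponential step.

Holding at −65 mV is enforced the way a patch experiment would: the injection
site is voltage-clamped during a settle period, the clamp current at steady
state becomes a constant bias current, and the chirp rides on top of it.

The inner loop is JIT-compiled with numba.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from numba import njit

from .builder import CompartmentalModel
from .channels import FARADAY, GAS_CONSTANT, GHKEnv
from .stimulus import ChirpStimulus
from .traces import TraceSet

_GCLAMP = 1.0e6  # penalty conductance (S/cm²) for the settle-phase voltage clamp


@dataclass
class CalciumPool:
    """Single-shell calcium pool (concentrations in mM internally)."""

    resting_mM: float = 1e-4      # 100 nM
    decay_tau_ms: float = 30.0
    shell_depth_um: float = 0.1
    influx_scale: float = 1.0

    def __post_init__(self):
        if self.decay_tau_ms <= 0 or self.shell_depth_um <= 0:
            raise ValueError("calcium pool parameters must be positive")


def update_calcium(pool: CalciumPool, ca_mM: float, i_cat_mA_cm2: float,
                   dt_ms: float) -> float:
    """One analytic-exponential step of the single-pool calcium ODE.

    d[Ca]/dt = −k·i_CaT/(2F·depth) − ([Ca] − rest)/τ; an inward (negative)
    CaT current density raises [Ca].  Same update the integration kernel uses.
    """
    drive = -1.0e4 * pool.influx_scale * i_cat_mA_cm2 / (
        2.0 * FARADAY * pool.shell_depth_um)  # mM/ms
    ca_inf = pool.resting_mM + pool.decay_tau_ms * drive
    out = ca_mM + (ca_inf - ca_mM) * (1.0 - math.exp(-dt_ms / pool.decay_tau_ms))
    return max(out, 0.0)


@dataclass
class SimulationConfig:
    dt_ms: float = 0.025
    temperature_c: float = 34.0
    hold_mV: float = -65.0
    record_dt_ms: float = 1.0
    settle_ms: float = 1000.0
    post_pad_s: float = 0.5
    env: GHKEnv = field(default_factory=GHKEnv)
    ca: CalciumPool = field(default_factory=CalciumPool)

    def __post_init__(self):
        if self.dt_ms <= 0:
            raise ValueError("dt must be positive")


@dataclass
class State:
    """Mutable integrator state (voltage mV, gate fractions, calcium mM)."""

    V: np.ndarray
    S: np.ndarray
    Ca: np.ndarray

    def copy(self) -> "State":
        return State(self.V.copy(), self.S.copy(), self.Ca.copy())


@njit(cache=True)
def _base_tau_nb(form, p, v):
    if form == 0:      # const
        return p[0]
    if form == 1:      # bell
        return p[0] + p[1] / (math.exp((v - p[2]) / p[3]) + math.exp(-(v - p[4]) / p[5]))
    if form == 2:      # sigmoid
        return p[0] + p[1] / (1.0 + math.exp((v - p[2]) / p[3]))
    # piecewise
    if v < p[0]:
        return math.exp((v + p[1]) / p[2])
    return p[3] + math.exp(-(v + p[4]) / p[5])


@njit(cache=True)
def _kernel(parent, ax_g, area, cdt, gpas, epas,
            chan_is_ghk, chan_erev, dens, gstart, gend,
            gate_exp, gate_vh, gate_k, gate_tform, gate_tp, gate_tfac, gate_toff,
            vshift,
            cao, ghk_f, ca_rest, ca_tau, ca_depth, ca_scale,
            stim, inj, bias, clamp, vhold,
            V, S, Ca, dt, stride, out_v, out_ca):
    n = V.shape[0]
    nch = chan_is_ghk.shape[0]
    nsteps = stim.shape[0]
    d = np.empty(n)
    r = np.empty(n)
    icat = np.empty(n)
    irec = 0
    for step in range(nsteps):
        if step % stride == 0:
            for i in range(n):
                out_v[i, irec] = V[i]
                out_ca[i, irec] = Ca[i]
            irec += 1
        # --- gate update (analytic exponential), then ionic terms ---
        for i in range(n):
            gs = gpas[i]
            ge = gpas[i] * epas[i]
            ic = 0.0
            for c in range(nch):
                de = dens[i, c]
                if de <= 0.0:
                    continue
                prod = 1.0
                for g in range(gstart[c], gend[c]):
                    veff = V[i] - vshift[i, g]
                    inf = 1.0 / (1.0 + math.exp(
                        min(max((gate_vh[g] - veff) / gate_k[g], -60.0), 60.0)))
                    tau = _base_tau_nb(gate_tform[g], gate_tp[g], veff) * gate_tfac[g] \
                        + gate_toff[g]
                    s = S[i, g] + (inf - S[i, g]) * (1.0 - math.exp(-dt / tau))
                    S[i, g] = s
                    for _ in range(gate_exp[g]):
                        prod *= s
                if chan_is_ghk[c] == 1:
                    x = V[i] / ghk_f
                    if abs(x) < 1e-12:
                        efun = 1.0
                    else:
                        efun = x / math.expm1(x)
                    drive = -ghk_f * (1.0 - (Ca[i] / cao) * math.exp(x)) * efun
                    ic += de * prod * drive
                else:
                    gc = de * prod
                    gs += gc
                    ge += gc * chan_erev[c]
            d[i] = cdt[i] + gs
            r[i] = cdt[i] * V[i] + ge - ic
            icat[i] = ic
        amp = stim[step] + bias
        r[inj] += amp * 1e-9 / area[inj]
        if clamp == 1:
            d[inj] += _GCLAMP
            r[inj] += _GCLAMP * vhold
        # --- axial terms and Hines solve ---
        for i in range(1, n):
            p = parent[i]
            d[i] += ax_g[i] / area[i]
            d[p] += ax_g[i] / area[p]
        for i in range(n - 1, 0, -1):
            p = parent[i]
            f = (-ax_g[i] / area[p]) / d[i]
            d[p] -= f * (-ax_g[i] / area[i])
            r[p] -= f * r[i]
        V[0] = r[0] / d[0]
        for i in range(1, n):
            p = parent[i]
            V[i] = (r[i] - (-ax_g[i] / area[i]) * V[p]) / d[i]
        # --- calcium pool ---
        for i in range(n):
            drive = -1.0e4 * ca_scale * icat[i] / (2.0 * FARADAY * ca_depth)  # mM/ms
            cainf = ca_rest + ca_tau * drive
            Ca[i] += (cainf - Ca[i]) * (1.0 - math.exp(-dt / ca_tau))
            if Ca[i] < 1e-12:
                Ca[i] = 1e-12
        if step % 2000 == 0 and not math.isfinite(V[inj]):
            return 1
    for i in range(n):
        out_v[i, irec] = V[i]
        out_ca[i, irec] = Ca[i]
    if not math.isfinite(V[inj]):
        return 1
    return 0


class IntegrationError(RuntimeError):
    pass


class CompiledCell:
    """A CompartmentalModel flattened to the arrays the kernel consumes.

    ``modifiers`` maps channel name -> gate role -> hooks (``v_shift``,
    ``tau_scale``, ``tau_offset``), the sweep entry points.
    """

    def __init__(self, model: CompartmentalModel, config: SimulationConfig | None = None,
                 modifiers: dict | None = None):
        cfg = config or SimulationConfig()
        self.model = model
        self.config = cfg
        n = model.n
        self.parent = model.parent.astype(np.int64)
        self.area = model.area_cm2
        self.ax_g = model.axial_conductance()
        self.cdt = 1e-3 * model.cm / cfg.dt_ms  # μF/cm² -> S/cm² scale at dt
        self.gpas = model.g_pas
        self.epas = model.e_pas.astype(float)

        names = [nm for nm in model.registry
                 if nm in model.dens and np.any(model.dens[nm] > 0)]
        self.chan_names = names
        specs = []
        for nm in names:
            spec = model.registry[nm]
            if modifiers and nm in modifiers:
                spec = spec.with_modifiers(modifiers[nm])
            specs.append(spec)
        nch = len(specs)
        self.chan_is_ghk = np.array(
            [1 if s.current_law == "ghk" else 0 for s in specs], dtype=np.int64)
        self.chan_erev = np.array([s.erev for s in specs])
        self.dens = np.column_stack([model.dens[nm] for nm in names]) \
            if nch else np.zeros((n, 0))

        gstart, gend = [], []
        gate_exp, gate_vh, gate_k, gate_tform, gate_tp = [], [], [], [], []
        gate_tfac, gate_toff = [], []
        vshift_cols = []
        for nm, spec in zip(names, specs):
            gstart.append(len(gate_exp))
            for g in spec.gates:
                gate_exp.append(g.exponent)
                gate_vh.append(g.vhalf)
                gate_k.append(g.k)
                gate_tform.append(g.tau_form)
                gate_tp.append(list(g.tau_params) + [0.0] * (6 - len(g.tau_params)))
                corr = g.q10 ** ((cfg.temperature_c - g.ref_temp) / 10.0)
                gate_tfac.append(g.tau_scale / corr)
                gate_toff.append(g.tau_offset)
                shift = np.full(n, g.v_half_shift)
                local = model.vhalf_shift.get((nm, g.name))
                if local is not None:
                    shift = shift + local
                vshift_cols.append(shift)
            gend.append(len(gate_exp))
        self.gstart = np.array(gstart, dtype=np.int64)
        self.gend = np.array(gend, dtype=np.int64)
        self.gate_exp = np.array(gate_exp, dtype=np.int64)
        self.gate_vh = np.array(gate_vh)
        self.gate_k = np.array(gate_k)
        self.gate_tform = np.array(gate_tform, dtype=np.int64)
        self.gate_tp = np.array(gate_tp) if gate_tp else np.zeros((0, 6))
        self.gate_tfac = np.array(gate_tfac)
        self.gate_toff = np.array(gate_toff)
        self.ng = len(gate_exp)
        self.vshift = np.column_stack(vshift_cols) if vshift_cols else np.zeros((n, 0))

        T = cfg.temperature_c + 273.15
        self.ghk_f = 1e3 * GAS_CONSTANT * T / (2.0 * FARADAY)  # mV
        self.cao = cfg.env.ca_out

    # ------------------------------------------------------------------
    def _gate_inf(self, g: int, v: np.ndarray) -> np.ndarray:
        z = np.clip((self.gate_vh[g] - v) / self.gate_k[g], -60, 60)
        return 1.0 / (1.0 + np.exp(z))

    def init_state(self, hold_mV: float | None = None) -> State:
        """All compartments at the holding voltage, gates at steady state,
        calcium at its local fixed point."""
        hold = self.config.hold_mV if hold_mV is None else hold_mV
        n = self.model.n
        V = np.full(n, float(hold))
        S = np.zeros((n, self.ng))
        for g in range(self.ng):
            S[:, g] = self._gate_inf(g, V - self.vshift[:, g])
        Ca = np.full(n, self.config.ca.resting_mM)
        for _ in range(4):
            icat = self._cat_current(V, S, Ca)
            Ca = self.config.ca.resting_mM - self.config.ca.decay_tau_ms * 1.0e4 \
                * self.config.ca.influx_scale * icat / (2.0 * FARADAY
                                                        * self.config.ca.shell_depth_um)
            Ca = np.maximum(Ca, 1e-12)
        return State(V, S, Ca)

    def _open_fraction(self, c: int, S: np.ndarray) -> np.ndarray:
        prod = np.ones(S.shape[0])
        for g in range(self.gstart[c], self.gend[c]):
            prod = prod * S[:, g] ** self.gate_exp[g]
        return prod

    def _cat_current(self, V, S, Ca) -> np.ndarray:
        """GHK channel current density (mA/cm²) summed over GHK channels."""
        out = np.zeros(len(V))
        for c in range(len(self.chan_names)):
            if self.chan_is_ghk[c] != 1:
                continue
            x = V / self.ghk_f
            efun = np.where(np.abs(x) < 1e-12, 1.0,
                            x / np.where(x != 0, np.expm1(x), 1.0))
            drive = -self.ghk_f * (1.0 - (Ca / self.cao) * np.exp(x)) * efun
            out += self.dens[:, c] * self._open_fraction(c, S) * drive
        return out

    def membrane_current_density(self, state: State) -> np.ndarray:
        """Total ionic membrane current density per compartment (mA/cm²)."""
        V, S, Ca = state.V, state.S, state.Ca
        i = self.gpas * (V - self.epas)
        for c in range(len(self.chan_names)):
            if self.chan_is_ghk[c] == 1:
                continue
            i = i + self.dens[:, c] * self._open_fraction(c, S) * (V - self.chan_erev[c])
        return i + self._cat_current(V, S, Ca)

    def axial_inflow_density(self, state: State) -> np.ndarray:
        """Net axial current flowing into each compartment (mA/cm²)."""
        V = state.V
        inflow = np.zeros(self.model.n)
        for i in range(1, self.model.n):
            p = self.parent[i]
            cur = (V[p] - V[i]) * self.ax_g[i]  # mA into i
            inflow[i] += cur / self.area[i]
            inflow[p] -= cur / self.area[p]
        return inflow

    # ------------------------------------------------------------------
    def _run_kernel(self, state: State, stim: np.ndarray, inj: int, bias: float,
                    clamp: bool, stride: int):
        nsteps = len(stim)
        nrec = (nsteps - 1) // stride + 2 if nsteps > 0 else 1
        out_v = np.empty((self.model.n, nrec))
        out_ca = np.empty((self.model.n, nrec))
        status = _kernel(
            self.parent, self.ax_g, self.area, self.cdt, self.gpas, self.epas,
            self.chan_is_ghk, self.chan_erev, self.dens, self.gstart, self.gend,
            self.gate_exp, self.gate_vh, self.gate_k, self.gate_tform, self.gate_tp,
            self.gate_tfac, self.gate_toff, self.vshift,
            self.cao, self.ghk_f, self.config.ca.resting_mM, self.config.ca.decay_tau_ms,
            self.config.ca.shell_depth_um, self.config.ca.influx_scale,
            stim, inj, bias, 1 if clamp else 0, self.config.hold_mV,
            state.V, state.S, state.Ca, self.config.dt_ms, stride, out_v, out_ca)
        if status != 0:
            raise IntegrationError("integration diverged (NaN/overflow in voltage)")
        t_rec = np.concatenate([np.arange(0, nsteps, stride), [nsteps]]) * self.config.dt_ms
        return t_rec, out_v, out_ca

    def step(self, state: State, n_steps: int = 1, stim_pA: float = 0.0,
             inj: int = 0, bias: float = 0.0) -> State:
        """Advance the state ``n_steps`` integration steps (testing hook)."""
        stim = np.full(n_steps, float(stim_pA))
        self._run_kernel(state, stim, inj, bias, clamp=False, stride=max(n_steps, 1))
        return state

    def settle(self, inj: int = 0, hold_mV: float | None = None,
               settle_ms: float | None = None) -> tuple[State, float]:
        """Clamp the injection site at the holding voltage until steady state;
        return the settled state and the constant bias current (pA) that keeps
        the site there once the clamp is released."""
        hold = self.config.hold_mV if hold_mV is None else hold_mV
        settle_ms = self.config.settle_ms if settle_ms is None else settle_ms
        state = self.init_state(hold)
        nsteps = int(round(settle_ms / self.config.dt_ms))
        stim = np.zeros(nsteps)
        self._run_kernel(state, stim, inj, 0.0, clamp=True, stride=nsteps)
        state.V[inj] = hold  # remove the ~nV clamp-penalty residual
        i_need = self.membrane_current_density(state) - self.axial_inflow_density(state)
        bias_pA = float(i_need[inj] * self.area[inj] * 1e9)
        return state, bias_pA

    def run(self, state: State, stim: np.ndarray, inj: int = 0, bias: float = 0.0,
            record_idx: list[int] | None = None, record_stride: int | None = None):
        """Integrate under a per-step stimulus array (pA at the injection site)."""
        stride = record_stride or max(int(round(self.config.record_dt_ms
                                                / self.config.dt_ms)), 1)
        t_rec, out_v, out_ca = self._run_kernel(state, stim, inj, bias,
                                                clamp=False, stride=stride)
        idx = record_idx if record_idx is not None else list(range(self.model.n))
        return t_rec, out_v[idx], out_ca[idx]


def run_chirp(model: CompartmentalModel, stim: ChirpStimulus | None = None,
              config: SimulationConfig | None = None,
              record_sites_um=(0.0,), inj_site_um: float = 0.0,
              site_type: str = "apical", modifiers: dict | None = None) -> TraceSet:
    """Full chirp protocol: settle at the holding potential, inject the chirp
    (plus bias) at ``inj_site_um``, record voltage and calcium at
    ``record_sites_um``.  Returns a TraceSet; the injected-current column is
    the oscillatory chirp only (the constant bias is in ``meta``)."""
    stim = stim or ChirpStimulus()
    cfg = config or SimulationConfig()
    cell = CompiledCell(model, cfg, modifiers=modifiers)
    inj = model.index_at(inj_site_um, site_type) if model.n > 1 else 0
    rec_idx = [model.index_at(x, site_type) if model.n > 1 else 0
               for x in record_sites_um]
    state, bias = cell.settle(inj=inj)
    total_ms = (stim.delay_s + stim.duration_s + cfg.post_pad_s) * 1e3
    stim_arr = stim.sample(cfg.dt_ms, total_ms)
    t_rec, v, ca = cell.run(state, stim_arr, inj=inj, bias=bias, record_idx=rec_idx)
    cur = stim.current(t_rec * 1e-3)
    meta = {
        "bias_pA": bias, "hold_mV": cfg.hold_mV, "dt_ms": cfg.dt_ms,
        "stim": {"amplitude_pA": stim.amplitude_pA, "f_start": stim.f_start,
                 "f_end": stim.f_end, "duration_s": stim.duration_s,
                 "delay_s": stim.delay_s},
        "inj_site_um": inj_site_um,
        "suprathreshold": bool(np.max(v) > -20.0),
    }
    if meta["suprathreshold"]:
        warnings.warn("suprathreshold excursion (V > -20 mV); analysis is flagged")
    sites = [f"{x:g}" for x in record_sites_um]
    return TraceSet(time_ms=t_rec, current_pA=cur, sites=sites, v_mV=v,
                    ca_nM=ca * 1e6, meta=meta)


def probe_impedance(model: CompartmentalModel, freq_hz: float,
                    amplitude_pA: float = 50.0, config: SimulationConfig | None = None,
                    site_um: float = 0.0, n_measure_cycles: int = 4,
                    transient_s: float = 2.0, modifiers: dict | None = None):
    """Single-frequency steady-state impedance probe (independent of the
    chirp-FFT route): drive with a pure sinusoid, discard the transient, and
    take the quadrature amplitude ratio over whole cycles.

    Returns (|Z_V| in MΩ, |Z_Ca| in nM/pA).
    """
    cfg = config or SimulationConfig()
    cell = CompiledCell(model, cfg, modifiers=modifiers)
    inj = model.index_at(site_um) if model.n > 1 else 0
    state, bias = cell.settle(inj=inj)
    period_ms = 1e3 / freq_hz
    total_ms = transient_s * 1e3 + n_measure_cycles * period_ms
    nsteps = int(round(total_ms / cfg.dt_ms))
    t = np.arange(nsteps) * cfg.dt_ms * 1e-3
    stim = amplitude_pA * np.sin(2 * np.pi * freq_hz * t)
    t_rec, v, ca = cell.run(state, stim, inj=inj, bias=bias, record_idx=[inj])
    tail = t_rec >= transient_s * 1e3
    tt = t_rec[tail] * 1e-3
    w = 2 * np.pi * freq_hz

    design = np.column_stack([np.sin(w * tt), np.cos(w * tt), np.ones_like(tt)])

    def _amp(x):
        coef, *_ = np.linalg.lstsq(design, x, rcond=None)
        return float(np.hypot(coef[0], coef[1]))

    amp_i = _amp(amplitude_pA * np.sin(w * tt))
    zv = _amp(v[0, tail]) / amp_i * 1e3       # mV/pA -> MΩ
    zca = _amp(ca[0, tail] * 1e6) / amp_i     # nM/pA
    return zv, zca
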