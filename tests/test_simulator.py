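"""Integrator correctness: analytic RC oracles, initialization, calcium pool,
numerical convergence, and trace round trips."""

import numpy as np
import pytest

from calres import build_single_compartment, run_chirp
from calres.analysis import impedance
from calres.engine import CalciumPool, CompiledCell, SimulationConfig
from calres.stimulus import ChirpStimulus
from calres.traces import TraceSet

R_IN_MOHM = 11e3 / (np.pi * 60e-4 * 60e-4) / 1e6  # 97.26
TAU_MS = 11.0


def test_chirp_stimulus_waveform():
    stim = ChirpStimulus()
    assert stim.current(stim.delay_s) == 0.0
    assert stim.current(0.1) == 0.0                       # pre-onset rest
    assert stim.current(stim.delay_s + 15.0) == pytest.approx(0.0, abs=1e-6)
    t = np.linspace(stim.delay_s, stim.delay_s + 15.0, 2_000_001)
    cur = stim.current(t)
    assert np.max(np.abs(cur)) <= 50.0 + 1e-9
    assert np.max(np.abs(cur)) == pytest.approx(50.0, rel=1e-4)
    assert stim.current(20.0) == 0.0                      # past the window


def test_passive_step_matches_rc_analytic():
    cell = CompiledCell(build_single_compartment())
    state, bias = cell.settle()
    assert bias == pytest.approx(0.0, abs=1e-6)  # leak reversal at the hold
    n = int(60.0 / cell.config.dt_ms)
    t, v, _ = cell.run(state, np.full(n, 50.0), record_stride=4)
    expected = -65.0 + 50e-12 * R_IN_MOHM * 1e6 * 1e3 * (1 - np.exp(-t / TAU_MS))
    assert np.max(np.abs(v[0] - expected)) < 0.01 * 50e-12 * R_IN_MOHM * 1e9


def test_equilibrium_is_fixed_point():
    # passive at the leak reversal with no input: nothing moves
    cell = CompiledCell(build_single_compartment())
    state = cell.init_state()
    cell.step(state, n_steps=2000)
    assert np.max(np.abs(state.V + 65.0)) < 1e-12


def test_charge_conserved_without_conductances():
    cell = CompiledCell(build_single_compartment(rm_kohm_cm2=1e15))
    state = cell.init_state(-53.2)
    cell.step(state, n_steps=5000)
    assert state.V[0] == pytest.approx(-53.2, abs=1e-9)


def test_initialize_settles_at_hold():
    model = build_single_compartment({"CaT": 500e-6})
    cell = CompiledCell(model)
    state, bias = cell.settle()
    assert state.Ca[0] > 0
    free = state.copy()
    cell.step(free, n_steps=int(1000 / cell.config.dt_ms), stim_pA=bias)
    assert abs(free.V[0] + 65.0) < 0.1


def test_calcium_initialized_at_fixed_point():
    model = build_single_compartment({"CaT": 500e-6})
    cell = CompiledCell(model)
    state, _ = cell.settle()
    icat = cell._cat_current(state.V, state.S, state.Ca)
    ca = cell.config.ca
    expected = ca.resting_mM - ca.decay_tau_ms * 1e4 * icat[0] / (
        2 * 96485.33212 * ca.shell_depth_um)
    assert state.Ca[0] == pytest.approx(expected, rel=1e-6)
    # resting calcium without any channel is exactly 100 nM
    passive = CompiledCell(build_single_compartment())
    st, _ = passive.settle()
    assert st.Ca[0] * 1e6 == pytest.approx(100.0)


def test_update_calcium_examples():
    from calres.engine import update_calcium
    pool = CalciumPool(decay_tau_ms=100.0)
    # pure decay from 200 nM follows the exponential exactly
    ca = 2e-4
    for _ in range(1000):
        ca = update_calcium(pool, ca, 0.0, 0.1)
    assert ca == pytest.approx(1e-4 + 1e-4 * np.exp(-1.0), rel=1e-9)
    # resting concentration is a fixed point
    assert update_calcium(pool, 1e-4, 0.0, 1.0) == pytest.approx(1e-4)
    # constant inward current: steady state = rest + τ × influx term
    i = -1e-3  # mA/cm², inward
    ca = 1e-4
    for _ in range(5000):
        ca = update_calcium(pool, ca, i, 1.0)
    expected = 1e-4 + 100.0 * 1e4 * 1e-3 / (2 * 96485.33212 * pool.shell_depth_um)
    assert ca == pytest.approx(expected, rel=1e-6)
    assert ca > 1e-4  # inward current raises calcium


def test_calcium_pure_decay_analytic():
    cell = CompiledCell(build_single_compartment(),
                        SimulationConfig(ca=CalciumPool(decay_tau_ms=100.0)))
    state = cell.init_state()
    state.Ca[:] = 2e-4  # 200 nM
    n = int(250.0 / cell.config.dt_ms)
    t, _, ca = cell.run(state, np.zeros(n), record_stride=40)
    expected = 1e-4 + 1e-4 * np.exp(-t / 100.0)
    assert np.max(np.abs(ca[0] - expected)) < 1e-9


def test_dt_halving_convergence():
    vals = []
    for dt in (0.025, 0.0125):
        cell = CompiledCell(build_single_compartment(), SimulationConfig(dt_ms=dt))
        state, _ = cell.settle()
        n = int(1000.0 / dt)
        _, v, _ = cell.run(state, np.full(n, 50.0), record_stride=n)
        vals.append(v[0, -1])
    assert abs(vals[0] - vals[1]) < 1e-6


def test_passive_impedance_matches_rc_closed_form(passive_traces):
    prof = impedance(passive_traces.v_mV[0], passive_traces.current_pA,
                     passive_traces.dt_ms, kind="voltage")
    c_tot = 1e-6 * np.pi * 60e-4 * 60e-4  # F
    expected = R_IN_MOHM / np.sqrt(
        1 + (2 * np.pi * prof.freq_hz * R_IN_MOHM * 1e6 * c_tot) ** 2)
    rel = np.abs(prof.magnitude - expected) / expected
    assert np.max(rel) < 0.02
    # passive envelope decreases monotonically with frequency (RC low-pass)
    sm = np.convolve(prof.magnitude, np.ones(9) / 9, mode="valid")
    assert np.all(np.diff(sm) < 1e-3)


def test_chirp_run_calcium_sane(cat_traces):
    ca = cat_traces.ca_nM[0]
    assert np.all(ca >= 0)
    # returns to rest well after the stimulus (padding ≫ 5 decay τ)
    assert ca[-1] == pytest.approx(ca[0], rel=0.01)
    assert not cat_traces.meta["suprathreshold"]


def test_suprathreshold_excursion_flagged():
    model = build_single_compartment({"Na": 16e-3, "KDR": 10e-3, "CaT": 500e-6})
    stim = ChirpStimulus(amplitude_pA=4000.0, duration_s=1.0, delay_s=0.1)
    cfg = SimulationConfig(settle_ms=200.0, post_pad_s=0.1)
    with pytest.warns(UserWarning, match="suprathreshold"):
        traces = run_chirp(model, stim, cfg)
    assert traces.meta["suprathreshold"]


def test_traceset_round_trips(tmp_path, cat_traces):
    for fmt, write, read in (
            ("csv", cat_traces.to_csv, TraceSet.from_csv),
            ("npz", cat_traces.to_npz, TraceSet.from_npz)):
        path = tmp_path / f"traces.{fmt}"
        write(path)
        back = read(path)
        assert np.array_equal(back.time_ms, cat_traces.time_ms)
        assert np.array_equal(back.v_mV, cat_traces.v_mV)
        assert np.array_equal(back.ca_nM, cat_traces.ca_nM)
        assert back.meta == cat_traces.meta
        assert back.sites == cat_traces.sites
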