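"""Gating curves, modifier hooks and the GHK current law."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from calres.channels import (FARADAY, GHKEnv, channel_current, default_registry,
                             gate_steady_state, gate_time_constant,
                             ghk_current_density, ghk_driving_force)

REG = default_registry()
ALL_GATES = [(cn, g.name, g) for cn, ch in REG.items() for g in ch.gates]
GATE_IDS = [f"{c}.{n}" for c, n, _ in ALL_GATES]
VGRID = np.linspace(-120.0, 60.0, 361)


@pytest.mark.parametrize("chan,gname,gate", ALL_GATES, ids=GATE_IDS)
def test_gate_curves_bounded_and_positive(chan, gname, gate):
    inf = gate.steady_state(VGRID)
    tau = gate.time_constant(VGRID, 34.0)
    assert np.all((inf >= 0) & (inf <= 1))
    assert np.all(tau > 0)


@settings(max_examples=60, derandomize=True)
@given(v=st.floats(-120, 60), shift=st.floats(-20, 20))
def test_vhalf_shift_translates_steady_state(v, shift):
    from dataclasses import replace
    gate = REG["CaT"].gates[0]
    shifted = replace(gate, v_half_shift=gate.v_half_shift + shift)
    assert shifted.steady_state(v + shift) == pytest.approx(
        gate.steady_state(v), rel=1e-12, abs=1e-15)
    # τ is V1/2-anchored: it translates with the same shift
    assert shifted.time_constant(v + shift, 34.0) == pytest.approx(
        gate.time_constant(v, 34.0), rel=1e-12)


def test_boltzmann_midpoint_and_monotonicity():
    gate = REG["KDR"].gates[0]
    assert gate.steady_state(gate.vhalf) == pytest.approx(0.5)
    inf = gate.steady_state(VGRID)
    assert inf[0] < inf[-1]  # activation gate rises with depolarization
    hgate = REG["h"].gates[0]
    assert hgate.steady_state(-120) > hgate.steady_state(-40)


def test_tau_scale_and_q10():
    from dataclasses import replace
    gate = REG["CaT"].gates[1]  # q10 = 3, ref 24 °C
    base = gate.time_constant(-65.0, gate.ref_temp)
    doubled = replace(gate, tau_scale=2.0)
    assert doubled.time_constant(-65.0, gate.ref_temp) == pytest.approx(2 * base)
    assert gate.time_constant(-65.0, gate.ref_temp + 10.0) == pytest.approx(base / 3.0)
    with pytest.raises(ValueError):
        replace(gate, tau_scale=-1.0).time_constant(-65.0)


def test_ghk_limits_and_sign():
    env = GHKEnv()
    # equal concentrations, v = 0: no driving force
    sym = GHKEnv(ca_out=1.0, ca_in=1.0)
    assert ghk_current_density(0.0, sym, 1e-4) == pytest.approx(0.0, abs=1e-15)
    # physiological gradient at rest: inward (negative) current
    assert ghk_current_density(-65.0, env, 1e-4) < 0
    # removable singularity: v -> 0 limit is P z F (ci - co)
    lim = 1e3 * 1.0 * env.valence * FARADAY * (env.ca_in - env.ca_out) * 1e-6
    for v in (1e-9, -1e-9):
        assert ghk_current_density(v, env, 1.0) == pytest.approx(lim, rel=1e-9)
    with pytest.raises(ValueError):
        ghk_current_density(-65.0, env, -1.0)


def test_ghk_driving_force_proportional_to_flux_form():
    """The conductance-units drive and the permeability flux form are the same
    expression up to a voltage-independent constant."""
    env = GHKEnv()
    v = np.linspace(-110, 50, 33)
    ratio = ghk_current_density(v, env, 1e-4) / ghk_driving_force(v, env)
    assert np.ptp(ratio) / np.mean(ratio) < 1e-12


def test_channel_current_rules():
    env = GHKEnv()
    kdr = REG["KDR"]
    assert channel_current(kdr, -40.0, [0.0], env) == 0.0
    assert channel_current(kdr, kdr.erev, [0.7], env) == pytest.approx(0.0)
    h = REG["h"]
    assert h.erev == -30.0
    assert channel_current(h, -65.0, [0.5], env) < 0  # inward, depolarizing
    with pytest.raises(ValueError):
        channel_current(REG["CaT"], -65.0, [0.5], env)  # gate count mismatch
    with pytest.raises(ValueError):
        channel_current(kdr, -40.0, [1.5], env)


def test_total_current_continuous_including_ghk_origin():
    env = GHKEnv()
    v = np.linspace(-120, 60, 3601)  # 0.05 mV steps straddling 0
    for chan in REG.values():
        states = [g.steady_state(v) for g in chan.gates]
        cur = channel_current(chan, v, states, env)
        dv = np.abs(np.diff(cur))
        scale = np.max(np.abs(cur)) + 1e-12
        assert np.max(dv) < 0.02 * scale


def test_cat_window_current_exists(registry):
    cat = registry["CaT"]
    act, inact = cat.gates
    v = np.linspace(-120, 60, 721)
    window = (act.steady_state(v) > 0.01) & (inact.steady_state(v) > 0.01)
    assert window.any(), "T-type window must admit subthreshold calcium entry"
    assert v[window].min() < -65.0 < v[window].max() + 5.0
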