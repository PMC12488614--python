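"""Impedance analysis against constructed profiles and the linear-circuit
fixture with a closed-form impedance."""

import numpy as np
import pytest

from calres.analysis import (ImpedanceProfile, impedance, resonance_frequency,
                             resonance_strength, summarize)
from calres.stimulus import ChirpStimulus
from calres.synthetic import RLCFixture, make_rlc_trace


def _chirp_samples(dt_ms=1.0, total_s=16.0):
    stim = ChirpStimulus()
    n = int(total_s * 1e3 / dt_ms)
    t = np.arange(n) * dt_ms * 1e-3
    return stim.current(t), dt_ms


def test_instantaneous_linear_response_gives_flat_profile():
    cur, dt = _chirp_samples()
    alpha = 0.37  # mV per pA
    prof = impedance(alpha * cur, cur, dt, kind="voltage")
    assert np.allclose(prof.magnitude, alpha * 1e3, rtol=1e-9)  # MΩ
    s = summarize(prof)
    assert s.q == pytest.approx(1.0, rel=1e-9)


def test_linearity_scaling_leaves_fr_and_q_unchanged(cat_traces):
    v = cat_traces.v_mV[0]
    cur = cat_traces.current_pA
    p1 = impedance(v, cur, cat_traces.dt_ms)
    p2 = impedance(2 * v - 65.0, cur, cat_traces.dt_ms)  # doubled + offset
    assert np.allclose(p2.magnitude, 2 * p1.magnitude, rtol=1e-6)
    assert resonance_frequency(p2) == pytest.approx(resonance_frequency(p1))
    assert resonance_strength(p2) == pytest.approx(resonance_strength(p1))


def test_gaussian_bump_argmax():
    f = np.arange(0.5, 15.0001, 0.0625)
    mag = 5.0 + 4.0 * np.exp(-0.5 * ((f - 6.0) / 1.5) ** 2)
    prof = ImpedanceProfile(freq_hz=f, z=mag.astype(complex), kind="voltage")
    assert resonance_frequency(prof) == pytest.approx(6.0, abs=0.0625)
    s = summarize(prof)
    assert not s.no_resonance


def test_monotone_profile_flags_no_resonance():
    f = np.arange(0.5, 15.0001, 0.0625)
    prof = ImpedanceProfile(freq_hz=f, z=(10.0 / (1 + f)).astype(complex),
                            kind="voltage")
    s = summarize(prof)
    assert s.no_resonance
    assert s.f_r_hz == pytest.approx(0.5)
    flat = ImpedanceProfile(freq_hz=f, z=np.full_like(f, 3.0, dtype=complex),
                            kind="voltage")
    assert resonance_strength(flat) == pytest.approx(1.0)


def test_impedance_error_paths():
    cur, dt = _chirp_samples()
    with pytest.raises(ValueError):
        impedance(cur[:-1], cur, dt)
    with pytest.raises(ValueError):
        impedance(cur, cur, dt, kind="conductance")
    with pytest.raises(ValueError):
        impedance(np.zeros(1000), np.zeros(1000), dt)  # no spectral content


def test_rlc_fixture_recovers_closed_form():
    fixture = RLCFixture()
    traces = make_rlc_trace(fixture, dt_ms=1.0)
    prof = impedance(traces.v_mV[0], traces.current_pA, traces.dt_ms,
                     kind="voltage")
    # |Z| matches the closed form across the band within 2%
    expected = fixture.magnitude_mohm(prof.freq_hz)
    assert np.max(np.abs(prof.magnitude - expected) / expected) < 0.02
    s = summarize(prof)
    f_closed = fixture.peak_frequency()
    assert s.f_r_hz == pytest.approx(f_closed, abs=0.0625)
    q_closed = fixture.magnitude_mohm(f_closed) / fixture.magnitude_mohm(0.5)
    assert s.q == pytest.approx(q_closed, rel=0.02)


def test_rlc_passive_limit_is_rc():
    fixture = RLCFixture(inductive=False)
    traces = make_rlc_trace(fixture, dt_ms=1.0)
    prof = impedance(traces.v_mV[0], traces.current_pA, traces.dt_ms,
                     kind="voltage")
    r, c = fixture.r_ohm, fixture.c_farad
    expected = (r / np.sqrt(1 + (2 * np.pi * prof.freq_hz * r * c) ** 2)) / 1e6
    assert np.max(np.abs(prof.magnitude - expected) / expected) < 0.01
    assert summarize(prof).no_resonance
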