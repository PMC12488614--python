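"""Chirp (ZAP) current stimulus.

A constant-amplitude sinusoid whose instantaneous frequency rises linearly
from ``f_start`` to ``f_end`` over ``duration``; the phase is the integral of
the instantaneous frequency, φ(t) = 2π[f₀t + (f₁−f₀)t²/(2T)].  Defaults are
the standard protocol used throughout this package: 50 pA, 0→15 Hz in 15 s,
with a 0.5 s pre-stimulus rest.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class ChirpStimulus:
    amplitude_pA: float = 50.0
    f_start: float = 0.0
    f_end: float = 15.0
    duration_s: float = 15.0
    delay_s: float = 0.5

    def __post_init__(self):
        if self.duration_s <= 0 or self.delay_s < 0:
            raise ValueError("duration must be positive, delay non-negative")

    def current(self, t_s):
        """Injected current (pA) at time t (s, measured from simulation start);
        zero outside the stimulus window."""
        t = np.asarray(t_s, dtype=float)
        tt = t - self.delay_s
        phase = 2.0 * np.pi * (self.f_start * tt
                               + (self.f_end - self.f_start) * tt ** 2
                               / (2.0 * self.duration_s))
        out = np.where((tt >= 0.0) & (tt <= self.duration_s),
                       self.amplitude_pA * np.sin(phase), 0.0)
        return float(out) if np.ndim(t_s) == 0 else out

    def sample(self, dt_ms: float, total_ms: float) -> np.ndarray:
        """Per-step current array on the simulation grid t = 0, dt, 2dt, ..."""
        n = int(round(total_ms / dt_ms))
        t = np.arange(n) * (dt_ms * 1e-3)
        return self.current(t)


def chirp_current(stim: ChirpStimulus, t_s):
    return stim.current(t_s)
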