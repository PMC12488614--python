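"""Impedance profiles and resonance measures.

The complex impedance is the Fourier transform of the (baseline-subtracted)
response divided by the Fourier transform of the injected chirp current,
restricted to the analysis band (0.5 Hz to the chirp's top frequency):

    Z(f) = FFT(response − baseline) / FFT(stimulus),   |Z| = sqrt(Re² + Im²)

For voltage responses |Z| is in MΩ; for calcium responses in nM/pA (the
resting calcium offset is the baseline that gets removed — the impedance
applies to the oscillatory component).

The resonance frequency f_R is the argmax of the (lightly smoothed) |Z(f)|,
ties broken toward the lower frequency; the resonance strength Q is
max |Z| divided by |Z(0.5 Hz)|, so Q ≥ 1 with equality for a profile that is
maximal at the band edge (no resonance).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .traces import TraceSet

F_REF_HZ = 0.5  # lower band edge and Q reference frequency


@dataclass
class ImpedanceProfile:
    freq_hz: np.ndarray
    z: np.ndarray            # complex
    kind: str                # "voltage" | "calcium"

    @property
    def magnitude(self) -> np.ndarray:
        return np.abs(self.z)


@dataclass
class ResonanceSummary:
    f_r_hz: float
    q: float
    peak_magnitude: float
    ref_magnitude: float
    no_resonance: bool


def _baseline(response: np.ndarray, stimulus: np.ndarray) -> float:
    """Pre-stimulus baseline: mean of the response over the leading run of
    exact zeros in the stimulus (the rest period); falls back to the first
    sample if the stimulus starts immediately."""
    nz = np.flatnonzero(stimulus != 0.0)
    n0 = nz[0] if len(nz) else len(stimulus)
    if n0 >= 2:
        return float(np.mean(response[:n0]))
    return float(response[0])


def impedance(response: np.ndarray, stimulus: np.ndarray, dt_ms: float,
              kind: str = "voltage", f_min: float = F_REF_HZ,
              f_max: float = 15.0) -> ImpedanceProfile:
    """Chirp-FFT impedance profile over [f_min, f_max].

    ``response`` is mV (voltage) or nM (calcium); ``stimulus`` is pA.
    Raises if the stimulus has negligible spectral content anywhere in band.
    """
    response = np.asarray(response, dtype=float)
    stimulus = np.asarray(stimulus, dtype=float)
    if response.shape != stimulus.shape:
        raise ValueError("response and stimulus must share the time grid")
    n = len(response)
    freqs = np.fft.rfftfreq(n, d=dt_ms * 1e-3)
    spec_i = np.fft.rfft(stimulus)
    spec_r = np.fft.rfft(response - _baseline(response, stimulus))
    band = (freqs >= f_min) & (freqs <= f_max)
    if not np.any(band):
        raise ValueError("empty analysis band")
    mag_i = np.abs(spec_i[band])
    smax = float(np.max(np.abs(spec_i)))
    if smax == 0.0 or np.min(mag_i) < 1e-4 * smax:
        raise ValueError("stimulus has negligible spectral content in the band")
    z = spec_r[band] / spec_i[band]
    if kind == "voltage":
        z = z * 1e3  # mV/pA -> MΩ
    elif kind != "calcium":
        raise ValueError(f"unknown impedance kind {kind!r}")
    return ImpedanceProfile(freq_hz=freqs[band], z=z, kind=kind)


def default_smooth_bins(freq_hz: np.ndarray, width_hz: float = 0.5) -> int:
    """Odd moving-average width covering ``width_hz`` of spectrum.

    The chirp-FFT impedance estimate carries ripple with a period of roughly
    half a hertz (onset/ring-down interference of the swept response); the
    argmax is only robust once the smoothing window spans that period, while
    staying well below the several-hertz width of the resonance peak itself.
    """
    df = float(freq_hz[1] - freq_hz[0])
    bins = max(int(round(width_hz / df)), 5)
    return bins + 1 if bins % 2 == 0 else bins


def _smooth(mag: np.ndarray, bins: int) -> np.ndarray:
    if bins <= 1:
        return mag
    pad = bins // 2
    padded = np.pad(mag, pad, mode="reflect")
    return np.convolve(padded, np.ones(bins) / bins, mode="valid")


def summarize(profile: ImpedanceProfile,
              smooth_bins: int | None = None) -> ResonanceSummary:
    """Resonance frequency and strength from a profile.

    ``smooth_bins`` defaults to a 0.5 Hz moving average (odd bin count)."""
    if smooth_bins is None:
        smooth_bins = default_smooth_bins(profile.freq_hz)
    mag = _smooth(profile.magnitude, smooth_bins)
    i_max = int(np.argmax(mag))  # first occurrence -> ties go to lower f
    ref = float(np.interp(F_REF_HZ, profile.freq_hz, mag))
    if ref <= 0:
        raise ValueError("zero impedance at the reference frequency")
    f_r = float(profile.freq_hz[i_max])
    if 0 < i_max < len(mag) - 1:
        # parabolic sub-bin refinement of the peak location
        a, b, c = mag[i_max - 1], mag[i_max], mag[i_max + 1]
        denom = a - 2.0 * b + c
        if denom < 0:
            f_r += 0.5 * (a - c) / denom * float(profile.freq_hz[1]
                                                 - profile.freq_hz[0])
    return ResonanceSummary(
        f_r_hz=f_r,
        q=float(mag[i_max] / ref),
        peak_magnitude=float(mag[i_max]),
        ref_magnitude=ref,
        no_resonance=(i_max == 0),
    )


def resonance_frequency(profile: ImpedanceProfile,
                        smooth_bins: int | None = None) -> float:
    """Frequency (Hz) at which |Z| peaks (band minimum if monotone decreasing)."""
    return summarize(profile, smooth_bins).f_r_hz


def resonance_strength(profile: ImpedanceProfile,
                       smooth_bins: int | None = None) -> float:
    """Q = max |Z| / |Z(0.5 Hz)|."""
    return summarize(profile, smooth_bins).q


def analyze_traces(traces: TraceSet, site: str | None = None,
                   smooth_bins: int | None = None) -> dict:
    """Voltage and calcium impedance summaries for one recorded site.

    Returns a dict with profiles and (f_R, Q) for both signals.
    """
    site = site or traces.sites[0]
    i = traces.site_index(site)
    f_max = traces.meta.get("stim", {}).get("f_end", 15.0)
    zv = impedance(traces.v_mV[i], traces.current_pA, traces.dt_ms,
                   kind="voltage", f_max=f_max)
    out = {"site": site, "voltage": (zv, summarize(zv, smooth_bins))}
    if traces.ca_nM is not None:
        zca = impedance(traces.ca_nM[i], traces.current_pA, traces.dt_ms,
                        kind="calcium", f_max=f_max)
        out["calcium"] = (zca, summarize(zca, smooth_bins))
    return out
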