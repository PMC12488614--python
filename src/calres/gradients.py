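"""Somato-apical parameter gradients.

The multi-compartment model distributes passive properties and channel
densities non-uniformly along the apical trunk as functions of distance x (μm)
from the soma:

* passive sigmoids (R_m, R_a): max + (min - max)/(1 + exp((d - x)/k)),
  decreasing from the somatic maximum to the distal minimum, midpoint at x = d;
* sigmoidal conductance gradients (h, CaT): g_B (1 + F/(1 + exp((d - x)/k))),
  rising from roughly g_B at the soma and saturating at g_B (1 + F) distally;
* the linear A-type K+ gradient: g_B (1 + F x/100);
* the piecewise-linear h-channel activation V1/2 map (-82 mV proximal to
  -90 mV beyond 300 μm) and the proximal/distal A-type model switch at 100 μm.

Default parameter values (soma/terminal R_m 125/85 kΩ·cm², R_a 120/70 Ω·cm,
h: 25 μS/cm² ×13-fold, CaT: 80 μS/cm² ×31-fold, K_A: 3.1 mS/cm² slope 8/100 μm)
are the printed constants of the CA1 model this package implements.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class PassiveGradient:
    """Sigmoidally decreasing passive parameter (R_m in kΩ·cm², R_a in Ω·cm)."""

    max_value: float
    min_value: float
    d: float  # half-maximal distance, μm
    k: float  # slope, μm

    def __post_init__(self):
        if self.k == 0:
            raise ValueError("slope k must be non-zero")

    def value_at(self, x):
        x = np.asarray(x, dtype=float)
        if np.any(x < 0):
            raise ValueError("distance must be non-negative")
        out = self.max_value + (self.min_value - self.max_value) / (
            1.0 + np.exp((self.d - x) / self.k))
        return float(out) if np.ndim(out) == 0 else out


@dataclass(frozen=True)
class SigmoidConductanceGradient:
    """Sigmoidally increasing conductance density (S/cm²)."""

    g_base: float
    fold: float
    d: float
    k: float

    def __post_init__(self):
        if self.k == 0:
            raise ValueError("slope k must be non-zero")

    def value_at(self, x):
        x = np.asarray(x, dtype=float)
        if np.any(x < 0):
            raise ValueError("distance must be non-negative")
        out = self.g_base * (1.0 + self.fold / (1.0 + np.exp((self.d - x) / self.k)))
        return float(out) if np.ndim(out) == 0 else out


@dataclass(frozen=True)
class LinearConductanceGradient:
    """Linearly increasing conductance density: g_B (1 + F·x/100)."""

    g_base: float
    fold_per_100um: float

    def value_at(self, x):
        x = np.asarray(x, dtype=float)
        if np.any(x < 0):
            raise ValueError("distance must be non-negative")
        out = self.g_base * (1.0 + self.fold_per_100um * x / 100.0)
        return float(out) if np.ndim(out) == 0 else out


def passive_at(grad: PassiveGradient, x):
    return grad.value_at(x)


def sigmoid_density_at(grad: SigmoidConductanceGradient, x):
    return grad.value_at(x)


def ka_density_at(grad: LinearConductanceGradient, x):
    return grad.value_at(x)


def h_vhalf_at(x):
    """Apical h-channel activation V1/2 (mV): -82 proximal, -90 beyond 300 μm,
    linear in between (100–300 μm)."""
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("distance must be non-negative")
    out = np.where(x <= 100.0, -82.0,
                   np.where(x >= 300.0, -90.0,
                            -82.0 - 8.0 * (x - 100.0) / 200.0))
    return float(out) if np.ndim(out) == 0 else out


def ka_model_at(x) -> str:
    """Which A-type K+ model applies at distance x: proximal below 100 μm."""
    if x < 0:
        raise ValueError("distance must be non-negative")
    return "KA_prox" if x < 100.0 else "KA_dist"


# Printed defaults of the gradient-endowed CA1 model.
RM_GRADIENT = PassiveGradient(125.0, 85.0, 300.0, 50.0)       # kΩ·cm²
RA_GRADIENT = PassiveGradient(120.0, 70.0, 300.0, 14.0)       # Ω·cm (k: see config note)
H_GRADIENT = SigmoidConductanceGradient(25.0e-6, 12.0, 320.0, 50.0)   # S/cm²
CAT_GRADIENT = SigmoidConductanceGradient(80.0e-6, 30.0, 350.0, 50.0)  # S/cm²
KA_GRADIENT = LinearConductanceGradient(3.1e-3, 8.0)          # S/cm²
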