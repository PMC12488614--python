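# Channel registry: one document per channel.
#
# Gate steady states are Boltzmann curves 1/(1 + exp((vhalf - v)/k)); a
# negative k gives an inactivation / hyperpolarization-activated gate.
# Time-constant forms (ms, at ref_temp; corrected by q10^((T - ref_temp)/10)):
#   const:     [tau0]
#   bell:      [tau0, amp, v1, k1, v2, k2] -> tau0 + amp/(exp((v-v1)/k1) + exp(-(v-v2)/k2))
#   sigmoid:   [tau0, amp, v1, k1]         -> tau0 + amp/(1 + exp((v-v1)/k1))
#   piecewise: [vb, a1, a2, c, a3, a4]     -> exp((v+a1)/a2) below vb, else c + exp(-(v+a4... )
#
# Densities are the somatic defaults (S/cm^2).  Ohmic reversal potentials:
# Na +55 mV, K -90 mV, h -30 mV.  The T-type Ca channel uses the GHK
# constant-field law (valence 2); its quoted density multiplies the GHK
# driving force in mV (conductance-units convention).

Na:
  current: ohmic
  erev: 55.0
  density: 16.0e-3
  ref_temp: 34.0
  gates:
    - {name: m, role: act, exponent: 3, vhalf: -30.0, k: 7.2,
       tau_form: const, tau_params: [0.15]}
    - {name: h, role: inact, exponent: 1, vhalf: -45.0, k: -4.0,
       tau_form: bell, tau_params: [0.5, 8.0, -50.0, 10.0, -50.0, 10.0]}

KDR:
  current: ohmic
  erev: -90.0
  density: 10.0e-3
  ref_temp: 34.0
  gates:
    - {name: n, role: act, exponent: 1, vhalf: 13.0, k: 8.8,
       tau_form: const, tau_params: [3.0]}

# A-type K+: rapidly activating / inactivating.  The distal model is the
# proximal model with the activation V1/2 moved 12 mV hyperpolarized
# (proximal +11 mV, distal -1 mV).
KA_prox:
  current: ohmic
  erev: -90.0
  density: 3.1e-3
  ref_temp: 34.0
  gates:
    - {name: a, role: act, exponent: 1, vhalf: 11.0, k: 18.0,
       tau_form: const, tau_params: [1.0]}
    - {name: b, role: inact, exponent: 1, vhalf: -56.0, k: -8.0,
       tau_form: const, tau_params: [8.0]}

KA_dist:
  current: ohmic
  erev: -90.0
  density: 3.1e-3
  ref_temp: 34.0
  gates:
    - {name: a, role: act, exponent: 1, vhalf: -1.0, k: 18.0,
       tau_form: const, tau_params: [1.0]}
    - {name: b, role: inact, exponent: 1, vhalf: -56.0, k: -8.0,
       tau_form: const, tau_params: [8.0]}

# HCN (h) channel: activated by hyperpolarization, mixed-cation reversal
# -30 mV.  Somatic activation V1/2 -82 mV; the apical gradient overrides this
# per compartment (down to -90 mV distally).
h:
  current: ohmic
  erev: -30.0
  density: 25.0e-6
  ref_temp: 34.0
  gates:
    - {name: l, role: act, exponent: 1, vhalf: -82.0, k: -8.0,
       tau_form: bell, tau_params: [10.0, 80.0, -82.0, 20.0, -82.0, 20.0]}

# Low-voltage-activated T-type Ca2+ channel, m^2 h, GHK current law.
# Thalamic-relay kinetic scheme (Huguenard-McCormick / Destexhe lineage),
# defined at 24 degC with the published q10s (2.5 activation, 3.0 inactivation).
# Its activation/inactivation window spans roughly -86 to -63 mV, which is what
# admits subthreshold calcium entry around the -65 mV holding potential.
CaT:
  current: ghk
  valence: 2
  density: 80.0e-6
  ref_temp: 24.0
  gates:
    - {name: m, role: act, exponent: 2, vhalf: -57.0, k: 6.2, q10: 2.5,
       tau_form: bell, tau_params: [0.612, 1.0, -16.8, 18.2, -132.0, 16.7]}
    - {name: h, role: inact, exponent: 1, vhalf: -81.0, k: -4.0, q10: 3.0,
       tau_form: piecewise, tau_params: [-80.0, 467.0, 66.6, 28.0, 22.0, 10.5]}
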