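# Methods

## Models

**Single compartment.** A cylinder with length = diameter = 60 μm and lateral
surface area π·d·L (no end caps), R_m = 11 kΩ·cm², C_m = 1 μF/cm²,
R_a = 100 Ω·cm, leak reversal −65 mV. These constants give a passive input
resistance of 97.3 MΩ and a membrane time constant of 11 ms. Channels are
added by density (S/cm²); the defaults used throughout are the somatic values
of the gradient model (CaT 80 μS/cm², h 25 μS/cm², K_A 3.1 mS/cm²), except
where the calibration below applies.

**Gradient trunk model.** A soma (20 × 20 μm cylinder) plus a somato-apical
trunk of ~425 μm, linearly tapered 2.5 → 1.0 μm over 10 sections (a synthetic
stand-in for a reconstructed CA1 apical trunk; optional basal equivalent
cylinder and axon stub are off by default). Along the apical path distance x:

| quantity | form | parameters |
|---|---|---|
| R_m(x) | max + (min−max)/(1+e^{(d−x)/k}) | 125 → 85 kΩ·cm², d = 300 μm, k = 50 μm |
| R_a(x) | same | 120 → 70 Ω·cm, d = 300 μm, k = 14 μm |
| ḡ_KA(x) | g_B(1 + F·x/100) | g_B = 3.1 mS/cm², F = 8; proximal model < 100 μm, distal beyond |
| ḡ_h(x) | g_B(1 + F/(1+e^{(d−x)/k})) | g_B = 25 μS/cm², F = 12, d = 320 μm, k = 50 μm |
| ḡ_CaT(x) | same | g_B = 80 μS/cm², F = 30, d = 350 μm, k = 50 μm |
| h V₁/₂(x) | piecewise linear | −82 mV (≤100 μm) → −90 mV (≥300 μm) |

The two printed values of the R_a slope conflict (50 vs 14 μm); 14 μm is the
default here and the parameter is exposed in `GradientSet`. Basal
compartments take somatic R_m/R_a and somatic channel values with the K_A
distribution applied along their own path distance; the axon carries Na/K_DR
only. Na (16 mS/cm²) and K_DR (10 mS/cm²) are uniform — values adopted from
the antecedent CA1 gradient-model family, since the trunk model's uniform
densities are not separately constrained. Gradients are evaluated at each
compartment's midpoint path distance.

**Discretization.** Sections are split into an odd number of equal
compartments by the d_λ rule (nseg = 2·⌊(L/(0.1·λ₁₀₀)+0.9)/2⌋+1 with
λ_f = ½·√(d/(π f R_a C_m)) at 100 Hz), then incremented by 2 until every
compartment — with its own tapered diameter and local R_a — is strictly
shorter than 0.1·λ₁₀₀. The default trunk yields 31 compartments.

## Channel kinetics

The channel registry (`calres/data/channels.yaml`) stores every gate as a
Boltzmann steady state 1/(1+e^{(V₁/₂−v)/k}) (negative k for inactivation and
for the hyperpolarization-activated h gate) plus a parametric time-constant
curve, with a reference temperature and q10 (default 3) applied as
τ(T) = τ_ref / q10^{(T−T_ref)/10}. Simulations run at 34 °C.

* **CaT** (GHK, valence 2): the thalamic low-voltage-activated m²h scheme
  (Huguenard–McCormick/Destexhe lineage; activation V₁/₂ −57 mV, k 6.2;
  inactivation V₁/₂ −81 mV, k 4; q10 2.5/3.0 from 24 °C). Its
  activation–inactivation window spans roughly −86 to −63 mV, which is what
  admits calcium entry around the −65 mV hold. The GHK current is evaluated
  in the conductance-units convention, I = ḡ·m²h·D(V) with D the
  constant-field driving term in mV, so the printed μS/cm² densities pass
  through unchanged; the permeability flux form is the same expression up to
  the constant z²F²[Ca]_o/RT (asserted in tests).
* **h**: single gate, V₁/₂ −82 mV (somatic; overridden along the apical map),
  k 8, reversal −30 mV, bell-shaped τ peaking ≈50 ms near −82 mV (≈39 ms at
  −65 mV).
* **K_A**: fast activation (V₁/₂ +11 mV proximal / −1 mV distal, k 18, τ 1 ms)
  and inactivation (V₁/₂ −56 mV, k 8, τ 8 ms), reversal −90 mV. The distal
  model is the proximal one with a −12 mV activation shift.
* **Na** (+55 mV) and **K_DR** (−90 mV): Boltzmann simplifications of the
  standard CA1 schemes; they are spectators at subthreshold potentials and
  exist so that suprathreshold excursions are detected and flagged.

The main text of the modelled study does not print its gating equations; the
cited kinetic schemes were transcribed as the named parameter sets above, so
replacing any of them is a registry edit, not a code change. Gate τ curves
are V₁/₂-anchored: an applied V₁/₂ shift translates both curves. Sweep hooks
per gate: additive V₁/₂ shift, multiplicative τ scale (the default reading of
"increasing the time constant"), additive τ offset as the alternative.

**Calcium pool.** One shell per compartment:
d[Ca]/dt = −i_CaT/(2F·depth) − ([Ca]−100 nM)/τ with depth 0.1 μm and
τ = 30 ms by default (conventional single-pool values of the model family;
both swept by the passive suite). Calcium feeds back into the GHK driving
term.

## Protocol and estimator

Holding at −65 mV is implemented the way a patch experiment does it: the
injection site is voltage-clamped during a 1 s settle, the steady-state clamp
current becomes a constant bias, and the 50 pA 0→15 Hz/15 s chirp rides on
that bias after a 0.5 s rest (0.5 s padding after; samples recorded at 1 ms).
The bias is recomputed per parameter set, so every sweep point is measured
from the same potential.

Impedance: FFT of the baseline-subtracted response over the full record
divided by the FFT of the chirp, restricted to 0.5–15 Hz (spectral resolution
1/16 s = 0.0625 Hz). The calcium baseline is the pre-stimulus resting level,
so Z_Ca describes the oscillatory component. f_R is the argmax of the
smoothed |Z|, refined by parabolic interpolation around the peak bin;
Q = max|Z| / |Z(0.5 Hz)|. The smoothing default is a 0.5 Hz moving average
(odd bin count, ≥5 bins): chirp estimates carry ripple of roughly that period
from onset/ring-down interference, and the window is chosen to span one
ripple period while remaining far below the several-hertz width of the
resonance peak. Window width, baseline handling and band edges are exposed.
A profile whose maximum sits at the 0.5 Hz band edge is flagged
"no resonance". An independent estimator — steady-state single-frequency
probes measured by least-squares quadrature after a 2 s transient — agrees
with the chirp route within 3% and serves as the cross-check in tests.

**Calibration.** The single-compartment CaT density behind the figure-level
results is unpublished. `calibrate_cat_density` scales that one knob to
minimise the joint squared relative error against the printed strength pair
(V-Q = 1.02, Ca-Q = 2.52), yielding 506.5 μS/cm² (V-Q 1.008, Ca-Q 2.529).
Experiments default to the printed somatic 80 μS/cm²; the calibrated value is
used where the figure-level regime matters and is always reported, never
hidden.

## Numerics

Backward-Euler voltage step with the instantaneous ohmic conductances on the
diagonal, solved on the tree by Hines elimination (parents before children,
O(n)); gates and calcium advance by their analytic exponential updates,
staggered after the voltage solve; the GHK current enters the right-hand side
explicitly at the current voltage (its density is ~10⁻³ of C_m/dt, so
stability is untouched). dt = 25 μs; halving it changes f_R and Q by well
under 1%. The GHK singularity at V = 0 is evaluated via expm1 and its
analytic limit. Gate arguments are clipped at ±60 to avoid overflow; calcium
is floored at 10⁻¹² mM. The settle clamp is a 10⁶ S/cm² penalty conductance
(residual ≈ nV). Integration failures (non-finite voltage) raise with a
diagnostic rather than returning garbage.

Problem sizes were chosen so the full experiment suites run in minutes on one
core: 16 s of simulated time per chirp at dt = 25 μs (640 000 steps), 9-point
log-spaced conductance/τ grids (0.25×–4×), 13-point V₁/₂ grids (±15 mV),
trunk maps at 25 μm spacing on the 31-compartment synthetic trunk.

## What the synthetic data does and does not emulate

The synthetic trunk reproduces the somato-apical extent, taper and gradient
structure of a reconstructed CA1 trunk, but not its oblique branches, soma
geometry details, or diameter irregularities (optional seeded jitter exists,
off by default). Consequently trunk-map results are qualitative maps along an
idealised cable, not predictions for a specific reconstruction; the
discretization of a real SWC file (including the published 809-compartment
count for the original reconstruction) is supported and opt-in. Passing tests
on synthetic inputs demonstrate internal consistency of model + estimator,
not agreement with any biological recording.

## Findings and known limitations

With all parameters frozen as above, the package reproduces: the strong
calcium / weak voltage resonance dissociation and its Q pair; calcium f_R
confined to ~5.1–5.4 Hz across a 16-fold conductance range while voltage f_R
climbs ~0.7→5.8 Hz; calcium f_R rising with g_h and falling with h-τ, calcium
decay τ and C_m; a theta-band (5.35 Hz) somatic voltage resonance of the
gradient trunk model; and flat calcium f_R over the proximal 200 μm of the
trunk.

Not reproduced, with the likely cause in each case being kinetic details the
source text does not constrain: the bell shape of calcium f_R vs h-V₁/₂
(here the rising limb saturates within ±15 mV); any K_A effect beyond
~0.03 Hz (here the A-type conductance acts as an essentially static leak at
−65 ± 5 mV, so the reported small g_KA and V₁/₂ effects have no lever); an
increase of calcium f_R with R_m (here it decreases, the plain RC
direction); and the distal rise of voltage and calcium f_R along the trunk —
distally the K_A gradient dominates the membrane as leak and the h gate
(V₁/₂ −90 mV) is only ~4% activated at −65 mV, so distal voltage resonance
flattens (Q → 1.006) instead of sharpening. These are properties of the
transcribed kinetic schemes, not of the estimator; the corresponding checks
in the test suite are left failing by design and document the gap. Other
limitations: no synaptic input, no spike-mediated calcium, single-shell
calcium without buffers or stores, no phase analysis, and temperature fixed
at 34 °C.
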