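# Methods

This note documents the physical models, the synthetic material fixtures,
the calibrations, and the numerical choices behind `pvretina`, in the order
the pipeline runs.

## Material fixtures (synthetic data)

All optical and tissue inputs are generated analytically so that the full
chain is reproducible offline. They emulate the *dispersion* of the real
materials over 400–800 nm, not any particular measured sample.

**Gold.** A Drude–Lorentz dielectric function

ε(E) = ε∞ − E_p²/(E² + iγE) + Δε·E_L²/((E_L² − E²) − iΓE)

with frozen parameters ε∞ = 6.5, E_p = 8.333 eV, γ = 0.092 eV, Δε = 1.5,
E_L = 2.8 eV, Γ = 0.8 eV (energies in eV; e^{−iωt} convention, Im ε ≥ 0).
The parameterization is representative of experimental gold in the visible
(metallic Re ε < 0 beyond 500 nm, interband absorption toward 400 nm) and is
anchored to the device optics this package models: the plasma/background
terms put Re ε(610 nm) = −7.60 ≈ −2·(1.95)², and the damping sets the peak
normalized absorption cross-section of a 10 nm sphere in the blend to ≈ 2.3.
Supported range 300–1000 nm.

**P3HT:PCBM blend.** Real index fixed flat at n = 1.95, chosen once (within
the plausible 1.7–2.2 band for the blend) so that the Fröhlich condition
Re ε_Au = −2n² falls at 610 nm; a flat n keeps the resonance calibration
transparent. The extinction band k(λ) is a monotone-cubic (PCHIP)
interpolant through eight anchors peaking at 500 nm. The anchors at 500 and
610 nm are not free: they are obtained by inverting the bare-layer
short-circuit relation J_sc = 4πk·I₀PqL/hc against the reported bare-layer
anchors (22 and 3.1 A/m² at 0.26 mW/mm², P = 0.792, L = 100 nm), giving
k(500) = 0.10541 and k(610) = 0.014853. This closes the calibration loop
exactly: feeding the fixture back through the photocurrent stage returns the
anchors to machine precision. The remaining anchors only shape a plausible
band and carry no quantitative claim.

**Tissue.** Conductivity/relative permittivity pairs (0.027 S/m, 4.06 × 10⁷)
at 10 Hz and (0.089 S/m, 3.90 × 10⁶) at 100 Hz.

Dispersion tables are exchanged as CSV (wavelength plus n,k or
eps_re,eps_im), interpolated linearly in ε on a 2 nm grid; permittivity and
index representations interconvert exactly through ε = (n + ik)².

What the fixtures do *not* emulate: measured gold datasets (Johnson–Christy
level accuracy), the blend's true dispersive n(λ), temperature dependence,
or frequency-dependent tissue spectra beyond the two tabulated points.
Passing tests therefore validate the model chain's internal consistency and
its agreement with the reported device numbers, not the absolute optical
constants of any physical sample.

## Quasi-static nanoparticle optics

Spheres with r ≤ 10 nm are far below the wavelength, so the dipole
(quasi-static) polarizability α = 3V(ε_m − ε_s)/(ε_m + 2ε_s) applies;
retardation, multipoles and particle–particle coupling are out of scope.
Two conventions are deliberately configurable:

* **Scattering prefactor.** The standard dipolar form C_scat =
  (1/6π)k⁴|α|² is the default; a `prefactor_16pi` flag switches to a 16π
  prefactor (the two differ by the constant 96π²). Only the standard form
  yields the ~10⁻² normalized scattering magnitudes that small gold spheres
  actually show, which is why it is the default.
* **Wavenumber.** k = 2π/λ (vacuum) by default; `medium_wavenumber=True`
  multiplies by √ε_s. The vacuum form is retained as the primary convention
  for consistency with the photocurrent calibration.

Exact consequences used as test invariants: Q_abs ∝ r and Q_scat ∝ r⁴ at
fixed λ; the resonance position is radius-independent; with the packaged
fixtures the peak Q_abs ratios across r = 10, 7.5, 5 nm are exactly
2 : 1.5 : 1. In an absorbing host the minimum of |ε_m + 2ε_s| sits a few nm
red of the Q_abs peak; the real-part zero crossing Re(ε_m + 2ε_s) = 0 is the
sharp locator of the peak.

## Photocurrent

Bare layer: G = αλI₀P/hc and J_sc = GqL, with α = 4πk/λ, so λ cancels and
the bare spectral shape is k(λ). Strict SI conversions are used
(1 mW/mm² = 1000 W/m²); h, c, q are compile-time CODATA constants.

Nanoparticle-loaded layer: the three-term volume split weights the depleted
blend by (1 − f_s(1 + v₁ + v₂)), the near-field absorption region by v₁f_s
and the scattering region by v₂f_s. The cross-section *areas* are converted
to region *volumes* by the equivalent-sphere construction r_x = √(C_x/π),
v_x = (r_x/r)³, which preserves the "region around the particle" picture and
makes v₁ = Q_abs^{3/2} an exact, testable identity.

**The lumped gain κ.** The effective absorption coefficient of the embedded
particles is not derivable from bulk gold: 4πk_Au/λ in the volume split
overshoots the reported currents by roughly an order of magnitude (this
`derived` mode is available and documented as non-reproducing — near-field
enhancement is not bulk absorption). The default `calibrated` mode lumps
P_np·α₂·[(1−Q_sc)v₁ + Q_sc v₂] at the calibration point into a single gain
κ [1/m], fitted by least squares through the origin to (f_s, J_sc) triples
after subtracting the occupancy-depleted bare term. Away from the
calibration wavelength/radius the AuNP term scales by
S(λ, r) = v₁(1−Q_sc) + v₂Q_sc normalized to its calibration value, which
carries both the LSPR line shape and the r^{3/2} size scaling. Calibrated on
the r = 10 nm triple (35, 51, 67 A/m² at f_s = 10/15/20 %, 610 nm,
0.26 mW/mm²), κ = 2.61 × 10⁷ m⁻¹ with reconstruction residuals < 0.04 A/m²,
and the same κ predicts the r = 7.5 nm triple at 0.38 mW/mm² within 3 %.
Known limitation: the pure r^{3/2} scaling overstates the r = 5 nm LSPR gain
relative to the reported finite-element trend (610/500 nm current ratio
≈ 1.4 instead of ≈ 1.1 at f_s = 20 %); the qualitative behavior — gain > 1
only at maximum loading for 5 nm particles — is reproduced.

Filling fractions above 20 % degrade the active layer and are rejected
(an explicit unsafe flag exists for exploration); occupancies
f_s(1 + v₁ + v₂) > 1 raise an error unless clipping is requested, and
clipping warns.

## Device stage

A two-parameter single-diode law replaces a drift-diffusion device model:
every downstream quantity (P_max, PCE, operating point) depends only on the
curve shape near its anchors, so a surrogate calibrated per configuration to
the reported (J_sc, V_oc, FF) triple suffices. For a trial ideality n the
Voc condition fixes J₀; FF is then monotone decreasing in n, and n ∈ [1, 3]
is solved by bracketed root finding (the stationarity condition of P = VJ is
itself solved by bracketing, no grid error). All ten reported rows calibrate
with n between 1.30 and 2.13 and re-derive their PCE within 0.06 percentage
points; series/shunt resistances are omitted (the reported FF range
0.72–0.78 is reachable with ideality alone) — a documented limitation, not a
fitted claim. T = 300 K; sampled curves use a 1 mV grid from 0 to
V_oc + 0.05 V; P_max from the 1 mV grid is within 0.1 % of the continuous
optimum. PCE is computed per-area (the 100 × 100 μm cell area cancels and is
carried as metadata).

## Neural stimulation stage

**Volume conductor.** Homogeneous, infinite, purely resistive medium
(σ = 0.027 S/m at 10 Hz); the plate is the sole source with return at
infinity. The huge low-frequency permittivity shifts phase but the
DC-resistive magnitude is used. The equipotential square plate is solved by
a method of moments: M × M = 32 × 32 point sources at patch centers, the
diagonal using the area-equivalent disk self-potential 1/(2√π σw). The
solved plate conductance agrees with the analytic isolated-square value to
0.7 %, and the criterion-line average current density changes by < 1 % from
M = 16 to M = 32. With M = 1 the solution reduces exactly to the point
source Φ = I/4πσr, the closed-form oracle.

**Axon.** Classic Hodgkin–Huxley squid membrane at its native temperature
(ḡ_Na = 120, ḡ_K = 36, ḡ_L = 0.3 mS/cm², E_Na = 50, E_K = −77,
E_L = −54.387 mV, C_m = 1 μF/cm², rest −65 mV) — the standard fully
published unmyelinated spatially-extended model. Diameter 1 μm, axial
resistivity 100 Ω·cm, 2 μm compartments, 500 μm total length (≥ 4× the
electrode side, against end effects), 5 μm above the plate center, parallel
to it. The extracellular potential drives the cable through the standard
activating-function coupling C_m dV/dt = g_ax·Δ²(V + V_e) − I_ion with
sealed ends. Integration: implicit (backward Euler) diffusion with ionic
conductances frozen at freshly advanced gates, exponential-Euler gates,
dt = 0.01 ms; instability (|V_m| > 500 mV) raises an error advising a
smaller step. The resting state drifts < 0.01 mV over 100 ms, and the
single-compartment limit matches an independent RK4 implementation.

**Threshold.** Monophasic cathodic rectangular pulses, 50 ms (the cathodic
half-period of the 10 Hz stimulus), simulation window pulse + 20 ms. The
unit-voltage field is solved once; bisection on the amplitude (1 mV
resolution, 2 V cap) with the spike criterion "any compartment crosses
0 mV". The result packages the threshold voltage, the criterion-line |J|
profile (5 μm height), its edge-to-edge trapezoidal average, the impedance
Z = |V_th|/J̄ (1 V per A/m² = 10³ kΩ·mm²), and the membrane trace of the
most depolarized compartment.

**Fidelity.** The geometric features are robust: the profile is symmetric to
machine precision and shows the characteristic current-crowding maxima
within one sample of the plate edges (±0.05 mm); spikes initiate at the edge
lobes of the activating function, and Z scales as 1/σ so the 100 Hz
impedance is lower than the 10 Hz one. The absolute threshold is not: this
reconstruction excites at −0.014 V (average criterion-line density
5.4 A/m², Z = 2.6 kΩ·mm², where the plate geometry alone fixes
J̄/V = 384 A/m² per volt). Reported values for this configuration from a
proprietary solver with unpublished membrane parameters are −0.065 V,
33.63 A/m² and 1.9 kΩ·mm²; matching them would require a membrane ~4× less
excitable than classic HH *and* a volume conductor delivering ~35 % more
average current per volt, neither of which is recoverable from published
parameters. The package keeps the fully published model and reports its own
computed values rather than fitting hidden parameters to the target numbers;
downstream coupling conclusions (the operating point at 0.26 mW/mm² for
r = 10 nm, f_s ≥ 15 % is suprathreshold) hold under either parameter set.

## Coupling

The operating point solves J_dev(V) = V/Z on [0, V_oc]; uniqueness follows
from the device curve being strictly decreasing and the load line strictly
increasing. The threshold light intensity bisects the intensity (resolution
10⁻³ mW/mm², current tolerance 0.1 A/m²) until the operating-point current
density reaches the neural threshold. The open-circuit voltages of all
configurations (≤ 0.64 V) sit well inside the 1.23 V water window. Note the
reported device/neuron numbers are not mutually consistent with a flat diode
curve (a 51 A/m² short-circuit device delivering 33.63 A/m² at 0.065 V
implies an operating point below the knee); the pipeline therefore reports
both the load-line operating point and the threshold pair, and treats the
stated working intensity as a sufficiency (suprathreshold) condition.

Scenario reports are deterministic — repeated runs are byte-identical; all
problem sizes above (2 nm wavelength grid, M = 32, 2 μm compartments,
dt = 0.01 ms, 1 mV bisection) are the package defaults chosen for converged
desk-scale runs.
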