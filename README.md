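# pvretina

Modelling chain for a **plasmonic organic solar-cell retinal prosthesis**: a
P3HT:PCBM bulk-heterojunction photovoltaic pixel with embedded spherical gold
nanoparticles (AuNPs), used as a subretinal/epiretinal light-to-current
transducer that stimulates a retinal ganglion cell axon.

The package is aimed at computational neuroengineers who want a desk-scale,
fully reproducible version of this device chain — no finite-element packages,
no downloads; every material fixture is generated from frozen analytic
parameterizations calibrated to the reported device anchors.

## The model

The chain couples five stages:

1. **Nanoparticle optics** (quasi-static dipole limit, r ≤ 10 nm):

       α_sp   = 3V (ε_m − ε_s)/(ε_m + 2ε_s),   V = (4/3)πr³
       C_abs  = (2π/λ) Im[α_sp]
       C_scat = (1/6π) (2π/λ)⁴ |α_sp|²
       Q_sc   = C_scat / (C_scat + C_abs)

   with `Q_abs = C_abs/πr²`, `Q_scat = C_scat/πr²`. Gold is a frozen
   Drude–Lorentz dielectric; the blend host has flat n = 1.95 so the Fröhlich
   condition Re ε_Au = −2n² lands at the 610 nm localized surface plasmon
   resonance (LSPR).

2. **Photocurrent**. Bare layer: `G = αλI₀P/hc`, `J_sc = GqL` with
   `α = 4πk/λ`, exciton dissociation probability P = 79.2 % and L = 100 nm.
   With filling fraction f_s of AuNPs the layer volume splits into the
   depleted blend `(1 − f_s(1 + v₁ + v₂))`, a near-field absorption region
   `v₁f_s` and a scattering region `v₂f_s` (v₁, v₂ from the equivalent-sphere
   construction, so v₁ = Q_abs^{3/2}); the AuNP contribution uses P = 84.4 %
   and a lumped gain κ calibrated by least squares to reported
   (f_s, J_sc) triples.

3. **Device I–V**: a single-diode model
   `J(V) = J_sc − J₀(exp(qV/nk_BT) − 1)` calibrated per configuration to the
   reported (J_sc, V_oc, FF) triples; `FF = P_max/(J_sc V_oc)`,
   `PCE = P_max/P_in`.

4. **Neural stimulation**: an equipotential 100 × 100 μm Ti plate in resistive
   tissue (method of moments), a classic Hodgkin–Huxley cable axon (d = 1 μm)
   5 μm above the plate, 50 ms monophasic cathodic pulses, threshold by
   bisection; interface impedance Z = |V_th|/J̄_th.

5. **Coupling**: the electrode load line J = V/Z intersects the device curve
   at the operating point; bisection over intensity yields the minimum light
   level that activates the neuron, checked against the 1.23 V water window.

## Worked example

```python
from pvretina import (NanoparticleSpec, cross_section_spectrum, find_resonance,
                      ActiveLayerSpec, PlasmonicLayerSpec, IlluminationSpec,
                      jsc_bare, jsc_plasmonic, default_gain,
                      calibrate_diode, diode_iv, performance)

spectrum = cross_section_spectrum(NanoparticleSpec.packaged(10.0))
print(f"LSPR wavelength:  {find_resonance(spectrum):.0f} nm")
print(f"peak Q_abs:       {spectrum.q_abs.max():.2f}")

layer = ActiveLayerSpec()
light = IlluminationSpec(610.0, 0.26)          # 610 nm, 0.26 mW/mm^2
plas = PlasmonicLayerSpec(layer, NanoparticleSpec.packaged(10.0), 0.20,
                          gain=default_gain())
print(f"bare Jsc:         {jsc_bare(layer, light):.1f} A/m^2")
print(f"loaded Jsc:       {jsc_plasmonic(plas, light):.1f} A/m^2")

params = calibrate_diode(67.0, 0.64, 0.746)    # anchor the diode surrogate
perf = performance(diode_iv(67.0, params), 0.26)
print(f"Pmax:             {perf.pmax_w_m2:.1f} W/m^2")
print(f"PCE:              {100*perf.pce:.1f} %")
```

prints

```
LSPR wavelength:  610 nm
peak Q_abs:       2.30
bare Jsc:         3.1 A/m^2
loaded Jsc:       67.0 A/m^2
Pmax:             32.0 W/m^2
PCE:              12.3 %
```

i.e. at the plasmon resonance a 20 % AuNP loading raises the short-circuit
current density of the pixel from 3.1 to 67 A/m² and the power conversion
efficiency to 12.3 % at 0.26 mW/mm² — roughly 3× the bare layer's
efficiency at its own 500 nm optimum.

A command-line interface mirrors the library
(`pvretina materials|plasmonics|photocurrent|device|neuron|tables|run`), e.g.

```bash
pvretina materials generate --out-dir fixtures
pvretina plasmonics spectrum --radius-nm 10 --out spectrum.csv
pvretina run --out report.json
```

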