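"""Physical constants (CODATA 2018, exact SI values) and unit conversions.

These are compile-time constants: the photocurrent equations are defined in
terms of them and no configuration mechanism may override them.
"""

PLANCK_J_S: float = 6.62607015e-34
"""Planck constant h [J s]."""

SPEED_OF_LIGHT_M_S: float = 2.99792458e8
"""Speed of light in vacuum c [m/s]."""

ELEMENTARY_CHARGE_C: float = 1.602176634e-19
"""Elementary charge q [C]."""

BOLTZMANN_J_K: float = 1.380649e-23
"""Boltzmann constant k_B [J/K]."""

HC_J_M: float = PLANCK_J_S * SPEED_OF_LIGHT_M_S
"""h*c [J m], the photon-energy/wavelength conversion factor."""

NM_TO_M: float = 1e-9

MW_PER_MM2_TO_W_PER_M2: float = 1000.0
"""1 mW/mm^2 = 1000 W/m^2 (strict SI conversion of light intensity)."""

OHM_M2_TO_KOHM_MM2: float = 1e3
"""1 V per (A/m^2) = 1 Ohm m^2 = 10^3 kOhm mm^2 (area-specific impedance)."""
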