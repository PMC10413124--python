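"""Independent oracle implementations, written as straight-line transcriptions
separate from the package code paths they cross-check."""

import math

import numpy as np


def quasistatic_cross_sections(radius_nm, eps_m, eps_s, wavelength_nm):
    """(C_abs, C_scat) [nm^2] from the dipolar formulas, transcribed directly."""
    volume = 4.0 / 3.0 * math.pi * radius_nm**3
    alpha = 3.0 * volume * (eps_m - eps_s) / (eps_m + 2.0 * eps_s)
    k = 2.0 * math.pi / wavelength_nm
    c_abs = k * alpha.imag
    c_scat = (1.0 / (6.0 * math.pi)) * k**4 * abs(alpha) ** 2
    return c_abs, c_scat


def point_source_potential(current_a, sigma_s_m, r_m):
    """Phi = I / (4 pi sigma r) for a point current source in a full space."""
    return current_a / (4.0 * math.pi * sigma_s_m * r_m)


def hh_single_compartment_rk4(i_stim_ua_cm2, duration_ms, t_end_ms, dt_ms=0.005):
    """Space-clamped Hodgkin-Huxley squid membrane, classic RK4 integration.

    Independent of the package's semi-implicit integrator: own rate
    functions, own state stepping.  Returns (t, Vm) in ms / mV.
    """

    def rates(v):
        am = 0.1 * (v + 40.0) / (1.0 - math.exp(-(v + 40.0) / 10.0)) if v != -40.0 else 1.0
        bm = 4.0 * math.exp(-(v + 65.0) / 18.0)
        ah = 0.07 * math.exp(-(v + 65.0) / 20.0)
        bh = 1.0 / (1.0 + math.exp(-(v + 35.0) / 10.0))
        an = 0.01 * (v + 55.0) / (1.0 - math.exp(-(v + 55.0) / 10.0)) if v != -55.0 else 0.1
        bn = 0.125 * math.exp(-(v + 65.0) / 80.0)
        return am, bm, ah, bh, an, bn

    def deriv(state, i_ext):
        v, m, h, n = state
        am, bm, ah, bh, an, bn = rates(v)
        ina = 120.0 * m**3 * h * (v - 50.0)
        ik = 36.0 * n**4 * (v + 77.0)
        il = 0.3 * (v + 54.387)
        dv = i_ext - ina - ik - il  # Cm = 1 uF/cm^2
        return np.array(
            [dv, am * (1 - m) - bm * m, ah * (1 - h) - bh * h, an * (1 - n) - bn * n]
        )

    v0 = -65.0
    am, bm, ah, bh, an, bn = rates(v0)
    state = np.array([v0, am / (am + bm), ah / (ah + bh), an / (an + bn)])
    n_steps = int(round(t_end_ms / dt_ms))
    t = np.arange(n_steps + 1) * dt_ms
    vm = np.empty(n_steps + 1)
    vm[0] = v0
    for i in range(1, n_steps + 1):
        ti = (i - 1) * dt_ms
        i_ext = i_stim_ua_cm2 if ti < duration_ms else 0.0
        k1 = deriv(state, i_ext)
        k2 = deriv(state + 0.5 * dt_ms * k1, i_ext)
        k3 = deriv(state + 0.5 * dt_ms * k2, i_ext)
        k4 = deriv(state + dt_ms * k3, i_ext)
        state = state + dt_ms / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
        vm[i] = state[0]
    return t, vm
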