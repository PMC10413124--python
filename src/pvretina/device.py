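"""Single-diode device model: I-V curves, fill factor, PCE, water window.

The device stage is a single-diode surrogate for the full drift-diffusion
device simulation: under illumination

    J(V) = Jsc - J0 (exp(q V / (n kB T)) - 1)

with reverse-saturation current density J0 and ideality factor n at T = 300 K.
``calibrate_diode`` inverts (Jsc, Voc, FF) triples into (J0, n): for a trial
n, J0 follows from J(Voc) = 0, and n is solved by bracketed root finding so
the curve's fill factor matches the target.  No series/shunt resistance is
included; the reported fill factors (0.72-0.78) are reachable with ideality
alone, which keeps the surrogate two-parameter and exactly anchorable.

Performance definitions: FF = Pmax / (Jsc Voc); PCE = Pmax / Pin with
Pin the incident intensity per unit area (the cell area cancels).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .constants import (
    BOLTZMANN_J_K,
    ELEMENTARY_CHARGE_C,
    MW_PER_MM2_TO_W_PER_M2,
)

__all__ = [
    "DiodeParams",
    "IVCurve",
    "DevicePerformance",
    "CalibrationInfeasibleError",
    "IncompleteCurveError",
    "diode_iv",
    "diode_current",
    "calibrate_diode",
    "performance",
    "water_window_check",
    "WATER_WINDOW_V",
    "CELL_AREA_UM2",
]

WATER_WINDOW_V = 1.23
"""Electrode potential magnitude beyond which water electrolysis sets in."""

CELL_AREA_UM2 = 100.0 * 100.0
"""Pixel cell area [um^2]; enters reports as metadata only (PCE is per-area)."""

DEFAULT_TEMPERATURE_K = 300.0


class CalibrationInfeasibleError(ValueError):
    """No (J0, n) with n in the bracket reproduces the requested fill factor."""


class IncompleteCurveError(ValueError):
    """The voltage grid does not bracket the open-circuit zero crossing."""


@dataclass(frozen=True)
class DiodeParams:
    """Single-diode parameters (J0 [A/m^2], ideality n, temperature [K])."""

    j0_a_m2: float
    n_ideality: float
    temperature_k: float = DEFAULT_TEMPERATURE_K

    def __post_init__(self):
        if self.j0_a_m2 <= 0:
            raise ValueError("J0 must be positive")
        if not (1.0 <= self.n_ideality <= 3.0):
            raise ValueError("ideality factor must lie in [1, 3]")

    @property
    def thermal_voltage_v(self) -> float:
        return self.n_ideality * BOLTZMANN_J_K * self.temperature_k / ELEMENTARY_CHARGE_C


@dataclass
class IVCurve:
    """Sampled current-density/voltage characteristic under illumination."""

    voltage_v: np.ndarray
    current_density_a_m2: np.ndarray
    jsc_a_m2: float
    voc_v: float
    params: DiodeParams | None = None

    def current_at(self, v: float) -> float:
        if self.params is not None:
            return diode_current(self.jsc_a_m2, self.params, v)
        return float(np.interp(v, self.voltage_v, self.current_density_a_m2))


@dataclass(frozen=True)
class DevicePerformance:
    """Jsc/Voc/FF/Pmax/PCE summary of one illuminated I-V curve."""

    jsc_a_m2: float
    voc_v: float
    ff: float
    pmax_w_m2: float
    pin_w_m2: float
    pce: float
    vmax_v: float
    cell_area_um2: float = CELL_AREA_UM2


def diode_current(jsc_a_m2: float, params: DiodeParams, v) -> float:
    """Illuminated diode law J(V) = Jsc - J0 (exp(V / n Vt) - 1) [A/m^2]."""
    vt = params.thermal_voltage_v
    out = jsc_a_m2 - params.j0_a_m2 * np.expm1(np.asarray(v, dtype=float) / vt)
    if np.ndim(v) == 0:
        return float(out)
    return out


def _voc(jsc_a_m2: float, params: DiodeParams) -> float:
    return float(params.thermal_voltage_v * np.log1p(jsc_a_m2 / params.j0_a_m2))


def diode_iv(
    jsc_a_m2: float,
    params: DiodeParams,
    v_grid: np.ndarray | None = None,
    grid_step_v: float = 1e-3,
) -> IVCurve:
    """Sample the diode curve from 0 to just past Voc (default 1 mV grid)."""
    if jsc_a_m2 <= 0:
        raise ValueError("Jsc must be positive")
    voc = _voc(jsc_a_m2, params)
    if v_grid is None:
        v_grid = np.arange(0.0, voc + 0.05 + grid_step_v / 2, grid_step_v)
    v_grid = np.asarray(v_grid, dtype=float)
    j = diode_current(jsc_a_m2, params, v_grid)
    if v_grid[0] > 0 or v_grid[-1] < voc:
        raise IncompleteCurveError(
            f"voltage grid [{v_grid[0]:g}, {v_grid[-1]:g}] V does not cover the "
            f"zero crossing at Voc = {voc:.4f} V"
        )
    return IVCurve(v_grid, j, jsc_a_m2, voc, params)


def _fill_factor(jsc_a_m2: float, params: DiodeParams) -> tuple[float, float, float]:
    """(ff, pmax, vmax) of the continuous diode curve, solved analytically.

    The power maximum satisfies dP/dV = 0 with P = V J(V); the stationarity
    condition is solved by bracketed root finding on [0, Voc].
    """
    voc = _voc(jsc_a_m2, params)
    vt = params.thermal_voltage_v
    j0 = params.j0_a_m2

    def dpdv(v):
        return jsc_a_m2 - j0 * (np.expm1(v / vt) + (v / vt) * np.exp(v / vt))

    vmax = brentq(dpdv, 0.0, voc, xtol=1e-12, rtol=1e-14)
    pmax = vmax * diode_current(jsc_a_m2, params, vmax)
    return pmax / (jsc_a_m2 * voc), pmax, vmax


def calibrate_diode(
    jsc_a_m2: float,
    voc_v: float,
    ff: float,
    temperature_k: float = DEFAULT_TEMPERATURE_K,
    n_bracket: tuple[float, float] = (1.0, 3.0),
) -> DiodeParams:
    """Find (J0, n) reproducing a (Jsc, Voc, FF) triple.

    For each trial ideality n, J0 is fixed by the Voc condition, so the fill
    factor is a monotone (decreasing) function of n alone; n is solved by
    bracketed root finding.  Raises :class:`CalibrationInfeasibleError` with
    the achievable FF range when the target lies outside it.
    """
    if not (0.0 < ff < 1.0):
        raise ValueError("fill factor must lie in (0, 1)")
    if voc_v <= 0 or jsc_a_m2 <= 0:
        raise ValueError("Jsc and Voc must be positive")

    def params_for(n: float) -> DiodeParams:
        vt = n * BOLTZMANN_J_K * temperature_k / ELEMENTARY_CHARGE_C
        j0 = jsc_a_m2 / np.expm1(voc_v / vt)
        return DiodeParams(j0, n, temperature_k)

    def ff_err(n: float) -> float:
        return _fill_factor(jsc_a_m2, params_for(n))[0] - ff

    lo, hi = n_bracket
    f_lo, f_hi = ff_err(lo), ff_err(hi)
    if f_lo * f_hi > 0:
        ff_hi = _fill_factor(jsc_a_m2, params_for(lo))[0]
        ff_lo = _fill_factor(jsc_a_m2, params_for(hi))[0]
        raise CalibrationInfeasibleError(
            f"target FF {ff:.3f} outside achievable range "
            f"[{ff_lo:.3f}, {ff_hi:.3f}] for n in [{lo}, {hi}] at Voc = {voc_v} V"
        )
    n = brentq(ff_err, lo, hi, xtol=1e-10)
    return params_for(n)


def performance(curve: IVCurve, intensity_mw_mm2: float) -> DevicePerformance:
    """FF/Pmax/PCE of a sampled curve under the stated incident intensity.

    Pmax is the grid maximum of J*V (both P terms are per-area, so the cell
    area cancels in the PCE).
    """
    if intensity_mw_mm2 <= 0:
        raise ValueError("intensity must be positive")
    p = curve.voltage_v * curve.current_density_a_m2
    i = int(np.argmax(p))
    pmax = float(p[i])
    vmax = float(curve.voltage_v[i])
    pin = intensity_mw_mm2 * MW_PER_MM2_TO_W_PER_M2
    ff = pmax / (curve.jsc_a_m2 * curve.voc_v)
    return DevicePerformance(
        jsc_a_m2=curve.jsc_a_m2,
        voc_v=curve.voc_v,
        ff=ff,
        pmax_w_m2=pmax,
        pin_w_m2=pin,
        pce=pmax / pin,
        vmax_v=vmax,
    )


def water_window_check(v: float) -> tuple[bool, float]:
    """(pass, margin [V]) against the 1.23 V water-electrolysis window."""
    margin = float(WATER_WINDOW_V - abs(v))
    return bool(margin >= 0.0), margin
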