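"""Extracellular neural stimulation by a plate microelectrode.

Volume conductor
----------------
The 100 x 100 um titanium plate is treated as an equipotential source in a
homogeneous, purely resistive tissue medium with the return electrode at
infinity.  The plate is discretized into M x M patches, each represented by a
point current source at its center; the source strengths are solved from the
boundary condition that every patch-center potential equals the applied
voltage (method of moments, with the standard equivalent-disk self-potential
for the diagonal).  Potential and current density anywhere in the medium then
follow analytically from the point-source superposition; J = -sigma grad Phi.
At 10 Hz the medium's large relative permittivity shifts the impedance phase
but the DC-resistive magnitude is used throughout.

Axon model
----------
An unmyelinated fiber (classic Hodgkin-Huxley squid membrane at its native
temperature, 1 um diameter, axial resistivity 100 Ohm cm, 2 um compartments)
runs parallel to the plate, 5 um above its center.  The extracellular
potential enters the cable equation through the standard extracellular-drive
formulation: the axial second difference of Ve acts as the distributed
stimulus (activating function).  Monophasic cathodic rectangular pulses of
50 ms (the half-period of the 10 Hz stimulus) are applied; the threshold is
the smallest amplitude, to 1 mV by bisection, for which any compartment's
membrane potential crosses 0 mV.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import solve_banded

from .constants import OHM_M2_TO_KOHM_MM2
from .materials import TISSUE_10HZ, TissueProperties

__all__ = [
    "ElectrodeSpec",
    "AxonSpec",
    "HHMembrane",
    "StimulusSpec",
    "ThresholdResult",
    "PlateField",
    "DiscretizationError",
    "IntegrationError",
    "NoThresholdError",
    "plate_field",
    "criterion_line_profile",
    "average_line_current_density",
    "hh_cable_simulate",
    "hh_point_simulate",
    "hh_steady_state_gates",
    "find_threshold",
    "interface_impedance",
]

UM = 1e-6


class DiscretizationError(ValueError):
    """Degenerate plate discretization (singular moment matrix)."""


class IntegrationError(RuntimeError):
    """Membrane integration became unstable; reduce dt."""


class NoThresholdError(RuntimeError):
    """No action potential up to the maximum tested amplitude."""


# --------------------------------------------------------------------------
# Specifications
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class ElectrodeSpec:
    """Square plate electrode centered at the origin of the z = 0 plane."""

    side_um: float = 100.0
    thickness_nm: float = 150.0
    material: str = "Ti"

    def __post_init__(self):
        if self.side_um <= 0:
            raise ValueError("electrode side length must be positive")

    @property
    def area_um2(self) -> float:
        return self.side_um**2

    @property
    def half_side_mm(self) -> float:
        return self.side_um / 2.0 * 1e-3


@dataclass(frozen=True)
class HHMembrane:
    """Hodgkin-Huxley membrane parameters (squid giant axon, 6.3 degC)."""

    gna_ms_cm2: float = 120.0
    gk_ms_cm2: float = 36.0
    gl_ms_cm2: float = 0.3
    ena_mv: float = 50.0
    ek_mv: float = -77.0
    el_mv: float = -54.387
    cm_uf_cm2: float = 1.0
    v_rest_mv: float = -65.0


@dataclass(frozen=True)
class AxonSpec:
    """Straight unmyelinated axon parallel to the electrode plane."""

    diameter_um: float = 1.0
    height_um: float = 5.0
    length_um: float = 500.0
    compartment_um: float = 2.0
    axial_resistivity_ohm_cm: float = 100.0
    membrane: HHMembrane = field(default_factory=HHMembrane)

    def __post_init__(self):
        if self.diameter_um <= 0 or self.height_um <= 0:
            raise ValueError("axon diameter and height must be positive")

    def compartment_x_m(self) -> np.ndarray:
        """Compartment-center x coordinates [m], centered over the plate."""
        n = int(round(self.length_um / self.compartment_um))
        x_um = (np.arange(n) - (n - 1) / 2.0) * self.compartment_um
        return x_um * UM


@dataclass(frozen=True)
class StimulusSpec:
    """Monophasic cathodic rectangular voltage pulse on the plate.

    The 50 ms duration is the cathodic half-period of the 10 Hz sinusoidal
    stimulus it stands in for.
    """

    duration_ms: float = 50.0
    frequency_tag_hz: float = 10.0
    post_window_ms: float = 20.0

    def __post_init__(self):
        if self.frequency_tag_hz == 10.0 and self.duration_ms != 50.0:
            raise ValueError(
                "a 10 Hz frequency tag implies a 50 ms cathodic half-period"
            )
        if self.duration_ms <= 0:
            raise ValueError("pulse duration must be positive")


@dataclass
class ThresholdResult:
    """Threshold stimulus plus the field and impedance summary at threshold."""

    threshold_voltage_v: float           # signed; negative (cathodic)
    profile: pd.DataFrame                # columns x_mm, j_a_m2
    average_current_density_a_m2: float  # |J| averaged over the footprint
    impedance_kohm_mm2: float            # |V| / J_avg, unit-converted
    spike_time_ms: np.ndarray
    spike_vm_mv: np.ndarray              # most depolarized compartment
    n_bisection_iterations: int


# --------------------------------------------------------------------------
# Equipotential plate: method of moments
# --------------------------------------------------------------------------


@dataclass
class PlateField:
    """Solved plate source distribution in an infinite resistive medium."""

    electrode: ElectrodeSpec
    tissue: TissueProperties
    v_applied_v: float
    patch_xy_m: np.ndarray      # (N, 2) patch centers
    patch_current_a: np.ndarray  # (N,) source strengths

    @property
    def total_current_a(self) -> float:
        return float(np.sum(self.patch_current_a))

    def potential(self, points_m: np.ndarray) -> np.ndarray:
        """Electric potential [V] at (..., 3) points (not on the plate plane sources)."""
        pts = np.atleast_2d(np.asarray(points_m, dtype=float))
        d = pts[:, None, :2] - self.patch_xy_m[None, :, :]
        r = np.sqrt(np.sum(d**2, axis=2) + pts[:, None, 2] ** 2)
        return (self.patch_current_a[None, :] / (4.0 * np.pi * self.tissue.conductivity_s_m * r)).sum(
            axis=1
        )

    def current_density(self, points_m: np.ndarray) -> np.ndarray:
        """Current density vector [A/m^2] at (..., 3) points."""
        pts = np.atleast_2d(np.asarray(points_m, dtype=float))
        dxy = pts[:, None, :2] - self.patch_xy_m[None, :, :]
        dz = pts[:, None, 2]
        r2 = np.sum(dxy**2, axis=2) + dz**2
        r3 = r2 * np.sqrt(r2)
        w = self.patch_current_a[None, :] / (4.0 * np.pi * r3)
        jx = np.sum(w * dxy[:, :, 0], axis=1)
        jy = np.sum(w * dxy[:, :, 1], axis=1)
        jz = np.sum(w * dz, axis=1)
        return np.stack([jx, jy, jz], axis=1)

    def current_density_magnitude(self, points_m: np.ndarray) -> np.ndarray:
        return np.linalg.norm(self.current_density(points_m), axis=1)


def plate_field(
    electrode: ElectrodeSpec,
    v_applied_v: float,
    tissue: TissueProperties = TISSUE_10HZ,
    n_patches_per_side: int = 32,
) -> PlateField:
    """Solve the equipotential-plate boundary problem by the method of moments.

    Each of the M x M patches carries a point source at its center; the
    self-coefficient uses the area-equivalent disk potential 1/(2 sqrt(pi)
    sigma w).  Patch currents are solved so every patch-center potential
    equals ``v_applied_v``.
    """
    m = int(n_patches_per_side)
    if m < 1:
        raise DiscretizationError("need at least one patch per side")
    side = electrode.side_um * UM
    w = side / m
    centers_1d = (np.arange(m) - (m - 1) / 2.0) * w
    gx, gy = np.meshgrid(centers_1d, centers_1d, indexing="ij")
    xy = np.stack([gx.ravel(), gy.ravel()], axis=1)

    sigma = tissue.conductivity_s_m
    diff = xy[:, None, :] - xy[None, :, :]
    r = np.sqrt(np.sum(diff**2, axis=2))
    with np.errstate(divide="ignore"):
        g = 1.0 / (4.0 * np.pi * sigma * r)
    np.fill_diagonal(g, 1.0 / (2.0 * np.sqrt(np.pi) * sigma * w))
    try:
        currents = np.linalg.solve(g, np.full(m * m, float(v_applied_v)))
    except np.linalg.LinAlgError as exc:
        raise DiscretizationError("singular moment matrix") from exc
    return PlateField(electrode, tissue, float(v_applied_v), xy, currents)


def criterion_line_profile(
    fld: PlateField,
    height_um: float = 5.0,
    x_range_mm: tuple[float, float] = (-0.1, 0.1),
    n_samples: int = 201,
) -> pd.DataFrame:
    """|J| sampled along the criterion line (y = 0, z = height) over the plate.

    Columns ``x_mm`` and ``j_a_m2``.
    """
    if height_um <= 0:
        raise ValueError("criterion-line height must be positive")
    x_mm = np.linspace(x_range_mm[0], x_range_mm[1], n_samples)
    pts = np.zeros((n_samples, 3))
    pts[:, 0] = x_mm * 1e-3
    pts[:, 2] = height_um * UM
    j = fld.current_density_magnitude(pts)
    return pd.DataFrame({"x_mm": x_mm, "j_a_m2": j})


def average_line_current_density(
    fld: PlateField, height_um: float = 5.0, n_samples: int = 101
) -> float:
    """Trapezoidal mean of |J| along the criterion line across the footprint
    (edge to edge of the active electrode)."""
    half = fld.electrode.half_side_mm
    prof = criterion_line_profile(fld, height_um, (-half, half), n_samples)
    x = prof["x_mm"].to_numpy()
    return float(np.trapezoid(prof["j_a_m2"].to_numpy(), x) / (x[-1] - x[0]))


def interface_impedance(v: float, j_avg_a_m2: float) -> float:
    """Total electrode-to-neuron impedance Z = |V| / J_avg [kOhm mm^2]."""
    if j_avg_a_m2 <= 0:
        raise ZeroDivisionError("average current density must be positive")
    return abs(v) / j_avg_a_m2 * OHM_M2_TO_KOHM_MM2


# --------------------------------------------------------------------------
# Hodgkin-Huxley membrane kinetics
# --------------------------------------------------------------------------


def _vtrap(x, y):
    """x / (1 - exp(-x/y)) with the removable singularity handled."""
    x = np.asarray(x, dtype=float)
    out = np.where(np.abs(x / y) < 1e-6, y * (1.0 + x / (2.0 * y)), x / -np.expm1(-x / y))
    return out


def _gate_rates(v_mv):
    v = np.asarray(v_mv, dtype=float)
    am = 0.1 * _vtrap(v + 40.0, 10.0)
    bm = 4.0 * np.exp(-(v + 65.0) / 18.0)
    ah = 0.07 * np.exp(-(v + 65.0) / 20.0)
    bh = 1.0 / (1.0 + np.exp(-(v + 35.0) / 10.0))
    an = 0.01 * _vtrap(v + 55.0, 10.0)
    bn = 0.125 * np.exp(-(v + 65.0) / 80.0)
    return am, bm, ah, bh, an, bn


def hh_steady_state_gates(v_mv):
    """(m, h, n) at their voltage-clamped steady state."""
    am, bm, ah, bh, an, bn = _gate_rates(v_mv)
    return am / (am + bm), ah / (ah + bh), an / (an + bn)


def _advance_gates(v, m, h, n, dt):
    am, bm, ah, bh, an, bn = _gate_rates(v)

    def step(x, a, b):
        tau = 1.0 / (a + b)
        xinf = a * tau
        return xinf + (x - xinf) * np.exp(-dt / tau)
    return step(m, am, bm), step(h, ah, bh), step(n, an, bn)


# --------------------------------------------------------------------------
# Cable simulation
# --------------------------------------------------------------------------


def hh_cable_simulate(
    axon: AxonSpec,
    ve_of_t,
    t_end_ms: float,
    dt_ms: float = 0.01,
    record_every: int = 5,
):
    """Integrate the HH cable driven by an extracellular potential.

    ``ve_of_t(t_ms)`` must return the extracellular potential [mV] at every
    compartment center at time ``t_ms``.  The membrane equation per
    compartment is

        cm dV/dt = g_ax * Lap(V + Ve) - I_ion(V, m, h, n)

    with sealed (Neumann) ends; diffusion is advanced implicitly (backward
    Euler with ionic conductances frozen at the freshly advanced gates),
    gates by exponential Euler.  Returns ``(t_ms, vm_mv)`` with ``vm_mv`` of
    shape (n_times, n_compartments).
    """
    mem = axon.membrane
    x = axon.compartment_x_m()
    n_comp = x.size
    dx_cm = axon.compartment_um * 1e-4
    d_cm = axon.diameter_um * 1e-4
    g_ax = d_cm / (4.0 * axon.axial_resistivity_ohm_cm * dx_cm**2) * 1000.0  # mS/cm^2

    lap_diag = np.full(n_comp, 2.0)
    lap_diag[0] = lap_diag[-1] = 1.0

    def lap(u):
        out = np.empty_like(u)
        out[1:-1] = u[:-2] - 2.0 * u[1:-1] + u[2:]
        out[0] = u[1] - u[0]
        out[-1] = u[-2] - u[-1]
        return out

    v = np.full(n_comp, mem.v_rest_mv)
    m, h, n = (np.full(n_comp, g) for g in hh_steady_state_gates(mem.v_rest_mv))

    n_steps = int(round(t_end_ms / dt_ms))
    times = [0.0]
    traces = [v.copy()]
    cm_dt = mem.cm_uf_cm2 / dt_ms

    ab = np.zeros((3, n_comp))
    ab[0, 1:] = -g_ax
    ab[2, :-1] = -g_ax

    for step in range(1, n_steps + 1):
        t = step * dt_ms
        m, h, n = _advance_gates(v, m, h, n, dt_ms)
        g_na = mem.gna_ms_cm2 * m**3 * h
        g_k = mem.gk_ms_cm2 * n**4
        g_sum = g_na + g_k + mem.gl_ms_cm2
        ge_sum = g_na * mem.ena_mv + g_k * mem.ek_mv + mem.gl_ms_cm2 * mem.el_mv
        ve = ve_of_t(t)
        rhs = cm_dt * v + ge_sum + g_ax * lap(ve)
        ab[1, :] = cm_dt + g_sum + g_ax * lap_diag
        v = solve_banded((1, 1), ab, rhs)
        if np.max(np.abs(v)) > 500.0:
            raise IntegrationError(
                "membrane potential exceeded 500 mV; reduce dt_ms"
            )
        if step % record_every == 0:
            times.append(t)
            traces.append(v.copy())
    return np.asarray(times), np.asarray(traces)


def hh_point_simulate(
    i_stim_ua_cm2: float,
    duration_ms: float,
    t_end_ms: float,
    dt_ms: float = 0.01,
    membrane: HHMembrane | None = None,
):
    """Space-clamped (single-compartment) HH response to a current step.

    Used as an independent oracle for the cable model's excitability and for
    strength-duration behavior.  Returns ``(t_ms, vm_mv)``.
    """
    mem = membrane or HHMembrane()
    v = mem.v_rest_mv
    m, h, n = hh_steady_state_gates(v)
    n_steps = int(round(t_end_ms / dt_ms))
    t_out = np.arange(n_steps + 1) * dt_ms
    v_out = np.empty(n_steps + 1)
    v_out[0] = v
    cm_dt = mem.cm_uf_cm2 / dt_ms
    for step in range(1, n_steps + 1):
        t = step * dt_ms
        m, h, n = _advance_gates(v, m, h, n, dt_ms)
        g_na = mem.gna_ms_cm2 * m**3 * h
        g_k = mem.gk_ms_cm2 * n**4
        g_sum = g_na + g_k + mem.gl_ms_cm2
        ge_sum = g_na * mem.ena_mv + g_k * mem.ek_mv + mem.gl_ms_cm2 * mem.el_mv
        i_ext = i_stim_ua_cm2 if t <= duration_ms else 0.0
        v = (cm_dt * v + ge_sum + i_ext) / (cm_dt + g_sum)
        v_out[step] = v
    return t_out, v_out


# --------------------------------------------------------------------------
# Threshold search
# --------------------------------------------------------------------------


def _spikes(vm_mv: np.ndarray, criterion_mv: float = 0.0) -> bool:
    return bool(np.max(vm_mv) > criterion_mv)


def find_threshold(
    electrode: ElectrodeSpec | None = None,
    tissue: TissueProperties = TISSUE_10HZ,
    axon: AxonSpec | None = None,
    stimulus: StimulusSpec | None = None,
    n_patches_per_side: int = 32,
    resolution_v: float = 1e-3,
    max_amplitude_v: float = 2.0,
    dt_ms: float = 0.01,
) -> ThresholdResult:
    """Bisection for the cathodic threshold voltage of the plate stimulus.

    The unit-voltage plate field is solved once; by linearity every candidate
    amplitude only rescales the extracellular profile.  The spike criterion is
    any compartment's membrane potential crossing 0 mV.
    """
    electrode = electrode or ElectrodeSpec()
    axon = axon or AxonSpec()
    stimulus = stimulus or StimulusSpec()
    if axon.length_um < 4.0 * electrode.side_um:
        warnings.warn(
            "modeled axon shorter than 4x the electrode side; end effects may "
            "bias the threshold",
            stacklevel=2,
        )

    unit_field = plate_field(electrode, 1.0, tissue, n_patches_per_side)
    x = axon.compartment_x_m()
    pts = np.zeros((x.size, 3))
    pts[:, 0] = x
    pts[:, 2] = axon.height_um * UM
    ve_unit_mv = unit_field.potential(pts) * 1e3  # mV per applied volt

    t_end = stimulus.duration_ms + stimulus.post_window_ms

    def simulate(amplitude_v: float):
        def ve_of_t(t_ms):
            if t_ms <= stimulus.duration_ms:
                return -amplitude_v * ve_unit_mv  # cathodic
            return np.zeros_like(ve_unit_mv)

        return hh_cable_simulate(axon, ve_of_t, t_end, dt_ms)

    # bracket: grow from a small amplitude until a spike occurs
    lo, hi = 0.0, 0.05
    n_iter = 0
    while True:
        n_iter += 1
        _, vm = simulate(hi)
        if _spikes(vm):
            break
        lo = hi
        hi *= 2.0
        if hi > max_amplitude_v:
            raise NoThresholdError(
                f"no action potential up to {max_amplitude_v} V"
            )
    while hi - lo > resolution_v:
        n_iter += 1
        mid = 0.5 * (lo + hi)
        _, vm = simulate(mid)
        if _spikes(vm):
            hi = mid
        else:
            lo = mid
    threshold = hi

    t_ms, vm = simulate(threshold)
    peak_comp = int(np.argmax(np.max(vm, axis=0)))

    field_at_th = plate_field(electrode, -threshold, tissue, n_patches_per_side)
    profile = criterion_line_profile(field_at_th, axon.height_um)
    j_avg = average_line_current_density(field_at_th, axon.height_um)
    return ThresholdResult(
        threshold_voltage_v=-threshold,
        profile=profile,
        average_current_density_a_m2=j_avg,
        impedance_kohm_mm2=interface_impedance(threshold, j_avg),
        spike_time_ms=t_ms,
        spike_vm_mv=vm[:, peak_comp],
        n_bisection_iterations=n_iter,
    )
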