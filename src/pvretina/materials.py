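"""Material dispersion and tissue-property fixtures.

All optical constants consumed by the optics/photocurrent chain are generated
here, from frozen analytic parameterizations, so that every downstream stage
runs without any external data download:

* gold: a Drude-Lorentz dielectric function representative of experimental
  gold data in the visible, with the damping chosen so that the quasi-static
  absorption peak of a small sphere in the blend medium matches the reported
  device optics (peak wavelength 610 nm, peak Q_abs ~ 2.3);
* P3HT:PCBM blend: a flat real index n = 1.95 (chosen so the Frohlich
  condition Re eps_Au = -2 n^2 lands at 610 nm) and an absorption band k(lambda)
  interpolated through anchors; the k anchors at 500 and 610 nm are obtained
  by inverting the bare-layer short-circuit-current model against the printed
  device anchors (22 and 3.1 A/m^2 at 0.26 mW/mm^2), so the calibration closes
  exactly;
* neural tissue: conductivity/permittivity pairs at 10 and 100 Hz.

Dispersion tables are exchanged as CSV (wavelength_nm plus either n,k or
eps_re,eps_im columns).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.interpolate import PchipInterpolator

from .constants import (
    ELEMENTARY_CHARGE_C,
    HC_J_M,
    MW_PER_MM2_TO_W_PER_M2,
)

__all__ = [
    "DispersionTable",
    "TissueProperties",
    "RangeError",
    "FormatError",
    "gold_permittivity",
    "blend_index",
    "gold_dispersion",
    "blend_dispersion",
    "tissue_properties",
    "read_dispersion_csv",
    "write_dispersion_csv",
    "write_tissue_csv",
    "generate_fixtures",
    "TISSUE_10HZ",
    "TISSUE_100HZ",
    "BLEND_N",
    "BLEND_K_ANCHORS",
    "DEFAULT_GRID_NM",
]


class RangeError(ValueError):
    """A wavelength (or other coordinate) lies outside the supported range."""


class FormatError(ValueError):
    """A dispersion file violates the expected format or a physical invariant."""


# --------------------------------------------------------------------------
# Gold: Drude-Lorentz dielectric function, e^{-i omega t} convention
# (Im eps >= 0 for a passive material).  Energies in eV.  Parameters frozen.
# --------------------------------------------------------------------------

GOLD_EPS_INF = 6.5
GOLD_DRUDE_ENERGY_EV = 8.333      # plasma energy
GOLD_DRUDE_DAMPING_EV = 0.092     # free-electron damping
GOLD_LORENTZ_STRENGTH = 1.5       # interband oscillator strength (Delta eps)
GOLD_LORENTZ_ENERGY_EV = 2.8      # interband transition energy
GOLD_LORENTZ_DAMPING_EV = 0.8     # interband broadening

GOLD_WAVELENGTH_RANGE_NM = (300.0, 1000.0)
BLEND_WAVELENGTH_RANGE_NM = (400.0, 800.0)

_EV_NM = 1239.8419843320026  # photon energy [eV] * wavelength [nm]


def _photon_energy_ev(wavelength_nm):
    return _EV_NM / np.asarray(wavelength_nm, dtype=float)


def gold_permittivity(wavelength_nm):
    """Complex relative permittivity of gold at ``wavelength_nm``.

    Drude term plus a single Lorentz interband oscillator.  Supported range
    300-1000 nm.  Scalar in, scalar out; array in, array out.
    """
    wl = np.asarray(wavelength_nm, dtype=float)
    lo, hi = GOLD_WAVELENGTH_RANGE_NM
    if np.any(wl < lo) or np.any(wl > hi):
        raise RangeError(
            f"gold permittivity is parameterized for {lo:.0f}-{hi:.0f} nm; "
            f"got wavelength outside that range"
        )
    e = _photon_energy_ev(wl)
    drude = GOLD_DRUDE_ENERGY_EV**2 / (e**2 + 1j * GOLD_DRUDE_DAMPING_EV * e)
    lorentz = (
        GOLD_LORENTZ_STRENGTH
        * GOLD_LORENTZ_ENERGY_EV**2
        / ((GOLD_LORENTZ_ENERGY_EV**2 - e**2) - 1j * GOLD_LORENTZ_DAMPING_EV * e)
    )
    eps = GOLD_EPS_INF - drude + lorentz
    if np.ndim(wavelength_nm) == 0:
        return complex(eps)
    return eps


# --------------------------------------------------------------------------
# P3HT:PCBM blend index: flat n, k band through calibrated anchors
# --------------------------------------------------------------------------

BLEND_N = 1.95
"""Flat real index of the blend; eps_s = BLEND_N**2 places the Frohlich
condition Re eps_Au(lambda) = -2 eps_s at 610 nm with the gold model above."""

# Printed bare-layer anchors used to calibrate the k band (see jsc_bare):
# Jsc = 4 pi k I0 P q L / (h c)  =>  k = Jsc h c / (4 pi I0 P q L)
_BARE_ANCHOR_INTENSITY_MW_MM2 = 0.26
_BARE_ANCHOR_P = 0.792
_BARE_ANCHOR_L_M = 100e-9
_BARE_JSC_500_A_M2 = 22.0
_BARE_JSC_610_A_M2 = 3.1


def _k_from_bare_jsc(jsc_a_m2: float) -> float:
    i0 = _BARE_ANCHOR_INTENSITY_MW_MM2 * MW_PER_MM2_TO_W_PER_M2
    return (jsc_a_m2 * HC_J_M) / (
        4.0 * math.pi * i0 * _BARE_ANCHOR_P * ELEMENTARY_CHARGE_C * _BARE_ANCHOR_L_M
    )


BLEND_K_500 = _k_from_bare_jsc(_BARE_JSC_500_A_M2)
BLEND_K_610 = _k_from_bare_jsc(_BARE_JSC_610_A_M2)

BLEND_K_ANCHORS: tuple[tuple[float, float], ...] = (
    (400.0, 0.055),
    (450.0, 0.085),
    (500.0, BLEND_K_500),
    (550.0, 0.055),
    (610.0, BLEND_K_610),
    (660.0, 0.0085),
    (700.0, 0.006),
    (800.0, 0.004),
)
"""(wavelength_nm, k) anchors; the 500/610 nm values are calibrated, the rest
shape a plausible absorption band peaking at 500 nm."""

_blend_k_interp = PchipInterpolator(
    [a[0] for a in BLEND_K_ANCHORS], [a[1] for a in BLEND_K_ANCHORS]
)


def blend_index(wavelength_nm):
    """Complex refractive index n + i k of the P3HT:PCBM blend (400-800 nm)."""
    wl = np.asarray(wavelength_nm, dtype=float)
    lo, hi = BLEND_WAVELENGTH_RANGE_NM
    if np.any(wl < lo) or np.any(wl > hi):
        raise RangeError(
            f"blend index is defined for {lo:.0f}-{hi:.0f} nm; "
            f"got wavelength outside that range"
        )
    out = BLEND_N + 1j * _blend_k_interp(wl)
    if np.ndim(wavelength_nm) == 0:
        return complex(out)
    return out


# --------------------------------------------------------------------------
# Dispersion table container
# --------------------------------------------------------------------------

DEFAULT_GRID_NM = np.arange(400.0, 800.0 + 1e-9, 2.0)
"""Standard visible sweep: 400-800 nm at 2 nm steps."""


@dataclass
class DispersionTable:
    """Wavelength-indexed complex optical constants of one material.

    Values are held internally as complex relative permittivity; the
    ``representation`` flag records which column pair a file used.  The two
    representations interconvert exactly through eps = (n + i k)^2.
    """

    material: str
    wavelength_nm: np.ndarray
    permittivity: np.ndarray
    representation: str = "permittivity"  # "permittivity" | "index"

    def __post_init__(self):
        self.wavelength_nm = np.asarray(self.wavelength_nm, dtype=float)
        self.permittivity = np.asarray(self.permittivity, dtype=complex)
        if self.wavelength_nm.ndim != 1 or self.wavelength_nm.size < 2:
            raise FormatError("dispersion table needs at least two wavelengths")
        if np.any(np.diff(self.wavelength_nm) <= 0):
            raise FormatError("wavelengths must be strictly increasing")
        if self.representation not in ("permittivity", "index"):
            raise FormatError(f"unknown representation {self.representation!r}")
        if np.any(self.permittivity.imag < -1e-15):
            raise FormatError("passivity violated: Im eps < 0 in dispersion table")

    @property
    def index(self) -> np.ndarray:
        """Complex refractive index n + i k (principal square root of eps)."""
        return np.sqrt(self.permittivity)

    def eps_at(self, wavelength_nm):
        """Permittivity at arbitrary wavelengths, linear interpolation in eps."""
        wl = np.asarray(wavelength_nm, dtype=float)
        if np.any(wl < self.wavelength_nm[0]) or np.any(wl > self.wavelength_nm[-1]):
            raise RangeError(
                f"wavelength outside table range "
                f"[{self.wavelength_nm[0]:g}, {self.wavelength_nm[-1]:g}] nm"
            )
        re = np.interp(wl, self.wavelength_nm, self.permittivity.real)
        im = np.interp(wl, self.wavelength_nm, self.permittivity.imag)
        out = re + 1j * im
        if np.ndim(wavelength_nm) == 0:
            return complex(out)
        return out

    def covers(self, wavelength_nm) -> bool:
        wl = np.asarray(wavelength_nm, dtype=float)
        return bool(
            np.all(wl >= self.wavelength_nm[0]) and np.all(wl <= self.wavelength_nm[-1])
        )


def gold_dispersion(grid_nm: np.ndarray | None = None) -> DispersionTable:
    """Packaged gold dispersion table on the standard grid."""
    grid = DEFAULT_GRID_NM if grid_nm is None else np.asarray(grid_nm, dtype=float)
    return DispersionTable("gold", grid, gold_permittivity(grid))


def blend_dispersion(grid_nm: np.ndarray | None = None) -> DispersionTable:
    """Packaged P3HT:PCBM blend table (index representation) on the grid."""
    grid = DEFAULT_GRID_NM if grid_nm is None else np.asarray(grid_nm, dtype=float)
    nk = blend_index(grid)
    return DispersionTable("p3ht_pcbm", grid, np.asarray(nk) ** 2, representation="index")


# --------------------------------------------------------------------------
# Tissue properties
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class TissueProperties:
    """Bulk electrical properties of neural tissue at one frequency."""

    frequency_hz: float
    conductivity_s_m: float
    relative_permittivity: float

    def __post_init__(self):
        if self.conductivity_s_m <= 0:
            raise ValueError("tissue conductivity must be positive")
        if self.relative_permittivity <= 0:
            raise ValueError("tissue relative permittivity must be positive")


TISSUE_10HZ = TissueProperties(10.0, 0.027, 4.06e7)
TISSUE_100HZ = TissueProperties(100.0, 0.089, 3.90e6)


def tissue_properties(frequency_hz: float) -> TissueProperties:
    """Packaged tissue properties (10 or 100 Hz only)."""
    for t in (TISSUE_10HZ, TISSUE_100HZ):
        if frequency_hz == t.frequency_hz:
            return t
    raise RangeError("tissue properties are tabulated at 10 and 100 Hz only")


# --------------------------------------------------------------------------
# CSV I/O
# --------------------------------------------------------------------------

_CSV_PRECISION = 9


def write_dispersion_csv(table: DispersionTable, path: str | Path) -> None:
    """Write a dispersion table as CSV.

    The header comment records material, representation and the fixed decimal
    precision; a write -> read round trip reproduces all values exactly as
    formatted.
    """
    path = Path(path)
    rep = table.representation
    if rep == "index":
        cols = ("n", "k")
        vals = table.index
    else:
        cols = ("eps_re", "eps_im")
        vals = table.permittivity
    fmt = f"%.{_CSV_PRECISION}f"
    with path.open("w", encoding="utf-8") as fh:
        fh.write(
            f"# material: {table.material}; representation: {rep}; "
            f"precision: {_CSV_PRECISION} decimal places\n"
        )
        fh.write(f"wavelength_nm,{cols[0]},{cols[1]}\n")
        for wl, v in zip(table.wavelength_nm, vals):
            fh.write(f"{fmt % wl},{fmt % v.real},{fmt % v.imag}\n")


def read_dispersion_csv(path: str | Path) -> DispersionTable:
    """Read a dispersion CSV written by :func:`write_dispersion_csv`.

    Accepts either an (n, k) or an (eps_re, eps_im) column pair.  Raises
    :class:`FormatError` identifying the offending data row for missing
    columns, non-ascending wavelengths or negative k / Im eps.
    """
    path = Path(path)
    material = path.stem
    lines = path.read_text(encoding="utf-8").splitlines()
    rows: list[str] = []
    for ln in lines:
        s = ln.strip()
        if not s:
            continue
        if s.startswith("#"):
            if "material:" in s:
                material = s.split("material:")[1].split(";")[0].strip()
            continue
        rows.append(s)
    if not rows:
        raise FormatError(f"{path}: empty dispersion file")
    header = [c.strip() for c in rows[0].split(",")]
    if "wavelength_nm" not in header:
        raise FormatError(f"{path}: missing required column 'wavelength_nm'")
    if {"n", "k"}.issubset(header):
        rep, c1, c2 = "index", "n", "k"
    elif {"eps_re", "eps_im"}.issubset(header):
        rep, c1, c2 = "permittivity", "eps_re", "eps_im"
    else:
        raise FormatError(
            f"{path}: expected columns (n, k) or (eps_re, eps_im), got {header}"
        )
    iw, i1, i2 = header.index("wavelength_nm"), header.index(c1), header.index(c2)
    wl, a, b = [], [], []
    for rownum, line in enumerate(rows[1:], start=1):
        parts = [c.strip() for c in line.split(",")]
        if len(parts) < len(header):
            raise FormatError(f"{path}: row {rownum}: expected {len(header)} columns")
        try:
            w, x, y = float(parts[iw]), float(parts[i1]), float(parts[i2])
        except ValueError as exc:
            raise FormatError(f"{path}: row {rownum}: non-numeric value") from exc
        if wl and w <= wl[-1]:
            raise FormatError(f"{path}: row {rownum}: wavelengths not ascending")
        if y < 0:
            name = "k" if rep == "index" else "eps_im"
            raise FormatError(f"{path}: row {rownum}: negative {name} ({y})")
        wl.append(w)
        a.append(x)
        b.append(y)
    vals = np.asarray(a) + 1j * np.asarray(b)
    eps = vals**2 if rep == "index" else vals
    return DispersionTable(material, np.asarray(wl), eps, representation=rep)


def write_tissue_csv(path: str | Path) -> None:
    """Write the packaged tissue property table as CSV."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("frequency_hz,conductivity_S_per_m,relative_permittivity\n")
        for t in (TISSUE_10HZ, TISSUE_100HZ):
            fh.write(
                f"{t.frequency_hz:g},{t.conductivity_s_m:g},{t.relative_permittivity:g}\n"
            )


def generate_fixtures(out_dir: str | Path) -> dict[str, Path]:
    """Emit the packaged fixtures (gold.csv, p3ht_pcbm.csv, tissue.csv)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "gold": out / "gold.csv",
        "p3ht_pcbm": out / "p3ht_pcbm.csv",
        "tissue": out / "tissue.csv",
    }
    write_dispersion_csv(gold_dispersion(), paths["gold"])
    write_dispersion_csv(blend_dispersion(), paths["p3ht_pcbm"])
    write_tissue_csv(paths["tissue"])
    return paths
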