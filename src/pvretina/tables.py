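"""Reported device performance rows used as calibration inputs.

Each row carries the configuration label, the measured-model triple
(Jsc [A/m^2], Voc [V], FF [%]) and the reported PCE [%] at the stated
incident intensity.  The diode surrogate is anchored to these triples and
the PCE column is recomputed, never copied, by the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["PerformanceRow", "TABLE_R75_038", "TABLE_R10_026", "ALL_ROWS"]


@dataclass(frozen=True)
class PerformanceRow:
    label: str
    jsc_a_m2: float
    voc_v: float
    ff_pct: float
    pce_pct: float
    intensity_mw_mm2: float
    radius_nm: float | None  # None: bare layer
    fs: float | None         # None: bare layer
    wavelength_nm: float


TABLE_R75_038: tuple[PerformanceRow, ...] = (
    PerformanceRow("bare, 610 nm", 4.5, 0.55, 76.5, 0.5, 0.38, None, None, 610.0),
    PerformanceRow("bare, 500 nm", 34.0, 0.63, 74.7, 4.2, 0.38, None, None, 500.0),
    PerformanceRow("r=7.5 nm, fs=10%", 35.0, 0.61, 75.4, 4.2, 0.38, 7.5, 0.10, 610.0),
    PerformanceRow("r=7.5 nm, fs=15%", 50.0, 0.63, 73.0, 6.0, 0.38, 7.5, 0.15, 610.0),
    PerformanceRow("r=7.5 nm, fs=20%", 67.0, 0.64, 72.2, 8.1, 0.38, 7.5, 0.20, 610.0),
)
"""r = 7.5 nm device set at 0.38 mW/mm^2."""

TABLE_R10_026: tuple[PerformanceRow, ...] = (
    PerformanceRow("bare, 610 nm", 3.1, 0.54, 77.6, 0.5, 0.26, None, None, 610.0),
    PerformanceRow("bare, 500 nm", 22.0, 0.62, 77.0, 4.0, 0.26, None, None, 500.0),
    PerformanceRow("r=10 nm, fs=10%", 35.0, 0.62, 73.7, 6.1, 0.26, 10.0, 0.10, 610.0),
    PerformanceRow("r=10 nm, fs=15%", 51.0, 0.63, 74.7, 9.2, 0.26, 10.0, 0.15, 610.0),
    PerformanceRow("r=10 nm, fs=20%", 67.0, 0.64, 74.6, 12.3, 0.26, 10.0, 0.20, 610.0),
)
"""r = 10 nm device set at 0.26 mW/mm^2."""

ALL_ROWS: tuple[PerformanceRow, ...] = TABLE_R75_038 + TABLE_R10_026
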