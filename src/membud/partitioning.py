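"""Quantification of photoswitch membrane incorporation from SEC traces.

Size-exclusion chromatography separates liposome-incorporated photoswitch
(eluting early, with the vesicles, near 5.4 mL on the column used here)
from the free switch (two later peaks near 7 and 8.1 mL from two aggregate
populations).  With absorbance detection at a fixed wavelength and the
minimal calibration assumption — peak area proportional to moles injected,
identical extinction for free and inserted switch — the arithmetic is:

    c_incorporated = c_total * (incorporated peak area) / (total peak area)
    fraction       = 100 * c_incorporated / c_total          [%]
    lipids/switch  = c_lipid / c_incorporated

Concentrations are molar throughout; percent appears only at the
reporting boundary.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd

__all__ = [
    "ElutionTrace",
    "PeakWindow",
    "PartitioningResult",
    "integrate_peak",
    "incorporated_concentration",
    "incorporated_fraction",
    "lipids_per_switch",
]


@dataclass(frozen=True)
class ElutionTrace:
    """Sampled elution profile: strictly increasing volume (mL) vs absorbance (AU)."""

    volume: np.ndarray
    absorbance: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.volume, dtype=float)
        a = np.asarray(self.absorbance, dtype=float)
        if v.ndim != 1 or v.shape != a.shape:
            raise ValueError("volume and absorbance must be 1-D arrays of equal length")
        if v.size < 2:
            raise ValueError("trace needs at least 2 samples")
        if np.any(np.diff(v) <= 0):
            raise ValueError("elution volumes must be strictly increasing")
        if not np.all(np.isfinite(a)):
            raise ValueError("absorbance contains non-finite values")
        object.__setattr__(self, "volume", v)
        object.__setattr__(self, "absorbance", a)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "ElutionTrace":
        """Build from a table with columns volume_mL, absorbance_AU."""
        return cls(df["volume_mL"].to_numpy(), df["absorbance_AU"].to_numpy())

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"volume_mL": self.volume, "absorbance_AU": self.absorbance})


@dataclass(frozen=True)
class PeakWindow:
    """Integration window [v_start, v_end] in mL."""

    v_start: float
    v_end: float

    def __post_init__(self) -> None:
        if not self.v_start < self.v_end:
            raise ValueError(f"empty window [{self.v_start}, {self.v_end}]")


@dataclass(frozen=True)
class PartitioningResult:
    """Incorporated concentration (M), fraction of total (%), lipid:switch ratio."""

    c_incorporated: float
    fraction_percent: float
    lipids_per_switch: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction_percent <= 100.0:
            raise ValueError(f"fraction {self.fraction_percent}% outside [0, 100]")
        if self.lipids_per_switch <= 0:
            raise ValueError("lipid:switch ratio must be positive")


def integrate_peak(
    trace: ElutionTrace,
    window: PeakWindow,
    baseline: Literal["none", "linear"] = "none",
) -> float:
    """Trapezoidal peak area (AU·mL) over a window, with optional linear baseline.

    The linear baseline connects the absorbance at the window endpoints
    (interpolated on the trace) and is subtracted before integration.
    Windows reaching outside the sampled volume range are rejected;
    windows with fewer than 3 interior samples are too coarse to
    integrate.  A negative net area (over-subtracted baseline) is
    returned as-is — the caller decides whether to flag it.
    """
    v, y = trace.volume, trace.absorbance
    if window.v_start < v[0] or window.v_end > v[-1]:
        raise ValueError(
            f"window [{window.v_start}, {window.v_end}] mL outside trace "
            f"support [{v[0]}, {v[-1]}] mL"
        )
    inside = (v >= window.v_start) & (v <= window.v_end)
    if inside.sum() < 3:
        raise ValueError("fewer than 3 trace samples inside the window")
    # include exact endpoint values by interpolation so the area is a
    # continuous function of the window bounds
    vv = np.concatenate([[window.v_start], v[inside], [window.v_end]])
    yy = np.concatenate(
        [[np.interp(window.v_start, v, y)], y[inside], [np.interp(window.v_end, v, y)]]
    )
    vv, keep = np.unique(vv, return_index=True)
    yy = yy[keep]
    if baseline == "linear":
        yy = yy - np.interp(vv, [vv[0], vv[-1]], [yy[0], yy[-1]])
    elif baseline != "none":
        raise ValueError(f"unknown baseline mode {baseline!r}")
    return float(np.trapezoid(yy, vv))


def incorporated_concentration(
    area_incorporated: float, area_total_all_peaks: float, c_total: float
) -> float:
    """Concentration (M) of membrane-incorporated switch from peak-area shares.

    Proportional-response calibration: the absorbance peak area is taken
    proportional to moles, with identical extinction for free and
    inserted switch, so the incorporated share of total area is the
    incorporated share of total concentration.
    """
    if area_incorporated < 0 or area_total_all_peaks <= 0:
        raise ValueError(
            "areas must satisfy area_incorporated >= 0 and total area > 0, got "
            f"{area_incorporated}, {area_total_all_peaks}"
        )
    if c_total <= 0:
        raise ValueError(f"total concentration must be positive, got {c_total}")
    return c_total * area_incorporated / area_total_all_peaks


def incorporated_fraction(c_inc: float, c_total: float) -> float:
    """Incorporated share of the total switch, in percent."""
    if c_total <= 0:
        raise ValueError(f"total concentration must be positive, got {c_total}")
    if not 0.0 <= c_inc <= c_total:
        raise ValueError(
            f"incorporated concentration {c_inc} outside [0, c_total={c_total}]"
        )
    return 100.0 * c_inc / c_total


def lipids_per_switch(c_lipid: float, c_inc: float) -> float:
    """Number of lipid molecules per membrane-inserted switch molecule."""
    if c_lipid <= 0 or c_inc <= 0:
        raise ValueError(
            f"both concentrations must be positive, got c_lipid={c_lipid}, c_inc={c_inc}"
        )
    return c_lipid / c_inc


def quantify_partitioning(
    trace: ElutionTrace,
    incorporated_window: PeakWindow,
    free_windows: list[PeakWindow],
    c_total: float,
    c_lipid: float,
    baseline: Literal["none", "linear"] = "none",
) -> PartitioningResult:
    """End-to-end SEC quantification: integrate, calibrate, report.

    The total area is the sum over the incorporated window and all free
    windows; negative window areas are clipped to zero with a warning-free
    floor (they arise only from baseline over-subtraction on noise).
    """
    a_inc = max(integrate_peak(trace, incorporated_window, baseline), 0.0)
    a_free = sum(
        max(integrate_peak(trace, w, baseline), 0.0) for w in free_windows
    )
    c_inc = incorporated_concentration(a_inc, a_inc + a_free, c_total)
    return PartitioningResult(
        c_incorporated=c_inc,
        fraction_percent=incorporated_fraction(c_inc, c_total),
        lipids_per_switch=lipids_per_switch(c_lipid, c_inc),
    )
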