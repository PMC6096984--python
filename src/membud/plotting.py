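"""Morphology-diagram and trace plots."""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .curvature import ElasticParams, limit_shape_line

__all__ = ["morphology_diagram", "plot_deformation_series", "plot_elution_trace"]


def morphology_diagram(
    records: pd.DataFrame | None,
    kappa_ratios: Sequence[float],
    ax=None,
    n_line: int = 200,
):
    """Limit-shape lines in the (nu, m_bar) plane, with optional data points.

    Each rigidity ratio gets one theoretical line; per-vesicle points
    from ``records`` (columns nu, m_bar, kappa_ratio) are overlaid with
    matching colours, so a population on the line shows the data
    collapse directly.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4.5))
    x_grid = np.geomspace(0.02, 1.0, n_line)
    for ratio in kappa_ratios:
        line = limit_shape_line(ElasticParams(ratio), x_grid)
        (ln,) = ax.plot(line.nu, line.m_bar, label=f"κ'/κ = {ratio:g}")
        if records is not None:
            sel = records[records["kappa_ratio"] == ratio]
            ax.plot(
                sel["nu"], sel["m_bar"], "o", ms=4, alpha=0.7, color=ln.get_color()
            )
    ax.set_xlabel("reduced volume ν")
    ax.set_ylabel("dimensionless spontaneous curvature m̄")
    ax.set_xlim(0.70, 1.0)
    ax.set_ylim(0, None)
    ax.legend(frameon=False, fontsize=8)
    return ax


def plot_deformation_series(series, ax=None):
    """Aspect ratio a/b over time, UV window shaded."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 3.5))
    df = series.to_dataframe()
    ax.plot(df["t_s"], df["a_um"] / df["b_um"], lw=1)
    if series.uv_onset_time is not None:
        ax.axvspan(
            series.uv_onset_time, df["t_s"].iloc[-1], alpha=0.15, color="violet"
        )
    ax.set_xlabel("time (s)")
    ax.set_ylabel("degree of deformation a/b")
    return ax


def plot_elution_trace(trace, windows=None, ax=None):
    """Elution profile with optional integration windows shaded."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 3.5))
    ax.plot(trace.volume, trace.absorbance, lw=1)
    for w in windows or []:
        ax.axvspan(w.v_start, w.v_end, alpha=0.15)
    ax.set_xlabel("elution volume (mL)")
    ax.set_ylabel("absorbance (AU)")
    return ax
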