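"""Model/Results front end over the analysis pipeline.

Three model classes, one per experimental modality, each built from data
and returning a Results object from ``fit()`` with estimates,
uncertainties and a ``summary()`` table:

* :class:`SpontaneousCurvatureModel` — budded-shape radius tables to
  per-vesicle curvature decompositions and cohort means per rigidity
  ratio, with the morphology-diagram plot;
* :class:`ElectrodeformationModel` — one or more deformation time series
  to relative area increases and the cohort mean ± SEM;
* :class:`SecPartitioningModel` — an elution trace plus sample
  concentrations to the incorporated concentration, percent incorporated
  and lipid:switch ratio.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from . import io as mio
from .curvature import (
    DEFAULT_KAPPA_RATIOS,
    PopulationSummary as CurvatureSummary,
    analyze_budded_population,
)
from .deformation import (
    AreaIncreaseResult,
    DeformationSeries,
    PopulationSummary,
    analyze_series,
    summarize_population,
)
from .geometry import BuddedShape
from .partitioning import ElutionTrace, PartitioningResult, PeakWindow, quantify_partitioning

__all__ = [
    "SpontaneousCurvatureModel",
    "SpontaneousCurvatureResults",
    "ElectrodeformationModel",
    "ElectrodeformationResults",
    "SecPartitioningModel",
    "SecPartitioningResults",
]


class SpontaneousCurvatureModel:
    """Neck-condition curvature analysis of a budded-vesicle population.

    Parameters
    ----------
    shapes : DataFrame or iterable of BuddedShape
        Radius table (columns vesicle_id, R_alpha_um, R_beta_um) or
        shapes directly.
    kappa_ratios : sequence of float
        Rigidity ratios kappa'/kappa at which to decompose the
        spontaneous curvature; default (0, 0.5, 1, 1.5, 2).

    Examples
    --------
    >>> import pandas as pd
    >>> from membud.models import SpontaneousCurvatureModel
    >>> table = pd.DataFrame({"vesicle_id": ["v0"], "R_alpha_um": [10.0],
    ...                       "R_beta_um": [1.5]})
    >>> res = SpontaneousCurvatureModel(table, kappa_ratios=[0.0]).fit()
    >>> round(res.records["m"].iloc[0], 6)
    0.383333
    """

    def __init__(
        self,
        shapes: pd.DataFrame | Iterable[BuddedShape],
        kappa_ratios: Sequence[float] = DEFAULT_KAPPA_RATIOS,
    ) -> None:
        self.shapes = shapes
        self.kappa_ratios = tuple(kappa_ratios)

    @classmethod
    def from_csv(
        cls, path: str | Path, kappa_ratios: Sequence[float] = DEFAULT_KAPPA_RATIOS
    ) -> "SpontaneousCurvatureModel":
        return cls(mio.read_radius_table(path), kappa_ratios)

    def fit(self) -> "SpontaneousCurvatureResults":
        records, summaries = analyze_budded_population(self.shapes, self.kappa_ratios)
        return SpontaneousCurvatureResults(model=self, records=records, summaries=summaries)


@dataclass(frozen=True)
class SpontaneousCurvatureResults:
    """Per-vesicle curvature decomposition and cohort summaries.

    Attributes
    ----------
    records : DataFrame
        One row per vesicle per rigidity ratio: nu, m_bar, m, m_nlo, m_eff.
    summaries : list of PopulationSummary
        Mean m ± SD/SEM per rigidity ratio, plus the 1/(L ± dL µm) form.
    """

    model: SpontaneousCurvatureModel
    records: pd.DataFrame
    summaries: list[CurvatureSummary]

    def summary(self) -> str:
        lines = [
            "Spontaneous-curvature analysis (neck condition, two-sphere shapes)",
            f"  vesicles: {self.records['vesicle_id'].nunique()}"
            f"   rigidity ratios: {list(self.model.kappa_ratios)}",
            "",
        ]
        lines += ["  " + s.formatted() for s in self.summaries]
        return "\n".join(lines)

    def plot_morphology_diagram(self, ax=None, n_line: int = 200):
        """(nu, m_bar) diagram: limit-shape lines plus the per-vesicle points."""
        from .plotting import morphology_diagram

        return morphology_diagram(
            self.records, self.model.kappa_ratios, ax=ax, n_line=n_line
        )


class ElectrodeformationModel:
    """Membrane-area increase from electrodeformation time series.

    Accepts a single :class:`DeformationSeries` or an iterable of them
    (a cohort); ``fit`` analyses each and, for cohorts, summarises the
    relative area increases as mean ± SEM.
    """

    def __init__(
        self,
        series: DeformationSeries | Iterable[DeformationSeries],
        smooth: bool = False,
    ) -> None:
        if isinstance(series, DeformationSeries):
            self.series: tuple[DeformationSeries, ...] = (series,)
        else:
            self.series = tuple(series)
        if not self.series:
            raise ValueError("no deformation series supplied")
        self.smooth = smooth

    @classmethod
    def from_csv(cls, paths: str | Path | Sequence[str | Path], smooth: bool = False):
        if isinstance(paths, (str, Path)):
            paths = [paths]
        return cls([mio.read_deformation_series(p) for p in paths], smooth=smooth)

    def fit(self) -> "ElectrodeformationResults":
        per_vesicle = [analyze_series(s, smooth=self.smooth) for s in self.series]
        cohort = (
            summarize_population([r.delta_A_rel for r in per_vesicle])
            if len(per_vesicle) >= 2
            else None
        )
        return ElectrodeformationResults(
            model=self, per_vesicle=per_vesicle, cohort=cohort
        )


@dataclass(frozen=True)
class ElectrodeformationResults:
    """Per-vesicle area-increase results and the cohort mean ± SEM (if n >= 2)."""

    model: ElectrodeformationModel
    per_vesicle: list[AreaIncreaseResult]
    cohort: PopulationSummary | None

    @property
    def delta_A_rel(self) -> np.ndarray:
        return np.array([r.delta_A_rel for r in self.per_vesicle])

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            dict(
                vesicle=range(len(self.per_vesicle)),
                A_baseline_um2=[r.A_baseline for r in self.per_vesicle],
                A_uv_max_um2=[r.A_uv_max for r in self.per_vesicle],
                delta_A_rel=[r.delta_A_rel for r in self.per_vesicle],
                nu_baseline=[r.nu_baseline for r in self.per_vesicle],
            )
        )

    def summary(self) -> str:
        lines = ["Electrodeformation area analysis"]
        for i, r in enumerate(self.per_vesicle):
            lines.append(
                f"  vesicle {i}: ΔA/A = {100 * r.delta_A_rel:.2f}%   "
                f"A = {r.A_baseline:.1f} µm²   nu = {r.nu_baseline:.4f}"
            )
        if self.cohort is not None:
            lines.append(
                f"  cohort (n={self.cohort.n}): mean ΔA/A = "
                f"{100 * self.cohort.mean:.2f}% ± {100 * self.cohort.sem:.2f}% (SEM)"
            )
        return "\n".join(lines)


class SecPartitioningModel:
    """SEC quantification of photoswitch membrane incorporation.

    Parameters
    ----------
    trace : ElutionTrace
    incorporated_window, free_windows : PeakWindow
        Integration windows for the membrane-incorporated peak and the
        free-switch peaks.
    c_total, c_lipid : float
        Total switch and lipid concentrations in the sample, molar.
    baseline : {"none", "linear"}
    """

    def __init__(
        self,
        trace: ElutionTrace,
        incorporated_window: PeakWindow,
        free_windows: Sequence[PeakWindow],
        c_total: float,
        c_lipid: float,
        baseline: Literal["none", "linear"] = "none",
    ) -> None:
        self.trace = trace
        self.incorporated_window = incorporated_window
        self.free_windows = list(free_windows)
        self.c_total = c_total
        self.c_lipid = c_lipid
        self.baseline = baseline

    @classmethod
    def from_csv(
        cls,
        path: str | Path,
        incorporated_window: PeakWindow,
        free_windows: Sequence[PeakWindow],
        c_total: float,
        c_lipid: float,
        baseline: Literal["none", "linear"] = "none",
    ) -> "SecPartitioningModel":
        return cls(
            mio.read_elution_trace(path),
            incorporated_window,
            free_windows,
            c_total,
            c_lipid,
            baseline,
        )

    def fit(self) -> "SecPartitioningResults":
        result = quantify_partitioning(
            self.trace,
            self.incorporated_window,
            self.free_windows,
            self.c_total,
            self.c_lipid,
            self.baseline,
        )
        return SecPartitioningResults(model=self, result=result)


@dataclass(frozen=True)
class SecPartitioningResults:
    model: SecPartitioningModel
    result: PartitioningResult

    @property
    def c_incorporated(self) -> float:
        return self.result.c_incorporated

    @property
    def fraction_percent(self) -> float:
        return self.result.fraction_percent

    @property
    def lipids_per_switch(self) -> float:
        return self.result.lipids_per_switch

    def summary(self) -> str:
        r = self.result
        return "\n".join(
            [
                "SEC partitioning analysis",
                f"  incorporated concentration: {r.c_incorporated:.3e} M",
                f"  fraction of total switch:   {r.fraction_percent:.2f}%",
                f"  lipids per switch molecule: {r.lipids_per_switch:.1f}",
            ]
        )
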