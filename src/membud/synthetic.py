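"""Seeded synthetic-data generators for every pipeline input.

Each generator emulates one class of raw observation and returns the
ground truth alongside the data, so each analysis stage admits an exact
round-trip test at zero noise and a statistical one at realistic noise:

* budded-shape populations whose (R_alpha, R_beta) satisfy the neck
  condition for a known true spontaneous curvature;
* electrodeformation time series shaped like the experiments — an
  exponential rise of the aspect ratio to a plateau under the AC field
  within a few seconds, UV onset near 7 s, then an exponential membrane
  area increase of a few percent at strictly constant volume;
* noisy 2-D vesicle outlines (ellipse sections and two-circle budded
  sections);
* elution traces as sums of Gaussian peaks with prescribed area shares.

All randomness flows through one ``numpy.random.Generator`` per call,
seeded explicitly; identical seed and config give bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import bisect

from .curvature import ElasticParams, neck_curvature
from .deformation import Contour, DeformationFrame, DeformationSeries
from .geometry import (
    BuddedShape,
    SpheroidShape,
    spheroid_area,
    spheroid_from_area_volume,
)
from .partitioning import ElutionTrace

__all__ = [
    "PopulationConfig",
    "DeformationConfig",
    "ContourConfig",
    "ElutionPeak",
    "ElutionConfig",
    "gen_budded_population",
    "gen_deformation_series",
    "gen_contour",
    "gen_elution_trace",
]


@dataclass(frozen=True)
class PopulationConfig:
    """Budded-shape population: mother radii log-normal, buds set by the neck condition.

    Defaults emulate the experimental cohorts: mother vesicles with
    median radius 7.5 µm (log-sd 0.25), a true local spontaneous
    curvature of 0.4 µm⁻¹ = 1/(2.5 µm), and 2% multiplicative radius
    noise from optical measurement.
    """

    n: int = 30
    m_true: float = 0.4
    kappa_ratio: float = 0.0
    R_alpha_median: float = 7.5
    R_alpha_log_sd: float = 0.25
    radius_noise: float = 0.02

    def __post_init__(self) -> None:
        if self.n < 1 or self.m_true <= 0 or self.R_alpha_median <= 0:
            raise ValueError(f"invalid population config {self}")
        if self.radius_noise < 0 or self.R_alpha_log_sd < 0 or self.kappa_ratio < 0:
            raise ValueError(f"invalid population config {self}")


@dataclass(frozen=True)
class DeformationConfig:
    """Electrodeformation series: field ramp, UV onset, area growth at fixed volume.

    Times in s, lengths in µm.  ``r_max`` is the aspect-ratio plateau
    under the AC field alone; ``delta_A_max`` the asymptotic relative
    area increase under UV.  Defaults follow the experimental protocol:
    vesicle radius 15 µm, maximal field deformation reached within 5-7 s
    (tau_field = 1.2 s), UV from 7.2 s, area growth saturating over tens
    of seconds with amplitude 4.6%.
    """

    R0: float = 15.0
    r_max: float = 1.05
    tau_field: float = 1.2
    t_uv: float = 7.2
    delta_A_max: float = 0.046
    tau_uv: float = 10.0
    frame_dt: float = 0.2
    t_end: float = 40.0
    frame_noise: float = 0.0

    def __post_init__(self) -> None:
        if self.R0 <= 0 or self.r_max < 1 or self.delta_A_max < 0:
            raise ValueError(f"invalid deformation config {self}")
        if min(self.tau_field, self.tau_uv, self.frame_dt) <= 0 or self.frame_noise < 0:
            raise ValueError(f"invalid deformation config {self}")
        if self.t_end <= self.t_uv:
            raise ValueError("series must extend past UV onset")


@dataclass(frozen=True)
class ContourConfig:
    """Sampled outline: number of points and isotropic point noise (µm)."""

    n_points: int = 100
    point_noise: float = 0.0

    def __post_init__(self) -> None:
        if self.point_noise < 0:
            raise ValueError("point noise must be >= 0")


@dataclass(frozen=True)
class ElutionPeak:
    """One Gaussian elution peak: centre (mL), width sigma (mL), amplitude (AU)."""

    center: float
    sigma: float
    amplitude: float

    @property
    def area(self) -> float:
        """Analytic area h * sigma * sqrt(2 pi), AU·mL."""
        return self.amplitude * self.sigma * math.sqrt(2.0 * math.pi)


def _default_peaks() -> tuple[ElutionPeak, ...]:
    # incorporated peak at 5.4 mL carrying 0.74% of the total area;
    # free-switch peaks at 7.0 and 8.1 mL share the rest
    free1 = ElutionPeak(7.0, 0.25, 1.0)
    free2 = ElutionPeak(8.1, 0.30, 1.2)
    share = 0.0074
    target_inc_area = share / (1.0 - share) * (free1.area + free2.area)
    sigma_inc = 0.15
    return (
        ElutionPeak(5.4, sigma_inc, target_inc_area / (sigma_inc * math.sqrt(2 * math.pi))),
        free1,
        free2,
    )


@dataclass(frozen=True)
class ElutionConfig:
    """Sum-of-Gaussians elution trace on a uniform volume grid.

    Default peaks sit at 5.4 (membrane-incorporated), 7.0 and 8.1 mL
    (free switch), with the incorporated peak carrying 0.74% of the
    total area.
    """

    peaks: tuple[ElutionPeak, ...] = field(default_factory=_default_peaks)
    v_start: float = 4.0
    v_end: float = 10.0
    step: float = 0.01
    noise: float = 0.0

    def __post_init__(self) -> None:
        if self.step <= 0 or self.v_start >= self.v_end or self.noise < 0:
            raise ValueError(f"invalid elution config {self}")
        for p in self.peaks:
            if not (self.v_start + 3 * p.sigma < p.center < self.v_end - 3 * p.sigma):
                import warnings

                warnings.warn(
                    f"peak at {p.center} mL overlaps the grid boundary "
                    f"[{self.v_start}, {self.v_end}]; its area will be truncated",
                    stacklevel=2,
                )


def _solve_bud_radius(
    R_alpha: float, m_true: float, params: ElasticParams
) -> float | None:
    """Bud radius R_beta in (0, R_alpha] with neck-condition curvature m_true.

    m(R_beta) decreases monotonically from +inf (vanishing bud) to its
    minimum at R_beta = R_alpha, so a root exists iff
    m(R_alpha, R_alpha) <= m_true; returns None when it does not.
    """

    def g(rb: float) -> float:
        return neck_curvature(BuddedShape(R_alpha, rb), params).m - m_true

    if g(R_alpha) > 0.0:
        return None
    lo = R_alpha * 1e-9
    while g(lo) < 0.0:  # pragma: no cover - lo is far inside the divergence
        lo *= 0.1
    return float(bisect(g, lo, R_alpha, xtol=1e-14, rtol=8.9e-16))


def gen_budded_population(
    config: PopulationConfig, seed: int
) -> tuple[pd.DataFrame, dict]:
    """Budded-shape population with known ground-truth curvature.

    Mother radii are sampled log-normally; each bud radius solves the
    neck condition for ``m_true`` at the configured rigidity ratio
    (exact to ~1e-10 before noise), then both radii get independent
    multiplicative Gaussian noise.  Sampled mothers too small to support
    a bud at ``m_true`` (no root with R_beta <= R_alpha) are rejected
    and re-drawn, with the rejection count recorded.

    Returns
    -------
    table : DataFrame
        Columns vesicle_id, R_alpha_um, R_beta_um (noisy, as measured).
    ground_truth : dict
        m_true, kappa_ratio, seed, n_rejected, and the noise-free radii.
    """
    rng = np.random.default_rng(seed)
    params = ElasticParams(config.kappa_ratio)
    rows = []
    clean = []
    n_rejected = 0
    max_draws = 1000 * config.n
    draws = 0
    while len(rows) < config.n:
        draws += 1
        if draws > max_draws:
            raise ValueError(
                f"rejection sampling exhausted: m_true={config.m_true} µm⁻¹ is "
                f"inadmissible for mothers near {config.R_alpha_median} µm"
            )
        ra = config.R_alpha_median * math.exp(rng.normal(0.0, config.R_alpha_log_sd))
        rb = _solve_bud_radius(ra, config.m_true, params)
        if rb is None:
            n_rejected += 1
            continue
        clean.append((ra, rb))
        ra_noisy = ra * (1.0 + rng.normal(0.0, config.radius_noise))
        rb_noisy = rb * (1.0 + rng.normal(0.0, config.radius_noise))
        # noise may not break the ordering or positivity contract
        ra_noisy = max(ra_noisy, 1e-6)
        rb_noisy = min(max(rb_noisy, 1e-6), ra_noisy)
        rows.append(
            dict(
                vesicle_id=f"v{len(rows):03d}",
                R_alpha_um=ra_noisy,
                R_beta_um=rb_noisy,
            )
        )
    table = pd.DataFrame(rows)
    ground_truth = dict(
        m_true=config.m_true,
        kappa_ratio=config.kappa_ratio,
        seed=seed,
        n_rejected=n_rejected,
        R_alpha_clean=[c[0] for c in clean],
        R_beta_clean=[c[1] for c in clean],
        config=asdict(config),
    )
    return table, ground_truth


def gen_deformation_series(
    config: DeformationConfig, seed: int
) -> tuple[DeformationSeries, dict]:
    """Synthetic electrodeformation experiment at strictly constant volume.

    Pre-UV, the aspect ratio follows r(t) = 1 + (r_max - 1)(1 - e^(-t/tau_field))
    at fixed volume V = (4/3) pi R0³, i.e. a = R0 r^(2/3), b = R0 r^(-1/3).
    From UV onset the membrane area grows from the last pre-UV (baseline)
    area A_0 as A(t) = A_0 (1 + delta_A_max g(t)) with a saturating
    exponential g normalised to reach 1 exactly at the final frame — the
    configured delta_A_max is the relative area increase over the recorded
    window, as it is measured.  Frame semiaxes are recovered by inverting
    (A, V) to the unique prolate spheroid.  Multiplicative Gaussian noise
    is applied per frame to a and b after the geometry is fixed, so the
    noise-free series conserves volume to 1e-9 relative.
    """
    if config.t_uv < 3.0 * config.tau_field:
        import warnings

        warnings.warn(
            "UV onset before the field ramp is substantially complete; the "
            "baseline will underestimate the fluctuation-free area",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    V = 4.0 / 3.0 * math.pi * config.R0**3
    times = np.arange(0.0, config.t_end + 0.5 * config.frame_dt, config.frame_dt)

    def ramp(t: float) -> float:
        return 1.0 + (config.r_max - 1.0) * (1.0 - math.exp(-t / config.tau_field))

    pre_times = times[times < config.t_uv]
    if pre_times.size == 0:
        raise ValueError("no pre-UV frames: t_uv precedes the first frame")
    r_base = ramp(float(pre_times[-1]))
    A_base = spheroid_area(
        SpheroidShape(config.R0 * r_base ** (2.0 / 3.0), config.R0 * r_base ** (-1.0 / 3.0))
    )
    t_last = float(times[-1])
    g_end = 1.0 - math.exp(-(t_last - config.t_uv) / config.tau_uv)
    frames = []
    for t in times:
        if t < config.t_uv:
            r = ramp(t)
            a = config.R0 * r ** (2.0 / 3.0)
            b = config.R0 * r ** (-1.0 / 3.0)
            uv = False
        else:
            g = (1.0 - math.exp(-(t - config.t_uv) / config.tau_uv)) / g_end
            A = A_base * (1.0 + config.delta_A_max * g)
            shape = spheroid_from_area_volume(A, V)
            a, b = shape.a, shape.b
            uv = True
        if config.frame_noise > 0:
            a *= 1.0 + rng.normal(0.0, config.frame_noise)
            b *= 1.0 + rng.normal(0.0, config.frame_noise)
            if a < b:
                a, b = b, a
        frames.append(DeformationFrame(t=float(t), a=a, b=b, uv_on=uv))
    series = DeformationSeries(
        frames=tuple(frames), field_on_time=0.0, uv_onset_time=config.t_uv
    )
    ground_truth = dict(
        delta_A_max=config.delta_A_max,
        r_max=config.r_max,
        V_um3=V,
        A_baseline_um2=A_base,
        seed=seed,
        config=asdict(config),
    )
    return series, ground_truth


def gen_contour(
    shape: SpheroidShape | BuddedShape, config: ContourConfig, seed: int
) -> Contour:
    """Noisy 2-D outline of an ellipse section or a two-circle budded section.

    For a budded shape the two circles are externally tangent (closed
    neck) along the x axis, and points are split between the circles in
    proportion to their circumference.  Isotropic Gaussian noise of sd
    ``point_noise`` is added to every point.
    """
    rng = np.random.default_rng(seed)
    if isinstance(shape, SpheroidShape):
        if config.n_points < 6:
            raise ValueError("ellipse outline needs >= 6 points")
        t = np.linspace(0.0, 2.0 * math.pi, config.n_points, endpoint=False)
        pts = np.column_stack([shape.a * np.cos(t), shape.b * np.sin(t)])
        label = "ellipse"
    elif isinstance(shape, BuddedShape):
        if config.n_points < 10:
            raise ValueError("budded outline needs >= 10 points")
        ra, rb = shape.R_alpha, shape.R_beta
        n_a = max(5, int(round(config.n_points * ra / (ra + rb))))
        n_b = max(5, config.n_points - n_a)
        ta = np.linspace(0.0, 2.0 * math.pi, n_a, endpoint=False)
        tb = np.linspace(0.0, 2.0 * math.pi, n_b, endpoint=False)
        mother = np.column_stack([ra * np.cos(ta), ra * np.sin(ta)])
        bud = np.column_stack([ra + rb + rb * np.cos(tb), rb * np.sin(tb)])
        pts = np.vstack([mother, bud])
        label = "budded"
    else:
        raise TypeError(f"unsupported shape type {type(shape).__name__}")
    if config.point_noise > 0:
        pts = pts + rng.normal(0.0, config.point_noise, size=pts.shape)
    return Contour(points=pts, shape_label=label)


def gen_elution_trace(config: ElutionConfig, seed: int) -> tuple[ElutionTrace, dict]:
    """Sum-of-Gaussians elution trace with analytic ground-truth peak areas."""
    rng = np.random.default_rng(seed)
    v = np.arange(config.v_start, config.v_end + 0.5 * config.step, config.step)
    y = np.zeros_like(v)
    for p in config.peaks:
        y += p.amplitude * np.exp(-0.5 * ((v - p.center) / p.sigma) ** 2)
    if config.noise > 0:
        y = y + rng.normal(0.0, config.noise, size=y.shape)
    trace = ElutionTrace(volume=v, absorbance=y)
    ground_truth = dict(
        true_areas=[p.area for p in config.peaks],
        centers=[p.center for p in config.peaks],
        seed=seed,
        config=dict(
            v_start=config.v_start,
            v_end=config.v_end,
            step=config.step,
            noise=config.noise,
            peaks=[asdict(p) for p in config.peaks],
        ),
    )
    return trace, ground_truth
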