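"""Membrane-area extraction from vesicle electrodeformation time series.

An AC field elongates a quasi-spherical vesicle into a prolate spheroid,
pulling the excess area stored in thermal fluctuations into the visible
contour.  The semiaxes (a, b) of the ellipse then give the true membrane
area via the prolate-spheroid closed form.  Switching on UV light (field
still on) photoisomerises the membrane-inserted switch and grows the
area; the relative area increase is

    delta_A_rel = (A_UV - A) / A

with A the area at maximal pre-UV deformation and A_UV the area at
maximal deformation under UV.  The baseline frame also yields the reduced
volume nu of the vesicle before irradiation.

Contour fitting (ellipse, two-circle budded outline) lives here too: it
is the measurement step that turns a digitised vesicle outline into the
(a, b) or (R_alpha, R_beta) the rest of the pipeline consumes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from skimage.measure import EllipseModel

from .geometry import (
    BuddedShape,
    SpheroidShape,
    VesicleGeometry,
    spheroid_area,
    spheroid_volume,
)

__all__ = [
    "DeformationFrame",
    "DeformationSeries",
    "AreaIncreaseResult",
    "Contour",
    "PopulationSummary",
    "EllipseFit",
    "NoBudError",
    "area_volume_series",
    "max_deformation",
    "relative_area_increase",
    "analyze_series",
    "summarize_population",
    "fit_ellipse",
    "fit_budded_contour",
]


class NoBudError(ValueError):
    """Raised when a contour is better described by a single circle than two."""


@dataclass(frozen=True)
class DeformationFrame:
    """One video frame: time t (s), prolate semiaxes a >= b (µm), UV flag."""

    t: float
    a: float
    b: float
    uv_on: bool

    def __post_init__(self) -> None:
        if not math.isfinite(self.t):
            raise ValueError(f"frame time must be finite, got {self.t}")
        SpheroidShape(self.a, self.b)  # validates a >= b > 0

    @property
    def aspect_ratio(self) -> float:
        return self.a / self.b


@dataclass(frozen=True)
class DeformationSeries:
    """Time-ordered electrodeformation frames with field/UV timing metadata."""

    frames: tuple[DeformationFrame, ...]
    field_on_time: float = 0.0
    uv_onset_time: float | None = None

    def __post_init__(self) -> None:
        if len(self.frames) == 0:
            raise ValueError("empty deformation series")
        ts = [f.t for f in self.frames]
        if any(t1 >= t2 for t1, t2 in zip(ts, ts[1:])):
            idx = next(i for i, (t1, t2) in enumerate(zip(ts, ts[1:])) if t1 >= t2)
            raise ValueError(
                f"frame times must be strictly increasing; violation at index {idx}"
            )
        onset = self.uv_onset_time
        if onset is not None:
            if onset < self.field_on_time:
                raise ValueError("UV onset precedes field switch-on")
            for i, f in enumerate(self.frames):
                if f.uv_on != (f.t >= onset):
                    raise ValueError(
                        f"frame {i} (t={f.t}): uv_on flag inconsistent with "
                        f"uv_onset_time={onset}"
                    )

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        field_on_time: float = 0.0,
        uv_onset_time: float | None = None,
    ) -> "DeformationSeries":
        """Build from a table with columns t_s, a_um, b_um, uv_on (0/1)."""
        frames = tuple(
            DeformationFrame(
                t=float(r.t_s), a=float(r.a_um), b=float(r.b_um), uv_on=bool(r.uv_on)
            )
            for r in df.itertuples()
        )
        if uv_onset_time is None and any(f.uv_on for f in frames):
            uv_onset_time = min(f.t for f in frames if f.uv_on)
        return cls(frames=frames, field_on_time=field_on_time, uv_onset_time=uv_onset_time)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t_s": [f.t for f in self.frames],
                "a_um": [f.a for f in self.frames],
                "b_um": [f.b for f in self.frames],
                "uv_on": [int(f.uv_on) for f in self.frames],
            }
        )

    def window(self, which: Literal["pre_uv", "post_uv"]) -> tuple[DeformationFrame, ...]:
        if which == "pre_uv":
            return tuple(f for f in self.frames if not f.uv_on)
        if which == "post_uv":
            return tuple(f for f in self.frames if f.uv_on)
        raise ValueError(f"unknown window {which!r}")


@dataclass(frozen=True)
class AreaIncreaseResult:
    """Outcome of one electrodeformation experiment.

    delta_A_rel = (A_uv_max - A_baseline)/A_baseline; nu_baseline is the
    reduced volume computed from the baseline (maximal pre-UV) frame.
    """

    A_baseline: float
    A_uv_max: float
    delta_A_rel: float
    nu_baseline: float


@dataclass(frozen=True)
class Contour:
    """Ordered 2-D outline points (µm) with the expected shape family."""

    points: np.ndarray  # (n, 2)
    shape_label: Literal["ellipse", "budded"] = "ellipse"

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ValueError("contour points must be an (n, 2) array")
        minimum = 6 if self.shape_label == "ellipse" else 10
        if pts.shape[0] < minimum:
            raise ValueError(
                f"{self.shape_label} contour needs >= {minimum} points, got {pts.shape[0]}"
            )
        # collinearity check via the smaller singular value of centred points
        centred = pts - pts.mean(axis=0)
        sv = np.linalg.svd(centred, compute_uv=False)
        if sv[-1] < 1e-12 * max(sv[0], 1.0):
            raise ValueError("degenerate (collinear) contour")
        object.__setattr__(self, "points", pts)


@dataclass(frozen=True)
class PopulationSummary:
    """Cohort mean with its standard error (SD with n-1 denominator over sqrt n)."""

    n: int
    mean: float
    sem: float


@dataclass(frozen=True)
class EllipseFit:
    """Geometric ellipse parameters: centre, semiaxes a >= b, orientation.

    The orientation is the angle of the long axis from the abscissa (the
    field axis), wrapped to (-pi/2, pi/2].
    """

    center: tuple[float, float]
    a: float
    b: float
    orientation: float


def area_volume_series(series: DeformationSeries) -> pd.DataFrame:
    """Per-frame prolate-spheroid area, volume and aspect ratio.

    Returns a DataFrame with columns t_s, A_um2, V_um3, aspect_ratio, uv_on.
    """
    rows = []
    for i, f in enumerate(series.frames):
        try:
            shape = SpheroidShape(f.a, f.b)
        except ValueError as exc:  # pragma: no cover - frames validate on build
            raise ValueError(f"frame {i} (t={f.t}): {exc}") from exc
        rows.append(
            dict(
                t_s=f.t,
                A_um2=spheroid_area(shape),
                V_um3=spheroid_volume(shape),
                aspect_ratio=f.aspect_ratio,
                uv_on=f.uv_on,
            )
        )
    return pd.DataFrame(rows)


def max_deformation(
    series: DeformationSeries,
    window: Literal["pre_uv", "post_uv"],
    smooth: bool = False,
) -> DeformationFrame:
    """Frame of maximal aspect ratio a/b within the pre- or post-UV window.

    Ties break to the earliest frame.  With ``smooth=True`` a rolling
    median (window 5) is applied to a/b before the argmax, to resist
    single-frame outliers; off by default so results are a deterministic
    function of the raw frames.
    """
    frames = series.window(window)
    if not frames:
        raise ValueError(f"no frames in window {window!r}")
    ratios = np.array([f.aspect_ratio for f in frames])
    if smooth and len(frames) >= 5:
        ratios = pd.Series(ratios).rolling(5, center=True, min_periods=1).median().to_numpy()
    return frames[int(np.argmax(ratios))]


def relative_area_increase(A_baseline: float, A_uv: float) -> float:
    """Relative area increase (A_uv - A_baseline) / A_baseline.

    May be negative; the contract does not forbid shrinkage.
    """
    if A_baseline <= 0:
        raise ValueError(f"baseline area must be positive, got {A_baseline}")
    return (A_uv - A_baseline) / A_baseline


def _plateau_estimate(series: DeformationSeries) -> tuple[float, float]:
    """Noise-suppressed (A_baseline, A_uv) exploiting volume conservation.

    Per-frame semiaxis noise enters the raw frame areas at full strength,
    and taking the single maximal frame then inherits the largest noise
    excursion.  Since the vesicle volume is constant throughout the
    experiment, each frame is instead projected onto the constant-volume
    manifold: the aspect ratio a/b is kept (it is the well-measured
    quantity) and the semiaxes are rebuilt from the median volume of the
    whole series.  Near the quasi-spherical baseline the area is
    quadratic in (a/b - 1), which suppresses aspect noise by two orders
    of magnitude.  The baseline averages the projected area over the
    pre-UV frames within 0.5% of the maximal aspect ratio (the field
    plateau); the UV endpoint evaluates a least-squares saturating
    exponential fitted to the projected post-UV areas at the last frame,
    falling back to the mean of the last tenth of frames if the fit
    fails.
    """
    from scipy.optimize import curve_fit

    t = np.array([f.t for f in series.frames])
    a = np.array([f.a for f in series.frames])
    b = np.array([f.b for f in series.frames])
    uv = np.array([f.uv_on for f in series.frames])
    if not uv.any() or uv.all():
        raise ValueError("series must span pre- and post-UV windows")
    r = a / b
    V = float(np.median(4.0 / 3.0 * math.pi * a * b * b))
    R = (3.0 * V / (4.0 * math.pi)) ** (1.0 / 3.0)
    A = np.array(
        [
            spheroid_area(SpheroidShape(R * ri ** (2.0 / 3.0), R * ri ** (-1.0 / 3.0)))
            for ri in r
        ]
    )
    r_pre, A_pre = r[~uv], A[~uv]
    plateau = r_pre >= 0.995 * r_pre.max()
    A0 = float(A_pre[plateau].mean())
    t_post, A_post = t[uv], A[uv]
    t0 = t_post[0]

    def trend(tt, c0, c1, tau):
        return c0 + c1 * np.exp(-(tt - t0) / tau)

    try:
        popt, _ = curve_fit(
            trend,
            t_post,
            A_post,
            p0=(float(A_post.max()), float(A_post.min() - A_post.max()), 10.0),
            maxfev=20000,
        )
        A1 = float(trend(t_post[-1], *popt))
    except RuntimeError:
        n_tail = max(1, len(A_post) // 10)
        A1 = float(A_post[-n_tail:].mean())
    return A0, A1


def analyze_series(
    series: DeformationSeries,
    smooth: bool = False,
    estimator: Literal["max", "plateau"] = "max",
) -> AreaIncreaseResult:
    """Full single-vesicle analysis of an electrodeformation experiment.

    The baseline is the area at maximal pre-UV deformation — the field has
    pulled the fluctuation reservoir flat — not the first frame; A_UV is
    the area at maximal deformation after UV onset.

    ``estimator="max"`` (default) takes the single frame of maximal a/b
    in each window, which is exact on noise-free data but inherits the
    largest noise excursion of the window on noisy data.
    ``estimator="plateau"`` uses the volume-conservation projection and
    trend fit of :func:`_plateau_estimate`, the recommended choice for
    noisy series.  ``nu_baseline`` always comes from the maximal pre-UV
    frame.
    """
    pre = max_deformation(series, "pre_uv", smooth=smooth)
    base_shape = SpheroidShape(pre.a, pre.b)
    if estimator == "plateau":
        A0, A1 = _plateau_estimate(series)
    elif estimator == "max":
        post = max_deformation(series, "post_uv", smooth=smooth)
        A0 = spheroid_area(base_shape)
        A1 = spheroid_area(SpheroidShape(post.a, post.b))
    else:
        raise ValueError(f"unknown estimator {estimator!r}")
    geom = VesicleGeometry.from_area_volume(
        spheroid_area(base_shape), spheroid_volume(base_shape)
    )
    return AreaIncreaseResult(
        A_baseline=A0,
        A_uv_max=A1,
        delta_A_rel=relative_area_increase(A0, A1),
        nu_baseline=geom.nu,
    )


def summarize_population(values: Sequence[float] | np.ndarray) -> PopulationSummary:
    """Cohort mean and SEM over per-vesicle measurements (n >= 2, SD with n-1)."""
    vals = np.asarray(values, dtype=float)
    if vals.size < 2:
        raise ValueError(f"need at least 2 values for a SEM, got {vals.size}")
    sd = float(np.std(vals, ddof=1))
    return PopulationSummary(
        n=int(vals.size), mean=float(np.mean(vals)), sem=sd / math.sqrt(vals.size)
    )


def fit_ellipse(contour: Contour) -> EllipseFit:
    """Least-squares ellipse through contour points (direct conic fit).

    Exact on noise-free sampled ellipses; semiaxes returned with a >= b
    and the orientation of the long axis in (-pi/2, pi/2].

    Raises
    ------
    ValueError
        On degenerate input or when the best conic is not an ellipse.
    """
    if contour.shape_label != "ellipse":
        raise ValueError("contour is not labelled as an ellipse outline")
    model = EllipseModel.from_estimate(contour.points)
    if not model:
        raise ValueError("ellipse fit failed (degenerate or non-elliptical points)")
    (xc, yc), (ax1, ax2), theta = model.center, model.axis_lengths, model.theta
    if not np.all(np.isfinite([xc, yc, ax1, ax2, theta])) or min(ax1, ax2) <= 0:
        raise ValueError("ellipse fit produced a non-elliptical conic")
    if ax1 >= ax2:
        a, b = ax1, ax2
    else:
        a, b = ax2, ax1
        theta += math.pi / 2.0
    theta = math.remainder(theta, math.pi)
    if theta <= -math.pi / 2.0:
        theta += math.pi
    return EllipseFit(center=(float(xc), float(yc)), a=float(a), b=float(b), orientation=float(theta))


def _kasa_circle(points: np.ndarray) -> tuple[np.ndarray, float, float]:
    """Algebraic least-squares circle (centre, radius, RSS of radial residuals)."""
    x, y = points[:, 0], points[:, 1]
    A = np.column_stack([2 * x, 2 * y, np.ones_like(x)])
    bvec = x * x + y * y
    sol, *_ = np.linalg.lstsq(A, bvec, rcond=None)
    cx, cy, c = sol
    r = math.sqrt(max(c + cx * cx + cy * cy, 0.0))
    resid = np.hypot(x - cx, y - cy) - r
    return np.array([cx, cy]), r, float(np.sum(resid**2))


def _bic(rss: float, n: int, k: int) -> float:
    # Gaussian BIC on radial residuals; floor avoids log(0) on exact data
    return n * math.log(max(rss, 1e-300) / n) + k * math.log(n)


def fit_budded_contour(contour: Contour, max_iter: int = 50) -> BuddedShape:
    """Two-circle least-squares fit of a budded (two-lobed) outline.

    Points are first split into two groups by a 1-D two-means cut along
    the principal axis of the outline; each group gets an algebraic
    circle fit, then points are reassigned to the nearer circle and the
    fits repeated until the assignment is stable.  Radii return with
    R_alpha >= R_beta.

    Raises
    ------
    NoBudError
        When a single circle explains the outline better (BIC), i.e. the
        vesicle has no resolvable bud.
    """
    if contour.shape_label != "budded":
        raise ValueError("contour is not labelled as a budded outline")
    pts = contour.points
    n = pts.shape[0]

    centred = pts - pts.mean(axis=0)
    _, _, vt = np.linalg.svd(centred, full_matrices=False)
    proj = centred @ vt[0]

    # 1-D two-means on the projection, initialised at the extremes
    c_lo, c_hi = proj.min(), proj.max()
    labels = np.zeros(n, dtype=bool)
    for _ in range(100):
        new_labels = np.abs(proj - c_hi) < np.abs(proj - c_lo)
        if new_labels.all() or (~new_labels).all():
            break
        c_lo = proj[~new_labels].mean()
        c_hi = proj[new_labels].mean()
        if np.array_equal(new_labels, labels):
            break
        labels = new_labels

    for _ in range(max_iter):
        if labels.sum() < 3 or (~labels).sum() < 3:
            raise NoBudError("lobe split left fewer than 3 points in one lobe")
        c1, r1, _ = _kasa_circle(pts[labels])
        c2, r2, _ = _kasa_circle(pts[~labels])
        d1 = np.abs(np.hypot(*(pts - c1).T) - r1)
        d2 = np.abs(np.hypot(*(pts - c2).T) - r2)
        new_labels = d1 < d2
        if np.array_equal(new_labels, labels):
            break
        labels = new_labels

    # final refit without neck-ambiguous points: near the tangent both
    # circles fit almost equally well and such points carry pure noise
    # leverage into the smaller lobe's radius
    sigma_hat = 1.4826 * float(np.median(np.minimum(d1, d2)))
    confident = np.abs(d1 - d2) > 2.0 * sigma_hat
    if (confident & labels).sum() >= 3 and (confident & ~labels).sum() >= 3:
        c1, r1, _ = _kasa_circle(pts[confident & labels])
        c2, r2, _ = _kasa_circle(pts[confident & ~labels])
        d1 = np.abs(np.hypot(*(pts - c1).T) - r1)
        d2 = np.abs(np.hypot(*(pts - c2).T) - r2)

    rss_two = float(np.sum(np.minimum(d1, d2) ** 2))
    _, _, rss_one = _kasa_circle(pts)
    # 3 params per circle vs 3 for one circle (+1 effective for the split)
    if _bic(rss_one, n, 3) <= _bic(rss_two, n, 7):
        raise NoBudError("single circle fits better: no bud resolved")
    radii = sorted([r1, r2], reverse=True)
    return BuddedShape(R_alpha=float(radii[0]), R_beta=float(radii[1]))
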