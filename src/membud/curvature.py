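"""Neck condition, spontaneous-curvature decomposition and limit-shape lines.

In the spontaneous-curvature / area-difference-elasticity description of a
budded vesicle, a closed membrane neck between a mother sphere (radius
R_alpha) and a bud (radius R_beta) fixes the local spontaneous curvature
``m`` through the neck condition

    2 m = 1/R_alpha + 1/R_beta
          - (2 pi kappa'/kappa) [sqrt(R_alpha² + R_beta²) - R_alpha - R_beta]
                                 / (R_alpha² + R_beta²)

where kappa and kappa' are the local and nonlocal bending rigidities; only
their ratio enters.  The term proportional to kappa'/kappa is (minus twice)
the nonlocal spontaneous curvature m_nlo arising from the preferred leaflet
area difference of the initial shape: since sqrt(x² + y²) < x + y for
positive radii, m_nlo <= 0 always, with equality only at kappa'/kappa = 0.
The effective curvature m_eff = m + m_nlo equals the mean inverse radius
(1/R_alpha + 1/R_beta)/2 regardless of the rigidity ratio.

The locus of such closed-neck ("limit") shapes in the plane of reduced
volume nu and dimensionless curvature m_bar = m * R_ve separates open-neck
buds (below the line) from closed ones (above); vesicle populations whose
buds sit on this line collapse onto it when plotted as (nu, m_bar).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import bisect

from .geometry import BuddedShape, two_sphere_geometry

__all__ = [
    "ElasticParams",
    "CurvatureResult",
    "LimitShapeLine",
    "neck_curvature",
    "limit_shape_line",
    "invert_limit_line",
    "classify_morphology",
    "analyze_budded_population",
    "pathway_trajectory",
    "curvature_as_reciprocal_length",
    "NU_TWO_SPHERE_MIN",
    "DEFAULT_KAPPA_RATIOS",
]

#: minimal reduced volume of a two-sphere shape (equal spheres): 1/sqrt(2)
NU_TWO_SPHERE_MIN = 1.0 / math.sqrt(2.0)

#: rigidity-ratio grid spanning the standard range 0..2
DEFAULT_KAPPA_RATIOS: tuple[float, ...] = (0.0, 0.5, 1.0, 1.5, 2.0)

MorphologyLabel = Literal["below_limit_line", "on_limit_line", "above_limit_line"]
PathwayLabel = Literal["area_increase_only", "curvature_only", "both"]


@dataclass(frozen=True)
class ElasticParams:
    """Elastic constants of the membrane: only the rigidity ratio kappa'/kappa enters."""

    kappa_ratio: float = 0.0

    def __post_init__(self) -> None:
        if not math.isfinite(self.kappa_ratio) or self.kappa_ratio < 0:
            raise ValueError(
                f"rigidity ratio kappa'/kappa must be >= 0, got {self.kappa_ratio}"
            )


@dataclass(frozen=True)
class CurvatureResult:
    """Spontaneous-curvature decomposition of one budded shape.

    Attributes
    ----------
    m : float
        Local spontaneous curvature, µm⁻¹.
    m_nlo : float
        Nonlocal contribution (area-difference elasticity), µm⁻¹; <= 0.
    m_eff : float
        Effective curvature m + m_nlo = (1/R_alpha + 1/R_beta)/2, µm⁻¹.
    m_bar : float
        Dimensionless curvature m * R_ve of the analyzed shape.
    """

    m: float
    m_nlo: float
    m_eff: float
    m_bar: float


@dataclass(frozen=True)
class LimitShapeLine:
    """Sampled line of closed-neck limit shapes for one rigidity ratio.

    Points are stored sorted by increasing nu; each carries the bud ratio
    x = R_beta/R_alpha that generated it.
    """

    kappa_ratio: float
    x: np.ndarray
    nu: np.ndarray
    m_bar: np.ndarray

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"bud_ratio": self.x, "nu": self.nu, "m_bar": self.m_bar}
        ).assign(kappa_ratio=self.kappa_ratio)

    def m_bar_at(self, nu: float | np.ndarray) -> float | np.ndarray:
        """Limit-line value of m_bar at reduced volume nu, by exact inversion."""
        scalar = np.isscalar(nu)
        nus = np.atleast_1d(np.asarray(nu, dtype=float))
        out = np.empty_like(nus)
        params = ElasticParams(self.kappa_ratio)
        for i, v in enumerate(nus):
            x = invert_limit_line(v, params)
            out[i] = neck_curvature(BuddedShape(1.0, x), params).m_bar
        return float(out[0]) if scalar else out


def neck_curvature(shape: BuddedShape, params: ElasticParams) -> CurvatureResult:
    """Solve the neck condition for one two-sphere budded shape.

    Returns the local curvature m, the (non-positive) nonlocal part
    m_nlo, their sum m_eff, and the dimensionless m_bar = m * R_ve with
    R_ve = sqrt(R_alpha² + R_beta²).  Scale covariance: rescaling both
    radii by lambda divides m, m_nlo, m_eff by lambda and leaves m_bar
    (and nu) unchanged.
    """
    ra, rb = shape.R_alpha, shape.R_beta
    r2 = ra * ra + rb * rb
    r_ve = math.sqrt(r2)
    m_eff = 0.5 * (1.0 / ra + 1.0 / rb)
    # neck-closure geometry factor: negative for all positive radii
    m_nlo = math.pi * params.kappa_ratio * (r_ve - ra - rb) / r2
    m = m_eff - m_nlo
    if not (math.isfinite(m) and math.isfinite(m_nlo)):
        raise ValueError(f"degenerate radii {shape}: non-finite curvature")
    return CurvatureResult(m=m, m_nlo=m_nlo, m_eff=m_eff, m_bar=m * r_ve)


def limit_shape_line(
    params: ElasticParams, x_grid: Sequence[float] | np.ndarray
) -> LimitShapeLine:
    """Sample the line of limit shapes over a grid of bud ratios x = R_beta/R_alpha.

    Each x in (0, 1] is mapped to the point (nu(x), m_bar(x)) of the
    closed-neck shape with R_alpha = 1, R_beta = x; both coordinates are
    invariant under the choice of normalisation.  For x -> 0 the line
    approaches (nu, m_bar) -> (1, +inf) (small buds need large curvature);
    at x = 1 it ends at (1/sqrt(2), sqrt(2) (1 + pi kappa'/kappa (2 - sqrt 2)/2)).
    """
    xs = np.asarray(list(x_grid), dtype=float)
    if xs.size < 2:
        raise ValueError("x_grid needs at least 2 points")
    if np.any(xs <= 0) or np.any(xs > 1):
        raise ValueError("bud ratios must lie in (0, 1]")
    nus = np.empty_like(xs)
    mbars = np.empty_like(xs)
    for i, x in enumerate(xs):
        shape = BuddedShape(1.0, float(x))
        nus[i] = two_sphere_geometry(shape).nu
        mbars[i] = neck_curvature(shape, params).m_bar
    order = np.argsort(nus)
    return LimitShapeLine(
        kappa_ratio=params.kappa_ratio, x=xs[order], nu=nus[order], m_bar=mbars[order]
    )


def _nu_of_bud_ratio(x: float) -> float:
    # nu of the two-sphere shape (1, x): (1 + x³) / (1 + x²)^(3/2)
    return (1.0 + x**3) / (1.0 + x * x) ** 1.5


def invert_limit_line(nu: float, params: ElasticParams) -> float:
    """Bud ratio x with nu(x) = nu on the two-sphere limit line.

    nu(x) decreases strictly from 1 (x -> 0) to 1/sqrt(2) (x = 1), so the
    root is unique; found by bisection on (1e-6, 1] to 1e-12 in x.  The
    rigidity ratio does not enter nu(x); it is accepted for interface
    symmetry with the forward map.
    """
    if not (NU_TWO_SPHERE_MIN < nu < 1.0):
        raise ValueError(
            f"nu={nu} outside the two-sphere range (1/sqrt(2), 1) ~ (0.7071, 1)"
        )
    lo, hi = 1e-6, 1.0
    if _nu_of_bud_ratio(lo) < nu:
        # bud smaller than the bracket floor: nu extremely close to 1
        return lo
    x = bisect(lambda t: _nu_of_bud_ratio(t) - nu, lo, hi, xtol=1e-12)
    return float(x)


def classify_morphology(
    nu: float,
    m_bar: float,
    params: ElasticParams,
    rtol: float = 1e-6,
) -> MorphologyLabel:
    """Place a point of the (nu, m_bar) morphology diagram relative to the limit line.

    Points below the line are buds with open necks; on the line the neck
    has just closed; above it the neck is closed.  ``rtol`` is the
    relative tolerance for calling a point "on" the line.
    """
    if not math.isfinite(m_bar):
        raise ValueError("m_bar must be finite")
    x = invert_limit_line(nu, params)
    line_val = neck_curvature(BuddedShape(1.0, x), params).m_bar
    if abs(m_bar - line_val) <= rtol * abs(line_val):
        return "on_limit_line"
    return "above_limit_line" if m_bar > line_val else "below_limit_line"


@dataclass(frozen=True)
class PopulationSummary:
    """Per-rigidity-ratio summary of a budded-vesicle population."""

    kappa_ratio: float
    n: int
    m_mean: float
    m_sd: float
    m_sem: float
    inv_length_um: float
    inv_length_sd_um: float

    def formatted(self) -> str:
        return (
            f"kappa'/kappa = {self.kappa_ratio:g}: m = {self.m_mean:.4f} "
            f"± {self.m_sd:.4f} µm⁻¹  ≅  1/({self.inv_length_um:.1f} "
            f"± {self.inv_length_sd_um:.1f} µm)   [n = {self.n}, SEM {self.m_sem:.4f}]"
        )


def curvature_as_reciprocal_length(m: float, m_sd: float = 0.0) -> tuple[float, float]:
    """Express a curvature m (µm⁻¹) as 1/(L µm) with first-order error propagation.

    The uncertainty on L = 1/m is sd(L) = sd(m)/m², mirroring the
    convention of quoting "m = 1/(2.8 ± 1.0 µm)" — the ± applies to the
    length, not the curvature.
    """
    if m <= 0:
        raise ValueError(f"curvature must be positive to invert, got {m}")
    return 1.0 / m, m_sd / (m * m)


def analyze_budded_population(
    shapes: Iterable[BuddedShape] | pd.DataFrame,
    kappa_ratios: Sequence[float] = DEFAULT_KAPPA_RATIOS,
) -> tuple[pd.DataFrame, list[PopulationSummary]]:
    """Per-vesicle curvature decomposition of a budded-shape population.

    Parameters
    ----------
    shapes : iterable of BuddedShape or DataFrame
        A DataFrame must carry columns ``R_alpha_um`` and ``R_beta_um``
        (optionally ``vesicle_id``).
    kappa_ratios : sequence of float
        Rigidity ratios kappa'/kappa to evaluate; default {0, 0.5, 1, 1.5, 2}.

    Returns
    -------
    records : DataFrame
        One row per vesicle per rigidity ratio with columns vesicle_id,
        kappa_ratio, R_alpha_um, R_beta_um, nu, m_bar, m, m_nlo, m_eff.
    summaries : list of PopulationSummary
        Mean, SD (n-1) and SEM of m per rigidity ratio, plus the
        reciprocal-length rendering 1/(L ± sd µm).

    Invalid rows raise with the offending vesicle identified.
    """
    if isinstance(shapes, pd.DataFrame):
        ids = (
            shapes["vesicle_id"].tolist()
            if "vesicle_id" in shapes.columns
            else list(range(len(shapes)))
        )
        shape_list = []
        for vid, (_, row) in zip(ids, shapes.iterrows()):
            try:
                shape_list.append(
                    BuddedShape(float(row["R_alpha_um"]), float(row["R_beta_um"]))
                )
            except (ValueError, KeyError) as exc:
                raise ValueError(f"vesicle {vid!r}: {exc}") from exc
    else:
        shape_list = list(shapes)
        ids = list(range(len(shape_list)))
    if not shape_list:
        raise ValueError("empty budded-shape population")

    rows = []
    for ratio in kappa_ratios:
        params = ElasticParams(ratio)
        for vid, shape in zip(ids, shape_list):
            geom = two_sphere_geometry(shape)
            res = neck_curvature(shape, params)
            rows.append(
                dict(
                    vesicle_id=vid,
                    kappa_ratio=ratio,
                    R_alpha_um=shape.R_alpha,
                    R_beta_um=shape.R_beta,
                    nu=geom.nu,
                    m_bar=res.m_bar,
                    m=res.m,
                    m_nlo=res.m_nlo,
                    m_eff=res.m_eff,
                )
            )
    records = pd.DataFrame(rows)

    summaries = []
    for ratio in kappa_ratios:
        ms = records.loc[records["kappa_ratio"] == ratio, "m"].to_numpy()
        n = ms.size
        mean = float(np.mean(ms))
        sd = float(np.std(ms, ddof=1)) if n > 1 else 0.0
        sem = sd / math.sqrt(n) if n > 1 else 0.0
        inv_len, inv_len_sd = curvature_as_reciprocal_length(mean, sd)
        summaries.append(
            PopulationSummary(
                kappa_ratio=ratio,
                n=n,
                m_mean=mean,
                m_sd=sd,
                m_sem=sem,
                inv_length_um=inv_len,
                inv_length_sd_um=inv_len_sd,
            )
        )
    return records, summaries


def pathway_trajectory(
    points: Sequence[tuple[float, float]], rel_threshold: float = 0.01
) -> PathwayLabel:
    """Classify a (nu, m_bar) trajectory by which coordinate moves.

    A photoactivated vesicle can descend the morphology diagram by area
    increase alone (nu drops, m_bar fixed), by curvature generation alone
    (m_bar grows, nu fixed), or by both.  A coordinate counts as moving
    when its total relative change from the first point exceeds
    ``rel_threshold``.
    """
    pts = list(points)
    if len(pts) < 2:
        raise ValueError("a trajectory needs at least 2 time-ordered points")
    nu0, mbar0 = pts[0]
    nu1, mbar1 = pts[-1]
    nu_moves = abs(nu1 - nu0) / abs(nu0) > rel_threshold
    mbar_moves = abs(mbar1 - mbar0) / abs(mbar0) > rel_threshold
    if nu_moves and mbar_moves:
        return "both"
    if nu_moves:
        return "area_increase_only"
    if mbar_moves:
        return "curvature_only"
    raise ValueError(
        "trajectory is stationary within the threshold: neither nu nor m_bar moved"
    )
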