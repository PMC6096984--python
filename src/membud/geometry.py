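"""Closed-form geometry of prolate spheroids and two-sphere budded vesicles.

Conventions, fixed package-wide: lengths in µm, areas in µm², volumes in
µm³, curvatures in µm⁻¹.  A deformed vesicle in an AC field is a prolate
spheroid with long semiaxis ``a`` parallel to the field and short semiaxis
``b``; a budded vesicle is a mother sphere of radius ``R_alpha`` joined to
a bud of radius ``R_beta`` by a closed neck of zero measure.

The two dimensionless shape descriptors used throughout are the reduced
volume

    nu = 6 sqrt(pi) V / A^(3/2)

(the ratio of the enclosed volume to the volume of the sphere with the
same membrane area; nu = 1 for a sphere, nu < 1 means excess area) and the
vesicle size R_ve = sqrt(A / 4 pi), the radius of that equal-area sphere.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.optimize import brentq

__all__ = [
    "SpheroidShape",
    "VesicleGeometry",
    "BuddedShape",
    "spheroid_area",
    "spheroid_volume",
    "reduced_volume",
    "vesicle_size",
    "two_sphere_geometry",
    "spheroid_from_area_volume",
]

#: values of nu in (1, 1 + NU_TOLERANCE] are clipped to 1; beyond is an error
NU_TOLERANCE = 1e-9

#: below this relative elongation the sphere-limit series branch is used
_SPHERE_LIMIT_EPS = 1e-8


@dataclass(frozen=True)
class SpheroidShape:
    """Prolate spheroid with semiaxes ``a >= b > 0`` (µm).

    ``a`` is the semiaxis along the field direction.  Inputs with
    ``a < b`` are rejected rather than swapped, to surface axis mix-ups
    in the input tables.
    """

    a: float
    b: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.a) and math.isfinite(self.b)):
            raise ValueError("spheroid semiaxes must be finite")
        if self.b <= 0:
            raise ValueError(f"semiaxes must be positive, got b={self.b}")
        if self.a < self.b:
            raise ValueError(
                f"long semiaxis a={self.a} < short semiaxis b={self.b}; "
                "prolate convention requires a >= b (axes not swapped silently)"
            )

    @property
    def aspect_ratio(self) -> float:
        """Degree of deformation a/b (>= 1)."""
        return self.a / self.b


@dataclass(frozen=True)
class BuddedShape:
    """Two-sphere budded vesicle: mother radius ``R_alpha`` >= bud ``R_beta`` > 0 (µm)."""

    R_alpha: float
    R_beta: float

    def __post_init__(self) -> None:
        if not (self.R_beta > 0 and math.isfinite(self.R_alpha)):
            raise ValueError(f"radii must be positive and finite, got {self}")
        if self.R_alpha < self.R_beta:
            raise ValueError(
                f"mother radius R_alpha={self.R_alpha} < bud radius "
                f"R_beta={self.R_beta}; the larger sphere is the mother vesicle"
            )

    @property
    def bud_ratio(self) -> float:
        """Bud-to-mother radius ratio R_beta/R_alpha in (0, 1]."""
        return self.R_beta / self.R_alpha


@dataclass(frozen=True)
class VesicleGeometry:
    """Membrane area A (µm²), enclosed volume V (µm³), reduced volume nu, size R_ve (µm)."""

    A: float
    V: float
    nu: float
    R_ve: float

    @classmethod
    def from_area_volume(cls, A: float, V: float) -> "VesicleGeometry":
        return cls(A=A, V=V, nu=reduced_volume(A, V), R_ve=vesicle_size(A))


def _asin_e_over_e(e2: float) -> float:
    # asin(e)/e with the e -> 0 limit handled by its Maclaurin series;
    # e2 = e^2 = 1 - (b/a)^2 is the squared eccentricity.
    if e2 < _SPHERE_LIMIT_EPS:
        return 1.0 + e2 / 6.0 + 3.0 * e2 * e2 / 40.0
    e = math.sqrt(e2)
    return math.asin(e) / e


def spheroid_area(shape: SpheroidShape) -> float:
    """Surface area of a prolate spheroid (µm²).

    Closed form ``A = 2 pi b^2 + 2 pi a b asin(e)/e`` with eccentricity
    ``e = sqrt(1 - b^2/a^2)``; continuous through the sphere limit a -> b,
    where it reduces to 4 pi R².
    """
    a, b = shape.a, shape.b
    e2 = 1.0 - (b / a) ** 2
    return 2.0 * math.pi * b * b + 2.0 * math.pi * a * b * _asin_e_over_e(e2)


def spheroid_volume(shape: SpheroidShape) -> float:
    """Volume of a prolate spheroid, V = (4/3) pi a b² (µm³)."""
    return 4.0 / 3.0 * math.pi * shape.a * shape.b * shape.b


def reduced_volume(A: float, V: float) -> float:
    """Reduced volume nu = 6 sqrt(pi) V / A^(3/2), clipped to <= 1 within tolerance.

    Raises
    ------
    ValueError
        If A or V is non-positive, or nu exceeds 1 by more than 1e-9
        (geometrically inadmissible area/volume pair).
    """
    if A <= 0 or V <= 0:
        raise ValueError(f"area and volume must be positive, got A={A}, V={V}")
    nu = 6.0 * math.sqrt(math.pi) * V / A**1.5
    if nu > 1.0 + NU_TOLERANCE:
        raise ValueError(
            f"reduced volume nu={nu} > 1: no shape encloses volume {V} "
            f"with area {A} (the sphere maximises volume at fixed area)"
        )
    if nu > 1.0 - 1e-12:
        # indistinguishable from a sphere at double precision: nu = 1 iff sphere
        return 1.0
    return nu


def vesicle_size(A: float) -> float:
    """Radius R_ve = sqrt(A / 4 pi) of the sphere with membrane area A (µm)."""
    if A <= 0:
        raise ValueError(f"area must be positive, got {A}")
    return math.sqrt(A / (4.0 * math.pi))


def two_sphere_geometry(shape: BuddedShape) -> VesicleGeometry:
    """Area, volume, nu and R_ve of a two-sphere budded shape.

    The closed neck has zero measure, so A = 4 pi (R_alpha² + R_beta²)
    and V = (4 pi / 3)(R_alpha³ + R_beta³).  nu is scale-invariant and
    ranges over (1/sqrt(2), 1): equal spheres give nu = 1/sqrt(2), a
    vanishing bud gives nu -> 1.
    """
    ra, rb = shape.R_alpha, shape.R_beta
    A = 4.0 * math.pi * (ra * ra + rb * rb)
    V = 4.0 * math.pi / 3.0 * (ra**3 + rb**3)
    return VesicleGeometry.from_area_volume(A, V)


def spheroid_from_area_volume(A: float, V: float) -> SpheroidShape:
    """The unique prolate spheroid with given area and volume.

    Inverts (a, b) -> (A, V): used by the synthetic electrodeformation
    generator to impose an area history at fixed vesicle volume.  Solves
    for ``a`` by bracketed root finding on the area residual with
    ``b(a) = sqrt(3 V / 4 pi a)``; round-trips with
    :func:`spheroid_area` / :func:`spheroid_volume` to 1e-9 relative.

    Raises
    ------
    ValueError
        If the pair is inadmissible (nu > 1, i.e. A below the sphere area
        for volume V).
    """
    nu = reduced_volume(A, V)  # validates admissibility
    r_sphere = (3.0 * V / (4.0 * math.pi)) ** (1.0 / 3.0)
    if nu >= 1.0:
        return SpheroidShape(a=r_sphere, b=r_sphere)

    def area_residual(a: float) -> float:
        b = math.sqrt(3.0 * V / (4.0 * math.pi * a))
        return spheroid_area(SpheroidShape(a=a, b=min(a, b))) - A

    # area grows monotonically with elongation at fixed volume
    a_lo = r_sphere
    a_hi = r_sphere * 2.0
    while area_residual(a_hi) < 0.0:
        a_hi *= 2.0
        if a_hi > 1e6 * r_sphere:  # pragma: no cover - unreachable for nu <= 1
            raise ValueError(f"no prolate spheroid with A={A}, V={V}")
    a = brentq(area_residual, a_lo, a_hi, xtol=1e-15, rtol=8.9e-16)
    b = math.sqrt(3.0 * V / (4.0 * math.pi * a))
    return SpheroidShape(a=a, b=min(a, b))


def spheroid_area_quadrature(a: float, b: float) -> float:
    """Surface of revolution integral for a prolate spheroid, by adaptive quadrature.

    Independent numerical oracle for :func:`spheroid_area`; not used in
    the analysis path.  Revolves z(x) about the long axis x in [-a, a]:
    A = 2 pi ∫ z sqrt(1 + z'(x)²) dx with z(x) = b sqrt(1 - x²/a²).
    """
    from scipy.integrate import quad

    # A = 2 pi ∫ sqrt(z² + (z z')²) dx, and z z' = -b² x / a² stays finite
    # at the poles, so the integrand is sqrt(b²(1 - u²) + (b² u / a)²), u = x/a.
    def f(x: float) -> float:
        u = x / a
        return math.sqrt(b * b * (1.0 - u * u) + (b * b * u / a) ** 2)

    val, _ = quad(f, -a, a, epsabs=0.0, epsrel=1e-12, limit=200)
    return 2.0 * math.pi * val
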