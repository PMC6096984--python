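# Methods

## Model

A vesicle's equilibrium shape is governed by curvature elasticity. Two
dimensionless controls describe it: the reduced volume
ν = 6√π·V·A^(−3/2) ∈ (0, 1] (ν = 1 for a sphere; ν < 1 means excess
membrane area) and the dimensionless spontaneous curvature m̄ = m·R_ve,
with R_ve = √(A/4π) the radius of the equal-area sphere and m the local
spontaneous curvature in µm⁻¹. Area-difference elasticity adds a nonlocal
contribution m_nlo, proportional to the rigidity ratio κ′/κ, reflecting
the energetic preference for the leaflet-area difference of the initial
shape when molecules cannot flip-flop; the effective curvature is
m_eff = m + m_nlo.

Budded shapes are idealised as two spheres (mother R_α ≥ bud R_β) joined
by a closed neck of zero measure, so A = 4π(R_α² + R_β²) and
V = (4π/3)(R_α³ + R_β³). Closed-neck ("limit") shapes satisfy the neck
condition

    2m = 1/R_α + 1/R_β − (2π κ′/κ) [√(R_α² + R_β²) − R_α − R_β] / (R_α² + R_β²)

The term proportional to κ′/κ equals −2·m_nlo; since
√(R_α² + R_β²) < R_α + R_β for positive radii, m_nlo ≤ 0 always, with
equality only at κ′/κ = 0, and m_eff reduces to the mean inverse radius
(1/R_α + 1/R_β)/2 independent of the rigidity ratio. Two consequences are
used as structural guards throughout the tests: m is affine-increasing in
κ′/κ at fixed shape, and m scales as 1/length under uniform rescaling
while ν and m̄ are scale-free.

The locus of limit shapes in the (ν, m̄) plane is parametrised by the bud
ratio x = R_β/R_α ∈ (0, 1]: ν(x) = (1 + x³)/(1 + x²)^(3/2) decreases
strictly from 1 to 1/√2, so the line is invertible by bisection; at x = 1
it ends at (1/√2, √2·(1 + π(κ′/κ)(2 − √2)/2)), and for x → 0 it diverges
(small buds need large curvature). `classify_morphology` places a
measured (ν, m̄) point below / on / above the line, i.e. open vs closed
neck. What is *not* solved here: the axisymmetric shape equations away
from the two-sphere limit — only the limit shapes themselves are
computed, which is all the per-vesicle analysis needs.

The main-text rendering of the neck condition in the source literature is
typographically ambiguous about the span of the radical; the grouping
above is adopted because it is the only reading that makes m_nlo ≤ 0 and
orders the inferred m increasingly with κ′/κ, both of which are
independently stated properties of the analysis. The nonlocal term is
isolated in one expression in `neck_curvature` and guarded by property
tests on both facts.

## Electrodeformation analysis

In an AC field a quasi-spherical vesicle with interior/exterior
conductivity contrast elongates into a prolate spheroid with the long
semiaxis a along the field, pulling the area stored in thermal
fluctuations flat; the membrane area then follows from the exact
prolate-spheroid closed form A = 2πb² + 2πab·asin(e)/e,
e² = 1 − (b/a)². The sphere limit uses the Maclaurin series of asin(e)/e
below e² = 1e-8 to avoid the vanishing-eccentricity division. The inverse
map (A, V) → (a, b), needed by the series generator, is solved by Brent
root finding on the monotone area–elongation relation at fixed volume.

The single-vesicle area increase is ΔĀ = (A_UV − A)/A with the baseline A
taken at maximal pre-UV deformation (field on, fluctuations smoothed) and
A_UV at maximal deformation after UV onset. Two estimators are provided:

* `estimator="max"` (default): the literal maximal-aspect-ratio frame in
  each window. Exact on noise-free data; on noisy data it inherits the
  largest noise excursion of the window (the expected maximum of ~10²
  per-frame area-noise draws), a positive bias of order 1–2% at 0.5%
  semiaxis noise.
* `estimator="plateau"` (recommended for noisy series): exploits the
  physical constraint that the vesicle volume is constant throughout the
  experiment (optical contrast and pre/post imaging both confirm it).
  Each frame is projected onto the constant-volume manifold — the aspect
  ratio a/b is retained, the semiaxes are rebuilt from the median volume
  of the series — which suppresses aspect noise quadratically near the
  quasi-spherical baseline. The baseline averages the projected areas
  over the pre-UV frames within 0.5% of the maximal aspect ratio; the UV
  endpoint evaluates a least-squares saturating exponential fitted to the
  projected post-UV areas at the last frame. At 0.5% frame noise this
  recovers a configured 4.6% area increase to ±0.05% (absolute, across
  seeds), versus ±1–2% for the max estimator.

ν of the vesicle before irradiation is computed from the baseline frame's
(A, V). Area extraction is meaningful only while the vesicle is still
elliptical; after budding starts the small buds are unresolved and the
ellipse underestimates the area, so cohort protocols read ΔĀ shortly
before budding, making it a lower bound on the total photoinduced area.

Contour measurement: `fit_ellipse` wraps the direct least-squares conic
fit (scikit-image's `EllipseModel`), normalised to a ≥ b with the long
axis angle in (−π/2, π/2] from the field axis. `fit_budded_contour` fits
two circles: points are split by a 1-D two-means cut along the principal
axis, each lobe gets an algebraic (Kåsa) circle fit, assignments are
iterated to stability, and a final refit drops neck-ambiguous points
(both circles fitting within 2× the robust noise scale) which otherwise
lever pure noise into the smaller lobe's radius. A single-circle model is
compared by BIC on the radial residuals; if it wins, `NoBudError` signals
that no bud is resolved.

## SEC partitioning

Peak areas on the absorbance trace are integrated by the trapezoid rule
with window endpoints interpolated onto the trace (so the area is
continuous in the window bounds), optionally minus a linear baseline
connecting the endpoints. Calibration assumes absorbance peak area
proportional to moles with the same extinction for free and
membrane-inserted switch — the minimal assumption when a single detection
wavelength is used — so c_inc = c_total · (incorporated area)/(total
area), the incorporated fraction is 100·c_inc/c_total and the
lipid:switch ratio is c_lipid/c_inc. The two free-switch peaks are close
(≈1.1 mL apart at σ ≈ 0.25–0.3 mL); no window can split them exactly, but
only their *sum* enters the arithmetic, so the split point between them
is immaterial. The boundary between the incorporated peak (5.4 mL) and
the first free peak (7.0 mL) is placed at 6.0 mL, ≥4σ from both, keeping
cross-talk below 0.2% of the incorporated area.

## Synthetic data

Generators emulate the study conditions; all randomness flows through one
seeded `numpy.random.Generator` per call and every generator returns its
ground truth, enabling exact round-trip tests at zero noise and
statistical ones at realistic noise.

* **Budded populations** (`gen_budded_population`): mother radii are
  log-normal (median 7.5 µm, log-sd 0.25 — GUV-scale vesicles); the bud
  radius solves the neck condition for the configured m_true (default
  0.4 µm⁻¹ = 1/(2.5 µm), the scale inferred for photoswitch-doped GUVs)
  by bisection; 2% multiplicative Gaussian radius noise models optical
  radius measurement. Mothers too small to support a bud at m_true
  (no root with R_β ≤ R_α) are rejected and redrawn; exhaustion raises
  rather than clamps, since clamping would bias recovery tests.
* **Deformation series** (`gen_deformation_series`): aspect ratio rises
  as 1 + (r_max − 1)(1 − e^(−t/τ_field)) with r_max = 1.05,
  τ_field = 1.2 s (maximal deformation within 5–7 s), at fixed volume
  V = (4/3)πR₀³, R₀ = 15 µm. From UV onset (t_uv = 7.2 s) the area grows
  from the last pre-UV area by a saturating exponential (τ_uv = 10 s)
  normalised to reach the configured ΔA_max (default 0.046) exactly at
  the final frame (t_end = 40 s, dt = 0.2 s) — ΔA_max is defined as the
  relative increase over the recorded window, matching how it is
  measured. Volume is conserved to machine precision before noise;
  multiplicative frame noise on a and b is applied last.
* **Contours** (`gen_contour`): ellipse sections or externally tangent
  two-circle sections sampled uniformly in arc parameter with isotropic
  Gaussian point noise.
* **Elution traces** (`gen_elution_trace`): sums of Gaussians at 5.4,
  7.0 and 8.1 mL on a 0.01 mL grid, the incorporated peak carrying 0.74%
  of the total analytic area by default.

What the generators do **not** emulate — and hence what passing tests do
not show about real data: thermal fluctuation spectra and their residual
contribution to apparent area; phase-contrast halo and segmentation bias
in real micrographs; photoisomerisation kinetics (the exponential time
constants are phenomenological); chromatographic tailing and baseline
drift; any difference in extinction between free and inserted switch.
Recovery tests demonstrate the *analysis* is correct and unbiased under
the stated noise models, not that those noise models are complete.

## Numerical choices

* Units package-wide: µm, µm², µm³, µm⁻¹; concentrations molar; percent
  only at reporting boundaries.
* ν is clipped to 1 within +1e-9 (beyond raises: the sphere bounds volume
  at fixed area) and snapped to exactly 1 within 1e-12, so "ν = 1 iff
  sphere" is robust at double precision.
* Inputs with a < b or R_β > R_α are rejected, not swapped, to surface
  data-entry errors.
* Limit-line inversion uses bisection (bracket-verified, xtol 1e-12);
  derivative-free root finding is preferred throughout the curvature
  module for robustness at desk scale.
* Rigidity-ratio grid default {0, 0.5, 1, 1.5, 2}, the standard range.
* Cohort summaries use the n−1 standard deviation; SEM = sd/√n. Mean
  curvatures are also rendered as reciprocal lengths 1/(L µm) with the
  spread propagated to the length by first-order error propagation
  (sd(L) = sd(m)/m²), matching how such curvatures are conventionally
  quoted.
* Tie-breaks: maximal-deformation frame ties resolve to the earliest
  frame; the optional rolling-median filter (window 5) is off by default
  so results are a deterministic function of the raw frames.

## Problem sizes

Tests and the acceptance script run populations of n = 100 vesicles,
single deformation series of ~200 frames, 30-series cohorts, contours of
100–200 points, and elution traces of ~600 samples — the scale of the
corresponding bench experiments; the whole suite completes in seconds.

## Known limitations

* The two-sphere idealisation ignores the finite neck; radii measured
  from micrographs of nearly closed necks are treated as exact sphere
  radii.
* κ and κ′ are never estimated — the rigidity ratio is an input scanned
  over a grid, and consistency across vesicles is inspected, not fitted.
* The per-vesicle m̂ distribution under multiplicative radius noise is
  right-skewed (reciprocal of a noisy radius), so ±k·SEM intervals have
  slightly less than nominal coverage at n = 100.
* Oblate and non-axisymmetric field deformations are out of scope (the
  conductivity conditions assumed give prolates only).
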