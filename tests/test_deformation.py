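"""Electrodeformation analysis: series handling, area extraction, contour fits."""

import math

import numpy as np
import pandas as pd
import pytest

from membud.deformation import (
    Contour,
    DeformationFrame,
    DeformationSeries,
    NoBudError,
    analyze_series,
    area_volume_series,
    fit_budded_contour,
    fit_ellipse,
    max_deformation,
    relative_area_increase,
    summarize_population,
)
from membud.geometry import BuddedShape, SpheroidShape, spheroid_area
from membud.synthetic import ContourConfig, DeformationConfig, gen_contour, gen_deformation_series


def sphere_series(R=10.0, n=10, uv_from=5):
    frames = tuple(
        DeformationFrame(t=float(i), a=R, b=R, uv_on=i >= uv_from) for i in range(n)
    )
    return DeformationSeries(frames=frames, uv_onset_time=float(uv_from))


class TestSeriesValidation:
    def test_unsorted_times_rejected(self):
        frames = (
            DeformationFrame(0.0, 1, 1, False),
            DeformationFrame(0.0, 1, 1, False),
        )
        with pytest.raises(ValueError, match="strictly increasing"):
            DeformationSeries(frames=frames)

    def test_uv_flag_must_match_onset(self):
        frames = (
            DeformationFrame(0.0, 1, 1, False),
            DeformationFrame(1.0, 1, 1, False),  # should be True past onset
        )
        with pytest.raises(ValueError, match="uv_on"):
            DeformationSeries(frames=frames, uv_onset_time=0.5)

    def test_dataframe_round_trip(self):
        s = sphere_series()
        df = s.to_dataframe()
        back = DeformationSeries.from_dataframe(df)
        assert back.frames == s.frames
        assert back.uv_onset_time == 5.0


class TestAreaVolumeSeries:
    def test_sphere_frames(self):
        df = area_volume_series(sphere_series(R=2.0))
        assert np.allclose(df["A_um2"], 16 * math.pi)
        assert np.allclose(df["aspect_ratio"], 1.0)

    def test_single_prolate_frame_matches_oracle(self):
        frames = (DeformationFrame(0.0, 2, 1, False), DeformationFrame(1.0, 2, 1, False))
        df = area_volume_series(DeformationSeries(frames=frames))
        assert df["A_um2"].iloc[0] == pytest.approx(21.478435, rel=1e-6)


class TestMaxDeformation:
    def test_monotone_series_picks_last_pre_uv(self, noisefree_series):
        series, _ = noisefree_series
        pre = max_deformation(series, "pre_uv")
        assert pre.t == max(f.t for f in series.frames if not f.uv_on)

    def test_flat_series_tie_breaks_earliest(self):
        s = sphere_series()
        assert max_deformation(s, "pre_uv").t == 0.0
        assert max_deformation(s, "post_uv").t == 5.0

    def test_plateau_matches_configured_r_max(self):
        cfg = DeformationConfig(r_max=1.08)
        series, _ = gen_deformation_series(cfg, seed=2)
        pre = max_deformation(series, "pre_uv")
        assert pre.aspect_ratio == pytest.approx(1.08, rel=1e-3)

    def test_empty_window_rejected(self):
        frames = (DeformationFrame(0.0, 1, 1, False), DeformationFrame(1.0, 1, 1, False))
        with pytest.raises(ValueError, match="post_uv"):
            max_deformation(DeformationSeries(frames=frames), "post_uv")


class TestRelativeAreaIncrease:
    @pytest.mark.parametrize(
        "A0,A1,expected",
        [(100.0, 100.0, 0.0), (100.0, 104.6, 0.046), (100.0, 105.1, 0.051), (100.0, 98.0, -0.02)],
    )
    def test_values(self, A0, A1, expected):
        assert relative_area_increase(A0, A1) == pytest.approx(expected, abs=1e-12)

    def test_rejects_nonpositive_baseline(self):
        with pytest.raises(ValueError):
            relative_area_increase(0.0, 1.0)

    def test_increments_compose_multiplicatively(self):
        A0 = 100.0
        d1, d2 = 0.02, 0.03
        A1 = A0 * (1 + d1)
        A2 = A1 * (1 + d2)
        total = relative_area_increase(A0, A2)
        assert total == pytest.approx((1 + d1) * (1 + d2) - 1, rel=1e-12)


class TestAnalyzeSeries:
    def test_noise_free_round_trip_exact(self, noisefree_series):
        series, truth = noisefree_series
        res = analyze_series(series)
        assert res.delta_A_rel == pytest.approx(truth["delta_A_max"], abs=1e-9)

    def test_noisy_recovery_with_plateau_estimator(self, noisy_series):
        series, truth = noisy_series
        res = analyze_series(series, estimator="plateau")
        assert res.delta_A_rel == pytest.approx(truth["delta_A_max"], abs=0.002)

    def test_nu_baseline_quasi_spherical(self, noisefree_series):
        series, _ = noisefree_series
        res = analyze_series(series)
        assert 0.95 < res.nu_baseline < 1.0

    def test_sphere_only_series(self):
        res = analyze_series(sphere_series())
        assert res.delta_A_rel == 0.0
        assert res.nu_baseline == 1.0

    def test_series_without_uv_rejected(self):
        frames = tuple(DeformationFrame(float(i), 1, 1, False) for i in range(5))
        with pytest.raises(ValueError):
            analyze_series(DeformationSeries(frames=frames))

    def test_volume_conserved_in_generated_series(self, noisefree_series):
        series, _ = noisefree_series
        df = area_volume_series(series)
        V = df["V_um3"].to_numpy()
        assert np.max(np.abs(V - V[0])) / V[0] < 1e-9


class TestSummarizePopulation:
    def test_closed_form(self):
        s = summarize_population([1.0, 2.0, 3.0])
        assert s.mean == 2.0
        assert s.sem == pytest.approx(1.0 / math.sqrt(3), rel=1e-12)

    def test_constant_sample(self):
        assert summarize_population([0.5] * 10).sem == 0.0

    def test_cohort_scale_sampling(self):
        """30 draws at the measured cohort scale: mean lands within 3 SEM of truth."""
        rng = np.random.default_rng(12)
        draws = rng.normal(0.043, 0.0022, size=30)
        s = summarize_population(draws)
        assert abs(s.mean - 0.043) < 3 * s.sem

    def test_needs_two(self):
        with pytest.raises(ValueError):
            summarize_population([1.0])


class TestFitEllipse:
    def test_exact_recovery(self):
        c = gen_contour(SpheroidShape(3, 2), ContourConfig(100, 0.0), seed=0)
        fit = fit_ellipse(c)
        assert fit.a == pytest.approx(3.0, abs=1e-9)
        assert fit.b == pytest.approx(2.0, abs=1e-9)
        assert abs(fit.orientation) < 1e-9

    def test_noisy_recovery_within_one_percent(self):
        c = gen_contour(SpheroidShape(3, 2), ContourConfig(200, 0.02), seed=1)
        fit = fit_ellipse(c)
        assert fit.a == pytest.approx(3.0, rel=0.01)
        assert fit.b == pytest.approx(2.0, rel=0.01)

    def test_too_few_points(self):
        pts = np.column_stack([np.cos(np.linspace(0, 5, 5)), np.sin(np.linspace(0, 5, 5))])
        with pytest.raises(ValueError):
            Contour(points=pts, shape_label="ellipse")

    def test_collinear_rejected(self):
        pts = np.column_stack([np.linspace(0, 1, 10), np.linspace(0, 2, 10)])
        with pytest.raises(ValueError, match="collinear"):
            Contour(points=pts, shape_label="ellipse")


class TestFitBuddedContour:
    def test_exact_two_circle_recovery(self):
        c = gen_contour(BuddedShape(5, 1), ContourConfig(120, 0.0), seed=0)
        shape = fit_budded_contour(c)
        assert shape.R_alpha == pytest.approx(5.0, abs=1e-6)
        assert shape.R_beta == pytest.approx(1.0, abs=1e-6)

    def test_noisy_recovery_within_two_percent(self):
        c = gen_contour(BuddedShape(5, 1), ContourConfig(200, 0.05), seed=0)
        shape = fit_budded_contour(c)
        assert shape.R_alpha == pytest.approx(5.0, rel=0.02)
        assert shape.R_beta == pytest.approx(1.0, rel=0.02)

    def test_single_circle_signals_no_bud(self):
        t = np.linspace(0, 2 * math.pi, 80, endpoint=False)
        pts = np.column_stack([5 * np.cos(t), 5 * np.sin(t)])
        with pytest.raises(NoBudError):
            fit_budded_contour(Contour(points=pts, shape_label="budded"))
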