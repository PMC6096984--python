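"""Neck condition, curvature decomposition, limit-shape lines and classification."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from membud.curvature import (
    DEFAULT_KAPPA_RATIOS,
    NU_TWO_SPHERE_MIN,
    ElasticParams,
    analyze_budded_population,
    classify_morphology,
    curvature_as_reciprocal_length,
    invert_limit_line,
    limit_shape_line,
    neck_curvature,
    pathway_trajectory,
)
from membud.geometry import BuddedShape


budded_shapes = st.builds(
    lambda ra, frac: BuddedShape(ra, frac * ra),
    ra=st.floats(min_value=0.5, max_value=50.0),
    frac=st.floats(min_value=1e-3, max_value=1.0),
)


class TestNeckCurvature:
    def test_zero_ratio_equal_spheres(self):
        res = neck_curvature(BuddedShape(1, 1), ElasticParams(0.0))
        assert res.m == pytest.approx(1.0, abs=1e-12)
        assert res.m_nlo == 0.0
        assert res.m_bar == pytest.approx(math.sqrt(2), rel=1e-12)

    def test_zero_ratio_is_mean_inverse_radius(self):
        res = neck_curvature(BuddedShape(10, 1.5), ElasticParams(0.0))
        assert res.m == pytest.approx((0.1 + 1 / 1.5) / 2, rel=1e-12)
        assert res.m == pytest.approx(0.383333, abs=1e-6)
        # the micron scale of experimentally observed buds: m ~ 1/(2.6 µm)
        assert 1 / res.m == pytest.approx(2.61, abs=0.01)

    def test_unit_ratio_equal_spheres(self):
        res = neck_curvature(BuddedShape(1, 1), ElasticParams(1.0))
        assert res.m == pytest.approx(1 + math.pi * (2 - math.sqrt(2)) / 2, rel=1e-12)

    def test_rejects_negative_ratio(self):
        with pytest.raises(ValueError):
            ElasticParams(-0.1)

    @settings(deadline=None, derandomize=True, max_examples=100)
    @given(shape=budded_shapes, ratio=st.floats(min_value=0.0, max_value=2.0))
    def test_decomposition_identity_and_sign(self, shape, ratio):
        """m_eff = m + m_nlo to 1e-12; m_nlo <= 0, zero iff the ratio is zero."""
        res = neck_curvature(shape, ElasticParams(ratio))
        assert res.m_eff == pytest.approx(res.m + res.m_nlo, abs=1e-12 * max(1, abs(res.m)))
        assert res.m_nlo <= 0.0
        assert (res.m_nlo == 0.0) == (ratio == 0.0)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(shape=budded_shapes, lam=st.sampled_from([0.5, 2.0, 10.0]))
    def test_scale_covariance(self, shape, lam):
        """m scales as 1/length; m_bar is scale-free."""
        p = ElasticParams(1.0)
        r1 = neck_curvature(shape, p)
        r2 = neck_curvature(BuddedShape(lam * shape.R_alpha, lam * shape.R_beta), p)
        assert r2.m == pytest.approx(r1.m / lam, rel=1e-9)
        assert r2.m_bar == pytest.approx(r1.m_bar, rel=1e-9)

    def test_m_affine_increasing_in_kappa_ratio(self):
        """Higher nonlocal rigidity implies larger inferred local curvature."""
        shape = BuddedShape(8.0, 1.2)
        ms = [neck_curvature(shape, ElasticParams(k)).m for k in (0, 0.5, 1, 1.5, 2)]
        diffs = np.diff(ms)
        assert np.all(diffs > 0)
        assert np.allclose(diffs, diffs[0], rtol=1e-12)  # affine in the ratio


class TestLimitShapeLine:
    def test_equal_sphere_endpoint(self):
        line = limit_shape_line(ElasticParams(0.0), [0.5, 1.0])
        i = np.argmin(line.nu)
        assert line.nu[i] == pytest.approx(1 / math.sqrt(2), rel=1e-9)
        assert line.m_bar[i] == pytest.approx(math.sqrt(2), rel=1e-9)

    def test_small_bud_divergence(self):
        line = limit_shape_line(ElasticParams(0.0), [0.01, 0.5])
        assert line.m_bar[np.argmax(line.nu)] > 10

    def test_nonlocal_term_raises_line(self):
        xs = np.linspace(0.05, 1.0, 30)
        l0 = limit_shape_line(ElasticParams(0.0), xs)
        l1 = limit_shape_line(ElasticParams(1.0), xs)
        assert np.all(l1.m_bar > l0.m_bar)

    def test_points_sorted_and_in_range(self):
        line = limit_shape_line(ElasticParams(2.0), np.linspace(0.02, 1.0, 50))
        assert np.all(np.diff(line.nu) > 0)
        assert np.all(line.nu > NU_TWO_SPHERE_MIN - 1e-9)
        assert np.all(line.nu < 1.0)
        assert np.all(np.isfinite(line.m_bar)) and np.all(line.m_bar > 0)

    @pytest.mark.parametrize("bad", [[], [0.5], [0.0, 0.5], [0.5, 1.2]])
    def test_rejects_bad_grid(self, bad):
        with pytest.raises(ValueError):
            limit_shape_line(ElasticParams(0.0), bad)


class TestInvertLimitLine:
    def test_endpoint(self):
        assert invert_limit_line(1 / math.sqrt(2) + 1e-9, ElasticParams(0.0)) == pytest.approx(
            1.0, abs=1e-4
        )

    @pytest.mark.parametrize("nu", [0.72, 0.85, 0.95, 0.999])
    def test_forward_round_trip(self, nu):
        from membud.geometry import two_sphere_geometry

        x = invert_limit_line(nu, ElasticParams(0.0))
        assert two_sphere_geometry(BuddedShape(1.0, x)).nu == pytest.approx(nu, abs=1e-10)

    @pytest.mark.parametrize("nu", [0.5, 1 / math.sqrt(2), 1.0, 1.2])
    def test_out_of_range(self, nu):
        with pytest.raises(ValueError):
            invert_limit_line(nu, ElasticParams(0.0))


class TestClassifyMorphology:
    def test_above_and_below(self):
        nu = 1 / math.sqrt(2) + 1e-6
        assert classify_morphology(nu, 1.6, ElasticParams(0.0)) == "above_limit_line"
        assert classify_morphology(nu, 1.0, ElasticParams(0.0)) == "below_limit_line"

    def test_line_points_classify_on(self):
        params = ElasticParams(1.0)
        line = limit_shape_line(params, np.linspace(0.1, 1.0, 20))
        for nu, mbar in zip(line.nu, line.m_bar):
            if NU_TWO_SPHERE_MIN < nu < 1.0:
                assert classify_morphology(nu, mbar, params) == "on_limit_line"


class TestAnalyzeBuddedPopulation:
    def test_single_equal_sphere_shape(self):
        records, summaries = analyze_budded_population([BuddedShape(1, 1)], [0.0])
        assert summaries[0].m_mean == pytest.approx(1.0, abs=1e-12)
        assert records.shape[0] == 1

    def test_noise_free_population_recovers_m_true(self, clean_population):
        table, truth = clean_population
        records, summaries = analyze_budded_population(table, [truth["kappa_ratio"]])
        assert summaries[0].m_mean == pytest.approx(truth["m_true"], abs=1e-9)
        assert np.allclose(records["m"], truth["m_true"], atol=1e-9)

    def test_nonlocal_ordering_on_noisy_shapes(self):
        from membud.synthetic import PopulationConfig, gen_budded_population

        table, _ = gen_budded_population(
            PopulationConfig(n=10, m_true=0.4, radius_noise=0.02), seed=3
        )
        _, summaries = analyze_budded_population(table, [0.0, 1.0])
        by_ratio = {s.kappa_ratio: s.m_mean for s in summaries}
        assert by_ratio[1.0] > by_ratio[0.0]

    def test_dataframe_input_with_row_diagnosis(self):
        df = pd.DataFrame(
            {"vesicle_id": ["ok", "bad"], "R_alpha_um": [5.0, 1.0], "R_beta_um": [1.0, 2.0]}
        )
        with pytest.raises(ValueError, match="bad"):
            analyze_budded_population(df, [0.0])

    def test_empty_population(self):
        with pytest.raises(ValueError):
            analyze_budded_population([], [0.0])

    def test_reciprocal_length_convention(self):
        """Mean reported as 1/(L µm) with the spread propagated onto the length."""
        L, dL = curvature_as_reciprocal_length(0.4, 0.1)
        assert L == pytest.approx(2.5)
        assert dL == pytest.approx(0.1 / 0.16)


class TestPathwayTrajectory:
    @pytest.mark.parametrize(
        "pts,label",
        [
            ([(0.99, 1.0), (0.95, 1.0)], "area_increase_only"),
            ([(0.95, 1.0), (0.95, 2.0)], "curvature_only"),
            ([(0.99, 1.0), (0.93, 1.8)], "both"),
        ],
    )
    def test_classification(self, pts, label):
        assert pathway_trajectory(pts) == label

    def test_needs_two_points(self):
        with pytest.raises(ValueError):
            pathway_trajectory([(0.9, 1.0)])
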