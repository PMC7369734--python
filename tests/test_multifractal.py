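"""Partition function, generalized dimensions, Legendre spectrum and the
scaling-relation dimension solver."""

import numpy as np
import pytest

import cgrsas as c
from cgrsas.multifractal import MultifractalSpectrum, aggregate_measure

LOG2_3 = np.log2(3.0)


def quarters_grid():
    """2x2 probability grid with p=1/4 everywhere."""
    return c.MeasureGrid(np.full((2, 2), 0.25), counts=False)


class TestPartitionFunction:
    def test_s_one_is_normalization(self):
        assert np.isclose(c.partition_function(quarters_grid(), 1.0, 1), 1.0)

    def test_s_zero_counts_occupied_boxes(self):
        grid = c.MeasureGrid(np.array([[0.5, 0.5], [0.0, 0.0]]), counts=False)
        assert c.partition_function(grid, 0.0, 1) == 2

    def test_four_quarter_boxes_closed_form(self):
        assert np.isclose(c.partition_function(quarters_grid(), 2.0, 1), 0.25)

    def test_requires_probability_mode(self):
        grid = c.MeasureGrid(np.ones((2, 2)), counts=True)
        with pytest.raises(ValueError):
            c.partition_function(grid, 2.0, 1)

    def test_aggregation_must_divide(self):
        with pytest.raises(ValueError):
            aggregate_measure(np.ones((6, 6)), 4)


class TestGeneralizedDimensions:
    def test_uniform_raster_d0_is_two(self, uniform_points):
        grid = c.rasterize(uniform_points, 128)
        spec = c.generalized_dimensions(
            grid, c.BoxCountingConfig(s_grid=np.array([0.0]))
        )
        assert abs(spec.D[0] - 2.0) < 0.05

    def test_cascade_matches_closed_form(self):
        s = np.arange(-5.0, 5.5, 0.5)
        grid = c.cascade_field(c.CascadeSpec(c.CASCADE_MODELS["M1"], 8))
        est = c.generalized_dimensions(grid, c.BoxCountingConfig(s_grid=s))
        ana = c.analytic_generalized_dimensions(c.CASCADE_MODELS["M1"], s)
        assert np.abs(est.D - ana.D).max() < 0.05

    def test_estimated_spectrum_monotone(self):
        s = np.arange(-4.0, 4.5, 0.5)
        grid = c.cascade_field(c.CascadeSpec(c.CASCADE_MODELS["M2"], 7))
        est = c.generalized_dimensions(grid, c.BoxCountingConfig(s_grid=s))
        assert (np.diff(est.D) <= 0.02).all()

    def test_diagnostics_attached(self):
        grid = c.cascade_field(c.CascadeSpec(c.CASCADE_MODELS["M7"], 6))
        spec = c.generalized_dimensions(grid)
        assert spec.diagnostics is not None
        assert (spec.diagnostics["r_squared"] > 0.99).all()

    def test_too_few_scales_rejected(self):
        grid = c.MeasureGrid(np.ones((4, 4)) / 16, counts=False)
        with pytest.raises(ValueError, match="scales"):
            c.generalized_dimensions(grid)


class TestLegendreSpectrum:
    def test_monofractal_collapses_to_point(self):
        s = np.arange(-5.0, 5.25, 0.25)
        spec = MultifractalSpectrum(s=s, D=np.full_like(s, 2.0), tau=2.0 * (s - 1))
        leg = c.legendre_spectrum(spec)
        np.testing.assert_allclose(leg.alpha, 2.0, atol=1e-10)
        np.testing.assert_allclose(leg.f, 2.0, atol=1e-10)

    def test_m4_point_at_log2_3(self):
        s = np.arange(-5.0, 5.25, 0.25)
        leg = c.legendre_spectrum(
            c.analytic_generalized_dimensions(c.CASCADE_MODELS["M4"], s)
        )
        np.testing.assert_allclose(leg.alpha, LOG2_3, atol=1e-9)
        np.testing.assert_allclose(leg.f, LOG2_3, atol=1e-9)

    def test_f_at_s_zero_equals_d0(self):
        s = np.arange(-5.0, 5.25, 0.25)
        for p in (c.CASCADE_MODELS["M5"], c.CASCADE_MODELS["M3"]):
            leg = c.legendre_spectrum(c.analytic_generalized_dimensions(p, s))
            i0 = np.argmin(np.abs(s))
            assert abs(leg.f[i0] - leg.D[i0]) < 1e-3

    def test_transform_consistency_and_concavity(self):
        s = np.arange(-8.0, 8.1, 0.1)
        leg = c.legendre_spectrum(
            c.analytic_generalized_dimensions(c.CASCADE_MODELS["M5"], s)
        )
        # s*alpha - f reproduces tau
        np.testing.assert_allclose(s * leg.alpha - leg.f, leg.tau, atol=1e-8)
        # Legendre slope property df/dalpha = s (alpha is monotone in s),
        # which implies concavity of f as a function of alpha
        dfda = np.gradient(leg.f, leg.alpha)
        np.testing.assert_allclose(dfda[2:-2], s[2:-2], atol=0.05)
        # chord check of concavity in alpha on a coarse subsample
        a, f = leg.alpha[::8], leg.f[::8]
        for i in range(len(a) - 2):
            lam = (a[i + 1] - a[i]) / (a[i + 2] - a[i])
            chord = (1 - lam) * f[i] + lam * f[i + 2]
            assert f[i + 1] >= chord - 1e-9

    def test_needs_three_points(self):
        spec = MultifractalSpectrum(
            s=np.array([0.0, 1.0]), D=np.array([2.0, 2.0]), tau=np.array([-2.0, 0.0])
        )
        with pytest.raises(ValueError):
            c.legendre_spectrum(spec)


class TestHeterogeneityWidth:
    def test_uniform_model_width_zero(self):
        s = np.arange(-10.0, 10.25, 0.25)
        leg = c.legendre_spectrum(
            c.analytic_generalized_dimensions(c.CASCADE_MODELS["M7"], s)
        )
        assert c.heterogeneity_width(leg).width < 1e-10

    def test_single_scale_gasket_width_zero(self):
        s = np.arange(-10.0, 10.25, 0.25)
        leg = c.legendre_spectrum(
            c.analytic_generalized_dimensions(c.CASCADE_MODELS["M4"], s)
        )
        assert c.heterogeneity_width(leg).width < 1e-9

    def test_m5_asymptotes(self):
        lo, hi = c.analytic_alpha_asymptotes(c.CASCADE_MODELS["M5"])
        np.testing.assert_allclose((lo, hi), (np.log2(2.75), np.log2(11.0)))
        # the finite s-grid extrema stay inside the analytic asymptotes
        s = np.arange(-10.0, 10.25, 0.25)
        leg = c.legendre_spectrum(
            c.analytic_generalized_dimensions(c.CASCADE_MODELS["M5"], s)
        )
        het = c.heterogeneity_width(leg)
        assert lo - 1e-9 <= het.alpha_min and het.alpha_max <= hi + 1e-9

    def test_requires_alpha(self):
        spec = c.analytic_generalized_dimensions(
            c.CASCADE_MODELS["M5"], np.arange(-2, 2.5, 0.5)
        )
        with pytest.raises(ValueError):
            c.heterogeneity_width(spec)


class TestDimensionFromScaling:
    def test_gasket_closed_form(self):
        assert np.isclose(c.dimension_from_scaling([3], [0.5]), LOG2_3, atol=1e-9)

    def test_plane_filling(self):
        assert np.isclose(c.dimension_from_scaling([4], [0.5]), 2.0, atol=1e-9)

    def test_two_scale_bisection_oracle(self):
        # frozen from an independent 200-step bisection of 0.5^D + 4*0.25^D = 1
        root = c.dimension_from_scaling([1, 4], [0.5, 0.25])
        assert np.isclose(root, 1.3570186368605763, atol=1e-8)

    def test_inconsistent_inputs_rejected(self):
        with pytest.raises(ValueError, match="no root"):
            c.dimension_from_scaling([5], [0.9])
        with pytest.raises(ValueError):
            c.dimension_from_scaling([3], [1.5])
        with pytest.raises(ValueError):
            c.dimension_from_scaling([0.5], [0.5])
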