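"""Pair-distance histograms, Debye curves, scattering regimes,
log-periodicity and the pair-distance distribution function."""

import numpy as np
import pytest

import cgrsas as c
from cgrsas.sas import PairDistanceHistogram, direct_debye_intensity


class TestPairDistanceHistogram:
    def test_two_points_single_bin(self):
        pts = c.PointSet2D([(0.0, 0.0), (0.3, 0.0)], edge=1.0)
        h = c.pair_distance_histogram(pts, bin_width=0.05)
        assert h.counts.sum() == 1
        (idx,) = np.nonzero(h.counts)
        assert h.bin_edges[idx] <= 0.3 < h.bin_edges[idx + 1]

    def test_unit_square_corners_enumeration(self):
        pts = c.PointSet2D([(0, 0), (1, 0), (1, 1), (0, 1)], edge=1.0)
        h = c.pair_distance_histogram(pts, bin_width=0.01)
        centers = h.centers[h.counts > 0]
        counts = h.counts[h.counts > 0]
        # 4 side pairs at distance 1, 2 diagonal pairs at sqrt(2)
        assert counts.tolist() == [4, 2]
        assert abs(centers[0] - 1.0) < 0.01 and abs(centers[1] - np.sqrt(2)) < 0.01

    def test_pair_count_conservation(self, uniform_hist):
        n = uniform_hist.n_points
        assert uniform_hist.counts.sum() == n * (n - 1) // 2 == 199_990_000

    def test_chunking_invariance(self):
        rng = np.random.default_rng(2)
        pts = c.PointSet2D(rng.random((300, 2)), edge=1.0)
        h1 = c.pair_distance_histogram(pts, bin_width=0.01, chunk=7)
        h2 = c.pair_distance_histogram(pts, bin_width=0.01, chunk=512)
        np.testing.assert_array_equal(h1.counts, h2.counts)

    def test_validation(self):
        pts = c.PointSet2D([(0.1, 0.1)], edge=1.0)
        with pytest.raises(ValueError):
            c.pair_distance_histogram(pts)
        two = c.PointSet2D([(0.1, 0.1), (0.2, 0.2)], edge=1.0)
        with pytest.raises(ValueError):
            c.pair_distance_histogram(two, bin_width=0.0)


class TestDebyeIntensity:
    def test_single_point_scatters_unity(self):
        h = PairDistanceHistogram(
            counts=np.zeros(4, dtype=int), bin_edges=np.linspace(0, 1, 5), n_points=1
        )
        curve = c.debye_intensity(h, np.array([0.0, 1.0, 10.0]))
        np.testing.assert_allclose(curve.intensity, 1.0)

    def test_q_zero_gives_n_squared(self, uniform_hist):
        curve = c.debye_intensity(uniform_hist, np.array([0.0]))
        assert curve.intensity[0] == 20_000**2
        assert curve.structure_factor[0] == 1.0

    def test_pair_at_sinc_zero(self):
        # two points at distance 0.05 placed at an exact bin center
        pts = c.PointSet2D([(0.0, 0.0), (0.05, 0.0)], edge=1.0)
        h = c.pair_distance_histogram(pts, bin_width=0.1)
        curve = c.debye_intensity(h, np.array([np.pi / 0.05]))
        assert abs(curve.intensity[0] - 2.0) < 1e-10

    def test_histogram_route_matches_direct_double_sum(self):
        # oracle equivalence at the default bin width (l/1000) on 200
        # points, over q where the binning resolves the phase (q*dr < 1)
        rng = np.random.default_rng(4)
        pts = c.PointSet2D(rng.random((200, 2)), edge=1.0)
        h = c.pair_distance_histogram(pts)
        q = np.geomspace(0.5, 2 * np.pi * 100, 120)
        hist_route = c.debye_intensity(h, q).intensity
        direct = direct_debye_intensity(pts, q).intensity
        rel = np.abs(hist_route - direct) / np.abs(direct)
        assert rel.max() < 0.01

    def test_empty_q_grid_rejected(self, uniform_hist):
        with pytest.raises(ValueError):
            c.debye_intensity(uniform_hist, np.array([]))


class TestRegimesAndPowerLaw:
    def test_synthetic_power_law_exact(self):
        q = np.geomspace(1, 100, 64)
        curve = c.ScatteringCurve(q=q, intensity=1e4 * q**-2.0, n_points=100)
        fit = c.fit_power_law_exponent(curve, (1.0, 100.0))
        assert np.isclose(fit.exponent, 2.0, atol=1e-10)

    def test_uniform_square_exponent_two(self, uniform_hist):
        # Euclidean 2-D object: scattering exponent 2
        l0 = 1.0 / np.sqrt(20_000)
        curve = c.debye_intensity(uniform_hist, c.default_q_grid(1.0, l0))
        fit = c.fit_power_law_exponent(curve, c.fractal_q_range(curve, 1.0, l0))
        assert abs(fit.exponent - 2.0) < 0.1

    def test_gasket_exponent_log2_3(self, sierpinski_hist):
        d = np.log2(3.0)
        l0 = 20_000.0 ** (-1 / d)
        curve = c.debye_intensity(sierpinski_hist, c.default_q_grid(1.0, l0))
        fit = c.fit_power_law_exponent(curve, c.fractal_q_range(curve, 1.0, l0))
        assert abs(fit.exponent - d) < 0.1

    def test_plateau_inverts_to_point_count(self, uniform_hist):
        l0 = 1.0 / np.sqrt(20_000)
        curve = c.debye_intensity(uniform_hist, c.default_q_grid(1.0, l0))
        regimes = c.detect_regimes(curve, 1.0, l0)
        assert np.isclose(regimes.q_guinier, 2 * np.pi)
        assert abs(regimes.k_estimate - 20_000) / 20_000 < 0.1

    def test_narrow_grid_rejected(self, uniform_hist):
        curve = c.debye_intensity(uniform_hist, np.geomspace(10, 20, 16))
        with pytest.raises(ValueError):
            c.detect_regimes(curve, 1.0, 0.01)
        with pytest.raises(ValueError):
            c.fit_power_law_exponent(curve, (1000.0, 2000.0))


class TestLogPeriodicity:
    @pytest.mark.parametrize("n", [5, 6, 7])
    def test_m4_cascade_recovers_half(self, n):
        """Binarized single-scale gasket: construction scale 1/2 per
        iteration; accepted minima grow with depth."""
        grid = c.cascade_field(c.CascadeSpec(c.CASCADE_MODELS["M4"], n))
        pts = c.binarize(c.equalize_histogram(grid), 0.4)
        h = c.pair_distance_histogram(pts, bin_width=pts.edge / 1000)
        curve = c.debye_intensity(h, c.default_q_grid(pts.edge, 1.0))
        fit = c.fit_power_law_exponent(
            curve, c.fractal_q_range(curve, pts.edge, 1.0)
        )
        lp = c.log_periodicity_analysis(
            curve,
            fit.exponent,
            q_range=c.fractal_q_range(curve, pts.edge, 1.0, plateau_margin=3.0),
        )
        assert 0.45 <= lp.beta <= 0.55

    def test_minima_count_grows_with_iterations(self):
        counts = []
        for n in (5, 6, 7):
            grid = c.cascade_field(c.CascadeSpec(c.CASCADE_MODELS["M4"], n))
            pts = c.binarize(c.equalize_histogram(grid), 0.4)
            h = c.pair_distance_histogram(pts, bin_width=pts.edge / 1000)
            curve = c.debye_intensity(h, c.default_q_grid(pts.edge, 1.0))
            lp = c.log_periodicity_analysis(
                curve,
                np.log2(3.0),
                q_range=c.fractal_q_range(curve, pts.edge, 1.0, plateau_margin=3.0),
            )
            counts.append(lp.n_minima)
        assert counts[0] <= counts[1] <= counts[2] and counts[0] < counts[2]

    def test_featureless_power_law_yields_nothing(self):
        q = np.geomspace(1, 1000, 256)
        curve = c.ScatteringCurve(q=q, intensity=1e6 * q**-2.0, n_points=1000)
        lp = c.log_periodicity_analysis(curve, 2.0)
        assert lp.n_minima == 0 and np.isnan(lp.beta)

    def test_uniform_points_show_no_periodicity(self, uniform_hist):
        l0 = 1.0 / np.sqrt(20_000)
        curve = c.debye_intensity(uniform_hist, c.default_q_grid(1.0, l0))
        lp = c.log_periodicity_analysis(
            curve, 2.0, q_range=c.fractal_q_range(curve, 1.0, l0, plateau_margin=3.0)
        )
        assert np.isnan(lp.beta)


class TestPddf:
    def test_normalization(self, sierpinski_hist):
        d = c.pddf(sierpinski_hist)
        assert np.isclose(
            np.sum(d.p) * sierpinski_hist.bin_width, 1.0, atol=1e-12
        )

    def test_uniform_square_mode_and_support(self, uniform_hist):
        # mode near half the edge; largest distance near sqrt(2)
        d = c.pddf(uniform_hist)
        assert abs(d.mode - 0.5) < 0.05
        assert abs(d.support_max - np.sqrt(2.0)) < 0.05
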