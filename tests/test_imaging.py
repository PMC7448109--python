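import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from prostadx import imaging
from prostadx.imaging import BoundaryChain

from conftest import convex_mask, hysteresis_bfs_oracle


class TestToGrayscale:
    def test_uniform_channels_identity(self):
        img = np.full((2, 2, 3), 255.0)
        assert np.allclose(imaging.to_grayscale(img), 255.0)
        img = np.full((2, 2, 3), 100.0)
        assert np.allclose(imaging.to_grayscale(img), 100.0)

    def test_weighted_sum(self):
        img = np.array([[[200.0, 100.0, 50.0]]])
        out = imaging.to_grayscale(img, (0.30, 0.59, 0.11))
        assert out[0, 0] == pytest.approx(124.5)

    def test_gray_passthrough(self):
        g = np.array([[10.0, 20.0], [30.0, 40.0]])
        assert np.allclose(imaging.to_grayscale(g), g)

    def test_empty_image_raises(self):
        with pytest.raises(ValueError):
            imaging.to_grayscale(np.empty((0, 0, 3)))

    @pytest.mark.parametrize("weights", [(0.5, 0.4, 0.1), (0.3, 0.5, 0.2), (0.3, 0.6, 0.3)])
    def test_out_of_range_weights_raise(self, weights):
        with pytest.raises(ValueError):
            imaging.to_grayscale(np.zeros((2, 2, 3)), weights)


class TestGaussianKernel:
    @given(st.floats(0.2, 5.0), st.integers(1, 4))
    @settings(max_examples=25, deadline=None)
    def test_sums_to_one(self, sigma, radius):
        k = imaging.gaussian_kernel(sigma, radius)
        assert abs(k.sum() - 1.0) < 1e-12
        assert k.shape == (2 * radius + 1,) * 2

    def test_center_is_max_and_symmetric(self):
        k = imaging.gaussian_kernel(1.4, 2)
        assert k[2, 2] == k.max()
        assert np.allclose(k, k[::-1, :])
        assert np.allclose(k, k.T)

    def test_center_corner_ratio(self):
        k = imaging.gaussian_kernel(1.0, 1)
        assert k[1, 1] / k[0, 0] == pytest.approx(np.e)

    def test_nonpositive_sigma_raises(self):
        with pytest.raises(ValueError):
            imaging.gaussian_kernel(0.0)
        with pytest.raises(ValueError):
            imaging.gaussian_kernel(-1.0)


class TestSmooth:
    def test_constant_fixed_point(self):
        g = np.full((8, 8), 42.0)
        out = imaging.smooth(g, imaging.gaussian_kernel(1.4, 2))
        assert np.allclose(out, 42.0)

    def test_impulse_response_is_kernel(self):
        g = np.zeros((11, 11))
        g[5, 5] = 1.0
        k = imaging.gaussian_kernel(1.0, 2)
        out = imaging.smooth(g, k)
        assert np.allclose(out[3:8, 3:8], k)

    def test_uniform_3x3_center(self):
        g = np.full((3, 3), 10.0)
        g[1, 1] = 100.0
        out = imaging.smooth(g, np.full((3, 3), 1 / 9))
        assert out[1, 1] == pytest.approx(20.0)

    def test_range_not_expanded(self, rng):
        g = rng.uniform(0, 255, (16, 16))
        out = imaging.smooth(g, imaging.gaussian_kernel(2.0, 2))
        assert out.min() >= g.min() - 1e-9 and out.max() <= g.max() + 1e-9

    def test_kernel_larger_than_image_raises(self):
        with pytest.raises(ValueError):
            imaging.smooth(np.zeros((3, 3)), np.full((5, 5), 1 / 25))


class TestGradient:
    def test_constant_zero(self):
        f = imaging.gradient(np.full((5, 5), 7.0))
        assert np.allclose(f.gx, 0) and np.allclose(f.gy, 0)
        assert np.allclose(f.magnitude, 0)

    def test_column_ramp(self):
        g = np.tile(np.arange(6, dtype=float), (5, 1))
        f = imaging.gradient(g)
        assert np.allclose(f.gx, 1.0)
        assert np.allclose(f.gy, 0.0)

    def test_row_ramp(self):
        g = np.tile(np.arange(6, dtype=float)[:, None], (1, 5))
        f = imaging.gradient(g)
        assert np.allclose(f.gy, 1.0)
        assert np.allclose(f.gx, 0.0)

    def test_magnitude_definition(self, rng):
        f = imaging.gradient(rng.uniform(0, 255, (10, 10)))
        assert np.allclose(f.magnitude**2, f.gx**2 + f.gy**2)

    def test_too_small_raises(self):
        with pytest.raises(ValueError):
            imaging.gradient(np.zeros((1, 5)))


class TestNonmaxSuppress:
    def test_zero_field(self):
        f = imaging.gradient(np.zeros((5, 5)))
        assert np.allclose(imaging.nonmax_suppress(f), 0)

    def test_isolated_peak_retained(self):
        g = np.zeros((9, 9))
        g[4, 4] = 100.0
        thin = imaging.nonmax_suppress(imaging.gradient(imaging.smooth(g, imaging.gaussian_kernel(1.0, 1))))
        assert thin.max() > 0

    def test_ridge_profile_survivor(self):
        # horizontal-gradient magnitudes 1,3,5,3,1 across columns: only the 5
        # column survives suppression
        h, w = 5, 5
        mag = np.tile(np.array([1.0, 3.0, 5.0, 3.0, 1.0]), (h, 1))
        field = imaging.GradientField(
            gx=mag.copy(), gy=np.zeros((h, w)), magnitude=mag, direction=np.zeros((h, w))
        )
        thin = imaging.nonmax_suppress(field)
        assert np.all(thin[:, 2] == 5.0)
        assert np.all(thin[:, [0, 1, 3, 4]] == 0.0)

    def test_subset_of_support(self, rng):
        g = rng.uniform(0, 255, (20, 20))
        f = imaging.gradient(g)
        thin = imaging.nonmax_suppress(f)
        assert np.all((thin > 0) <= (f.magnitude > 0))
        assert np.all((thin == f.magnitude) | (thin == 0))


class TestHysteresis:
    def test_all_below_low_empty(self):
        assert imaging.hysteresis_threshold(np.full((4, 4), 1.0), 5.0, 10.0).sum() == 0

    def test_all_strong_retained(self):
        mag = np.full((4, 4), 20.0)
        assert imaging.hysteresis_threshold(mag, 5.0, 10.0).sum() == 16

    def test_weak_path_connected_to_strong(self):
        mag = np.zeros((5, 5))
        mag[2, 0] = 20.0  # strong
        mag[2, 1] = mag[2, 2] = mag[2, 3] = 7.0  # weak path
        out = imaging.hysteresis_threshold(mag, 5.0, 10.0)
        assert out[2, :4].sum() == 4
        assert out.sum() == 4

    def test_bfs_oracle_equality(self, rng):
        for _ in range(20):
            mag = rng.uniform(0, 30, (32, 32))
            out = imaging.hysteresis_threshold(mag, 8.0, 22.0)
            assert np.array_equal(out, hysteresis_bfs_oracle(mag, 8.0, 22.0))

    def test_low_above_high_raises(self):
        with pytest.raises(ValueError):
            imaging.hysteresis_threshold(np.zeros((3, 3)), 10.0, 5.0)


class TestTraceBoundary:
    def test_single_pixel_degenerate_chain(self):
        m = np.zeros((3, 3), bool)
        m[1, 1] = True
        chain = imaging.trace_boundary(m)
        assert chain.start == (1, 1)
        assert chain.codes == ()
        assert chain.is_closed()

    def test_2x2_square(self):
        m = np.zeros((4, 4), bool)
        m[1:3, 1:3] = True
        chain = imaging.trace_boundary(m)
        assert len(chain.codes) == 4
        assert chain.is_closed()

    def test_closure_on_random_convex(self, rng):
        for _ in range(10):
            chain = imaging.trace_boundary(convex_mask(rng, 32))
            assert chain.is_closed()

    def test_chain_points_are_boundary_pixels(self, rng):
        from scipy import ndimage

        m = convex_mask(rng, 32)
        interior = ndimage.binary_erosion(m, structure=np.ones((3, 3)))
        boundary = m & ~interior
        for r, c in imaging.trace_boundary(m).points():
            assert boundary[r, c]

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            imaging.trace_boundary(np.zeros((3, 3), bool))

    def test_multiple_components_raise(self):
        m = np.zeros((5, 5), bool)
        m[0, 0] = m[4, 4] = True
        with pytest.raises(ValueError):
            imaging.trace_boundary(m)


class TestLabelChain:
    @pytest.mark.parametrize(
        "code,label",
        [(0, 0), (1, -1), (2, -1), (3, -1), (4, 0), (5, 1), (6, 1), (7, 1)],
    )
    def test_mapping(self, code, label):
        assert imaging.label_chain_code(code) == label

    def test_invalid_code_raises(self):
        with pytest.raises(ValueError):
            imaging.label_chain_code(8)

    def test_labels_match_row_steps(self):
        chain = BoundaryChain(start=(0, 0), codes=(0, 6, 4, 2))
        assert chain.labels == (0, 1, 0, -1)


class TestChainArea:
    def test_single_pixel(self):
        assert imaging.chain_area(BoundaryChain(start=(0, 0), codes=())) == 1

    def test_3x3_square(self):
        m = np.zeros((5, 5), bool)
        m[1:4, 1:4] = True
        assert imaging.chain_area(imaging.trace_boundary(m)) == 9

    @pytest.mark.parametrize("w", range(2, 11))
    def test_rectangles(self, w):
        for h in range(2, 11):
            m = np.zeros((h + 2, w + 2), bool)
            m[1 : 1 + h, 1 : 1 + w] = True
            assert imaging.chain_area(imaging.trace_boundary(m)) == w * h

    def test_flood_fill_oracle_random_convex(self, rng):
        for _ in range(50):
            m = convex_mask(rng, 64)
            assert imaging.chain_area(imaging.trace_boundary(m)) == int(m.sum())

    def test_open_chain_raises(self):
        with pytest.raises(ValueError):
            imaging.chain_area(BoundaryChain(start=(0, 0), codes=(0, 0)))


class TestMeanGray:
    def test_uniform(self):
        g = np.full((4, 4), 180.0)
        assert imaging.mean_gray_level(g, np.ones((4, 4), bool)) == 180.0

    def test_two_values(self):
        g = np.array([[100.0, 200.0]])
        assert imaging.mean_gray_level(g, np.array([[True, True]])) == 150.0

    def test_three_values(self):
        g = np.array([[10.0, 20.0, 40.0]])
        m = np.array([[True, True, True]])
        assert imaging.mean_gray_level(g, m) == pytest.approx(23.333333333)

    def test_empty_mask_raises(self):
        with pytest.raises(ValueError):
            imaging.mean_gray_level(np.zeros((2, 2)), np.zeros((2, 2), bool))


class TestExtractLesionMetrics:
    def test_blank_image_not_informative(self):
        m = imaging.extract_lesion_metrics(np.full((32, 32), 100.0))
        assert not m.informative
        assert m.area_px == 0
        assert np.isnan(m.mean_gray)

    def test_ellipse_area_within_10pct(self):
        from prostadx import synth

        rng = np.random.default_rng(9)
        model = synth.LesionModel(noise_scale=0.0)
        for stage in (1, 2, 3, 4):
            img, true_area, _ = synth.render_lesion_image(stage, model, rng)
            m = imaging.extract_lesion_metrics(img)
            assert abs(m.area_px - true_area) <= 0.10 * true_area
            assert m.n_pixels == m.area_px

    def test_uniform_lesion_mean_gray(self):
        from prostadx import synth

        rng = np.random.default_rng(5)
        model = synth.LesionModel(noise_scale=0.0, intensities=(200.0,) * 4)
        img, _, _ = synth.render_lesion_image(3, model, rng)
        m = imaging.extract_lesion_metrics(img)
        assert m.mean_gray == pytest.approx(200.0, abs=5.0)
        assert m.informative  # area > 50 px and gray >= 180
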