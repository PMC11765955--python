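"""Vesselness filter: normalization, smoothing, Hessian, eigenvalues, response."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vesselseg import (
    FrangiParams,
    PhantomSpec,
    eigenvalues_2x2,
    gaussian_smooth,
    generate_phantom,
    hessian_at_scale,
    multiscale_vesselness,
    normalize_intensity,
    threshold_vesselness,
    vesselness_response,
)
from vesselseg.frangi import HessianField

from helpers import direct_gaussian_convolve


class TestNormalizeIntensity:
    def test_linear_rescale(self):
        img = np.array([[2.0, 4.0], [6.0, 3.0]])
        out = normalize_intensity(img)
        assert out[0, 1] == pytest.approx(0.5)
        assert out.min() == 0.0 and out.max() == 1.0

    def test_constant_image_maps_to_zeros(self):
        np.testing.assert_array_equal(normalize_intensity(np.full((4, 4), 7.0)), 0.0)

    def test_unit_range_unchanged(self):
        img = np.array([[0.0, 0.25], [0.75, 1.0]])
        np.testing.assert_allclose(normalize_intensity(img), img)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            normalize_intensity(np.array([[0.0, np.nan]]))


class TestGaussianSmooth:
    def test_constant_preserved(self):
        out = gaussian_smooth(np.full((16, 16), 3.5), sigma=2.0)
        np.testing.assert_allclose(out, 3.5)

    def test_impulse_response_sums_to_one(self):
        img = np.zeros((41, 41))
        img[20, 20] = 1.0
        out = gaussian_smooth(img, sigma=2.0)
        assert out.sum() == pytest.approx(1.0, abs=1e-10)
        assert out[20, 20] == out.max()

    def test_matches_direct_convolution_oracle(self):
        rng = np.random.default_rng(0)
        img = rng.random((9, 9))
        np.testing.assert_allclose(
            gaussian_smooth(img, 1.5), direct_gaussian_convolve(img, 1.5), atol=1e-6
        )

    def test_invalid_sigma(self):
        with pytest.raises(ValueError):
            gaussian_smooth(np.zeros((4, 4)), 0.0)


class TestHessian:
    def test_quadratic_ramp_second_derivatives(self):
        """I(x, y) = x^2 has ixx = 2, iyy = ixy = 0 in the interior."""
        x = np.arange(64, dtype=float)
        img = np.tile(x**2, (64, 1))
        h = hessian_at_scale(img, sigma=2.0, gamma_normalize=False)
        interior = np.s_[16:48, 16:48]
        np.testing.assert_allclose(h.ixx[interior], 2.0, atol=1e-6)
        np.testing.assert_allclose(h.iyy[interior], 0.0, atol=1e-6)
        np.testing.assert_allclose(h.ixy[interior], 0.0, atol=1e-6)

    def test_constant_image_zero_hessian(self):
        h = hessian_at_scale(np.full((16, 16), 2.0), sigma=1.0)
        for f in (h.ixx, h.ixy, h.iyy):
            np.testing.assert_allclose(f, 0.0, atol=1e-12)

    def test_matches_gaussian_derivative_convolution_oracle(self):
        """Smooth-then-difference agrees with direct Gaussian-derivative
        convolution (scipy order= kernels) on a smooth random image."""
        from scipy import ndimage as ndi

        rng = np.random.default_rng(2)
        img = ndi.gaussian_filter(rng.random((64, 64)), 2.0)
        h = hessian_at_scale(img, sigma=3.0, gamma_normalize=False)
        ref_xx = ndi.gaussian_filter(img, 3.0, order=(0, 2), mode="reflect")
        ref_yy = ndi.gaussian_filter(img, 3.0, order=(2, 0), mode="reflect")
        ref_xy = ndi.gaussian_filter(img, 3.0, order=(1, 1), mode="reflect")
        scale = np.abs(ref_xx).max()
        assert np.abs(h.ixx - ref_xx).max() < 0.05 * scale
        assert np.abs(h.iyy - ref_yy).max() < 0.05 * scale
        assert np.abs(h.ixy - ref_xy).max() < 0.05 * scale

    def test_gamma_normalization_scales_by_sigma_squared(self):
        rng = np.random.default_rng(1)
        img = rng.random((32, 32))
        raw = hessian_at_scale(img, 3.0, gamma_normalize=False)
        scaled = hessian_at_scale(img, 3.0, gamma_normalize=True)
        np.testing.assert_allclose(scaled.ixx, 9.0 * raw.ixx)
        np.testing.assert_allclose(scaled.ixy, 9.0 * raw.ixy)


def _field(ixx, ixy, iyy):
    return HessianField(
        ixx=np.atleast_2d(float(ixx)),
        ixy=np.atleast_2d(float(ixy)),
        iyy=np.atleast_2d(float(iyy)),
    )


class TestEigenvalues:
    @pytest.mark.parametrize(
        "ixx,ixy,iyy,l1,l2",
        [
            (3, 0, 3, 3, 3),  # scalar matrix
            (0, 0, -4, 0, -4),  # diagonal, magnitude ordering
            (0, 1, 0, -1, 1),  # magnitude tie: lambda1 takes the smaller signed value
        ],
    )
    def test_closed_form_cases(self, ixx, ixy, iyy, l1, l2):
        eig = eigenvalues_2x2(_field(ixx, ixy, iyy))
        assert eig.lambda1[0, 0] == pytest.approx(l1)
        assert eig.lambda2[0, 0] == pytest.approx(l2)

    def test_matches_numpy_eigensolver_on_random_matrices(self):
        """Closed form agrees with numpy.linalg.eigvalsh after magnitude sorting."""
        rng = np.random.default_rng(42)
        n = 1000
        ixx, ixy, iyy = rng.normal(size=(3, n)) * 10
        eig = eigenvalues_2x2(
            HessianField(ixx=ixx[None], ixy=ixy[None], iyy=iyy[None])
        )
        for i in range(n):
            ref = np.linalg.eigvalsh([[ixx[i], ixy[i]], [ixy[i], iyy[i]]])
            ref = ref[np.argsort(np.abs(ref), kind="stable")]
            assert abs(eig.lambda1[0, i] - ref[0]) < 1e-8
            assert abs(eig.lambda2[0, i] - ref[1]) < 1e-8

    def test_magnitude_ordering_and_trace_invariants(self):
        rng = np.random.default_rng(7)
        h = HessianField(*rng.normal(size=(3, 20, 20)))
        eig = eigenvalues_2x2(h)
        assert (np.abs(eig.lambda1) <= np.abs(eig.lambda2) + 1e-12).all()
        np.testing.assert_allclose(eig.lambda1 + eig.lambda2, h.ixx + h.iyy, atol=1e-9)


class TestVesselnessResponse:
    def test_hand_evaluated_value(self):
        """lambda1=0, lambda2=-2, alpha=0.5, beta=1 -> 1 - exp(-2)."""
        v = vesselness_response(0.0, -2.0, alpha=0.5, beta=1.0)
        assert v == pytest.approx(1.0 - np.exp(-2.0), abs=1e-12)

    def test_positive_lambda2_gives_zero(self):
        for l1 in (-5.0, 0.0, 5.0):
            assert vesselness_response(l1, 1.0, 0.5, 1.0) == 0.0

    def test_degenerate_zero_eigenvalues_give_zero(self):
        assert vesselness_response(0.0, 0.0, 0.5, 1.0) == 0.0

    def test_blob_suppressed_relative_to_ridge(self):
        ridge = vesselness_response(0.0, -2.0, 0.5, 1.0)
        blob = vesselness_response(-2.0, -2.0, 0.5, 1.0)
        assert blob < ridge

    @given(
        l1=st.floats(-50, 50),
        l2=st.floats(-50, 50),
        alpha=st.floats(0.1, 2.0),
        beta=st.floats(0.1, 10.0),
    )
    @settings(max_examples=200, derandomize=True)
    def test_response_always_in_unit_interval(self, l1, l2, alpha, beta):
        """V lies in [0, 1); at extreme S/beta ratios the strictly-below-one
        value is only representable up to float rounding."""
        if abs(l1) > abs(l2):
            l1, l2 = l2, l1
        v = vesselness_response(l1, l2, alpha, beta)
        assert 0.0 <= v <= 1.0
        if (l1 * l1 + l2 * l2) / (2 * beta * beta) < 30:
            assert v < 1.0


class TestMultiscale:
    def test_params_validation(self):
        with pytest.raises(ValueError):
            FrangiParams(sigma_min=4, sigma_max=2)
        with pytest.raises(ValueError):
            FrangiParams(sigma_step=0)
        with pytest.raises(ValueError):
            FrangiParams(alpha=-1)
        with pytest.raises(ValueError):
            FrangiParams(t_vesselness=1.5)

    def test_scale_grid_inclusive_of_endpoint(self):
        np.testing.assert_allclose(
            FrangiParams(sigma_min=1, sigma_max=8, sigma_step=1).scales, np.arange(1, 9)
        )
        np.testing.assert_allclose(
            FrangiParams(sigma_min=1, sigma_max=2, sigma_step=0.5).scales,
            [1.0, 1.5, 2.0],
        )

    def test_single_scale_equals_singleton_max(self):
        img, _ = generate_phantom(PhantomSpec(image_size=(64, 64), rng_seed=1))
        p1 = FrangiParams(sigma_min=2, sigma_max=2)
        v1 = multiscale_vesselness(img, p1)
        assert v1.shape == img.shape
        assert (v1 >= 0).all() and (v1 < 1).all()

    def test_adding_scales_only_increases_response(self):
        img, _ = generate_phantom(PhantomSpec(image_size=(64, 64), rng_seed=1))
        v_small = multiscale_vesselness(img, FrangiParams(sigma_min=1, sigma_max=2))
        v_large = multiscale_vesselness(img, FrangiParams(sigma_min=1, sigma_max=4))
        assert (v_large >= v_small - 1e-12).all()

    def test_flat_image_zero_response(self):
        v = multiscale_vesselness(np.full((40, 40), 0.5), FrangiParams(sigma_max=2))
        np.testing.assert_allclose(v, 0.0)


class TestThresholdVesselness:
    def test_boundary_inclusive(self):
        v = np.array([[0.2, 0.5, 0.8]])
        np.testing.assert_array_equal(
            threshold_vesselness(v, 0.5), [[False, True, True]]
        )

    def test_zero_threshold_selects_everything(self):
        assert threshold_vesselness(np.zeros((3, 3)), 0.0).all()

    def test_unit_threshold_selects_nothing_below_one(self):
        assert not threshold_vesselness(np.full((3, 3), 0.9999), 1.0).any()
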