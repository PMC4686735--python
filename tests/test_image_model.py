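import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from retinahaze import (
    DegenerateInputError,
    FormatError,
    GeometryError,
    ParameterError,
    convolve,
    gaussian_kernel,
    load_image,
    normalize_joint_max,
    save_image,
)

from _oracle import direct_convolve


class TestGaussianKernel:
    @pytest.mark.parametrize("sigma,radius", [(0.5, 2), (1.0, 3), (5 / 3, 5), (10 / 3, 10)])
    def test_normalized_symmetric_and_peaked(self, sigma, radius):
        k = gaussian_kernel(sigma, radius)
        w = k.weights
        assert w.shape == (2 * radius + 1, 2 * radius + 1)
        assert abs(w.sum() - 1.0) <= 1e-9
        # symmetric under quarter rotation and both axis flips
        assert np.array_equal(w, np.rot90(w))
        assert np.array_equal(w, w[::-1])
        assert np.array_equal(w, w[:, ::-1])
        # peaked at the centre, monotone along a half-axis
        centre = w[radius, radius]
        assert centre == w.max()
        assert np.all(np.diff(w[radius, radius:]) < 0)

    def test_weight_ratio_matches_analytic_gaussian(self):
        # renormalization-invariant: w(1,0)/w(0,0) = exp(-1/(2 sigma^2))
        k = gaussian_kernel(1.0, 3)
        ratio = k.weights[3, 4] / k.weights[3, 3]
        assert ratio == pytest.approx(math.exp(-0.5), abs=1e-12)

    @pytest.mark.parametrize("sigma,radius", [(0.0, 3), (-1.0, 3), (1.0, 0), (1.0, 1.5)])
    def test_invalid_parameters_rejected(self, sigma, radius):
        with pytest.raises(ParameterError):
            gaussian_kernel(sigma, radius)


class TestConvolve:
    def test_constant_plane_preserved(self):
        k = gaussian_kernel(1.0, 3)
        plane = np.full((9, 11), 0.37)
        assert np.allclose(convolve(plane, k), 0.37, atol=1e-12)

    def test_impulse_reproduces_kernel(self):
        k = gaussian_kernel(1.0, 2)
        plane = np.zeros((11, 11))
        plane[5, 5] = 1.0
        out = convolve(plane, k)
        assert np.allclose(out[3:8, 3:8], k.weights, atol=1e-14)

    @pytest.mark.parametrize("shape,radius", [((7, 7), 3), ((9, 12), 2), ((16, 16), 5)])
    def test_matches_direct_sum_oracle(self, rng, shape, radius):
        plane = rng.uniform(0.0, 1.0, size=shape)
        k = gaussian_kernel(radius / 3 + 0.2, radius)
        assert np.abs(convolve(plane, k) - direct_convolve(plane, k.weights)).max() <= 1e-10

    @given(
        hnp.arrays(np.float64, (8, 8), elements=st.floats(-1, 1)),
        hnp.arrays(np.float64, (8, 8), elements=st.floats(-1, 1)),
        st.floats(-3, 3),
    )
    def test_linearity(self, a, b, lam):
        k = gaussian_kernel(0.8, 2)
        lhs = convolve(a + lam * b, k)
        rhs = convolve(a, k) + lam * convolve(b, k)
        assert np.abs(lhs - rhs).max() <= 1e-10

    def test_flip_equivariance(self, rng):
        k = gaussian_kernel(1.2, 3)
        plane = rng.uniform(size=(10, 10))
        assert np.allclose(convolve(plane[::-1], k), convolve(plane, k)[::-1], atol=1e-14)

    def test_oversized_kernel_rejected(self):
        k = gaussian_kernel(2.0, 6)  # side 13 > 2*5+1
        with pytest.raises(GeometryError):
            convolve(np.zeros((5, 8)), k)


class TestNormalizeJointMax:
    def test_divides_by_global_maximum(self):
        img = np.zeros((2, 2, 3))
        img[..., 0], img[..., 1], img[..., 2] = 0.5, 0.25, 0.1
        out = normalize_joint_max(img)
        assert out[..., 0].max() == pytest.approx(1.0)
        assert out[..., 1].max() == pytest.approx(0.5)
        assert out[..., 2].max() == pytest.approx(0.2)

    def test_identity_when_already_normalized(self, random_image):
        img = random_image / random_image.max()
        assert np.array_equal(normalize_joint_max(img), img)

    def test_constant_image_maps_to_one(self):
        out = normalize_joint_max(np.full((4, 4, 3), 0.4))
        assert np.allclose(out, 1.0)

    def test_all_zero_rejected(self):
        with pytest.raises(DegenerateInputError):
            normalize_joint_max(np.zeros((4, 4, 3)))


class TestImageIO:
    def test_uint8_roundtrip_full_scale(self, tmp_path):
        path = tmp_path / "img.png"
        arr = np.zeros((4, 5, 3))
        arr[0, 0] = 1.0
        arr[1, 1] = 100 / 255
        save_image(path, arr)
        back = load_image(path)
        assert back.shape == (4, 5, 3)
        assert back[0, 0, 0] == pytest.approx(1.0)
        assert back[1, 1, 0] == pytest.approx(100 / 255)
        assert back[3, 4, 2] == pytest.approx(0.0)

    def test_grayscale_replicated_to_three_planes(self, tmp_path):
        import imageio.v3 as iio

        path = tmp_path / "gray.png"
        iio.imwrite(path, np.array([[0, 128], [255, 64]], dtype=np.uint8))
        img = load_image(path)
        assert img.shape == (2, 2, 3)
        assert np.array_equal(img[..., 0], img[..., 1])
        assert np.array_equal(img[..., 0], img[..., 2])
        assert img[1, 0, 0] == pytest.approx(1.0)

    def test_sixteen_bit_roundtrip(self, tmp_path):
        path = tmp_path / "deep.png"
        save_image(path, np.full((3, 3), 0.5), bit_depth=16)
        back = load_image(path)
        assert back[0, 0, 0] == pytest.approx(0.5, abs=1e-4)

    def test_unreadable_file_raises_io_error(self, tmp_path):
        with pytest.raises(OSError):
            load_image(tmp_path / "missing.png")

    def test_unsupported_bit_depth_rejected(self, tmp_path):
        with pytest.raises(FormatError):
            save_image(tmp_path / "x.png", np.zeros((2, 2, 3)), bit_depth=12)
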