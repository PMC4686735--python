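import numpy as np
import pytest

from retinahaze import (
    GanglionParams,
    ParameterError,
    StructuralError,
    ganglion_layer,
    ganglion_opponent,
    opponent_channels,
    subunit_response,
    surround_pool,
)
from retinahaze.amacrine import ModulatedBipolar
from retinahaze.image_model import convolve

from _oracle import direct_convolve

CHANNELS = ("R", "G", "B", "Y")


class TestGanglionParams:
    def test_sigma_is_one_third_of_radius(self):
        p = GanglionParams(r_cen=3, r_sur=10, r_sub=3)
        assert p.sigma_cen == pytest.approx(1.0)
        assert p.sigma_sur == pytest.approx(10 / 3)
        assert p.sigma_sub == pytest.approx(1.0)
        assert p.center_kernel().weights.shape == (7, 7)
        assert p.surround_kernel().weights.shape == (21, 21)

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(r_cen=0),
            dict(r_sur=1, r_cen=1),
            dict(r_sub=0),
            dict(A_cen=0.0),
            dict(A_s=-1.0),
            dict(A_u=-0.1),
        ],
    )
    def test_invalid_rejected(self, kwargs):
        with pytest.raises(ParameterError):
            GanglionParams(**kwargs)


class TestSubunitResponse:
    def test_no_mutual_inhibition_passes_through(self, rng):
        plane = rng.uniform(size=(7, 7))
        out = subunit_response(plane, GanglionParams(A_u=0.0))
        assert np.array_equal(out, plane)

    def test_constant_fully_self_inhibits_at_unit_sensitivity(self):
        out = subunit_response(np.full((8, 8), 0.9), GanglionParams(A_u=1.0))
        assert np.abs(out).max() <= 1e-12

    def test_matches_direct_sum_oracle(self, rng):
        plane = rng.uniform(size=(9, 9))
        params = GanglionParams(A_u=0.5)
        expected = np.maximum(
            plane - 0.5 * direct_convolve(plane, params.subunit_kernel().weights), 0.0
        )
        assert np.abs(subunit_response(plane, params) - expected).max() <= 1e-10


class TestSurroundPool:
    def test_constant_preserved_and_zero_maps_to_zero(self):
        params = GanglionParams()
        assert np.allclose(surround_pool(np.full((9, 9), 0.3), params), 0.3, atol=1e-12)
        assert np.array_equal(surround_pool(np.zeros((9, 9)), params), np.zeros((9, 9)))

    def test_impulse_spreads_with_unit_mass(self):
        params = GanglionParams(r_cen=1, r_sur=3)
        plane = np.zeros((15, 15))
        plane[7, 7] = 1.0
        out = surround_pool(plane, params)
        assert out.sum() == pytest.approx(1.0, abs=1e-9)
        assert out[7, 7] == out.max()


class TestGanglionOpponent:
    def test_zero_surround_gives_scaled_center_blur(self, rng):
        params = GanglionParams(A_cen=2.0)
        center = rng.uniform(size=(9, 9))
        out = ganglion_opponent(center, np.zeros((9, 9)), params)
        expected = 2.0 * convolve(center, params.center_kernel())
        assert np.abs(out - expected).max() <= 1e-12

    def test_zero_center_is_clamped_to_zero(self, rng):
        params = GanglionParams()
        out = ganglion_opponent(np.zeros((8, 8)), rng.uniform(size=(8, 8)), params)
        assert np.array_equal(out, np.zeros((8, 8)))

    def test_strong_surround_fully_suppresses(self):
        params = GanglionParams(A_s=2.0)
        c = np.full((8, 8), 0.5)
        assert np.abs(ganglion_opponent(c, c, params)).max() == 0.0


class TestGanglionLayer:
    def test_uniform_input_gives_spatially_constant_outputs(self):
        mbp = ModulatedBipolar(
            on={c: np.full((13, 13), 0.4) for c in CHANNELS},
            off={c: np.full((13, 13), 0.6) for c in CHANNELS},
        )
        gc = ganglion_layer(mbp)
        for planes in (gc.on, gc.off):
            assert set(planes) == {"R", "G", "B"}
            for plane in planes.values():
                assert np.ptp(plane) <= 1e-12
                assert plane.min() >= 0.0

    def test_missing_channel_rejected(self):
        with pytest.raises(StructuralError):
            opponent_channels({"R": np.zeros((5, 5))}, GanglionParams())

    def test_classical_inhibition_without_disinhibitory_rescue(self):
        """A_u = 0 with a strong surround wipes out the response to a
        centre stimulus embedded in its opponent field."""
        img_r = np.zeros((15, 15))
        img_r[6:9, 6:9] = 1.0
        img_g = 1.0 - img_r
        channels = {"R": img_r, "G": img_g, "B": img_r, "Y": img_g}
        suppressed = opponent_channels(channels, GanglionParams(A_u=0.0, A_s=5.0, A_cen=1.0))
        rescued = opponent_channels(channels, GanglionParams(A_u=1.0, A_s=5.0, A_cen=1.0))
        assert suppressed["R"][7, 7] == 0.0
        assert rescued["R"][7, 7] > 0.0

    def test_response_monotone_in_subunit_sensitivity(self):
        """Disinhibition monotonicity: with a fixed centre and opponent
        surround stimulus, GC_R is non-decreasing in A_u."""
        rows, cols = np.mgrid[0:21, 0:21]
        dist = np.hypot(rows - 10, cols - 10)
        img_r = (dist <= 3).astype(float)
        img_g = ((dist > 3) & (dist <= 9)).astype(float)
        channels = {"R": img_r, "G": img_g, "B": np.zeros((21, 21)), "Y": img_g}
        params = [GanglionParams(r_cen=3, r_sur=8, r_sub=3, A_cen=1.0, A_s=3.0, A_u=a)
                  for a in (0.2, 0.4, 0.6, 0.8)]
        responses = [opponent_channels(channels, p)["R"][10, 10] for p in params]
        assert all(b >= a for a, b in zip(responses, responses[1:]))
        assert responses[-1] > responses[0]
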