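"""Quaternion algebra, the symplectic HFT and its polar decomposition."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hscsaliency.quaternion import (
    QuaternionSpectrum,
    encode_hsv,
    encode_spatiotemporal,
    hft_forward,
    hft_inverse,
    polar_decompose,
    qmult,
    qnorm,
    quaternion_dft_bruteforce,
    symplectic_decompose,
    symplectic_recompose,
)

ONE = np.array([1.0, 0, 0, 0])
I = np.array([0.0, 1, 0, 0])
J = np.array([0.0, 0, 1, 0])
K = np.array([0.0, 0, 0, 1])


class TestAlgebra:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            (I, I, -ONE),
            (J, J, -ONE),
            (K, K, -ONE),
            (I, J, K),
            (J, I, -K),
            (J, K, I),
            (K, J, -I),
            (K, I, J),
            (I, K, -J),
        ],
    )
    def test_multiplication_table(self, a, b, expected):
        np.testing.assert_allclose(qmult(a, b), expected, atol=1e-15)

    @settings(deadline=None, max_examples=60)
    @given(
        st.lists(
            st.floats(-10, 10, allow_nan=False), min_size=8, max_size=8
        )
    )
    def test_norm_is_multiplicative(self, coeffs):
        q1 = np.array(coeffs[:4])
        q2 = np.array(coeffs[4:])
        assert abs(qnorm(qmult(q1, q2)) - qnorm(q1) * qnorm(q2)) < 1e-10

    def test_broadcast_over_grids(self, random_qimage):
        a = random_qimage(3, 5)
        b = random_qimage(3, 5)
        prod = qmult(a, b)
        np.testing.assert_allclose(prod[1, 2], qmult(a[1, 2], b[1, 2]))


class TestEncoding:
    def test_hsv_pixel_mapping(self):
        hsv = np.array([[[0.5, 0.25, 1.0]]])
        np.testing.assert_array_equal(encode_hsv(hsv)[0, 0], [0, 0.5, 0.25, 1.0])

    def test_zero_image_and_basis_case(self):
        assert not encode_hsv(np.zeros((3, 4, 3))).any()
        np.testing.assert_array_equal(
            encode_hsv(np.array([[[1.0, 0, 0]]]))[0, 0], [0, 1, 0, 0]
        )

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="\\[0, 1\\]"):
            encode_hsv(np.full((2, 2, 3), 1.5))

    def test_spatiotemporal_zero_motion_reduces_to_static(self, rng):
        hsv = rng.uniform(0, 1, (4, 6, 3))
        np.testing.assert_array_equal(
            encode_spatiotemporal(np.zeros((4, 6)), hsv), encode_hsv(hsv)
        )

    def test_spatiotemporal_scalar_channel_and_norm(self):
        q = encode_spatiotemporal(np.array([[0.3]]), np.zeros((1, 1, 3)))
        np.testing.assert_array_equal(q[0, 0], [0.3, 0, 0, 0])
        q = encode_spatiotemporal(np.array([[-1.0]]), np.ones((1, 1, 3)))
        assert qnorm(q[0, 0]) == pytest.approx(2.0)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError, match="does not match"):
            encode_spatiotemporal(np.zeros((2, 2)), np.zeros((3, 3, 3)))


class TestSymplectic:
    def test_single_channel_case(self):
        q = np.zeros((1, 1, 4))
        q[0, 0] = [0, 2, 0, 0]
        f1, f2 = symplectic_decompose(q)
        assert f1[0, 0] == 2j
        assert f2[0, 0] == 0

    def test_hsv_example(self):
        q = np.array([[[0.0, 0.5, 0.25, 1.0]]])
        f1, f2 = symplectic_decompose(q)
        assert f1[0, 0] == 0.5j
        assert f2[0, 0] == 0.25 + 1.0j

    def test_round_trip(self, random_qimage):
        q = random_qimage(4, 4)
        np.testing.assert_allclose(
            symplectic_recompose(*symplectic_decompose(q)), q, atol=1e-15
        )


class TestTransform:
    def test_constant_image_is_dc_only(self):
        q0 = np.array([0.2, -0.4, 0.6, 0.8])
        q = np.broadcast_to(q0, (3, 5, 4))
        Q = hft_forward(q).values
        np.testing.assert_allclose(Q[0, 0], np.sqrt(15) * q0, atol=1e-12)
        rest = Q.copy()
        rest[0, 0] = 0
        assert np.abs(rest).max() < 1e-12

    def test_two_pixel_dft(self, rng):
        a, b = rng.normal(size=(2, 4))
        q = np.stack([a, b])[None, :, :]
        Q = hft_forward(q).values
        np.testing.assert_allclose(Q[0, 0], (a + b) / np.sqrt(2), atol=1e-12)
        np.testing.assert_allclose(Q[0, 1], (a - b) / np.sqrt(2), atol=1e-12)

    @pytest.mark.parametrize("m, n", [(2, 2), (3, 5), (4, 4), (8, 8), (1, 7)])
    def test_matches_bruteforce_oracle(self, m, n, random_qimage):
        q = random_qimage(m, n)
        fast = hft_forward(q).values
        slow = quaternion_dft_bruteforce(q).values
        assert np.abs(fast - slow).max() < 1e-9

    def test_round_trip_identity(self, random_qimage):
        q = random_qimage(16, 16)
        np.testing.assert_allclose(hft_inverse(hft_forward(q)), q, atol=1e-10)

    def test_inverse_of_dc_spectrum_is_constant(self):
        q0 = np.array([1.0, 2.0, 3.0, 4.0])
        spectrum = np.zeros((4, 4, 4))
        spectrum[0, 0] = 4.0 * q0  # sqrt(MN) * q0
        img = hft_inverse(spectrum)
        np.testing.assert_allclose(img, np.broadcast_to(q0, (4, 4, 4)), atol=1e-12)

    def test_zero_spectrum_gives_zero_image(self):
        assert not hft_inverse(np.zeros((3, 3, 4))).any()

    def test_parseval(self, random_qimage):
        q = random_qimage(12, 9)
        energy_space = np.sum(q**2)
        energy_freq = np.sum(hft_forward(q).values ** 2)
        assert abs(energy_space - energy_freq) / energy_space < 1e-10

    def test_bruteforce_guard_and_small_cases(self, random_qimage):
        with pytest.raises(ValueError, match="too large"):
            quaternion_dft_bruteforce(np.zeros((65, 65, 4)))
        q0 = np.array([1.0, -2.0, 0.5, 3.0])
        np.testing.assert_allclose(
            quaternion_dft_bruteforce(q0.reshape(1, 1, 4)).values[0, 0], q0
        )
        const = np.broadcast_to(q0, (2, 2, 4))
        Q = quaternion_dft_bruteforce(const).values
        np.testing.assert_allclose(Q[0, 0], 2 * q0, atol=1e-12)
        assert np.abs(Q[1:, :]).max() < 1e-12 and np.abs(Q[0, 1:]).max() < 1e-12


class TestPolar:
    def test_pure_j_direction(self):
        Q = np.zeros((1, 1, 4))
        Q[0, 0] = [0, 0, 3, 0]
        spec = polar_decompose(QuaternionSpectrum(values=Q))
        assert spec.amplitude[0, 0] == pytest.approx(3.0)
        np.testing.assert_allclose(spec.unit_phase[0, 0], [0, 0, 1, 0])

    def test_complex_subfield_case(self):
        Q = np.zeros((1, 1, 4))
        Q[0, 0] = [1, 1, 0, 0]
        spec = polar_decompose(QuaternionSpectrum(values=Q))
        assert spec.amplitude[0, 0] == pytest.approx(np.sqrt(2))
        np.testing.assert_allclose(
            spec.unit_phase[0, 0], np.array([1, 1, 0, 0]) / np.sqrt(2)
        )

    def test_zero_amplitude_flagged_identity(self):
        spec = polar_decompose(QuaternionSpectrum(values=np.zeros((2, 2, 4))))
        assert spec.zero_mask.all()
        np.testing.assert_array_equal(spec.unit_phase[..., 0], 1.0)
        np.testing.assert_array_equal(spec.unit_phase[..., 1:], 0.0)

    def test_reconstruction_where_nonzero(self, random_qimage):
        spec = polar_decompose(hft_forward(random_qimage(6, 6)))
        rec = spec.amplitude[..., None] * spec.unit_phase
        nz = spec.amplitude > 1e-12
        assert np.abs((rec - spec.values)[nz]).max() < 1e-10
        assert np.abs(qnorm(spec.unit_phase)[~spec.zero_mask] - 1).max() < 1e-12

    def test_fixed_j_axis_reading(self):
        # a spectrum confined to the {1, j} subfield reconstructs under the
        # literal fixed-axis form; general spectra do not
        Q = np.zeros((1, 1, 4))
        Q[0, 0] = [np.sqrt(2), 0, np.sqrt(2), 0]
        spec = polar_decompose(QuaternionSpectrum(values=Q), axis="j")
        rec = spec.amplitude[..., None] * spec.unit_phase
        np.testing.assert_allclose(rec, Q, atol=1e-12)
        with pytest.raises(ValueError, match="axis"):
            polar_decompose(QuaternionSpectrum(values=Q), axis="k")
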