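import numpy as np
import pytest

from gnlsd.gradients import (
    AcquisitionScheme,
    CoilTensor,
    bmatrix_from_bvec,
    bval_max_deviation,
    canonical_hemisphere,
    effective_bmatrix,
    effective_bval_dir,
    effective_gradient,
    mean_effective_bval,
    signal_deviation,
)
from gnlsd.simulate import get_directions


class TestEffectiveGradient:
    @pytest.mark.parametrize("L, g, expected", [
        (np.eye(3), [1, 0, 0], [1, 0, 0]),
        (np.diag([0.87, 0.86, 0.95]), [0, 1, 0], [0, 0.86, 0]),
        (np.diag([1.13, 1.14, 1.05]), [0, 0, 1], [0, 0, 1.05]),
    ])
    def test_matrix_vector_map(self, L, g, expected):
        out = effective_gradient(CoilTensor(L), np.array(g, dtype=float))
        np.testing.assert_allclose(out, expected, atol=1e-15)

    def test_rejects_non_finite(self):
        with pytest.raises(ValueError):
            effective_gradient(CoilTensor(np.eye(3)), np.array([np.nan, 0, 0]))
        with pytest.raises(ValueError):
            CoilTensor(np.full((3, 3), np.inf))


class TestEffectiveBMatrix:
    def test_identity_coil_is_exact(self, rng):
        A = rng.normal(size=(3, 3))
        B = A @ A.T  # random PSD
        out = effective_bmatrix(CoilTensor(np.eye(3)), B)
        np.testing.assert_array_equal(out, B)

    def test_shrunk_x_gradient_bval(self):
        L = CoilTensor(np.diag([0.87, 0.86, 0.95]))
        B = bmatrix_from_bvec(3000.0, [1, 0, 0])
        out = effective_bmatrix(L, B)
        assert np.trace(out) == pytest.approx(3000 * 0.87 ** 2)  # 2270.7

    def test_zero_bmatrix(self, rng):
        L = CoilTensor(rng.normal(size=(3, 3)))
        np.testing.assert_array_equal(effective_bmatrix(L, np.zeros((3, 3))),
                                      np.zeros((3, 3)))

    def test_asymmetric_input_rejected(self):
        B = np.array([[1.0, 2.0, 0], [0, 1, 0], [0, 0, 1]])
        with pytest.raises(ValueError, match="symmetric"):
            effective_bmatrix(CoilTensor(np.eye(3)), B)

    def test_output_psd_for_random_coils(self, rng):
        for _ in range(50):
            L = CoilTensor(np.eye(3) + 0.3 * rng.normal(size=(3, 3)))
            A = rng.normal(size=(3, 3))
            B = A @ A.T
            out = effective_bmatrix(L, B)
            np.testing.assert_allclose(out, out.T, atol=1e-12)
            assert np.trace(out) >= 0
            assert np.linalg.eigvalsh(out).min() >= -1e-10 * np.abs(out).max()

    def test_rank1_trace_identity(self, rng):
        # trace(L B L^T) = b * ||L g||^2 for B = b g g^T
        for _ in range(20):
            g = rng.normal(size=3)
            g /= np.linalg.norm(g)
            L = CoilTensor(np.eye(3) + 0.2 * rng.normal(size=(3, 3)))
            b = float(rng.uniform(500, 5000))
            out = effective_bmatrix(L, bmatrix_from_bvec(b, g))
            assert np.trace(out) == pytest.approx(b * np.linalg.norm(L.L @ g) ** 2)


class TestEffectiveBvalDir:
    def test_pure_y_shell(self):
        b, g = effective_bval_dir(bmatrix_from_bvec(3000.0, [0, 1, 0]))
        assert b == pytest.approx(3000.0)
        np.testing.assert_allclose(g, [0, 1, 0], atol=1e-12)

    def test_diagonal_coil_keeps_axis(self):
        L = CoilTensor(np.diag([0.87, 0.86, 0.95]))
        Beff = effective_bmatrix(L, bmatrix_from_bvec(3000.0, [1, 0, 0]))
        b, g = effective_bval_dir(Beff)
        assert b == pytest.approx(2270.7)
        np.testing.assert_allclose(g, [1, 0, 0], atol=1e-12)

    def test_zero_matrix_flagged(self):
        b, g = effective_bval_dir(np.zeros((3, 3)))
        assert b == 0.0 and g is None


class TestMeanEffectiveBval:
    def test_identity_preserves_shell(self, scheme60):
        assert mean_effective_bval(scheme60, CoilTensor.identity()) == pytest.approx(3000.0)

    def test_negative_deviation_shrinks_to_80_percent(self, scheme60):
        # a diag(-13%,-14%,-5%) coil deviation pulls the shell average down
        # to roughly 80% of the imposed b-value
        L = CoilTensor.from_deviation(np.array([-0.13, -0.14, -0.05]))
        bbar = mean_effective_bval(scheme60, L)
        assert bbar == pytest.approx(0.80 * 3000, rel=0.02)

    def test_single_direction_hand_value(self):
        scheme = AcquisitionScheme(np.array([[1.0, 0, 0]]), np.array([1000.0]))
        L = CoilTensor.from_deviation(np.array([0.1, 0.0, 0.0]))
        assert mean_effective_bval(scheme, L) == pytest.approx(1210.0)

    def test_empty_scheme_rejected(self):
        scheme = AcquisitionScheme(np.zeros((1, 3)), np.zeros(1))
        with pytest.raises(ValueError):
            mean_effective_bval(scheme, CoilTensor.identity())


class TestSignalDeviationModel:
    def test_zero_deviation_and_zero_b(self):
        b = np.linspace(0, 5000, 11)
        np.testing.assert_array_equal(signal_deviation(b, 0.7e-3, 0.0), np.zeros(11))
        assert signal_deviation(0.0, 0.7e-3, -0.15) == 0.0

    @pytest.mark.parametrize("dL, expected", [(-0.05, 1503.1), (-0.15, 1673.3)])
    def test_closed_form_argmax(self, dL, expected):
        assert bval_max_deviation(0.7e-3, dL) == pytest.approx(expected, abs=0.5)

    def test_closed_form_matches_grid_search(self, rng):
        bgrid = np.arange(1.0, 8001.0)
        for _ in range(20):
            D = float(rng.uniform(0.3e-3, 2e-3))
            dL = float(rng.uniform(-0.2, 0.2))
            if abs(dL) < 0.01:
                continue
            bstar = bval_max_deviation(D, dL)
            brute = bgrid[np.argmax(np.abs(signal_deviation(bgrid, D, dL)))]
            assert abs(bstar - brute) <= 1.0

    def test_peak_range_for_moderate_negative_deviations(self):
        # deviations between -15% and -5% at D = 0.7e-3 put the worst-case
        # b-value between 1500 and 2000 s/mm2
        for dL in np.linspace(-0.15, -0.05, 21):
            assert 1500 <= bval_max_deviation(0.7e-3, dL) <= 2000

    def test_zero_deviation_rejected(self):
        with pytest.raises(ValueError):
            bval_max_deviation(0.7e-3, 0.0)


class TestSchemeAndConventions:
    def test_canonical_hemisphere_first_nonzero_positive(self):
        v = canonical_hemisphere(np.array([[-1.0, 0, 0], [0, -2.0, 1.0], [0, 0, -3.0]]))
        np.testing.assert_allclose(v, [[1, 0, 0], [0, 2, -1], [0, 0, 3]])

    def test_scheme_normalizes_and_validates(self):
        with pytest.raises(ValueError):
            AcquisitionScheme(np.zeros((2, 3)), np.array([0.0, 1000.0]))
        s = AcquisitionScheme(np.array([[0, 0, 0], [2.0, 0, 0]]), np.array([0.0, 1000.0]))
        np.testing.assert_allclose(np.linalg.norm(s.directions[1]), 1.0)

    def test_effective_scheme_consistency(self, scheme60):
        L = CoilTensor.from_deviation(np.array([-0.13, -0.14, -0.05]))
        eff = scheme60.effective(L)
        dw = scheme60.dwi_mask
        # b_eff from the b-matrix trace equals b * ||L g||^2 row-wise
        expect = scheme60.bvals[dw] * np.linalg.norm(scheme60.directions[dw] @ L.L.T, axis=1) ** 2
        np.testing.assert_allclose(eff.bvals[dw], expect, rtol=1e-12)
        np.testing.assert_allclose(np.linalg.norm(eff.directions[dw], axis=1), 1.0)

    def test_direction_fixture_is_hemisphere_unit(self):
        d = get_directions(60)
        assert d.shape == (60, 3)
        np.testing.assert_allclose(np.linalg.norm(d, axis=1), 1.0, atol=1e-10)
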