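import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from gnlsd.gradients import CoilTensor, bmatrix_from_bvec
from gnlsd.simulate import (
    FiberConfig,
    NoiseModel,
    PhantomSpec,
    add_rician_noise,
    build_phantom,
    generate_directions,
    get_directions,
    make_scheme,
    scenario,
    tensor_signal,
)


class TestTensorSignal:
    def test_b0_returns_s0(self):
        cfg = FiberConfig(np.array([[1.0, 0, 0]]))
        assert tensor_signal(cfg, np.zeros((3, 3)), S0=2.5) == pytest.approx(2.5)

    def test_parallel_and_perpendicular_attenuation(self):
        cfg = FiberConfig(np.array([[1.0, 0, 0]]))
        Bpar = bmatrix_from_bvec(3000.0, [1, 0, 0])
        Bperp = bmatrix_from_bvec(3000.0, [0, 1, 0])
        assert tensor_signal(cfg, Bpar) == pytest.approx(np.exp(-5.1))   # 0.00610
        assert tensor_signal(cfg, Bperp) == pytest.approx(np.exp(-0.6))  # 0.5488

    def test_crossing_is_fraction_weighted_sum(self):
        o = np.array([[1.0, 0, 0], [0, 1.0, 0]])
        cfg = FiberConfig(o, [0.5, 0.5])
        B = bmatrix_from_bvec(3000.0, [1, 0, 0])
        expect = 0.5 * np.exp(-5.1) + 0.5 * np.exp(-0.6)
        assert tensor_signal(cfg, B) == pytest.approx(expect)

    def test_rotation_invariance(self, rng):
        dirs = get_directions(60)
        bm = np.array([bmatrix_from_bvec(3000.0, d) for d in dirs])
        for _ in range(5):
            R = Rotation.random(random_state=rng).as_matrix()
            cfg = FiberConfig(np.array([[1.0, 0, 0], [0, 1, 0]]), [0.6, 0.4])
            cfg_rot = FiberConfig(cfg.orientations @ R.T, [0.6, 0.4])
            bm_rot = np.einsum("ab,mbc,dc->mad", R, bm, R)
            np.testing.assert_allclose(tensor_signal(cfg_rot, bm_rot),
                                       tensor_signal(cfg, bm), atol=1e-10)

    def test_invalid_fractions_rejected(self):
        with pytest.raises(ValueError):
            FiberConfig(np.array([[1.0, 0, 0], [0, 1, 0]]), [0.7, 0.7])


class TestRicianNoise:
    def test_vanishes_at_infinite_snr(self, rng):
        S = np.full(100, 0.4)
        out = add_rician_noise(S, NoiseModel(1e12), rng=rng)
        np.testing.assert_allclose(out, S, atol=1e-9)

    def test_second_moment_identity(self, rng):
        # E[noisy^2] = S^2 + 2 sigma^2 for Rician magnitudes
        S, snr = 0.5, 10.0
        sigma = 1.0 / snr
        draws = add_rician_noise(np.full(100_000, S), NoiseModel(snr), rng=rng)
        assert np.mean(draws ** 2) == pytest.approx(S ** 2 + 2 * sigma ** 2, rel=0.01)

    def test_rayleigh_mean_at_zero_signal(self, rng):
        snr = 30.0
        sigma = 1.0 / snr
        draws = add_rician_noise(np.zeros(100_000), NoiseModel(snr), rng=rng)
        assert np.mean(draws) == pytest.approx(sigma * np.sqrt(np.pi / 2), rel=0.02)

    def test_high_snr_variance(self, rng):
        # for S >> sigma the magnitude noise is approximately N(S, sigma^2)
        snr = 30.0
        draws = add_rician_noise(np.ones(100_000), NoiseModel(snr), rng=rng)
        assert np.var(draws) == pytest.approx((1 / snr) ** 2, rel=0.05)

    def test_invalid_snr(self):
        with pytest.raises(ValueError):
            NoiseModel(-5.0)


class TestDirections:
    def test_small_set_well_separated(self):
        d = generate_directions(6, seed=0)
        c = np.abs(d @ d.T)
        np.fill_diagonal(c, 0.0)
        min_angle = np.degrees(np.arccos(c.max()))
        assert min_angle >= 60.0

    def test_unit_norm(self):
        d = generate_directions(20, seed=3)
        np.testing.assert_allclose(np.linalg.norm(d, axis=1), 1.0, atol=1e-10)

    def test_fixture_stable_across_loads(self):
        np.testing.assert_array_equal(get_directions(60), get_directions(60))

    def test_too_few_rejected(self):
        with pytest.raises(ValueError):
            generate_directions(3)


class TestScenarios:
    def test_simulation_one_configuration(self):
        cfg = scenario("I")
        assert len(cfg.cells) == 3
        cell = cfg.cells[0]
        assert cell.bval == 3000.0 and cell.n_dirs == 60 and cell.snr == 30.0
        assert cell.n_reps == 10_000
        np.testing.assert_allclose(np.diag(cell.coil.deviation), [-0.13, -0.14, -0.05])
        fibers = {c.label: c.fibers.orientations[0] for c in cfg.cells}
        np.testing.assert_allclose(fibers["fiber-x"], [1, 0, 0])
        np.testing.assert_allclose(fibers["fiber-z"], [0, 0, 1])

    def test_simulation_three_grid(self):
        cfg = scenario("III")
        assert all(c.n_dirs == 90 for c in cfg.cells)
        labels = {c.label for c in cfg.cells}
        assert "baseline" in labels and "dev-y-0.2" in labels
        cell = next(c for c in cfg.cells if c.label == "dev-y-0.2")
        np.testing.assert_allclose(np.diag(cell.coil.deviation), [0, -0.2, 0])

    def test_simulation_five_crossings(self):
        cfg = scenario("V")
        angles = set()
        for c in cfg.cells:
            o = c.fibers.orientations
            ang = np.degrees(np.arccos(abs(o[0] @ o[1])))
            angles.add(round(ang))
            np.testing.assert_allclose(c.fibers.fractions, [0.5, 0.5])
        assert angles == {90, 75, 60, 45}

    def test_unknown_id_rejected(self):
        with pytest.raises(ValueError):
            scenario("VI")


class TestPhantom:
    def test_identity_coil_noiseless_matches_direct_signal(self):
        spec = PhantomSpec(shape=(3, 3, 3), corner_deviation=(0, 0, 0), snr=None)
        scheme = make_scheme(3000.0, 12)
        vol, truth, coil = build_phantom(spec, scheme)
        np.testing.assert_array_equal(coil, np.broadcast_to(np.eye(3), coil.shape))
        idx = (0, 2, 1)
        cfg = FiberConfig(truth[idx][None, :])
        np.testing.assert_allclose(vol[idx], tensor_signal(cfg, scheme.bmatrices),
                                   atol=1e-12)

    def test_isocenter_voxel_is_identity(self):
        spec = PhantomSpec(shape=(5, 5, 3), snr=None)
        coil = spec.coil_field()
        np.testing.assert_allclose(coil[2, 2, 1], np.eye(3), atol=1e-15)

    def test_corner_matches_single_voxel_simulation(self):
        spec = PhantomSpec(shape=(3, 3, 3), corner_deviation=(-0.13, -0.14, -0.05),
                           snr=None)
        scheme = make_scheme(3000.0, 12)
        vol, truth, coil = build_phantom(spec, scheme)
        L = CoilTensor(coil[0, 0, 0])
        np.testing.assert_allclose(np.diag(L.deviation), [-0.13, -0.14, -0.05])
        cfg = FiberConfig(truth[0, 0, 0][None, :])
        expect = tensor_signal(cfg, scheme.effective(L).bmatrices)
        np.testing.assert_allclose(vol[0, 0, 0], expect, atol=1e-12)

    def test_deviation_monotone_from_isocenter(self):
        spec = PhantomSpec(shape=(9, 9, 5), snr=None)
        coil = spec.coil_field()
        norm = np.linalg.norm(coil - np.eye(3), axis=(-2, -1))
        mid = (4, 4, 2)
        for axis in range(3):
            line = [norm[tuple(np.array(mid) + step * np.eye(3, dtype=int)[axis])]
                    for step in range(0, spec.shape[axis] - mid[axis])]
            assert np.all(np.diff(line) >= -1e-15)

    def test_shape_mismatch_rejected(self, monkeypatch):
        spec = PhantomSpec(shape=(3, 3, 3), snr=None)
        scheme = make_scheme(1000.0, 6)
        orig = PhantomSpec.orientation_field
        monkeypatch.setattr(PhantomSpec, "orientation_field",
                            lambda self: orig(self)[:2])
        with pytest.raises(ValueError, match="shape"):
            build_phantom(spec, scheme)
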