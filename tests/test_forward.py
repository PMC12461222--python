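"""Polychromatic projection, mismatch decomposition, noise and motion."""

import numpy as np
import pytest

import cbctlab as cl


class TestPolyProject:
    def test_toy_single_and_double_metal_values(self, toy_phantom, toy_spectrum, toy_matrix):
        P = cl.poly_project(toy_phantom, toy_spectrum, toy_matrix).values.ravel()
        single = -np.log(0.5 * np.exp(-64.0) + 0.5 * np.exp(-5.0))
        double = -np.log(0.5 * np.exp(-128.0) + 0.5 * np.exp(-10.0))
        # rays through one metal pixel: (0,1), (0,3), (pi/4,1), (pi/4,3)
        for i in (0, 2, 3, 5):
            assert P[i] == pytest.approx(single, abs=1e-9)
        assert P[7] == pytest.approx(double, abs=1e-9)
        assert P[single == P].size or P[1] == pytest.approx(0.0, abs=1e-12)

    def test_beam_hardening_subadditivity(self, toy_phantom, toy_spectrum, toy_matrix):
        P = cl.poly_project(toy_phantom, toy_spectrum, toy_matrix).values.ravel()
        assert P[7] < 2 * P[0]  # doubling the metal path is subadditive

    def test_delta_spectrum_reduces_to_radon(self, dental64, sm64):
        spec = cl.make_spectrum([70.0], [1.0])
        P = cl.poly_project(dental64, spec, sm64).values
        R = cl.forward_project(sm64, cl.monochrome_image(dental64, 70.0))
        np.testing.assert_allclose(P, R, atol=1e-12)

    def test_monotone_in_added_material(self, dental64, dental_spectrum, sm64):
        with_metal = cl.insert_metal(dental64, (42, 26), 3)
        P0 = cl.poly_project(dental64, dental_spectrum, sm64).values
        P1 = cl.poly_project(with_metal, dental_spectrum, sm64).values
        assert np.all(P1 >= P0 - 1e-12)


class TestMismatch:
    def test_decomposition_identity(self, dental64_metal, dental_spectrum, sm64):
        ref = cl.monochrome_image(dental64_metal, 90.0)
        P = cl.poly_project(dental64_metal, dental_spectrum, sm64).values
        z = cl.mismatch_zeta_u(dental64_metal, dental_spectrum, sm64, ref).values
        np.testing.assert_allclose(P, cl.forward_project(sm64, ref) + z, atol=1e-10)

    def test_delta_spectrum_zero_mismatch(self, dental64, sm64):
        spec = cl.make_spectrum([70.0], [1.0])
        ref = cl.monochrome_image(dental64, 70.0)
        z = cl.mismatch_zeta_u(dental64, spec, sm64, ref).values
        np.testing.assert_allclose(z, 0.0, atol=1e-12)

    def test_toy_mismatch_on_double_metal_ray(self, toy_phantom, toy_spectrum, toy_matrix):
        single = -np.log(0.5 * np.exp(-64.0) + 0.5 * np.exp(-5.0))
        ideal = np.zeros((3, 3))
        ideal[1, 0] = ideal[1, 2] = single
        z = cl.mismatch_zeta_u(toy_phantom, toy_spectrum, toy_matrix, ideal).values.ravel()
        double = -np.log(0.5 * np.exp(-128.0) + 0.5 * np.exp(-10.0))
        assert z[7] == pytest.approx(double - 2 * single, abs=1e-9)

    def test_air_phantom_zero_reference_zero_mismatch(self, toy_spectrum):
        labels = np.zeros((3, 3), dtype=np.int64)
        ph = cl.Phantom(labels, 1.0, {0: cl.MATERIAL_PRESETS["air"]})
        sm = cl.build_system_matrix(cl.toy_geometry(), (3, 3), 1.0)
        z = cl.mismatch_zeta_u(ph, toy_spectrum, sm, np.zeros((3, 3))).values
        np.testing.assert_allclose(z, 0.0, atol=1e-14)


class TestNoise:
    def test_air_scan_high_flux_near_zero(self, toy_spectrum):
        labels = np.zeros((8, 8), dtype=np.int64)
        ph = cl.Phantom(labels, 1.0, {0: cl.MATERIAL_PRESETS["air"]})
        geom = cl.parallel_geometry(10, 11)
        sm = cl.build_system_matrix(geom, (8, 8), 1.0)
        sino = cl.poly_project(ph, toy_spectrum, sm)
        noisy = cl.add_photon_noise(sino, ph, toy_spectrum, sm, I_in=1e12, rng_seed=1)
        assert np.abs(noisy.values).max() < 1e-5

    def test_deterministic_under_seed(self, dental64, dental_spectrum, sm64):
        sino = cl.poly_project(dental64, dental_spectrum, sm64)
        a = cl.add_photon_noise(sino, dental64, dental_spectrum, sm64, 1e5, 2.0, rng_seed=7)
        b = cl.add_photon_noise(sino, dental64, dental_spectrum, sm64, 1e5, 2.0, rng_seed=7)
        np.testing.assert_array_equal(a.values, b.values)

    def test_monte_carlo_mean_matches_noiseless(self, dental_spectrum):
        """Mean of repeated noisy realisations of a mid-attenuation ray
        stays within 3 standard errors of the noiseless value."""
        ph = cl.make_dental_phantom(32, seed=2)
        geom = cl.parallel_geometry(4, 31)
        sm = cl.build_system_matrix(geom, (32, 32), 1.0)
        sino = cl.poly_project(ph, dental_spectrum, sm)
        ray = np.unravel_index(np.argmin(np.abs(sino.values - 1.0)), sino.values.shape)
        vals = [cl.add_photon_noise(sino, ph, dental_spectrum, sm, 1e5,
                                    rng_seed=s).values[ray] for s in range(300)]
        vals = np.asarray(vals)
        se = vals.std(ddof=1) / np.sqrt(vals.size)
        # noisy log values carry a small Jensen bias ~ 1/(2 I_exit)
        assert abs(vals.mean() - sino.values[ray]) < 3 * se + 1e-3

    def test_rejects_nonpositive_flux(self, dental64, dental_spectrum, sm64):
        sino = cl.poly_project(dental64, dental_spectrum, sm64)
        with pytest.raises(ValueError):
            cl.add_photon_noise(sino, dental64, dental_spectrum, sm64, 0.0)


@pytest.fixture(scope="module")
def motion_setup(dental64_metal, dental_spectrum, sm64):
    static = cl.poly_project(dental64_metal, dental_spectrum, sm64)
    traj = cl.make_motion_trajectory(90, (20, 35), 4.0, 3, seed=3)
    moved = cl.motion_corrupt(dental64_metal, traj, sm64, dental_spectrum)
    return static, traj, moved


class TestMotion:

    def test_zero_trajectory_identical(self, dental64_metal, dental_spectrum, sm64):
        traj = cl.make_motion_trajectory(90, (20, 35), 0.0, 3, seed=0)
        moved = cl.motion_corrupt(dental64_metal, traj, sm64, dental_spectrum)
        static = cl.poly_project(dental64_metal, dental_spectrum, sm64)
        np.testing.assert_array_equal(moved.values, static.values)

    def test_views_outside_window_bitwise_static(self, motion_setup):
        static, traj, moved = motion_setup
        outside = traj.displacements == 0.0
        assert outside.sum() >= 75
        np.testing.assert_array_equal(moved.values[outside], static.values[outside])
        assert np.abs(moved.values[~outside] - static.values[~outside]).max() > 1e-3

    def test_integer_shift_preserves_view_mass(self, dental_spectrum):
        """An integer-pixel shift of an interior phantom conserves each
        view's total ray sum on an untruncated parallel detector."""
        ph = cl.make_dental_phantom(32, seed=5)
        # embed in a larger grid so shifts stay interior
        labels = np.zeros((48, 48), dtype=np.int64)
        labels[8:40, 8:40] = ph.labels
        big = cl.Phantom(labels, 1.0, dict(ph.material_map))
        geom = cl.parallel_geometry(6, 95, angular_range=np.pi)
        sm = cl.build_system_matrix(geom, (48, 48), 1.0)
        spec = cl.make_spectrum([70.0], [1.0])  # mono so sums are linear
        d = np.zeros(6)
        d[2] = 3.0
        traj = cl.MotionTrajectory(d, (2, 3), 5.0)
        moved = cl.motion_corrupt(big, traj, sm, spec)
        static = cl.poly_project(big, spec, sm)
        np.testing.assert_allclose(moved.values[2].sum(), static.values[2].sum(),
                                   rtol=1e-6)

    def test_trajectory_length_mismatch_raises(self, dental64_metal, dental_spectrum, sm64):
        traj = cl.make_motion_trajectory(10, (2, 5), 1.0, 1, seed=0)
        with pytest.raises(ValueError):
            cl.motion_corrupt(dental64_metal, traj, sm64, dental_spectrum)
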