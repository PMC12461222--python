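"""Classical reconstruction: FBP, FDK, least squares, TV, MAR inpainting."""

import numpy as np
import pytest

import cbctlab as cl
from cbctlab.phantoms import METAL


class TestFBP:
    def test_uniform_disc_recovered(self):
        """Analytic disc sinogram (chord lengths) reconstructs to ~1
        inside the disc."""
        geom = cl.parallel_geometry(360, 185)
        s = geom.det_coords_u()
        R = 32.0
        vals = np.tile(2 * np.sqrt(np.maximum(R**2 - s**2, 0.0)), (360, 1))
        rec = cl.fbp2d(cl.Sinogram(vals, geom), grid_shape=(128, 128))
        X, Y = np.meshgrid(np.arange(128) - 63.5, 63.5 - np.arange(128))
        inside = X**2 + Y**2 < (0.8 * R) ** 2
        assert rec.image[inside].mean() == pytest.approx(1.0, abs=0.05)

    def test_zero_sinogram_zero_image(self, par_geom90):
        rec = cl.fbp2d(cl.Sinogram(np.zeros((90, 95)), par_geom90),
                       grid_shape=(64, 64))
        assert not rec.image.any()

    def test_linearity(self, par_geom90, rng):
        p1 = rng.random((90, 95))
        p2 = rng.random((90, 95))
        a, b = 2.0, -0.7
        lhs = cl.fbp2d(cl.Sinogram(a * p1 + b * p2, par_geom90), grid_shape=(64, 64)).image
        rhs = (a * cl.fbp2d(cl.Sinogram(p1, par_geom90), grid_shape=(64, 64)).image
               + b * cl.fbp2d(cl.Sinogram(p2, par_geom90), grid_shape=(64, 64)).image)
        np.testing.assert_allclose(lhs, rhs, atol=1e-10)

    def test_metal_streaks_energy_exceeds_metal_free(
            self, dental64, dental64_metal, dental_spectrum, sm64):
        """Bichromatic two-metal data produce streaks: RMSE vs the
        metal-free reference (outside metal) strictly exceeds the
        metal-free reconstruction's RMSE."""
        ref = cl.monochrome_image(dental64, 90.0)
        out = dental64_metal.labels != METAL
        rec_free = cl.fbp2d(cl.poly_project(dental64, dental_spectrum, sm64),
                            grid_shape=(64, 64)).image
        rec_metal = cl.fbp2d(cl.poly_project(dental64_metal, dental_spectrum, sm64),
                             grid_shape=(64, 64)).image
        rmse_free = cl.compute_metrics(rec_free, ref, out)["rmse"]
        rmse_metal = cl.compute_metrics(rec_metal, ref, out)["rmse"]
        assert rmse_metal > rmse_free

    def test_unsupported_geometry_rejected(self):
        geom = cl.cone_geometry(4, 8, 4, 1.0, 50.0, 50.0)
        with pytest.raises(ValueError):
            cl.fbp2d(cl.Sinogram(np.zeros((4, 8, 4)), geom))

    def test_unknown_filter_rejected(self, par_geom90):
        with pytest.raises(ValueError):
            cl.fbp2d(cl.Sinogram(np.zeros((90, 95)), par_geom90), "hann")


@pytest.fixture(scope="module")
def cone_setup():
    ph2 = cl.make_dental_phantom(48, seed=1)
    ns = 9
    labels3 = np.repeat(ph2.labels[:, :, None], ns, axis=2)
    ph3 = cl.Phantom(labels3, 1.0, dict(ph2.material_map))
    geom3 = cl.cone_geometry(150, 95, 31, 1.2, 200.0, 200.0)
    sm3 = cl.build_system_matrix(geom3, ph3.shape, 1.0)
    u3 = cl.monochrome_image(ph3, 70.0)
    sino3 = cl.Sinogram(cl.forward_project(sm3, u3), geom3)
    return ph2, ns, geom3, sino3


class TestFDK:

    def test_midplane_matches_fan_fbp(self, cone_setup):
        """FDK is exact in the midplane: its central slice agrees with
        fan-beam FBP of the midplane sinogram."""
        ph2, ns, geom3, sino3 = cone_setup
        rec3 = cl.fdk3d(sino3, (48, 48, ns), 1.0)
        mid = rec3.image[:, :, ns // 2]
        geomf = cl.fan_geometry(150, 95, 1.2, 200.0, 200.0)
        smf = cl.build_system_matrix(geomf, (48, 48), 1.0)
        sinof = cl.Sinogram(
            cl.forward_project(smf, cl.monochrome_image(ph2, 70.0)), geomf)
        recf = cl.fbp2d(sinof, grid_shape=(48, 48))
        rmse = cl.compute_metrics(mid, recf.image)["rmse"]
        assert rmse < 0.05 * np.abs(recf.image).max()

    def test_zero_sinogram_zero_volume(self, cone_setup):
        _, ns, geom3, sino3 = cone_setup
        rec = cl.fdk3d(cl.Sinogram(np.zeros_like(sino3.values), geom3), (48, 48, ns))
        assert not rec.image.any()

    def test_wrong_geometry_rejected(self, par_geom90):
        with pytest.raises(ValueError):
            cl.fdk3d(cl.Sinogram(np.zeros((90, 95)), par_geom90), (8, 8, 4))


class TestLsqMinnorm:
    def test_identity_system_reproduces_input(self):
        from scipy import sparse

        geom = cl.parallel_geometry(1, 9)
        sm = cl.SystemMatrix(sparse.identity(9, format="csr"), geom, (3, 3), 1.0)
        rng = np.random.default_rng(1)
        p = rng.random(9)
        rec = cl.lsq_minnorm(sm, p.reshape(1, 9))
        np.testing.assert_allclose(rec.image.ravel(), p, atol=1e-10)

    def test_consistent_toy_recovers_ideal(self, toy_matrix):
        single = -np.log(0.5 * np.exp(-64.0) + 0.5 * np.exp(-5.0))
        p = cl.forward_project(
            toy_matrix,
            np.array([[0, 0, 0], [single, 0, single], [0, 0, 0]]))
        rec = cl.lsq_minnorm(toy_matrix, p)
        ideal = np.zeros((3, 3))
        ideal[1, 0] = ideal[1, 2] = single
        np.testing.assert_allclose(rec.image, ideal, atol=1e-9)

    def test_solution_orthogonal_to_null_space(self, toy_matrix, toy_phantom,
                                               toy_spectrum):
        P = cl.poly_project(toy_phantom, toy_spectrum, toy_matrix)
        rec = cl.lsq_minnorm(toy_matrix, P)
        null = np.array([-1, 1, 0, 1, 0, -1, 0, -1, 1], dtype=float)
        assert abs(rec.image.ravel() @ null) < 1e-9

    def test_normal_equations_satisfied(self, sm64, dental64, dental_spectrum):
        P = cl.poly_project(dental64, dental_spectrum, sm64)
        rec = cl.lsq_minnorm(sm64, P)
        A = sm64.matrix
        g = A.T @ (A @ rec.image.ravel() - P.values.ravel())
        assert np.linalg.norm(g) <= 1e-8 * np.linalg.norm(A.T @ P.values.ravel())


class TestTV:
    def test_lambda_zero_converges_to_least_squares(self):
        # well-conditioned full-rank system: FISTA with lam=0 is plain
        # accelerated gradient descent on the least-squares objective
        geom = cl.parallel_geometry(60, 15)
        sm = cl.build_system_matrix(geom, (8, 8), 1.0)
        rng = np.random.default_rng(0)
        u_true = rng.random((8, 8)) * 0.05
        sino = cl.Sinogram(cl.forward_project(sm, u_true), geom)
        u_ls = cl.lsq_minnorm(sm, sino).image
        rec = cl.tv_reconstruct(sm, sino, lam=0.0, n_iters=500)
        assert np.linalg.norm(rec.image - u_ls) < 1e-4

    def test_piecewise_constant_recovery(self):
        ph = cl.make_dental_phantom(32, seed=3)
        geom = cl.parallel_geometry(60, 47)
        sm = cl.build_system_matrix(geom, (32, 32), 1.0)
        u_true = cl.monochrome_image(ph, 70.0)
        sino = cl.Sinogram(cl.forward_project(sm, u_true), geom)
        rec = cl.tv_reconstruct(sm, sino, lam=0.05, n_iters=300)
        rmse = cl.compute_metrics(rec.image, u_true)["rmse"]
        assert rmse < 0.02 * (u_true.max() - u_true.min())

    def test_objective_trace_non_increasing(self, sm64, dental64, dental_spectrum):
        sino = cl.poly_project(dental64, dental_spectrum, sm64)
        rec = cl.tv_reconstruct(sm64, sino, lam=0.02, n_iters=40)
        assert np.all(np.diff(rec.objective_trace) <= 1e-9 * rec.objective_trace[0])


class TestMarInpaint:
    def test_empty_mask_noop(self, sm64, dental64, dental_spectrum):
        sino = cl.poly_project(dental64, dental_spectrum, sm64)
        out = cl.mar_inpaint(sino, np.zeros((64, 64)), sm64)
        np.testing.assert_array_equal(out.values, sino.values)

    def test_constant_sinogram_unchanged(self, sm64, dental64_metal):
        vals = np.full((90, 95), 2.5)
        sino = cl.Sinogram(vals, sm64.geometry)
        mask = (dental64_metal.labels == METAL).astype(float)
        out = cl.mar_inpaint(sino, mask, sm64)
        np.testing.assert_allclose(out.values, 2.5, atol=1e-12)

    def test_single_gap_linear_midpoint(self):
        geom = cl.parallel_geometry(1, 5)
        sm = cl.build_system_matrix(geom, (5, 5), 1.0)
        vals = np.array([[1.0, 2.0, 99.0, 4.0, 5.0]])
        mask = np.zeros((5, 5))
        mask[:, 2] = 1.0  # metal column -> trace is detector cell 2 at view 0
        out = cl.mar_inpaint(cl.Sinogram(vals, geom), mask, sm)
        assert out.values[0, 2] == pytest.approx(3.0, abs=1e-12)
        np.testing.assert_array_equal(out.values[0, [0, 1, 3, 4]],
                                      vals[0, [0, 1, 3, 4]])

    def test_trace_equals_geometric_intersection(self, sm64, dental64_metal,
                                                 dental_spectrum):
        mask = (dental64_metal.labels == METAL).astype(float)
        trace = cl.forward_project(sm64, mask) > 1e-12
        sino = cl.poly_project(dental64_metal, dental_spectrum, sm64)
        out = cl.mar_inpaint(sino, mask, sm64)
        changed = out.values != sino.values
        assert np.all(trace[changed])  # only trace rays modified
        assert not np.any(changed & ~trace)

    def test_full_view_trace_falls_back_to_mean(self):
        geom = cl.parallel_geometry(1, 3)
        sm = cl.build_system_matrix(geom, (3, 3), 1.0)
        vals = np.array([[1.0, 2.0, 3.0]])
        mask = np.ones((3, 3))
        out = cl.mar_inpaint(cl.Sinogram(vals, geom), mask, sm)
        np.testing.assert_allclose(out.values, 2.0)
        assert "mean-fill" in out.provenance
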