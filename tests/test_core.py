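import numpy as np
import pytest

import lvtrack as lt
from lvtrack.baselines import lk_track_step
from lvtrack.core import (
    ContourState,
    ShapeBasis,
    SingularShapeError,
    TrackerConfig,
    assemble_global_system,
    local_system,
    solve_step,
)

from conftest import make_textured_pair


class TestGaussianWindow:
    @pytest.mark.parametrize("side", [2, 4, 0, -3, 1])
    def test_rejects_bad_side(self, side):
        with pytest.raises(ValueError):
            lt.gaussian_window(side, 5.0)

    def test_rejects_nonpositive_sigma(self):
        with pytest.raises(ValueError):
            lt.gaussian_window(21, 0.0)

    def test_center_weight_is_maximum(self):
        w = lt.gaussian_window(21, 5.0)
        assert w.weights[10, 10] == w.weights.max() == 1.0

    def test_flat_limit_unit_sum(self):
        w = lt.gaussian_window(3, 1e6, normalize="sum")
        assert np.allclose(w.weights, 1.0 / 9.0, atol=1e-6)

    def test_matches_direct_formula(self):
        # brute-force elementwise evaluation of the Gaussian
        side, sigma = 5, 2.0
        expected = np.empty((side, side))
        for i in range(side):
            for j in range(side):
                dx, dy = j - 2, i - 2
                expected[i, j] = np.exp(-(dx**2 + dy**2) / (2 * sigma**2))
        w = lt.gaussian_window(side, sigma)
        assert np.allclose(w.weights, expected, atol=1e-12)
        w_sum = lt.gaussian_window(side, sigma, normalize="sum")
        assert np.allclose(w_sum.weights, expected / expected.sum(), atol=1e-12)

    def test_reflection_symmetry(self):
        w = lt.gaussian_window(9, 2.5)
        assert np.allclose(w.weights, w.weights[::-1, :])
        assert np.allclose(w.weights, w.weights[:, ::-1])


class TestImageDerivatives:
    def test_constant_frames(self):
        f = np.full((20, 30), 7.0)
        grad, dt = lt.image_derivatives(f, f)
        assert np.allclose(grad, 0) and np.allclose(dt, 0)

    def test_linear_ramp(self):
        y, x = np.mgrid[0:20, 0:30]
        f = 2.0 * x + 3.0 * y
        grad, dt = lt.image_derivatives(f, f)
        assert np.allclose(grad[1:-1, 1:-1, 0], 2.0)
        assert np.allclose(grad[1:-1, 1:-1, 1], 3.0)
        assert np.allclose(dt, 0.0)

    def test_temporal_offset(self):
        f = np.random.default_rng(0).random((15, 15))
        _, dt = lt.image_derivatives(f, f + 7.0)
        assert np.allclose(dt, 7.0)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError, match="differ"):
            lt.image_derivatives(np.zeros((5, 5)), np.zeros((6, 5)))


class TestLocalSystem:
    def test_zero_temporal_zero_lam(self, window, rng):
        frame = rng.random((64, 64)) * 100
        grad, dt = lt.image_derivatives(frame, frame)
        ls = local_system(grad, dt, (30.0, 30.0), window, lam=0.0)
        assert ls.xi == pytest.approx(0.0, abs=1e-12)
        assert ls.eta == pytest.approx(0.0, abs=1e-12)

    def test_pure_lambda_terms(self, window):
        frame = np.full((64, 64), 5.0)  # zero gradient everywhere
        grad, dt = lt.image_derivatives(frame, frame)
        ls = local_system(grad, dt, (10.0, 20.0), window, lam=2.0)
        assert ls.alpha == pytest.approx(2.0) and ls.gamma == pytest.approx(2.0)
        assert ls.beta == pytest.approx(0.0)
        assert (ls.xi, ls.eta) == (pytest.approx(20.0), pytest.approx(40.0))

    def test_matches_double_loop_oracle(self, window, rng):
        frame_t = rng.random((64, 64)) * 100
        frame_n = rng.random((64, 64)) * 100
        grad, dt = lt.image_derivatives(frame_t, frame_n)
        px, py = 31, 29  # integer-centered, fully interior window
        lam = 3.5
        ls = local_system(grad, dt, (px, py), window, lam)
        a = b = g = xi = eta = 0.0
        h = window.side // 2
        for i in range(window.side):
            for j in range(window.side):
                wv = window.weights[i, j]
                gx = grad[py + i - h, px + j - h, 0]
                gy = grad[py + i - h, px + j - h, 1]
                bt = dt[py + i - h, px + j - h]
                a += wv * gx * gx
                b += wv * gx * gy
                g += wv * gy * gy
                xi += wv * gx * bt
                eta += wv * gy * bt
        assert ls.alpha == pytest.approx(a + lam, abs=1e-10)
        assert ls.beta == pytest.approx(b, abs=1e-10)
        assert ls.gamma == pytest.approx(g + lam, abs=1e-10)
        assert ls.xi == pytest.approx(xi + lam * px, abs=1e-10)
        assert ls.eta == pytest.approx(eta + lam * py, abs=1e-10)

    def test_point_outside_image(self, window, rng):
        frame = rng.random((40, 40))
        grad, dt = lt.image_derivatives(frame, frame)
        ls = local_system(grad, dt, (-100.0, -100.0), window, lam=4.0)
        assert ls.out_of_image
        assert ls.alpha == 4.0 and ls.gamma == 4.0 and ls.beta == 0.0


class TestShapeSpace:
    def test_design_matrix_triangle(self):
        phi = lt.build_design_matrix([(0, 0), (1, 0), (0, 1)])
        assert np.array_equal(phi, [[0, 0, 1], [1, 0, 1], [0, 1, 1]])

    def test_design_matrix_reference_points(self):
        phi = lt.build_design_matrix(lt.TABLE1_POINTS[0])
        assert phi.shape == (13, 3)
        assert np.array_equal(phi[0], [152.0, 201.0, 1.0])
        assert np.all(phi[:, 2] == 1.0)

    def test_design_matrix_needs_three_points(self):
        with pytest.raises(ValueError):
            lt.build_design_matrix([(0, 0), (1, 1)])

    def test_projection_three_points_is_identity(self):
        phi = lt.build_design_matrix([(0, 0), (4, 1), (2, 5)])
        assert np.allclose(lt.projection_matrix(phi), np.eye(3), atol=1e-10)

    def test_projection_matches_pseudoinverse_oracle(self):
        phi = lt.build_design_matrix(lt.TABLE1_POINTS[0])
        P = lt.projection_matrix(phi)
        P_oracle = phi @ np.linalg.pinv(phi)
        assert np.allclose(P, P_oracle, atol=1e-8)
        assert np.trace(P) == pytest.approx(3.0, abs=1e-9)
        assert np.allclose(P @ phi, phi, atol=1e-9)
        assert np.allclose(P, P.T, atol=1e-12)
        assert np.allclose(P @ P, P, atol=1e-9)

    def test_collinear_points_raise(self):
        pts = [(0.0, 0.0), (1.0, 1.0), (2.0, 2.0), (3.0, 3.0)]
        with pytest.raises(SingularShapeError):
            lt.projection_matrix(lt.build_design_matrix(pts))

    def test_affine_identity(self):
        pts = lt.TABLE1_POINTS[0]
        phi = lt.build_design_matrix(pts)
        aff = lt.affine_coefficients(phi, pts)
        assert np.allclose(aff.as_tuple(), (1, 0, 0, 1, 0, 0), atol=1e-10)

    def test_affine_recovers_contraction(self):
        # exactly transformed points give back the generating coefficients
        pts = lt.TABLE1_POINTS[0]
        phi = lt.build_design_matrix(pts)
        targets = lt.CONTRACTION_AFFINE.apply(pts)
        aff = lt.affine_coefficients(phi, targets)
        assert np.allclose(aff.as_tuple(), lt.CONTRACTION_AFFINE.as_tuple(), atol=1e-8)

    def test_affine_matches_normal_equation_oracle(self, rng):
        pts = rng.random((10, 2)) * 100
        targets = rng.random((10, 2)) * 100
        phi = lt.build_design_matrix(pts)
        aff = lt.affine_coefficients(phi, targets)
        C = np.linalg.solve(phi.T @ phi, phi.T @ targets)
        oracle = (C[0, 0], C[1, 0], C[0, 1], C[1, 1], C[2, 0], C[2, 1])
        assert np.allclose(aff.as_tuple(), oracle, atol=1e-10)


class TestSolveStep:
    def test_lambda_zero_equals_pointwise_lk(self, window, table1_scene):
        pts = lt.TABLE1_POINTS[0]
        contour = ContourState(pts, pts)
        shape = ShapeBasis.from_points(pts)
        f0, f1 = table1_scene.frames[0], table1_scene.frames[1]
        disp, _ = solve_step(f0, f1, contour, shape, TrackerConfig(lam=0.0, window=window))
        lk, _ = lk_track_step(f0, f1, pts, window)
        assert np.max(np.abs(disp - lk)) < 1e-8

    def test_zero_temporal_affine_points_zero_displacement(self, window, rng):
        frame = rng.random((128, 128)) * 100
        initial = rng.random((8, 2)) * 60 + 30
        current = lt.AffineParams(0.9, 0.05, -0.03, 1.1, 4.0, -2.0).apply(initial)
        contour = ContourState(initial, current)
        shape = ShapeBasis.from_points(initial)
        disp, _ = solve_step(frame, frame, contour, shape, TrackerConfig(lam=50.0, window=window))
        assert np.max(np.abs(disp)) < 1e-8

    def test_recovers_global_subpixel_shift(self, window, textured_pair):
        f0, f1 = textured_pair  # shifted by (0.5, 0)
        pts = np.array([(x, y) for x in (40, 64, 88) for y in (30, 48, 66)], float)
        contour = ContourState(pts, pts)
        shape = ShapeBasis.from_points(pts)
        disp, _ = solve_step(f0, f1, contour, shape, TrackerConfig(lam=0.0, window=window))
        mean = disp.mean(axis=0)
        assert abs(mean[0] - 0.5) < 0.2 and abs(mean[1]) < 0.2

    def test_block_matrix_matches_elementwise_oracle(self, window, table1_scene):
        pts = lt.TABLE1_POINTS[0]
        contour = ContourState(pts, pts)
        shape = ShapeBasis.from_points(pts)
        lam = 300.0
        sys = assemble_global_system(
            table1_scene.frames[0], table1_scene.frames[1], contour, shape,
            TrackerConfig(lam=lam, window=window),
        )
        n = 13
        P = shape.proj
        M = np.zeros((2 * n, 2 * n))
        for j in range(n):
            for i in range(n):
                M[j, i] = (j == i) * sys.lam_diag[j] - lam * P[j, i]
                M[n + j, n + i] = (j == i) * sys.gam_diag[j] - lam * P[j, i]
            M[j, n + j] = sys.b_diag[j]
            M[n + j, j] = sys.b_diag[j]
        assert np.allclose(sys.matrix, M, atol=1e-9)
        assert np.allclose(sys.matrix, sys.matrix.T, atol=1e-9)
        rhs = np.concatenate([
            -sys.xi_vec + lam * (P @ pts[:, 0]),
            -sys.eta_vec + lam * (P @ pts[:, 1]),
        ])
        assert np.allclose(sys.rhs, rhs, atol=1e-9)


class TestTrackSequence:
    def test_identical_frames_stay_put(self, window, rng):
        frame = rng.random((96, 96)) * 100
        frames = [frame] * 4
        pts = rng.random((6, 2)) * 40 + 25
        traj = lt.track_sequence(frames, pts, TrackerConfig(lam=10.0, window=window))
        assert np.max(np.abs(traj.displacements)) < 1e-8
        assert np.allclose(traj.points[-1], pts)

    def test_trajectory_invariant_exact(self, window, table1_scene):
        traj = lt.track_sequence(
            table1_scene.frames, lt.TABLE1_POINTS[0], TrackerConfig(lam=300.0, window=window)
        )
        for t in range(traj.n_frames - 1):
            assert np.array_equal(traj.points[t + 1], traj.points[t] + traj.displacements[t])

    def test_shape_residual_monotone_in_lambda(self, window, table1_scene):
        """Stronger regularization pulls the configuration monotonically into
        the affine shape space; in the limit the residual vanishes."""
        pts = lt.TABLE1_POINTS[0]
        shape = ShapeBasis.from_points(pts)
        P = shape.proj
        f0, f1 = table1_scene.frames[0], table1_scene.frames[1]
        residuals = []
        for lam in [0.0, 10.0, 100.0, 1000.0, 10000.0, 1e8]:
            contour = ContourState(pts, pts)
            disp, upd = solve_step(f0, f1, contour, shape, TrackerConfig(lam=lam, window=window))
            tgt = upd.current_points
            residuals.append(np.linalg.norm(tgt - P @ tgt))
        assert all(residuals[i + 1] <= residuals[i] + 1e-9 for i in range(len(residuals) - 1))
        assert residuals[-1] < 1e-3 * residuals[0]

    def test_translation_equivariance(self, window):
        """Embedding the same scene at an integer offset leaves the estimated
        displacements unchanged (away from borders)."""
        f0, f1 = make_textured_pair(shift=(0.7, -0.4), shape=(80, 80), seed=9)
        big0 = np.zeros((120, 140))
        big1 = np.zeros((120, 140))
        pts = np.array([(30.0, 30.0), (50.0, 30.0), (40.0, 50.0), (32.0, 44.0)])
        out = []
        for ox, oy in [(0, 0), (17, 23)]:
            b0, b1 = big0.copy(), big1.copy()
            b0[oy : oy + 80, ox : ox + 80] = f0
            b1[oy : oy + 80, ox : ox + 80] = f1
            p = pts + [ox, oy]
            contour = ContourState(p, p)
            shape = ShapeBasis.from_points(p)
            disp, _ = solve_step(b0, b1, contour, shape, TrackerConfig(lam=30.0, window=window))
            out.append(disp)
        assert np.allclose(out[0], out[1], atol=1e-9)
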