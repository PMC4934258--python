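import numpy as np
import pytest

from pxretinex.exponent_field import ExponentConfig
from pxretinex.grid_ops import Gradient, div_backward, grad_forward, laplacian
from pxretinex.pipeline import to_log
from pxretinex.solver import (
    SolverParams,
    energy,
    project_l,
    run_decomposition,
    shrink_magnitude,
    solve_b_subproblem,
    solve_l_subproblem,
    update_t,
)

from conftest import centered_rmse


def dense_neumann_solve(i, b, t, gamma):
    """Independent oracle: assemble (gamma+1)*Lap with the replicate-Neumann
    stencil row by row, add a mean constraint, solve by least squares."""
    h, w = i.shape
    n = h * w
    A = np.zeros((n, n))
    for r in range(h):
        for c in range(w):
            k = r * w + c
            for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                rr, cc = r + dr, c + dc
                if 0 <= rr < h and 0 <= cc < w:
                    A[k, rr * w + cc] += gamma + 1.0
                    A[k, k] -= gamma + 1.0
    rhs = (gamma * div_backward(Gradient(b.x - t.x, b.y - t.y)) + laplacian(i)).ravel()
    A_aug = np.vstack([A, np.full((1, n), 1.0 / n)])
    rhs_aug = np.concatenate([rhs, [i.mean()]])
    sol, *_ = np.linalg.lstsq(A_aug, rhs_aug, rcond=None)
    return sol.reshape(h, w)


class TestLSubproblem:
    def test_constant_input_is_fixed_point(self):
        i = np.full((6, 6), 2.0)
        z = np.zeros_like(i)
        g = Gradient(z, z)
        l = solve_l_subproblem(i, g, g, 1e3)
        assert np.allclose(l, 2.0, atol=1e-12)

    def test_matches_dense_direct_solve(self, rng):
        gamma = 1e3
        i = rng.uniform(0, 5, size=(8, 8))
        b = Gradient(rng.normal(size=(8, 8)), rng.normal(size=(8, 8)))
        t = Gradient(rng.normal(size=(8, 8)), rng.normal(size=(8, 8)))
        l_gs = solve_l_subproblem(i, b, t, gamma, gs_max_sweeps=100000, gs_tol=1e-13)
        l_direct = dense_neumann_solve(i, b, t, gamma)
        assert np.max(np.abs(l_gs - l_direct)) < 1e-6

    def test_residual_when_b_equals_t(self, rng):
        """With b = t the system reduces to (gamma+1) Lap l = Lap i."""
        gamma = 1e3
        i = rng.uniform(0, 5, size=(10, 10))
        g = Gradient(rng.normal(size=(10, 10)), rng.normal(size=(10, 10)))
        l = solve_l_subproblem(i, g, g, gamma, gs_max_sweeps=100000, gs_tol=1e-14)
        res = (gamma + 1.0) * laplacian(l) - laplacian(i)
        assert np.max(np.abs(res)) < 1e-6

    def test_fft_path_solves_periodic_system(self, rng):
        from pxretinex.grid_ops import div_periodic, laplacian_periodic

        gamma = 1e3
        i = rng.uniform(0, 5, size=(16, 16))
        b = Gradient(rng.normal(size=(16, 16)), rng.normal(size=(16, 16)))
        t = Gradient(rng.normal(size=(16, 16)), rng.normal(size=(16, 16)))
        l = solve_l_subproblem(i, b, t, gamma, method="fft")
        rhs = gamma * div_periodic(Gradient(b.x - t.x, b.y - t.y)) + laplacian_periodic(i)
        assert np.max(np.abs((gamma + 1.0) * laplacian_periodic(l) - rhs)) < 1e-9
        assert abs(l.mean() - i.mean()) < 1e-12

    def test_invalid_inputs_rejected(self):
        i = np.ones((4, 4))
        g = Gradient(np.zeros((4, 4)), np.zeros((4, 4)))
        with pytest.raises(ValueError):
            solve_l_subproblem(i, g, g, -1.0)
        with pytest.raises(ValueError):
            solve_l_subproblem(i, Gradient(np.zeros((3, 3)), np.zeros((3, 3))), g, 1e3)


def brute_force_magnitude(u, p, lam, gam, n_grid=20001):
    """Fine-grid minimizer of lam*m^p + gam*(m-u)^2 over [0, u]."""
    grid = np.linspace(0.0, u, n_grid)
    obj = lam * grid**p + gam * (grid - u) ** 2
    return grid[np.argmin(obj)]


class TestBSubproblem:
    def test_zero_input_gives_zero(self):
        v = Gradient(np.zeros((4, 4)), np.zeros((4, 4)))
        b = solve_b_subproblem(v, np.full((4, 4), 1.5), 80.0, 1e3)
        assert np.all(b.x == 0) and np.all(b.y == 0)

    def test_p_two_closed_form(self, rng):
        lam, gam = 80.0, 1e3
        v = Gradient(rng.normal(size=(6, 6)), rng.normal(size=(6, 6)))
        b = solve_b_subproblem(v, np.full((6, 6), 2.0), lam, gam)
        assert np.allclose(b.x, gam * v.x / (lam + gam), atol=1e-10)
        assert np.allclose(b.y, gam * v.y / (lam + gam), atol=1e-10)

    def test_p_to_one_limit_is_soft_thresholding(self, rng):
        lam, gam = 80.0, 1e3
        v = Gradient(rng.uniform(-1, 1, size=(8, 8)), rng.uniform(-1, 1, size=(8, 8)))
        b = solve_b_subproblem(v, np.full((8, 8), 1.0 + 1e-9), lam, gam)
        u = np.hypot(v.x, v.y)
        m_soft = np.maximum(u - lam / (2 * gam), 0.0)
        m_got = np.hypot(b.x, b.y)
        assert np.max(np.abs(m_got - m_soft)) < 1e-4

    def test_magnitude_matches_brute_force(self, rng):
        lam, gam = 80.0, 1e3
        for _ in range(50):
            u = float(rng.uniform(1e-4, 2.0))
            p = float(rng.uniform(1.01, 2.0))
            m = shrink_magnitude(np.array([u]), np.array([p]), lam, gam)[0]
            m_bf = brute_force_magnitude(u, p, lam, gam)
            assert abs(m - m_bf) < 1e-4

    def test_sign_and_direction_inherited_from_v(self, rng):
        v = Gradient(rng.normal(size=(5, 5)), rng.normal(size=(5, 5)))
        b = solve_b_subproblem(v, np.full((5, 5), 1.3), 80.0, 1e3)
        # b is a nonnegative multiple of v at every pixel
        assert np.all(b.x * v.x >= -1e-15)
        assert np.all(b.y * v.y >= -1e-15)
        cross = b.x * v.y - b.y * v.x
        assert np.max(np.abs(cross)) < 1e-10

    def test_invalid_exponent_rejected(self):
        v = Gradient(np.ones((3, 3)), np.ones((3, 3)))
        with pytest.raises(ValueError):
            solve_b_subproblem(v, np.full((3, 3), 1.0), 80.0, 1e3)
        with pytest.raises(ValueError):
            solve_b_subproblem(v, np.full((3, 3), 2.5), 80.0, 1e3)


class TestUpdateTAndProjection:
    def test_t_stays_zero_when_constraint_met(self, rng):
        gl = Gradient(rng.normal(size=(4, 4)), rng.normal(size=(4, 4)))
        z = Gradient(np.zeros((4, 4)), np.zeros((4, 4)))
        t = update_t(z, gl, gl)
        assert np.all(t.x == 0) and np.all(t.y == 0)

    def test_t_accumulates_residuals(self, rng):
        z = Gradient(np.zeros((4, 4)), np.zeros((4, 4)))
        g1 = Gradient(rng.normal(size=(4, 4)), rng.normal(size=(4, 4)))
        g2 = Gradient(rng.normal(size=(4, 4)), rng.normal(size=(4, 4)))
        b1 = Gradient(rng.normal(size=(4, 4)), rng.normal(size=(4, 4)))
        t1 = update_t(z, g1, b1)
        t2 = update_t(t1, g2, b1)
        assert np.allclose(t2.x, g1.x + g2.x - 2 * b1.x)

    def test_projection_raises_only_deficient_pixels(self, rng):
        i = rng.uniform(0, 5, size=(6, 6))
        l = i + rng.uniform(-1, 1, size=(6, 6))
        out = project_l(l, i)
        low = l < i
        assert np.all(out[low] == i[low])
        assert np.all(out[~low] == l[~low])
        assert np.array_equal(project_l(out, i), out)  # idempotent


class TestEnergy:
    def test_zero_for_matching_constants(self):
        c = np.full((5, 5), 3.0)
        assert energy(c, c, np.full((5, 5), 2.0), 80.0) == 0.0

    def test_fidelity_vanishes_at_l_equals_i(self, rng):
        i = rng.uniform(0, 5, size=(6, 6))
        p = np.full((6, 6), 1.5)
        g = grad_forward(i)
        mag = np.hypot(g.x, g.y)
        expected = 80.0 * np.sum(mag[mag > 0] ** 1.5)
        assert abs(energy(i, i, p, 80.0) - expected) < 1e-10

    def test_three_by_three_hand_summed_instance(self):
        l = np.array([[0.0, 1.0, 1.0], [2.0, 0.5, 1.5], [1.0, 1.0, 0.0]])
        i = np.array([[0.5, 0.5, 1.5], [1.0, 1.0, 1.0], [0.0, 2.0, 1.0]])
        p = np.array([[2.0, 1.5, 1.2], [1.8, 1.1, 2.0], [1.4, 1.6, 1.9]])
        lam = 80.0
        # independent summation with explicit loops
        fid = reg = 0.0
        for r in range(3):
            for c in range(3):
                glx = l[r, c + 1] - l[r, c] if c < 2 else 0.0
                gly = l[r + 1, c] - l[r, c] if r < 2 else 0.0
                gix = i[r, c + 1] - i[r, c] if c < 2 else 0.0
                giy = i[r + 1, c] - i[r, c] if r < 2 else 0.0
                fid += (glx - gix) ** 2 + (gly - giy) ** 2
                mag = np.sqrt(glx**2 + gly**2)
                if mag > 0:
                    reg += mag ** p[r, c]
        assert abs(energy(l, i, p, lam) - (fid + lam * reg)) < 1e-12


class TestRunDecomposition:
    def test_constant_image_returns_input(self):
        i = to_log(np.full((16, 16), 100.0))
        l, trace = run_decomposition(i, SolverParams())
        assert np.allclose(l, i, atol=1e-12)
        assert trace.converged

    def test_constraint_holds_every_iteration(self, shadow_scene):
        i = to_log(shadow_scene.composite)
        l, trace = run_decomposition(i, SolverParams(w=1e9, max_outer_iters=12,
                                                     epsilon_tol=1e-12))
        assert min(trace.min_l_minus_i) >= 0.0
        assert np.all(l >= i)

    def test_shadow_recovery_rmse(self, shadow_scene):
        i = to_log(shadow_scene.composite)
        l, trace = run_decomposition(i, SolverParams(w=1e9))
        assert trace.converged
        assert centered_rmse(l, np.log(shadow_scene.illumination_true)) < 0.1

    def test_fixed_mode_energy_nonincreasing(self, shadow_scene):
        i = to_log(shadow_scene.composite)
        params = SolverParams(w=1e9, exponent=ExponentConfig(mode="fixed"))
        _, trace = run_decomposition(i, params)
        assert max(np.diff(trace.energies), default=0.0) <= 1e-8

    def test_recovered_l_has_less_total_variation_than_input(self, shadow_scene):
        i = to_log(shadow_scene.composite)
        l, _ = run_decomposition(i, SolverParams(w=1e9))
        tv = lambda u: float(np.sum(grad_forward(u).magnitude()))
        assert tv(l) <= tv(i)

    def test_trace_lengths_match_iterations(self, ramp_scene):
        i = to_log(ramp_scene.composite)
        _, trace = run_decomposition(i, SolverParams(max_outer_iters=5, epsilon_tol=1e-12))
        assert trace.iterations_run == 5
        assert not trace.converged
        assert len(trace.energies) == len(trace.relative_changes) == 5

    def test_homomorphic_limit_optimality(self):
        """w=0 (p identically 2), projection off: the converged iterate
        satisfies the global quadratic optimality (1+lambda) Lap l = Lap i."""
        from pxretinex.synthetic_data import compose, make_illumination, make_texture

        r = make_texture(32, 32, "filtered_noise", 5)
        L = make_illumination(32, 32, "smooth_ramp", low=0.4)
        i = to_log(compose(r, L).composite)
        params = SolverParams(w=0.0, enforce_constraint=False, epsilon_tol=1e-15,
                              max_outer_iters=400, gs_max_sweeps=200, gs_tol=1e-13)
        l, _ = run_decomposition(i, params)
        res = (1 + params.lambda_reg) * laplacian(l) - laplacian(i)
        assert np.max(np.abs(res)) < 1e-4

    def test_determinism(self, ramp_scene):
        i = to_log(ramp_scene.composite)
        params = SolverParams(max_outer_iters=6, epsilon_tol=1e-12)
        l1, _ = run_decomposition(i, params)
        l2, _ = run_decomposition(i, params)
        assert np.array_equal(l1, l2)

    def test_param_validation(self):
        with pytest.raises(ValueError):
            SolverParams(lambda_reg=-1.0)
        with pytest.raises(ValueError):
            SolverParams(l_solver="magic")
        with pytest.raises(ValueError):
            SolverParams(epsilon_tol=0.0)
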