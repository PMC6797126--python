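"""Collocation tests: Radau scheme construction, transcription layout and
counts, AD/FD callback agreement, scaling round-trips, exactness on a toy
problem with polynomial solution, and solve determinism."""

import numpy as np
import pytest
from scipy.optimize import brentq

from tapetraj import adgraph as ad
from tapetraj import collocation as col


@pytest.fixture
def rng():
    return np.random.default_rng(11)


class TestRadauScheme:
    def test_degree_one_is_implicit_euler(self):
        s = col.make_radau(1)
        assert np.array_equal(s.points, [1.0])
        assert np.allclose(s.diff_matrix, [[-1.0, 1.0]])
        assert np.allclose(s.quad_weights, [1.0])

    def test_degree_three_abscissae_match_root_finding_oracle(self):
        # roots of the Radau polynomial (P3 - P2)(2x - 1) on (0, 1]
        from numpy.polynomial import legendre

        def radau_poly(x):
            s = 2 * x - 1
            return legendre.legval(s, [0, 0, 0, 1]) - legendre.legval(s, [0, 0, 1])

        r1 = brentq(radau_poly, 0.01, 0.5)
        r2 = brentq(radau_poly, 0.5, 0.9)
        s = col.make_radau(3)
        assert np.allclose(s.points, [r1, r2, 1.0], atol=1e-12)
        assert np.allclose(s.points[:2], [0.1550510, 0.6449490], atol=1e-6)

    @pytest.mark.parametrize("d", [1, 2, 3, 4, 5])
    def test_quadrature_exact_to_degree_2d_minus_2(self, d):
        s = col.make_radau(d)
        for k in range(2 * d - 1):
            estimate = float(s.quad_weights @ s.points ** k)
            assert estimate == pytest.approx(1.0 / (k + 1), abs=1e-12), (d, k)

    def test_quartic_exact_at_degree_three(self):
        s = col.make_radau(3)
        assert float(s.quad_weights @ s.points ** 4) == pytest.approx(0.2, abs=1e-13)

    def test_diff_matrix_differentiates_cubics(self):
        s = col.make_radau(3)
        basis = np.concatenate([[0.0], s.points])
        for coeffs in np.eye(4):
            p = np.polynomial.Polynomial(coeffs)
            vals = p(basis)
            assert np.allclose(s.diff_matrix @ vals, p.deriv()(s.points),
                               atol=1e-12)

    def test_unsupported_degree(self):
        with pytest.raises(ValueError):
            col.make_radau(10)
        with pytest.raises(ValueError):
            col.make_radau(0)


class TestScaling:
    def test_round_trip_identity(self, rng):
        s = col.ScalingSet.from_bounds([-3, -20], [3, 20], [-500], [500])
        x = rng.normal(size=2)
        assert np.allclose((x / s.x_scale) * s.x_scale, x, rtol=1e-14)

    def test_bound_derived_scales_map_into_unit_box(self):
        s = col.ScalingSet.from_bounds([-2, 0], [1, 5], [-7], [3])
        assert np.array_equal(s.x_scale, [2, 5])
        assert np.array_equal(s.u_scale, [7])

    def test_zero_scale_rejected(self):
        with pytest.raises(ValueError):
            col.ScalingSet(np.array([0.0]), np.array([1.0]), np.zeros(0))


def toy_problem(N, pinned=False):
    """Linear dynamics with the known polynomial solution x1 = t + t^3,
    x2 = 1 from x(0) = (0, 1):  x1' = x2 + 3 t^2,  x2' = u.

    With ``pinned=True`` the control is fixed to zero by equal bounds, so
    the trajectory is fully determined by the collocation equations and any
    deviation from the cubic is pure discretization error.  With a free
    control in [-1, 1] and objective integral(u^2) the same trajectory is
    the optimum, reached to solver tolerance.
    """
    scaling = col.ScalingSet(np.array([2.0, 2.0]), np.array([1.0]), np.zeros(0))

    def rates(x, u, p, t):
        return [x[1] + 3.0 * t * t, u[0]]

    ub = 0.0 if pinned else 1.0
    ocp = col.OptimalControlProblem(
        state_names=["x1", "x2"], control_names=["u"],
        x_lb=np.array([-5.0, -5.0]), x_ub=np.array([5.0, 5.0]),
        u_lb=np.array([-ub]), u_ub=np.array([ub]),
        rates=rates, integrand=lambda x, u, p, t: u[0] * u[0],
        boundary=lambda x0, xN, p: [x0[0], x0[1] - 1.0],
        scaling=scaling, t_f=1.0, name="toy")
    return col.transcribe(ocp, N)


class TestTranscriptionLayout:
    def test_trivial_hand_count(self):
        # n_x=1, n_u=0, N=1, d=1, no path/boundary rows: 2 variables
        # (mesh states) + 1 collocation state; 1 collocation equation + 1
        # continuity row
        scaling = col.ScalingSet(np.ones(1), np.ones(0), np.zeros(0))
        ocp = col.OptimalControlProblem(
            state_names=["x"], control_names=[],
            x_lb=np.array([-1.0]), x_ub=np.array([1.0]),
            u_lb=np.zeros(0), u_ub=np.zeros(0),
            rates=lambda x, u, p, t: [-x[0]],
            integrand=lambda x, u, p, t: x[0] * x[0],
            scaling=scaling, t_f=1.0)
        nlp = col.transcribe(ocp, 1, scheme=col.make_radau(1))
        assert nlp.n_vars == 3
        assert nlp.n_coll_rows == 1
        assert nlp.n_eq == 2  # one collocation equation + one continuity row

    def test_variable_and_constraint_closed_forms(self):
        # closed-form counters as functions of (N, d, dims) on the toy OCP
        for N in (1, 4, 7):
            nlp = toy_problem(N)
            n_x, n_u, d = 2, 1, 3
            assert nlp.n_vars == n_x * (N + 1) + n_x * N * d + n_u * N
            assert nlp.n_eq == n_x * N * d + n_x * N + 2

    def test_constant_integrand_quadrature_equals_horizon(self, rng):
        scaling = col.ScalingSet(np.ones(1), np.ones(1), np.zeros(0))
        ocp = col.OptimalControlProblem(
            state_names=["x"], control_names=["u"],
            x_lb=np.array([-1.0]), x_ub=np.array([1.0]),
            u_lb=np.array([-1.0]), u_ub=np.array([1.0]),
            rates=lambda x, u, p, t: [u[0]],
            integrand=lambda x, u, p, t: 3.7,
            scaling=scaling, t_f=2.5)
        for N in (1, 3, 8):
            nlp = col.transcribe(ocp, N)
            z = rng.normal(size=nlp.n_vars)
            assert nlp.objective(z) == pytest.approx(3.7 * 2.5, rel=1e-13)


class TestCallbacks:
    def test_ad_jacobian_matches_fd(self, rng):
        nlp = toy_problem(4)
        z = np.clip(rng.normal(scale=0.2, size=nlp.n_vars), nlp.z_lb, nlp.z_ub)
        J = nlp.jacobian_eq(z).toarray()
        Jfd = ad.fd_jacobian(nlp.constraints_eq, z, h=1e-7, scheme="central")
        assert np.max(np.abs(J - Jfd)) <= 1e-5 * (1 + np.max(np.abs(J)))

    def test_constant_objective_zero_gradient(self):
        scaling = col.ScalingSet(np.ones(1), np.ones(1), np.zeros(0))
        ocp = col.OptimalControlProblem(
            state_names=["x"], control_names=["u"],
            x_lb=np.array([-1.0]), x_ub=np.array([1.0]),
            u_lb=np.array([-1.0]), u_ub=np.array([1.0]),
            rates=lambda x, u, p, t: [u[0]],
            integrand=lambda x, u, p, t: 1.0,
            scaling=scaling, t_f=1.0)
        nlp = col.transcribe(ocp, 3)
        g = nlp.gradient(np.zeros(nlp.n_vars))
        assert np.array_equal(g, np.zeros(nlp.n_vars))

    def test_exact_hessian_matches_fd_of_gradient(self, rng):
        nlp = toy_problem(3)
        z = np.clip(rng.normal(scale=0.2, size=nlp.n_vars), nlp.z_lb, nlp.z_ub)
        H = nlp.hessian_objective(z).toarray()
        Hfd = ad.fd_jacobian(nlp.gradient, z, h=1e-6, scheme="central")
        assert np.allclose(H, Hfd, rtol=1e-4, atol=1e-7)
        v = rng.normal(size=nlp.n_eq)
        He = nlp.hessian_eq(z, v).toarray()
        Hefd = ad.fd_jacobian(lambda x: nlp.jacobian_eq(x).toarray().T @ v,
                              z, h=1e-6, scheme="central")
        assert np.allclose(He, Hefd, rtol=1e-4, atol=1e-6)

    def test_fd_mode_gradient_eval_count(self):
        nlp = toy_problem(2)
        nlp.mode = "fd"
        z = nlp.initial_guess_zero()
        before = nlp.counters["obj_evals"]
        nlp.gradient(z)
        assert nlp.counters["obj_evals"] - before == nlp.n_vars + 1


class TestToyProblemExactness:
    @pytest.mark.parametrize("N", [1, 2, 5])
    def test_polynomial_solution_to_machine_precision(self, N):
        # cubic solution, degree-3 collocation, pinned control: the
        # interpolant reproduces the cubic exactly at any mesh size
        nlp = toy_problem(N, pinned=True)
        rec = col.solve(nlp, col.SolveOptions(hessian="exact", tol=1e-12))
        assert rec.constr_violation < 1e-11
        ts = np.linspace(0, 1, 17)
        X = nlp.interp_states(rec.z, ts)
        assert np.allclose(X[:, 0], ts + ts ** 3, atol=1e-10)
        assert np.allclose(X[:, 1], 1.0, atol=1e-10)

    def test_free_control_optimum_reaches_same_cubic(self):
        # with the control free, the optimizer recovers the cubic to
        # solver tolerance and the objective is ~0
        nlp = toy_problem(4)
        rec = col.solve(nlp, col.SolveOptions(hessian="exact"))
        assert rec.status == "solved"
        ts = np.linspace(0, 1, 9)
        X = nlp.interp_states(rec.z, ts)
        assert np.allclose(X[:, 0], ts + ts ** 3, atol=1e-4)
        assert rec.objective == pytest.approx(0.0, abs=1e-8)

    def test_mesh_refine_identical_when_exact(self):
        # the cubic is representable at N=1 and N=2 alike: interpolants
        # coincide and the collocation residuals are at machine precision
        report = col.mesh_refine_check(
            lambda N: toy_problem(N, pinned=True), 1, factor=2,
            threshold=1e-9,
            options=col.SolveOptions(hessian="exact", tol=1e-12))
        assert report["pass"]
        assert report["coarse"].constr_violation < 1e-11
        assert report["fine"].constr_violation < 1e-11


class TestSolveAdapter:
    def test_determinism_identical_runs(self):
        r1 = col.solve(toy_problem(3), col.SolveOptions(hessian="exact"))
        r2 = col.solve(toy_problem(3), col.SolveOptions(hessian="exact"))
        assert r1.iterations == r2.iterations
        assert r1.objective == pytest.approx(r2.objective, abs=1e-12)
        assert np.array_equal(r1.z, r2.z)

    def test_out_of_bounds_guess_clamped_with_warning(self):
        nlp = toy_problem(2)
        g = np.zeros(nlp.n_vars)
        g[::5] = 10.0  # some entries far above the upper bound
        with pytest.warns(UserWarning, match="clamp"):
            rec = col.solve(nlp, col.SolveOptions(initial_guess=g,
                                                  hessian="exact"))
        assert rec.status == "solved"
        assert np.all(rec.z >= nlp.z_lb - 1e-9)
        assert np.all(rec.z <= nlp.z_ub + 1e-9)

    def test_failure_surfaces_status_not_raise(self):
        # an infeasible problem: x pinned to different values at both ends
        # with zero dynamics
        scaling = col.ScalingSet(np.ones(1), np.ones(1), np.zeros(0))
        ocp = col.OptimalControlProblem(
            state_names=["x"], control_names=["u"],
            x_lb=np.array([-1.0]), x_ub=np.array([1.0]),
            u_lb=np.array([0.0]), u_ub=np.array([0.0]),
            rates=lambda x, u, p, t: [0.0 * x[0]],
            integrand=lambda x, u, p, t: u[0] * u[0],
            boundary=lambda x0, xN, p: [x0[0], xN[0] - 1.0],
            scaling=scaling, t_f=1.0)
        nlp = col.transcribe(ocp, 2)
        rec = col.solve(nlp, col.SolveOptions(max_iter=60))
        assert rec.status in ("infeasible", "max_iter", "stalled")
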