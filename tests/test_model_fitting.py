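import numpy as np
import pytest

from grit import (
    FitConfig,
    LinearDriftModel,
    SnapshotSeries,
    barycentric_targets,
    cell_velocities,
    fit,
    model_error,
    propagate,
    sinkhorn,
    solve_model_given_plans,
    squared_distance_matrix,
    total_cost,
)
from grit.data_model import GritValidationError
from grit.entropic_ot import TransportPlan


def uniform(m):
    return np.full(m, 1.0 / m)


def identity_plan(m, epsilon=0.1):
    """A plan coupling cell i to cell i with mass 1/m."""
    M = np.eye(m) / m
    return TransportPlan(
        uniform(m), uniform(m), epsilon, np.zeros(m), np.zeros(m), M=M
    )


class TestPropagate:
    def test_zero_drift_is_identity(self, rng):
        Y = rng.random((3, 5))
        assert np.allclose(propagate(Y, np.zeros((3, 3)), np.zeros(3), 0.7), Y)

    def test_scalar_example(self):
        out = propagate(np.array([[2.0]]), np.array([[-1.0]]), np.array([3.0]), 0.5)
        assert np.allclose(out, [[2.5]])

    def test_matches_per_cell_loop(self, rng):
        Y = rng.normal(size=(4, 6))
        A = rng.normal(size=(4, 4))
        b = rng.normal(size=4)
        out = propagate(Y, A, b, 0.3)
        ref = np.column_stack(
            [Y[:, i] + 0.3 * (A @ Y[:, i] + b) for i in range(6)]
        )
        assert np.max(np.abs(out - ref)) < 1e-12

    def test_dimension_mismatch(self):
        with pytest.raises(GritValidationError):
            propagate(np.ones((2, 3)), np.ones((3, 3)), np.ones(3), 1.0)


class TestTotalCost:
    def test_identical_snapshots_identity_model_cost_is_entropy(self):
        Y = np.array([[0.0, 1.0, 2.0]])
        series = SnapshotSeries(["g"], [Y, Y], np.array([0.0, 1.0]))
        config = FitConfig(epsilon=0.5)
        plan = identity_plan(3, 0.5)
        model = LinearDriftModel(np.zeros((1, 1)), np.zeros(1))
        J = total_cost(model, series, [plan], config)
        # zero transport distance, so only the entropic term remains
        assert np.isclose(J, 0.5 * np.log(1 / 3))

    def test_load_penalty_enters_linearly(self, tiny_series):
        model = LinearDriftModel(np.zeros((2, 2)), np.array([1.0, 2.0]))
        plan = identity_plan(3, 0.3)
        base = total_cost(model, tiny_series, [plan], FitConfig(epsilon=0.3, lambda_b=0.0))
        lam = total_cost(model, tiny_series, [plan], FitConfig(epsilon=0.3, lambda_b=0.7))
        assert np.isclose(lam - base, 0.7 * 5.0)

    def test_matches_term_by_term_reference(self, rng):
        n, m0, m1 = 3, 4, 5
        Y0 = rng.random((n, m0))
        Y1 = rng.random((n, m1))
        dT = 0.8
        series = SnapshotSeries([f"g{i}" for i in range(n)], [Y0, Y1], np.array([0.0, dT]))
        A = rng.normal(size=(n, n)) * 0.2
        b = rng.normal(size=n)
        eps = 0.4
        lamA = 0.3
        lamb = 0.2
        X = propagate(Y0, A, b, dT)
        plan = sinkhorn(squared_distance_matrix(X, Y1), uniform(m0), uniform(m1), eps)
        config = FitConfig(epsilon=eps, Lambda_A=lamA, lambda_b=lamb)
        J = total_cost(LinearDriftModel(A, b), series, [plan], config)
        M = plan.dense()
        ref = 0.0
        for i in range(m0):
            for j in range(m1):
                ref += M[i, j] * np.sum((X[:, i] - Y1[:, j]) ** 2)
                ref += eps * M[i, j] * np.log(M[i, j])
        ref /= dT
        ref += lamA * np.sum(A**2) + lamb * np.sum(b**2)
        assert abs(J - ref) < 1e-10


class TestSolveModelGivenPlans:
    def test_underdetermined_returns_minimum_norm(self):
        Y0 = np.array([[1.0]])
        Y1 = np.array([[2.0]])
        series = SnapshotSeries(["g"], [Y0, Y1], np.array([0.0, 1.0]))
        plan = identity_plan(1)
        with pytest.warns(UserWarning, match="singular"):
            A, b = solve_model_given_plans(series, [plan], FitConfig(epsilon=0.1))
        # any a + b = 1 is optimal; the jittered solve picks (0.5, 0.5)
        assert np.allclose([A[0, 0], b[0]], [0.5, 0.5], atol=1e-6)

    def test_exact_recovery_from_noiseless_dynamics(self, rng):
        n, m = 3, 8
        A_true = rng.normal(size=(n, n)) * 0.3 - 0.5 * np.eye(n)
        b_true = rng.random(n)
        Y0 = rng.random((n, m)) * 2
        dT = 0.5
        Y1 = propagate(Y0, A_true, b_true, dT)
        series = SnapshotSeries(
            [f"g{i}" for i in range(n)], [Y0, Y1], np.array([0.0, dT])
        )
        A, b = solve_model_given_plans(series, [identity_plan(m)], FitConfig(epsilon=0.1))
        assert np.max(np.abs(A - A_true)) < 1e-8
        assert np.max(np.abs(b - b_true)) < 1e-8

    def test_agrees_with_numerical_minimizer(self, rng):
        from scipy.optimize import minimize

        n, m = 3, 5
        Y0 = rng.random((n, m))
        Y1 = rng.random((n, m))
        dT = 0.7
        series = SnapshotSeries(
            [f"g{i}" for i in range(n)], [Y0, Y1], np.array([0.0, dT])
        )
        eps = 0.3
        config = FitConfig(epsilon=eps, Lambda_A=0.05, lambda_b=0.02)
        X0 = propagate(Y0, np.zeros((n, n)), np.zeros(n), dT)
        plan = sinkhorn(
            squared_distance_matrix(X0, Y1), uniform(m), uniform(m), eps, tol=1e-11
        )
        A_opt, b_opt = solve_model_given_plans(series, [plan], config)

        def objective(theta):
            A = theta[: n * n].reshape(n, n)
            b = theta[n * n :]
            return total_cost(LinearDriftModel(A, b), series, [plan], config)

        res = minimize(objective, np.zeros(n * n + n), method="L-BFGS-B",
                       options={"maxiter": 2000, "ftol": 1e-15, "gtol": 1e-12})
        J_closed = objective(np.concatenate([A_opt.ravel(), b_opt]))
        assert J_closed <= res.fun + 1e-6 * max(1.0, abs(res.fun))
        assert abs(J_closed - res.fun) <= 1e-6 * max(1.0, abs(res.fun))

    def test_cross_moment_sufficiency(self, rng):
        """Two plans with equal marginals and cross-moments give identical solves."""
        n, m = 2, 8
        Y0 = rng.random((n, m))
        Y1 = rng.random((n, m))
        series = SnapshotSeries(["a", "b"], [Y0, Y1], np.array([0.0, 1.0]))
        eps = 0.4
        plan = sinkhorn(
            squared_distance_matrix(Y0, Y1), uniform(m), uniform(m), eps, tol=1e-11
        )
        M = plan.dense()
        # search the nullspace of the constraints (marginals + cross-moment)
        constraints = []
        for i in range(m):
            row = np.zeros((m, m))
            row[i, :] = 1
            constraints.append(row.ravel())
        for j in range(m):
            col = np.zeros((m, m))
            col[:, j] = 1
            constraints.append(col.ravel())
        ext0 = np.vstack([Y0, np.ones(m)])
        ext1 = np.vstack([Y1, np.ones(m)])
        for gi in range(n + 1):
            for gj in range(n + 1):
                constraints.append(np.outer(ext0[gi], ext1[gj]).ravel())
        _, s, Vt = np.linalg.svd(np.asarray(constraints))
        null = Vt[np.sum(s > 1e-10) :]
        assert null.shape[0] > 0, "need slack to build an alternative plan"
        direction = null[0].reshape(m, m)
        scale = 0.4 * M.min() / max(np.abs(direction).max(), 1e-12)
        M2 = M + scale * direction
        assert np.all(M2 > 0)
        plan2 = TransportPlan(
            uniform(m), uniform(m), eps, np.zeros(m), np.zeros(m), M=M2
        )
        config = FitConfig(epsilon=eps)
        A1, b1 = solve_model_given_plans(series, [plan], config)
        A2, b2 = solve_model_given_plans(series, [plan2], config)
        assert np.max(np.abs(A1 - A2)) < 1e-9
        assert np.max(np.abs(b1 - b2)) < 1e-9


class TestFit:
    def test_deterministic_given_inputs(self, linear_series, fast_config):
        r1 = fit(linear_series, fast_config)
        r2 = fit(linear_series, fast_config)
        assert np.array_equal(r1.cost_trace, r2.cost_trace)
        assert np.array_equal(r1.model.A, r2.model.A)

    def test_cost_trace_nonincreasing(self, linear_series, fast_config):
        res = fit(linear_series, fast_config)
        diffs = np.diff(res.cost_trace)
        assert np.all(diffs <= 10 * fast_config.sinkhorn_tol)

    def test_error_shrinks_with_more_cells(self, small_truth):
        from grit import simulate_linear_discrete

        errs = []
        for m in [150, 1200]:
            series = simulate_linear_discrete(small_truth, N=5, m=m, epsilon=0.2, seed=3)
            cfg = FitConfig(epsilon=2 * 0.2**2, outer_tol=1e-6, max_outer_iter=120)
            errs.append(model_error(fit(series, cfg).model, small_truth))
        assert errs[1] < errs[0]

    def test_stationary_data_has_stationary_model(self, rng):
        """On i.i.d. snapshots the fitted drift vanishes at the sample mean."""
        n, m = 3, 300
        snaps = [rng.normal(2.0, 0.3, size=(n, m)) for _ in range(3)]
        series = SnapshotSeries([f"g{i}" for i in range(n)], snaps, np.arange(3.0))
        cfg = FitConfig(epsilon=2 * 0.3**2, outer_tol=1e-7, max_outer_iter=60)
        res = fit(series, cfg)
        ybar = series.pooled().mean(axis=1)
        assert np.linalg.norm(res.model.A @ ybar + res.model.b) < 0.1

    def test_single_cell_snapshot_rejected(self):
        Y0 = np.ones((2, 1))
        Y1 = np.ones((2, 3))
        series = SnapshotSeries(["a", "b"], [Y0, Y1], np.array([0.0, 1.0]))
        with pytest.raises(GritValidationError):
            fit(series, FitConfig(epsilon=0.1))


class TestPlanDerivedQuantities:
    def test_identity_plan_targets_are_successors(self, tiny_series):
        targets = barycentric_targets(tiny_series, [identity_plan(3)])
        assert np.allclose(targets[0], tiny_series.snapshots[1])

    def test_uniform_plan_targets_are_snapshot_mean(self, tiny_series):
        M = np.full((3, 3), 1 / 9)
        plan = TransportPlan(uniform(3), uniform(3), 0.1, np.zeros(3), np.zeros(3), M=M)
        targets = barycentric_targets(tiny_series, [plan])
        mean = tiny_series.snapshots[1].mean(axis=1)
        assert np.allclose(targets[0], mean[:, None] @ np.ones((1, 3)))

    def test_targets_live_in_convex_hull(self, rng):
        """Barycentric targets are convex combinations of next-time cells."""
        from scipy.optimize import linprog

        n, m = 2, 6
        Y0 = rng.random((n, m))
        Y1 = rng.random((n, m))
        series = SnapshotSeries(["a", "b"], [Y0, Y1], np.array([0.0, 1.0]))
        plan = sinkhorn(
            squared_distance_matrix(Y0, Y1), uniform(m), uniform(m), 0.2, tol=1e-10
        )
        targets = barycentric_targets(series, [plan])[0]
        for i in range(m):
            # feasibility LP: does a convex combination reproduce the target?
            res = linprog(
                np.zeros(m),
                A_eq=np.vstack([Y1, np.ones(m)]),
                b_eq=np.concatenate([targets[:, i], [1.0]]),
                bounds=[(0, 1)] * m,
                method="highs",
            )
            assert res.success

    def test_velocity_difference_quotient(self):
        Y0 = np.array([[0.0, 0.0]])
        Y1 = np.array([[2.0, 2.0]])
        series = SnapshotSeries(["g"], [Y0, Y1], np.array([0.0, 0.5]))
        vel = cell_velocities(series, [identity_plan(2)])
        assert np.allclose(vel[0], 4.0)

    def test_identical_snapshots_zero_velocity(self, rng):
        Y = rng.random((2, 4))
        series = SnapshotSeries(["a", "b"], [Y, Y], np.array([0.0, 1.0]))
        vel = cell_velocities(series, [identity_plan(4)])
        assert np.max(np.abs(vel[0])) < 1e-12

    def test_mean_velocity_matches_drift_on_simulated_data(self, small_truth):
        from grit import simulate_linear_discrete

        series = simulate_linear_discrete(small_truth, N=2, m=800, epsilon=0.2, seed=9)
        cfg = FitConfig(epsilon=2 * 0.2**2, outer_tol=1e-6, max_outer_iter=80)
        res = fit(series, cfg)
        vel = cell_velocities(series, res.plans)[0]
        ybar = series.snapshots[0].mean(axis=1)
        expected = small_truth.A_true @ ybar + small_truth.b_true
        assert np.linalg.norm(vel.mean(axis=1) - expected) < 0.25 * max(
            1.0, np.linalg.norm(expected)
        )
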