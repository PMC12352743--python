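"""Fitting the linear drift model to snapshot data by entropic transport.

The estimation principle: propagate the cells measured at time ``T_{k-1}``
through one Euler step of a candidate model,

    X_k = (I + dT_k A) Y_{k-1} + dT_k b,

and measure the entropic transport cost between the propagated cloud and the
cells actually measured at ``T_k``.  Summing over transitions (weighted by
``1/dT_k``, reflecting how noise variance accumulates with time) and adding
ridge penalties gives the objective

    J(A, b) = sum_k (1/dT_k) W(X_k, Y_k) + ||A Lambda_A^{1/2}||_F^2
              + lambda_b ||b||^2.

J is minimized by block coordinate descent: with (A, b) fixed, each W is a
standard entropic OT problem solved by Sinkhorn iterations; with the
transport plans fixed, the problem is quadratic in (A, b) and solved exactly
from its normal equations.  Both half-steps decrease J, so the cost trace is
non-increasing (up to the Sinkhorn tolerance).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .data_model import (
    FitConfig,
    GritValidationError,
    LinearDriftModel,
    SnapshotSeries,
)
from .entropic_ot import (
    TransportPlan,
    sinkhorn_from_points,
    squared_distance_matrix,
    transport_cost,
)

__all__ = [
    "FitResult",
    "propagate",
    "total_cost",
    "solve_model_given_plans",
    "fit",
    "barycentric_targets",
    "cell_velocities",
    "fit_ot_projection",
]

#: Above this many coupling-matrix entries, plans are kept in factored form
#: (potentials + points) instead of densely.
DENSE_PLAN_LIMIT = 30_000_000

#: Jitter added to a singular unregularized normal matrix.
RIDGE_JITTER = 1e-10


@dataclass
class FitResult:
    """Outcome of a block-coordinate-descent model fit."""

    model: LinearDriftModel
    plans: list[TransportPlan]
    cost_trace: np.ndarray
    n_iter: int
    converged: bool
    config: FitConfig | None = None
    extra: dict = field(default_factory=dict)

    @property
    def cost(self) -> float:
        return float(self.cost_trace[-1])


def propagate(Y: np.ndarray, A: np.ndarray, b: np.ndarray, dT: float) -> np.ndarray:
    """One Euler step of the drift applied to every cell (column) of Y."""
    Y = np.asarray(Y, dtype=float)
    A = np.asarray(A, dtype=float)
    b = np.asarray(b, dtype=float).ravel()
    if Y.ndim != 2 or A.shape != (Y.shape[0], Y.shape[0]) or b.shape != (Y.shape[0],):
        raise GritValidationError(
            f"incompatible shapes: Y {Y.shape}, A {A.shape}, b {b.shape}"
        )
    if dT <= 0:
        raise GritValidationError("dT must be > 0")
    return Y + dT * (A @ Y + b[:, None])


def fit_ot_projection(series: SnapshotSeries, ot_dim: int) -> np.ndarray:
    """Orthonormal PCA basis (n x ot_dim) of the pooled cells.

    Used only inside the transport cost, leaving model coordinates untouched.
    """
    from sklearn.decomposition import PCA

    pooled = series.pooled().T
    d = min(ot_dim, series.n_genes, pooled.shape[0])
    pca = PCA(n_components=d, svd_solver="full")
    pca.fit(pooled)
    return np.ascontiguousarray(pca.components_.T)


# ---------------------------------------------------------------------------
# Cost evaluation
# ---------------------------------------------------------------------------


def _transition_cost(plan: TransportPlan, X: np.ndarray, Q: np.ndarray, epsilon: float) -> float:
    """<C(X, Q), M> + eps sum M log M for a fixed plan and fresh source points."""
    if plan._M is not None and plan._points is None:
        C = squared_distance_matrix(X, Q)
        return transport_cost(C, plan)
    Xp, Qp = X, Q
    if plan._projection is not None:
        Xp = plan._projection.T @ X
        Qp = plan._projection.T @ Q
    r = plan.row_marginals()
    c = plan.col_marginals()
    x2 = np.einsum("ij,ij->j", Xp, Xp)
    q2 = np.einsum("ij,ij->j", Qp, Qp)
    cross = plan.cross_moment(Xp, Qp)
    transport = float(r @ x2 + c @ q2 - 2.0 * np.trace(cross))
    if plan._penalty_mask is not None:
        lp, lq, penalty = plan._penalty_mask
        masked_mass = 0.0
        for i0, i1, blk in plan._iter_blocks():
            masked_mass += float(blk[lp[i0:i1, None] != lq[None, :]].sum())
        transport += penalty * masked_mass
    return transport + epsilon * plan.entropy()


def _penalty_terms(A: np.ndarray, b: np.ndarray, config: FitConfig) -> float:
    lam = config.lambda_A_vector(A.shape[0])
    return float(np.sum(A * A * lam[None, :]) + config.lambda_b * np.sum(b * b))


def total_cost(
    model: LinearDriftModel,
    series: SnapshotSeries,
    plans: list[TransportPlan],
    config: FitConfig,
) -> float:
    """The objective J at a given model with the given (fixed) plans."""
    if len(plans) != series.n_transitions:
        raise GritValidationError("need one plan per transition")
    J = _penalty_terms(model.A, model.b, config)
    for k in range(1, series.n_transitions + 1):
        dT = series.dT(k)
        X = propagate(series.snapshots[k - 1], model.A, model.b, dT)
        J += _transition_cost(plans[k - 1], X, series.snapshots[k], config.epsilon) / dT
    return J


# ---------------------------------------------------------------------------
# Quadratic (A, b) update
# ---------------------------------------------------------------------------


def _accumulate_normal_equations(transitions) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Normal-equation pieces of the fixed-plan weighted least squares.

    Each transition contributes, for design matrix ``Phi`` (p x m_prev, the
    regressor rows evaluated at the source cells) and target snapshot ``Y``:

        H += dT * Phi diag(mu) Phi^T
        B += Phi diag(mu) Yprev^T - Phi M Y^T
        d += (1/dT) * [mu . yprev_g^2 + nu . y_g^2 - 2 (Yprev M Y^T)_gg]

    so that for any coefficient block theta_g the data term equals
    ``theta_g^T H theta_g + 2 B[:, g] . theta_g + d_g``.  The plan enters
    only through its fixed marginals and the cross-moment ``Phi M Y^T`` — a
    consequence of the quadratic structure.
    """
    first = transitions[0]
    p = first["Phi"].shape[0]
    n = first["Yprev"].shape[0]
    H = np.zeros((p, p))
    B = np.zeros((p, n))
    d = np.zeros(n)
    for tr in transitions:
        Phi, Yprev, Ynext, plan, dT = (
            tr["Phi"],
            tr["Yprev"],
            tr["Ynext"],
            tr["plan"],
            tr["dT"],
        )
        mu = plan.mu_P
        nu = plan.mu_Q
        Phi_w = Phi * mu[None, :]
        H += dT * (Phi_w @ Phi.T)
        T = plan.apply(Ynext.T)  # M @ Ynext^T, usually cached by the solver
        cross_Y = Yprev @ T
        cross_Phi = Phi @ T
        B += Phi_w @ Yprev.T - cross_Phi
        d += (
            (Yprev * Yprev) @ mu + (Ynext * Ynext) @ nu - 2.0 * np.diag(cross_Y)
        ) / dT
    return H, B, d


def _solve_ridge(H: np.ndarray, B: np.ndarray, penalty: np.ndarray) -> np.ndarray:
    """theta = -(H + diag(penalty))^{-1} B, with jitter fallback if singular."""
    Hreg = H + np.diag(penalty)
    try:
        L = np.linalg.cholesky(Hreg)
        from scipy.linalg import cho_solve

        return -cho_solve((L, True), B)
    except np.linalg.LinAlgError:
        scale = max(1.0, float(np.trace(H)) / H.shape[0])
        warnings.warn(
            "singular normal matrix in the quadratic model update; adding "
            f"{RIDGE_JITTER:g} ridge jitter (minimum-norm-like solution)",
            UserWarning,
            stacklevel=3,
        )
        return -np.linalg.solve(Hreg + RIDGE_JITTER * scale * np.eye(H.shape[0]), B)


def solve_model_given_plans(
    series: SnapshotSeries,
    plans: list[TransportPlan],
    config: FitConfig,
) -> tuple[np.ndarray, np.ndarray]:
    """Exact minimizer of J over (A, b) with the transport plans held fixed.

    The fixed-plan problem separates over target genes into ridge-penalized
    weighted least squares; the normal equations share one Gram matrix, so a
    single (n+1)-dimensional solve recovers the whole model.
    """
    if len(plans) != series.n_transitions:
        raise GritValidationError("need one plan per transition")
    n = series.n_genes
    transitions = []
    for k in range(1, series.n_transitions + 1):
        Yprev = series.snapshots[k - 1]
        Phi = np.vstack([Yprev, np.ones((1, Yprev.shape[1]))])
        transitions.append(
            {
                "Phi": Phi,
                "Yprev": Yprev,
                "Ynext": series.snapshots[k],
                "plan": plans[k - 1],
                "dT": series.dT(k),
            }
        )
    H, B, d = _accumulate_normal_equations(transitions)
    penalty = np.concatenate([config.lambda_A_vector(n), [config.lambda_b]])
    theta = _solve_ridge(H, B, penalty)
    A = theta[:n, :].T
    b = theta[n, :]
    return A, b


# ---------------------------------------------------------------------------
# Block coordinate descent
# ---------------------------------------------------------------------------


def _solve_transition_plans(
    series: SnapshotSeries,
    A: np.ndarray,
    b: np.ndarray,
    config: FitConfig,
    warm: list[tuple[np.ndarray, np.ndarray] | None],
    projection: np.ndarray | None,
    extra_loads: np.ndarray | None = None,
) -> tuple[list[TransportPlan], float]:
    """Sinkhorn solves of all transitions for the current model.

    Returns the plans and the summed weighted transport cost
    ``sum_k W_k / dT_k`` (evaluated exactly from the dual potentials).
    ``extra_loads`` optionally adds a per-transition load vector to the
    propagation (used for perturbation fits).
    """
    plans: list[TransportPlan] = []
    W_total = 0.0
    for k in range(1, series.n_transitions + 1):
        dT = series.dT(k)
        bk = b if extra_loads is None else b + extra_loads[k - 1]
        X = propagate(series.snapshots[k - 1], A, bk, dT)
        Y = series.snapshots[k]
        labels = None
        if series.branch_labels is not None:
            labels = (series.branch_labels[k - 1], series.branch_labels[k])
        plan = sinkhorn_from_points(
            X,
            Y,
            series.weights[k - 1],
            series.weights[k],
            config.epsilon,
            tol=config.sinkhorn_tol,
            max_iter=config.sinkhorn_max_iter,
            init=warm[k - 1],
            projection=projection,
            labels=labels,
            keep_dense=False,
            dtype=config.ot_dtype,
            apply_B=Y.T,
        )
        warm[k - 1] = (plan.f, plan.g)
        plans.append(plan)
        W_total += plan.regularized_cost() / dT
    return plans, W_total


def _accelerated_bcd(
    solve_plans,
    solve_quad,
    theta0: np.ndarray,
    config: FitConfig,
    max_outer: int,
    anderson_depth: int = 8,
    collect_trace: bool = True,
    safeguard: bool = True,
):
    """Anderson-accelerated block coordinate descent on a fixed-point map.

    ``solve_plans(theta)`` performs the transport half-step and returns
    ``(plans, J)``; ``solve_quad(plans)`` performs the quadratic half-step
    and returns the next parameter vector.  The plain alternation is a
    fixed-point iteration ``theta <- F(theta)``; Anderson mixing over the
    last few residuals accelerates its slow geometric tail.  Every
    extrapolated candidate is evaluated through ``solve_plans`` before
    acceptance: if it fails to decrease the objective (within a slack of
    ``10 * sinkhorn_tol``, the precision to which J itself is computed), the
    iteration retreats to the plain alternation point, whose objective is
    certified not to increase — so the recorded cost trace is non-increasing
    up to that slack.  Convergence requires both a relative objective change
    below ``outer_tol`` and a small fixed-point residual (the objective
    alone is too flat near the optimum to signal convergence reliably).
    """
    from collections import deque

    theta = theta0.copy()
    slack = 10.0 * config.sinkhorn_tol if safeguard else np.inf
    resid_tol = max(100.0 * config.outer_tol, 1e-5)
    thetas_F: deque = deque(maxlen=anderson_depth)
    resids: deque = deque(maxlen=anderson_depth)
    trace: list[float] = []
    J_prev = np.inf
    fallback: np.ndarray | None = None
    resid_rel = np.inf
    converged = False
    plans = None
    it = 0
    for it in range(max_outer):
        plans, J = solve_plans(theta)
        if J > J_prev + slack and fallback is not None:
            theta = fallback
            fallback = None
            plans, J = solve_plans(theta)
        if collect_trace:
            trace.append(J)
        if abs(J_prev - J) <= config.outer_tol * (1.0 + abs(J)) and resid_rel <= resid_tol:
            converged = True
            break
        J_prev = J
        theta_F = solve_quad(plans)
        resid = theta_F - theta
        resid_rel = float(np.linalg.norm(resid) / (1.0 + np.linalg.norm(theta_F)))
        thetas_F.append(theta_F.copy())
        resids.append(resid)
        fallback = theta_F
        if len(resids) >= 2:
            R = np.array(resids)
            dR = R[:-1] - R[-1]
            coef, *_ = np.linalg.lstsq(dR.T, -R[-1], rcond=None)
            Fs = np.array(thetas_F)
            theta = theta_F + coef @ (Fs[:-1] - Fs[-1])
        else:
            theta = theta_F
    return theta, plans, trace, it + 1, converged


#: Entropic-continuation schedule: (multiplier of the target epsilon, outer
#: iteration budget) for the warm-up stages preceding the final stage at the
#: target epsilon.  Coarse stages are cheap (diffuse plans converge in a few
#: alternations) and carry the model most of the way, which both cuts total
#: runtime and avoids poor stationary points of the non-convex objective.
CONTINUATION_SCHEDULE = ((8.0, 15), (3.0, 20))


def fit(
    series: SnapshotSeries,
    config: FitConfig,
    init: LinearDriftModel | None = None,
) -> FitResult:
    """Transport-based fit of the linear drift model.

    Block coordinate descent alternates Sinkhorn solves of all transition
    plans (model fixed) with the exact quadratic (A, b) update (plans
    fixed), starting from A = 0, b = 0 so that the first plans are plain
    static OT between consecutive snapshots.  Warm-up passes at inflated
    entropic regularization (see ``CONTINUATION_SCHEDULE``) precede the
    final stage at ``config.epsilon``; Anderson mixing accelerates the
    alternation throughout.  The returned cost trace covers the final stage
    and is non-increasing up to ``10 * sinkhorn_tol``.
    """
    if series.n_transitions < 1:
        raise GritValidationError("need at least two snapshots to fit dynamics")
    for k, mk in enumerate(series.cell_counts):
        if mk < 2:
            raise GritValidationError(f"snapshot {k} has fewer than 2 cells")
    n = series.n_genes
    if init is None:
        theta = np.zeros(n * (n + 1))
    else:
        theta = np.concatenate([init.A.ravel(), init.b.copy()])
    projection = None
    if config.ot_dim is not None and config.ot_dim < n:
        projection = fit_ot_projection(series, config.ot_dim)

    def unpack(th):
        return th[: n * n].reshape(n, n), th[n * n :]

    stages = [
        (mult * config.epsilon, budget) for mult, budget in CONTINUATION_SCHEDULE
    ] + [(config.epsilon, config.max_outer_iter)]

    plans: list[TransportPlan] = []
    trace: list[float] = []
    n_iter = 0
    converged = False
    for stage_idx, (eps, budget) in enumerate(stages):
        final = stage_idx == len(stages) - 1
        if final:
            stage_config = replace(config, epsilon=eps)
        else:
            # warm-up stages only need a rough minimizer: coarse tolerances
            # keep them cheap without affecting the final stage's precision
            stage_config = replace(
                config,
                epsilon=eps,
                outer_tol=max(config.outer_tol, 1e-5),
                sinkhorn_tol=max(config.sinkhorn_tol, 1e-6),
            )
        warm: list[tuple[np.ndarray, np.ndarray] | None] = [None] * series.n_transitions

        def solve_plans(th, _cfg=stage_config, _warm=warm):
            A, b = unpack(th)
            p, W = _solve_transition_plans(series, A, b, _cfg, _warm, projection)
            return p, W + _penalty_terms(A, b, _cfg)

        def solve_quad(p, _cfg=stage_config):
            A_new, b_new = solve_model_given_plans(series, p, _cfg)
            return np.concatenate([A_new.ravel(), b_new])

        theta, plans, stage_trace, its, conv = _accelerated_bcd(
            solve_plans, solve_quad, theta, stage_config, budget,
            collect_trace=final,
        )
        if final:
            trace = stage_trace
            n_iter = its
            converged = conv
    A, b = unpack(theta)
    model = LinearDriftModel(A=A, b=b, epsilon=config.epsilon)
    return FitResult(
        model=model,
        plans=plans,
        cost_trace=np.asarray(trace),
        n_iter=n_iter,
        converged=converged,
        config=config,
    )


# ---------------------------------------------------------------------------
# Plan-derived quantities
# ---------------------------------------------------------------------------


def barycentric_targets(
    series: SnapshotSeries, plans: list[TransportPlan]
) -> list[np.ndarray]:
    """Per-cell target points: plan-weighted means of next-time cells.

    For transition k the target of source cell i is the barycentric
    projection ``(Y_k M_k^T)_{:, i} / (M_k 1)_i`` — a convex combination of
    time-k cells, hence inside their convex hull.
    """
    if len(plans) != series.n_transitions:
        raise GritValidationError("need one plan per transition")
    targets = []
    for k in range(1, series.n_transitions + 1):
        plan = plans[k - 1]
        Y = series.snapshots[k]
        r = plan.row_marginals()
        if np.any(r <= 0):
            raise GritValidationError("plan has an empty row; cannot form targets")
        T = plan.apply(Y.T).T / r[None, :]
        targets.append(T)
    return targets


def cell_velocities(
    series: SnapshotSeries, plans: list[TransportPlan]
) -> list[np.ndarray]:
    """Difference-quotient velocity estimates (targets - Y_{k-1}) / dT_k."""
    targets = barycentric_targets(series, plans)
    return [
        (T - series.snapshots[k - 1]) / series.dT(k)
        for k, T in zip(range(1, series.n_transitions + 1), targets)
    ]
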