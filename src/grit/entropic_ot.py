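"""Entropy-regularized optimal transport between weighted point clouds.

Given point clouds ``P`` (n x m_P) and ``Q`` (n x m_Q) with weights ``mu_P``
and ``mu_Q``, the regularized transport cost is

    W(P, Q) = min_M  sum_ij ||p_i - q_j||^2 M_ij + eps * sum_ij M_ij log M_ij
    s.t.     M 1 = mu_P,   M^T 1 = mu_Q,   M >= 0.

The plain entropy term (not KL against the product coupling) is used; the
minimizing plan is the same either way, only the reported cost differs by a
constant.  The problem is solved by Sinkhorn scaling iterations on the Gibbs
kernel ``exp(-C/eps)``, stabilized by absorbing large scalings into the dual
potentials so that cost-to-regularization ratios of order 10^3 and beyond do
not overflow.

Besides serving as a goodness-of-fit measure, the entropy regularization has
a dynamical reading: for squared-distance cost, the Gibbs kernel with
``eps = 2 sigma^2`` equals the transition density of an isotropic Gaussian
step of variance ``sigma^2``, so entropic transport acts as noise
deconvolution when matched to the noise of the process that generated the
data.
"""

from __future__ import annotations

import warnings

import numpy as np

from .data_model import GritValidationError

__all__ = [
    "TransportPlan",
    "SinkhornWarning",
    "squared_distance_matrix",
    "branch_mask",
    "sinkhorn",
    "sinkhorn_from_points",
    "transport_cost",
]

#: Cross-branch cost penalty, as a multiple of the largest within-branch cost.
BRANCH_PENALTY_FACTOR = 1e6


class SinkhornWarning(UserWarning):
    """Sinkhorn iterations exited before reaching the marginal tolerance."""


# ---------------------------------------------------------------------------
# Cost matrices
# ---------------------------------------------------------------------------


def squared_distance_matrix(
    P: np.ndarray,
    Q: np.ndarray,
    projection: np.ndarray | None = None,
    out: np.ndarray | None = None,
) -> np.ndarray:
    """Pairwise squared Euclidean distances between columns of P and of Q.

    ``projection`` (n x d, orthonormal columns) is applied to both clouds
    before the distance computation; this implements a reduced-dimension
    transport space without affecting the caller's coordinates.
    """
    P = np.asarray(P)
    Q = np.asarray(Q)
    if not np.issubdtype(P.dtype, np.floating):
        P = P.astype(float)
    if Q.dtype != P.dtype:
        Q = Q.astype(P.dtype)
    if P.ndim != 2 or Q.ndim != 2 or P.shape[0] != Q.shape[0]:
        raise GritValidationError(
            f"point clouds must share the coordinate dimension; got {P.shape} and {Q.shape}"
        )
    if projection is not None:
        projection = np.asarray(projection, dtype=P.dtype)
        P = projection.T @ P
        Q = projection.T @ Q
    p2 = np.einsum("ij,ij->j", P, P)
    q2 = np.einsum("ij,ij->j", Q, Q)
    C = np.matmul(P.T, Q, out=out)
    C *= -2.0
    C += p2[:, None]
    C += q2[None, :]
    np.maximum(C, 0.0, out=C)
    return C


def branch_mask(labels_P: np.ndarray, labels_Q: np.ndarray) -> np.ndarray:
    """Boolean matrix marking cross-branch (penalized) source/target pairs."""
    lp = np.asarray(labels_P)
    lq = np.asarray(labels_Q)
    return lp[:, None] != lq[None, :]


def _apply_branch_penalty(C: np.ndarray, mask: np.ndarray) -> float:
    """Add a large finite penalty to cross-branch entries of C, in place.

    A finite penalty (rather than infinity) keeps the Sinkhorn problem
    well-posed for any marginals; the resulting plan agrees with a block-wise
    per-branch solve whenever branch masses match.
    """
    within = C[~mask]
    scale = float(within.max()) if within.size else 1.0
    penalty = BRANCH_PENALTY_FACTOR * max(scale, 1.0)
    C[mask] += penalty
    return penalty


# ---------------------------------------------------------------------------
# Transport plans
# ---------------------------------------------------------------------------


class TransportPlan:
    """An entropic-OT coupling, stored densely or in factored (Gibbs) form.

    The optimal plan has the form ``M = exp((f_i + g_j - C_ij) / eps)`` for
    dual potentials ``f`` and ``g``.  For moderate problem sizes the dense
    ``M`` is kept; for large clouds only the potentials plus the source and
    target points are kept, and all contractions of ``M`` are computed in row
    blocks without materializing it.
    """

    def __init__(
        self,
        mu_P: np.ndarray,
        mu_Q: np.ndarray,
        epsilon: float,
        f: np.ndarray,
        g: np.ndarray,
        M: np.ndarray | None = None,
        points: tuple[np.ndarray, np.ndarray] | None = None,
        projection: np.ndarray | None = None,
        penalty_mask: tuple[np.ndarray, np.ndarray, float] | None = None,
        converged: float = np.nan,
        n_iter: int = 0,
        block_rows: int = 2048,
    ) -> None:
        self.mu_P = np.asarray(mu_P, dtype=float)
        self.mu_Q = np.asarray(mu_Q, dtype=float)
        self.epsilon = float(epsilon)
        self.f = np.asarray(f, dtype=float)
        self.g = np.asarray(g, dtype=float)
        self._M = M
        self._points = points
        self._projection = projection
        self._penalty_mask = penalty_mask
        self.converged = float(converged)
        self.n_iter = int(n_iter)
        self.block_rows = int(block_rows)
        # contractions harvested from the solver workspace (marginals and an
        # M @ B product), avoiding kernel rebuilds for the common reductions
        self._row_marg: np.ndarray | None = None
        self._col_marg: np.ndarray | None = None
        self._apply_cache: tuple[np.ndarray, np.ndarray] | None = None
        if M is None and points is None:
            raise GritValidationError("plan needs either a dense matrix or point factors")

    # -- construction helpers ---------------------------------------------

    @property
    def shape(self) -> tuple[int, int]:
        return (self.mu_P.size, self.mu_Q.size)

    def _cost_block(self, i0: int, i1: int) -> np.ndarray:
        X, Q = self._points
        C = squared_distance_matrix(X[:, i0:i1], Q, projection=self._projection)
        if self._penalty_mask is not None:
            lp, lq, penalty = self._penalty_mask
            C[lp[i0:i1, None] != lq[None, :]] += penalty
        return C

    def _block(self, i0: int, i1: int) -> np.ndarray:
        """Rows i0:i1 of M."""
        if self._M is not None:
            return self._M[i0:i1]
        C = self._cost_block(i0, i1)
        C -= self.f[i0:i1, None]
        C -= self.g[None, :]
        C /= -self.epsilon
        return np.exp(C, out=C)

    def _iter_blocks(self):
        m = self.shape[0]
        for i0 in range(0, m, self.block_rows):
            i1 = min(i0 + self.block_rows, m)
            yield i0, i1, self._block(i0, i1)

    # -- contractions ------------------------------------------------------

    def dense(self) -> np.ndarray:
        """The full coupling matrix (materialized on demand)."""
        if self._M is None:
            self._M = np.concatenate([blk for _, _, blk in self._iter_blocks()], axis=0)
        return self._M

    def row_marginals(self) -> np.ndarray:
        if self._row_marg is not None:
            return self._row_marg
        out = np.empty(self.shape[0])
        for i0, i1, blk in self._iter_blocks():
            out[i0:i1] = blk.sum(axis=1)
        self._row_marg = out
        return out

    def col_marginals(self) -> np.ndarray:
        if self._col_marg is not None:
            return self._col_marg
        out = np.zeros(self.shape[1])
        for _, _, blk in self._iter_blocks():
            out += blk.sum(axis=0)
        self._col_marg = out
        return out

    def total_mass(self) -> float:
        return float(self.row_marginals().sum())

    def apply(self, B: np.ndarray) -> np.ndarray:
        """M @ B for an (m_Q x k) matrix B."""
        B = np.asarray(B, dtype=float)
        if self._apply_cache is not None:
            cached_B, cached_MB = self._apply_cache
            if cached_B.shape == B.shape and np.array_equal(cached_B, B):
                return cached_MB
        out = np.empty((self.shape[0],) + B.shape[1:])
        for i0, i1, blk in self._iter_blocks():
            out[i0:i1] = blk @ B
        return out

    def apply_transpose(self, B: np.ndarray) -> np.ndarray:
        """M.T @ B for an (m_P x k) matrix B."""
        B = np.asarray(B, dtype=float)
        out = np.zeros((self.shape[1],) + B.shape[1:])
        for i0, i1, blk in self._iter_blocks():
            out += blk.T @ B[i0:i1]
        return out

    def cross_moment(self, L: np.ndarray, R: np.ndarray) -> np.ndarray:
        """L @ M @ R.T for matrices with m_P and m_Q columns respectively."""
        out = np.zeros((L.shape[0], R.shape[0]))
        for i0, i1, blk in self._iter_blocks():
            out += L[:, i0:i1] @ (blk @ R.T)
        return out

    def entropy(self) -> float:
        """sum_ij M_ij log M_ij with the convention 0 log 0 = 0."""
        total = 0.0
        for _, _, blk in self._iter_blocks():
            pos = blk[blk > 0]
            total += float(np.sum(pos * np.log(pos)))
        return total

    def regularized_cost(self) -> float:
        """<C, M> + eps * sum M log M, evaluated from the dual potentials.

        For a Gibbs-form plan, ``C_ij + eps log M_ij = f_i + g_j``, so the
        regularized cost collapses to ``f . (M 1) + g . (M^T 1)`` — exact
        and free of any m x m reduction.
        """
        return float(self.f @ self.row_marginals() + self.g @ self.col_marginals())

    def marginal_violation(self) -> float:
        return float(
            np.abs(self.row_marginals() - self.mu_P).sum()
            + np.abs(self.col_marginals() - self.mu_Q).sum()
        )

    def save_matrix_market(self, path) -> None:
        """Write the dense coupling to a matrix-market file for inspection."""
        from scipy.io import mmwrite
        from scipy.sparse import csr_matrix

        mmwrite(str(path), csr_matrix(self.dense()))

    def summary(self) -> "TransportPlan":
        """A lightweight copy without the dense matrix (factored plans only)."""
        if self._points is None:
            return self
        return TransportPlan(
            self.mu_P,
            self.mu_Q,
            self.epsilon,
            self.f,
            self.g,
            M=None,
            points=self._points,
            projection=self._projection,
            penalty_mask=self._penalty_mask,
            converged=self.converged,
            n_iter=self.n_iter,
            block_rows=self.block_rows,
        )


# ---------------------------------------------------------------------------
# Sinkhorn solver
# ---------------------------------------------------------------------------


def _validate_marginals(mu_P: np.ndarray, mu_Q: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mu_P = np.asarray(mu_P, dtype=float).ravel()
    mu_Q = np.asarray(mu_Q, dtype=float).ravel()
    for name, mu in (("mu_P", mu_P), ("mu_Q", mu_Q)):
        if np.any(mu < 0) or not np.isclose(mu.sum(), 1.0):
            raise GritValidationError(f"{name} must be nonnegative and sum to 1")
        if np.any(mu == 0):
            raise GritValidationError(f"{name} must be strictly positive")
    return mu_P, mu_Q


def _sinkhorn_potentials(
    build_K,
    mu_P: np.ndarray,
    mu_Q: np.ndarray,
    epsilon: float,
    tol: float,
    max_iter: int,
    f0: np.ndarray | None = None,
    g0: np.ndarray | None = None,
    omega: float = 1.8,
    apply_B: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, float, int, tuple | None]:
    """Stabilized, overrelaxed Sinkhorn scaling with kernel rebuilds.

    ``build_K(f, g)`` must return ``exp((f_i + g_j - C_ij)/eps)`` as a dense
    array.  Scalings are absorbed into the potentials (and the kernel rebuilt)
    whenever they grow large, so arbitrarily small ``eps`` is handled without
    overflow.  Successive-overrelaxation of the scaling updates (exponent
    ``omega`` in (1, 2)) accelerates the slow geometric tail at small ``eps``;
    the exponent is backed off automatically whenever the marginal violation
    stops decreasing, which keeps the iteration safe.  Returns final
    potentials, the l1 marginal violation at exit, and the iteration count.
    """
    m_P, m_Q = mu_P.size, mu_Q.size
    f = np.zeros(m_P) if f0 is None else np.array(f0, dtype=float)
    g = np.zeros(m_Q) if g0 is None else np.array(g0, dtype=float)
    K = build_K(f, g)
    dtype = K.dtype
    if dtype != np.float64:
        # single-precision workspace: cheaper kernels; marginal accuracy is
        # then limited to ~1e-5, so don't pretend to tighter tolerances
        tol = max(tol, 1e-5)
        mu_P = mu_P.astype(dtype)
        mu_Q = mu_Q.astype(dtype)
    tiny = float(np.finfo(dtype).tiny)
    absorb_hi = 1e30 if dtype != np.float64 else 1e50
    u = np.ones(m_P, dtype=dtype)
    v = np.ones(m_Q, dtype=dtype)
    Kv = K @ v
    violation = np.inf
    prev_violation = np.inf
    w = 1.0  # plain updates first; switch to overrelaxation once stable
    it = 0
    while it < max_iter:
        it += 1
        ru = mu_P / np.maximum(Kv, tiny)
        u = ru if w == 1.0 else u ** (1.0 - w) * ru**w
        KTu = K.T @ u
        rv = mu_Q / np.maximum(KTu, tiny)
        v = rv if w == 1.0 else v ** (1.0 - w) * rv**w
        if max(u.max(), v.max()) > absorb_hi or min(u.min(), v.min()) < 1.0 / absorb_hi:
            f += epsilon * np.log(np.maximum(u, tiny)).astype(float)
            g += epsilon * np.log(np.maximum(v, tiny)).astype(float)
            K = None  # release before rebuilding: halves peak memory at scale
            K = build_K(f, g)
            u = np.ones(m_P, dtype=dtype)
            v = np.ones(m_Q, dtype=dtype)
            Kv = K @ v
            continue
        Kv = K @ v
        violation = float(
            np.abs((u * Kv).astype(float) - mu_P).sum()
            + np.abs((v * KTu).astype(float) - mu_Q).sum()
        )
        if violation <= tol:
            break
        if it == 3:
            w = omega
        elif violation > 1.5 * prev_violation and w > 1.0:
            w = 1.0 + 0.5 * (w - 1.0)  # back off when overrelaxation overshoots
        prev_violation = violation
    # harvest cheap contractions from the final workspace before dropping it:
    # the plan is M = diag(u) K diag(v), so marginals and M @ B are two
    # matvecs plus one slim GEMM instead of a later kernel rebuild
    cached = None
    r = (u * (K @ v)).astype(float)
    c = (v * (K.T @ u)).astype(float)
    if apply_B is not None:
        vB = v[:, None] * np.asarray(apply_B, dtype=K.dtype)
        MB = (u[:, None] * (K @ vB)).astype(float)
        cached = (r, c, MB)
    else:
        cached = (r, c, None)
    f = f + epsilon * np.log(np.maximum(u, tiny)).astype(float)
    g = g + epsilon * np.log(np.maximum(v, tiny)).astype(float)
    return f, g, violation, it, cached


def sinkhorn(
    C: np.ndarray,
    mu_P: np.ndarray,
    mu_Q: np.ndarray,
    epsilon: float,
    tol: float = 1e-9,
    max_iter: int = 20000,
    init: tuple[np.ndarray, np.ndarray] | None = None,
) -> TransportPlan:
    """Solve the entropic OT problem for an explicit cost matrix.

    Returns a dense :class:`TransportPlan`.  Non-convergence within
    ``max_iter`` is reported through a warning and the plan's ``converged``
    attribute (the marginal violation at exit), not as an error.
    """
    if epsilon <= 0:
        raise GritValidationError("entropic epsilon must be > 0")
    C = np.asarray(C, dtype=float)
    mu_P, mu_Q = _validate_marginals(mu_P, mu_Q)
    if C.shape != (mu_P.size, mu_Q.size):
        raise GritValidationError(
            f"cost matrix shape {C.shape} does not match marginals "
            f"({mu_P.size}, {mu_Q.size})"
        )

    def build_K(f, g):
        logK = (f[:, None] + g[None, :] - C) / epsilon
        return np.exp(logK)

    f0 = g0 = None
    if init is not None:
        f0, g0 = init
    else:
        # start from row-min-subtracted kernel so small eps cannot zero out
        # entire rows of exp(-C/eps)
        f0 = C.min(axis=1)
        g0 = np.zeros(mu_Q.size)
    f, g, violation, n_iter, _ = _sinkhorn_potentials(
        build_K, mu_P, mu_Q, epsilon, tol, max_iter, f0, g0
    )
    if violation > tol:
        warnings.warn(
            f"Sinkhorn did not reach tol={tol:g} in {max_iter} iterations "
            f"(violation {violation:.3e})",
            SinkhornWarning,
            stacklevel=2,
        )
    M = build_K(f, g)
    return TransportPlan(
        mu_P, mu_Q, epsilon, f, g, M=M, converged=violation, n_iter=n_iter
    )


def sinkhorn_from_points(
    P: np.ndarray,
    Q: np.ndarray,
    mu_P: np.ndarray,
    mu_Q: np.ndarray,
    epsilon: float,
    tol: float = 1e-9,
    max_iter: int = 20000,
    init: tuple[np.ndarray, np.ndarray] | None = None,
    projection: np.ndarray | None = None,
    labels: tuple[np.ndarray, np.ndarray] | None = None,
    keep_dense: bool = True,
    dtype: str | np.dtype | None = None,
    apply_B: np.ndarray | None = None,
) -> TransportPlan:
    """Entropic OT between point clouds, building the cost matrix internally.

    With ``keep_dense=False`` the returned plan stores only the dual
    potentials and the point factors, so memory stays at one m_P x m_Q
    workspace during the solve and O(m) afterwards — the path used for
    large-population model fits.  ``labels`` activates the cross-branch cost
    penalty.  ``dtype="float32"`` runs the kernel workspace in single
    precision (half the memory and roughly twice the speed; marginal
    accuracy then bottoms out around 1e-5) — the returned plan always
    reconstructs in double precision from its potentials.
    """
    if epsilon <= 0:
        raise GritValidationError("entropic epsilon must be > 0")
    mu_P, mu_Q = _validate_marginals(mu_P, mu_Q)
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if P.shape[1] != mu_P.size or Q.shape[1] != mu_Q.size:
        raise GritValidationError("marginal lengths must match cloud sizes")
    work_dtype = np.float64 if dtype is None else np.dtype(dtype)

    # project once; the workspace then needs no further projection handling
    P_ot = projection.T @ P if projection is not None else P
    Q_ot = projection.T @ Q if projection is not None else Q
    Pw = np.ascontiguousarray(P_ot, dtype=work_dtype)
    Qw = np.ascontiguousarray(Q_ot, dtype=work_dtype)

    penalty_info = None
    if labels is not None:
        lp = np.asarray(labels[0])
        lq = np.asarray(labels[1])
        mask = branch_mask(lp, lq)
        Cprobe = squared_distance_matrix(Pw, Qw)
        penalty = _apply_branch_penalty(Cprobe, mask)
        del Cprobe
        penalty_info = (lp, lq, float(penalty))

    def build_K(f, g):
        C = squared_distance_matrix(Pw, Qw)
        if penalty_info is not None:
            C[branch_mask(penalty_info[0], penalty_info[1])] += penalty_info[2]
        C -= np.asarray(f, dtype=work_dtype)[:, None]
        C -= np.asarray(g, dtype=work_dtype)[None, :]
        C /= -epsilon
        return np.exp(C, out=C)

    if init is not None:
        f0, g0 = init
    else:
        # row-min stabilization so small eps cannot zero out entire rows
        g0 = np.zeros(mu_Q.size)
        C0 = squared_distance_matrix(Pw, Qw)
        if penalty_info is not None:
            C0[branch_mask(penalty_info[0], penalty_info[1])] += penalty_info[2]
        f0 = C0.min(axis=1).astype(float)
        del C0
    f, g, violation, n_iter, cached = _sinkhorn_potentials(
        build_K, mu_P, mu_Q, epsilon, tol, max_iter, f0, g0, apply_B=apply_B
    )
    if violation > tol:
        warnings.warn(
            f"Sinkhorn did not reach tol={tol:g} in {max_iter} iterations "
            f"(violation {violation:.3e})",
            SinkhornWarning,
            stacklevel=2,
        )
    M = build_K(f, g) if keep_dense and work_dtype == np.float64 else None
    plan = TransportPlan(
        mu_P,
        mu_Q,
        epsilon,
        f,
        g,
        M=M,
        points=(P.copy(), Q.copy()),
        projection=projection,
        penalty_mask=penalty_info,
        converged=violation,
        n_iter=n_iter,
    )
    if cached is not None:
        plan._row_marg, plan._col_marg, MB = cached
        if apply_B is not None and MB is not None:
            plan._apply_cache = (np.asarray(apply_B, dtype=float).copy(), MB)
    if keep_dense and M is None:
        plan.dense()  # materialize in double precision from the potentials
    return plan


def transport_cost(C: np.ndarray, plan: TransportPlan) -> float:
    """Regularized transport cost of a given plan under a given cost matrix.

    ``W = sum_ij C_ij M_ij + eps sum_ij M_ij log M_ij`` with ``0 log 0 = 0``.
    The entropy term is negative for diffuse plans, so W may be negative.
    """
    M = plan.dense()
    C = np.asarray(C, dtype=float)
    if C.shape != M.shape:
        raise GritValidationError("cost matrix and plan shapes differ")
    transport = float(np.sum(C * M))
    return transport + plan.epsilon * plan.entropy()
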