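"""Synthetic single-cell snapshot generators with known regulatory networks.

A ladder of generators of increasing realism, all emitting
:class:`~grit.data_model.SnapshotSeries` with cross-sectional sampling —
every snapshot is an independent cohort of cells propagated from time zero,
mimicking destructive measurement:

1. linear discrete-time dynamics (the model class the fit assumes exactly),
2. linear continuous-time dynamics (Euler–Maruyama with fine substeps),
3. nonlinear Michaelis–Menten kinetics with state-dependent Langevin noise,
4. Michaelis–Menten regulation routed through hidden protein states.

Ground truth is a sparse stable drift matrix plus load vector; its nonzero
off-diagonal pattern is the regulatory network used for evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data_model import GritValidationError, SnapshotSeries

__all__ = [
    "GroundTruth",
    "MMParams",
    "random_sparse_stable_system",
    "simulate_linear_discrete",
    "simulate_linear_continuous",
    "simulate_michaelis_menten",
    "simulate_with_proteins",
    "bulk_collapse",
    "default_mm_params",
]

#: Discrete-time stability margin: spectral radius of (I + dT*A) after rescaling.
SPECTRAL_RADIUS_BOUND = 0.98

#: Variance of the initial-state distribution P0 = N(m0, P0_VAR * I).
P0_VAR = 0.1

#: Default dynamical noise intensity of the linear generators: roughly 60%
#: of the initial population spread (sqrt(P0_VAR) ~ 0.32), so the dynamics
#: are genuinely stochastic while the regime stays cleanly identifiable.
DEFAULT_NOISE = 0.2


@dataclass
class GroundTruth:
    """A generating system (A_true, b_true) and its regulatory network.

    ``adjacency[h, g]`` is True when regulator h acts on target g, i.e. when
    ``A_true[g, h]`` is a structural nonzero (off-diagonal); ``sign`` holds
    the corresponding signs (+1 activation, -1 inhibition).
    """

    A_true: np.ndarray
    b_true: np.ndarray
    adjacency: np.ndarray = field(init=False)
    sign: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.A_true = np.asarray(self.A_true, dtype=float)
        self.b_true = np.asarray(self.b_true, dtype=float).ravel()
        n = self.A_true.shape[0]
        if self.A_true.shape != (n, n) or self.b_true.shape != (n,):
            raise GritValidationError("A_true must be square and b_true length-matched")
        off = self.A_true.T != 0.0
        np.fill_diagonal(off, False)
        self.adjacency = off
        self.sign = np.sign(self.A_true.T) * off

    @property
    def n_genes(self) -> int:
        return self.A_true.shape[0]

    @property
    def fixed_point(self) -> np.ndarray:
        return np.linalg.solve(self.A_true, -self.b_true)

    def stacked(self) -> np.ndarray:
        return np.hstack([self.A_true, self.b_true[:, None]])

    def permuted(self, perm: np.ndarray) -> "GroundTruth":
        """The same system with genes relabelled by ``perm``."""
        perm = np.asarray(perm)
        return GroundTruth(
            A_true=self.A_true[np.ix_(perm, perm)], b_true=self.b_true[perm]
        )


def random_sparse_stable_system(
    n: int,
    density: float = 0.2,
    seed: int | np.random.Generator = 0,
    dT: float = 1.0,
) -> GroundTruth:
    """Draw a sparse, discretely stable linear system with positive fixed point.

    Off-diagonal support is Bernoulli(density) with signed uniform weights;
    diagonals are negative (self-degradation).  The one-step map
    ``G = I + dT*A`` is rescaled, if needed, so its spectral radius is at
    most 0.98 — rescaling G preserves the support and signs of A's
    off-diagonal entries.  The load is chosen so the fixed point -A^{-1} b
    lies in [1, 2]^n.
    """
    if not 0.0 <= density <= 1.0:
        raise GritValidationError("density must be in [0, 1]")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    A = np.zeros((n, n))
    support = rng.random((n, n)) < density
    np.fill_diagonal(support, False)
    magnitudes = rng.uniform(0.25, 1.0, size=(n, n))
    signs = rng.choice([-1.0, 1.0], size=(n, n))
    A[support] = (magnitudes * signs)[support]
    np.fill_diagonal(A, rng.uniform(-1.2, -0.5, size=n))
    G = np.eye(n) + dT * A
    rho = float(np.max(np.abs(np.linalg.eigvals(G))))
    if rho > SPECTRAL_RADIUS_BOUND:
        G *= SPECTRAL_RADIUS_BOUND / rho
        A = (G - np.eye(n)) / dT
    x_star = rng.uniform(1.0, 2.0, size=n)
    b = -A @ x_star
    return GroundTruth(A_true=A, b_true=b)


def _initial_cells(
    truth: GroundTruth,
    m: int,
    rng: np.random.Generator,
    x0_mean: np.ndarray | None = None,
) -> np.ndarray:
    """Draws from P0 = N(m0, P0_VAR * I), truncated at zero.

    The default m0 = 0 places the population far from the system's fixed
    point (expression onset), so every snapshot series contains a clear mean
    transient toward the attractor — without it the mean never moves and the
    dynamics are observable only through weak covariance relaxation.
    """
    m0 = np.zeros(truth.n_genes) if x0_mean is None else np.asarray(x0_mean, dtype=float)
    x0 = m0[:, None] + np.sqrt(P0_VAR) * rng.standard_normal((truth.n_genes, m))
    return np.maximum(x0, 0.0)


def _make_series(truth: GroundTruth, snapshots, times) -> SnapshotSeries:
    return SnapshotSeries(
        gene_names=[f"g{i}" for i in range(truth.n_genes)],
        snapshots=snapshots,
        times=np.asarray(times, dtype=float),
    )


def simulate_linear_discrete(
    truth: GroundTruth,
    N: int,
    dT: float = 1.0,
    m: int = 1000,
    epsilon: float = DEFAULT_NOISE,
    seed: int | np.random.Generator = 0,
    longitudinal: bool = False,
    x0_mean: np.ndarray | None = None,
) -> SnapshotSeries:
    """Snapshots of the discrete-time linear recursion.

    Each cell follows ``x_k = (I + dT A) x_{k-1} + dT b + sqrt(dT) eps w_k``
    with standard-normal ``w_k`` (Euler–Maruyama increments of the linear
    SDE).  With ``longitudinal=False`` (the default) every snapshot is an
    independent cohort propagated from t=0, so no cell is observed twice;
    ``longitudinal=True`` tracks one cohort through all times (debugging of
    couplings only — real snapshot data are never longitudinal).
    """
    if N < 0 or m < 1 or dT <= 0:
        raise GritValidationError("need N >= 0, m >= 1, dT > 0")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    G = np.eye(truth.n_genes) + dT * truth.A_true
    shift = dT * truth.b_true[:, None]
    noise_scale = epsilon * np.sqrt(dT)
    snapshots = []
    if longitudinal:
        X = _initial_cells(truth, m, rng, x0_mean)
        snapshots.append(X.copy())
        for _ in range(N):
            X = G @ X + shift + noise_scale * rng.standard_normal(X.shape)
            snapshots.append(X.copy())
    else:
        for k in range(N + 1):
            X = _initial_cells(truth, m, rng, x0_mean)
            for _ in range(k):
                X = G @ X + shift + noise_scale * rng.standard_normal(X.shape)
            snapshots.append(X)
    return _make_series(truth, snapshots, dT * np.arange(N + 1))


def simulate_linear_continuous(
    truth: GroundTruth,
    times,
    m: int = 1000,
    epsilon: float = DEFAULT_NOISE,
    seed: int | np.random.Generator = 0,
    substeps: int = 100,
    x0_mean: np.ndarray | None = None,
) -> SnapshotSeries:
    """Euler–Maruyama simulation of the linear SDE observed at given times.

    Each observation interval is subdivided into ``substeps`` internal steps;
    every snapshot is an independent cohort integrated from t=0.
    """
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or times.size < 1 or np.any(np.diff(times) <= 0):
        raise GritValidationError("times must be strictly increasing")
    if times[0] != 0.0:
        raise GritValidationError("first observation time must be 0")
    if substeps < 1:
        raise GritValidationError("substeps must be >= 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    A, b = truth.A_true, truth.b_true[:, None]
    snapshots = []
    for k, t_obs in enumerate(times):
        X = _initial_cells(truth, m, rng, x0_mean)
        for j in range(k):
            h = (times[j + 1] - times[j]) / substeps
            for _ in range(substeps):
                X = X + h * (A @ X + b) + epsilon * np.sqrt(h) * rng.standard_normal(X.shape)
        snapshots.append(X)
    return _make_series(truth, snapshots, times)


@dataclass
class MMParams:
    """Rate parameters of the Michaelis–Menten simulators.

    ``V`` maximal transcription rates, ``gamma`` mRNA degradation rates,
    ``K`` the shared half-saturation constant; ``k_tl`` and ``gamma_p`` are
    used only by the hidden-protein simulator.
    """

    V: np.ndarray
    gamma: np.ndarray
    K: float = 1.0
    k_tl: np.ndarray | None = None
    gamma_p: np.ndarray | None = None


def default_mm_params(
    truth: GroundTruth,
    seed: int | np.random.Generator = 0,
    k_tl_range: tuple[float, float] = (0.5, 2.0),
    gamma_p_range: tuple[float, float] = (0.25, 2.0),
) -> MMParams:
    """Randomized rates: V in [1, 3], gamma in [0.5, 1.5], K = 1.

    Protein translation/degradation rates are drawn per gene from the given
    ranges; their spread is the main source of replicate-to-replicate
    performance variability in the hidden-state regime.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    n = truth.n_genes
    return MMParams(
        V=rng.uniform(1.0, 3.0, size=n),
        gamma=rng.uniform(0.5, 1.5, size=n),
        K=1.0,
        k_tl=rng.uniform(*k_tl_range, size=n),
        gamma_p=rng.uniform(*gamma_p_range, size=n),
    )


def _mm_production(X: np.ndarray, truth: GroundTruth, params: MMParams) -> np.ndarray:
    """Multiplicative Michaelis–Menten regulation evaluated per cell.

    production_g = V_g * prod_{h activates g} x_h/(K + x_h)
                       * prod_{h inhibits g} K/(K + x_h)
    """
    K = params.K
    act = X / (K + X)          # saturating activation response, in (0, 1)
    inh = K / (K + X)          # inhibition response
    log_act = np.log(np.maximum(act, 1e-300))
    log_inh = np.log(np.maximum(inh, 1e-300))
    A_mask = (truth.sign > 0).astype(float)  # regulator x target
    I_mask = (truth.sign < 0).astype(float)
    log_prod = A_mask.T @ log_act + I_mask.T @ log_inh
    return params.V[:, None] * np.exp(log_prod)


def _simulate_langevin(
    truth: GroundTruth,
    params: MMParams,
    times: np.ndarray,
    m: int,
    rng: np.random.Generator,
    substeps: int,
    hidden_proteins: bool,
    x0_range: tuple[float, float] = (0.2, 2.0),
) -> list[np.ndarray]:
    """Shared Langevin integrator for the nonlinear simulators."""
    n = truth.n_genes
    snapshots = []
    for k, t_obs in enumerate(times):
        X = rng.uniform(*x0_range, size=(n, m))
        if hidden_proteins:
            P = (params.k_tl / params.gamma_p)[:, None] * X
        for j in range(k):
            h = (times[j + 1] - times[j]) / substeps
            for _ in range(substeps):
                reg_state = P if hidden_proteins else X
                prod = _mm_production(reg_state, truth, params)
                deg = params.gamma[:, None] * X
                noise_sd = np.sqrt(np.maximum(prod + deg, 0.0) * h)
                X = X + h * (prod - deg) + noise_sd * rng.standard_normal(X.shape)
                np.maximum(X, 0.0, out=X)
                if hidden_proteins:
                    # exact solution of dp = (k_tl x - gamma_p p) dt over the
                    # substep (x held constant) — unconditionally stable, so
                    # arbitrarily fast protein rates remain well-behaved
                    decay = np.exp(-params.gamma_p * h)[:, None]
                    qss = (params.k_tl / params.gamma_p)[:, None] * X
                    P = qss + (P - qss) * decay
        snapshots.append(X)
    return snapshots


def simulate_michaelis_menten(
    truth: GroundTruth,
    params: MMParams | None = None,
    times=None,
    m: int = 1000,
    seed: int | np.random.Generator = 0,
    substeps: int = 100,
) -> SnapshotSeries:
    """Nonlinear kinetics: saturating transcription, linear degradation,
    state-dependent Langevin noise (variance = production + degradation),
    states clipped at zero.  Activation/inhibition follow the signs of the
    ground-truth network.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    if params is None:
        params = default_mm_params(truth, rng)
    times = np.arange(6, dtype=float) if times is None else np.asarray(times, dtype=float)
    if times[0] != 0.0 or np.any(np.diff(times) <= 0):
        raise GritValidationError("times must start at 0 and be strictly increasing")
    snapshots = _simulate_langevin(
        truth, params, times, m, rng, substeps, hidden_proteins=False
    )
    return _make_series(truth, snapshots, times)


def simulate_with_proteins(
    truth: GroundTruth,
    params: MMParams | None = None,
    times=None,
    m: int = 1000,
    seed: int | np.random.Generator = 0,
    substeps: int = 100,
) -> SnapshotSeries:
    """Michaelis–Menten regulation read from hidden protein concentrations.

    Each gene gets one protein with linear translation/degradation dynamics
    ``dp = (k_tl x - gamma_p p) dt``; regulation functions take proteins as
    input, and only mRNA levels are emitted in the snapshots.  In the limit
    of fast protein rates (k_tl, gamma_p large at fixed ratio) the output
    approaches :func:`simulate_michaelis_menten` distributionally.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    if params is None:
        params = default_mm_params(truth, rng)
    if params.k_tl is None or params.gamma_p is None:
        raise GritValidationError("protein simulation requires k_tl and gamma_p rates")
    times = np.arange(6, dtype=float) if times is None else np.asarray(times, dtype=float)
    if times[0] != 0.0 or np.any(np.diff(times) <= 0):
        raise GritValidationError("times must start at 0 and be strictly increasing")
    snapshots = _simulate_langevin(
        truth, params, times, m, rng, substeps, hidden_proteins=True
    )
    return _make_series(truth, snapshots, times)


def bulk_collapse(series: SnapshotSeries) -> SnapshotSeries:
    """Replace every cell by its snapshot's weighted mean expression.

    Cell counts are preserved, so the collapsed series is the bulk-data
    counterpart of the single-cell series (used to quantify how much the
    per-cell information contributes to inference).
    """

    collapsed = []
    for Y, w in zip(series.snapshots, series.weights):
        mean = (Y @ w)[:, None]
        collapsed.append(np.repeat(mean, Y.shape[1], axis=1))
    return SnapshotSeries(
        gene_names=list(series.gene_names),
        snapshots=collapsed,
        times=series.times.copy(),
        weights=[w.copy() for w in series.weights],
        branch_labels=None
        if series.branch_labels is None
        else [lbl.copy() for lbl in series.branch_labels],
        branch_origins=set(series.branch_origins),
    )
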