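"""Regulatory-link confidence scores via greedy variable selection.

After the transport fit has converged, the plans are frozen and the model
objective becomes, per target gene, an ordinary (weighted, ridge-penalized)
least-squares problem over candidate regulator genes plus an intercept.
Link confidences come from a greedy forward-backward sweep on that problem:

* an initial active set per target combines the strongest absolute
  gene–gene correlations with forward-greedy picks (each step adds the
  regressor giving the largest cost decrease);
* a backward sweep then removes, at every step, the regressor whose removal
  increases the cost least, recording that increment.

The increment recorded at a regressor's removal is its confidence score —
raw drift-matrix magnitudes are sensitive to expression scale, whereas cost
increments measure how much predictive power a regulator actually carries.
Scores are normalized per target by the intercept-only (empty-set) cost so
they are comparable across genes; signs come from the fitted drift matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np

from .data_model import FitConfig, GritValidationError, LinearDriftModel, SnapshotSeries
from .entropic_ot import TransportPlan
from .model_fitting import _accumulate_normal_equations

__all__ = [
    "EdgeScores",
    "RegressionStats",
    "build_regression_stats",
    "initial_regressor_set",
    "backward_sweep",
    "edge_confidence_scores",
    "signed_edges",
]

DEFAULT_SIZE_CAP = 100


@dataclass
class EdgeScores:
    """Regulator x target confidence matrix with optional signs."""

    score: np.ndarray
    regulator_names: list[str]
    target_names: list[str]
    sign: np.ndarray | None = None
    self_edges_masked: bool = True

    def __post_init__(self) -> None:
        self.score = np.asarray(self.score, dtype=float)
        if np.any(~np.isfinite(self.score)) or np.any(self.score < 0):
            raise GritValidationError("scores must be finite and nonnegative")
        if self.sign is not None:
            self.sign = np.asarray(self.sign)
            if np.any((self.sign != 0) & (self.score == 0)):
                raise GritValidationError("sign must be zero where score is zero")


@dataclass
class RegressionStats:
    """Sufficient statistics of the fixed-plan regression, per target gene.

    ``H`` is the shared (n+1) x (n+1) Gram matrix over gene regressors plus
    intercept, ``C[:, g]`` the cross-moment vector of target g, ``d[g]`` the
    constant term, and ``penalty`` the ridge diagonal.  The cost of any
    regressor subset S for target g is

        cost(g, S) = d_g - c^T (H_SS + R_SS)^{-1} c,   c = C[S, g],

    evaluated in O(|S|^3); the intercept is always part of S.
    """

    H: np.ndarray
    C: np.ndarray
    d: np.ndarray
    penalty: np.ndarray
    gene_names: list[str] = field(default_factory=list)

    @property
    def n_genes(self) -> int:
        return self.d.size

    @property
    def intercept_index(self) -> int:
        """The intercept is always the last design column."""
        return self.H.shape[0] - 1

    def cost(self, target: int, regressors, include_self: bool = True) -> float:
        """Minimized fixed-plan cost of predicting ``target`` from a subset.

        The intercept is always active.  With ``include_self`` (the default)
        the target's own expression is also kept as an unscored regressor:
        first-order degradation acts on every gene, and leaving it out would
        force correlated other genes to absorb the decay term, corrupting
        the cost increments the link scores are built from.
        """
        idx = list(regressors)
        if include_self and target not in idx:
            idx = idx + [target]
        idx = idx + [self.intercept_index]
        Hs = self.H[np.ix_(idx, idx)] + np.diag(self.penalty[idx])
        c = self.C[idx, target]
        try:
            sol = np.linalg.solve(Hs, c)
        except np.linalg.LinAlgError:
            sol = np.linalg.lstsq(Hs, c, rcond=None)[0]
        value = self.d[target] - float(c @ sol)
        return value


def build_regression_stats(
    series: SnapshotSeries,
    plans: list[TransportPlan],
    config: FitConfig,
) -> RegressionStats:
    """Assemble the per-target quadratic forms from the frozen plans."""
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
    return RegressionStats(
        H=H, C=B, d=d, penalty=penalty, gene_names=list(series.gene_names)
    )


def _pooled_correlations(series: SnapshotSeries) -> np.ndarray:
    """Pearson correlations between genes over all pooled cells."""
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(series.pooled())
    return np.nan_to_num(corr, nan=0.0)


def initial_regressor_set(
    stats: RegressionStats,
    correlations: np.ndarray,
    target: int,
    size_cap: int,
    mask_self: bool = True,
) -> list[int]:
    """Initial active set: top correlations plus forward-greedy picks.

    The union of (i) the top-ceil(size_cap/2) genes by absolute correlation
    with the target and (ii) forward-greedy additions (each step adds the
    regressor with the largest cost decrease) until the set reaches
    ``size_cap``.  Ties break toward the lowest gene index.
    """
    n = stats.n_genes
    if size_cap < 1:
        raise GritValidationError("size_cap must be >= 1")
    candidates = [h for h in range(n) if not (mask_self and h == target)]
    cap = min(size_cap, len(candidates))
    if cap < size_cap:
        warnings.warn(
            f"size_cap clipped to the number of candidate regressors ({cap})",
            UserWarning,
            stacklevel=2,
        )
    n_corr = int(np.ceil(cap / 2))
    corr = np.abs(np.asarray(correlations)[:, target]).astype(float)
    # stable sort on (-|corr|, index) -> ties toward lower index
    ranked = sorted(candidates, key=lambda h: (-corr[h], h))
    active = ranked[:n_corr]
    while len(active) < cap:
        current = stats.cost(target, active)
        best_h, best_cost = None, np.inf
        for h in candidates:
            if h in active:
                continue
            c = stats.cost(target, active + [h])
            if c < best_cost - 1e-15:
                best_h, best_cost = h, c
        if best_h is None:
            break
        # least-squares cost cannot increase when a regressor is added
        active.append(best_h)
    return sorted(active)


def backward_sweep(
    stats: RegressionStats, target: int, active_set
) -> list[tuple[int, float]]:
    """Remove regressors one at a time, cheapest-to-remove first.

    At every step the regressor whose removal yields the smallest cost
    increase is dropped; returns ``(regressor, increment)`` pairs in removal
    order.  Increments are nonnegative (up to numerical noise) and telescope:
    their sum equals cost(empty) - cost(full active set).
    """
    active = sorted(active_set)
    removals: list[tuple[int, float]] = []
    current = stats.cost(target, active)
    while active:
        best_h, best_cost = None, np.inf
        for h in active:
            c = stats.cost(target, [x for x in active if x != h])
            if c < best_cost - 1e-15:
                best_h, best_cost = h, c
        removals.append((best_h, best_cost - current))
        active.remove(best_h)
        current = best_cost
    return removals


def edge_confidence_scores(
    series: SnapshotSeries,
    plans: list[TransportPlan],
    config: FitConfig,
    size_cap: int | None = None,
    regulators: list[int] | None = None,
) -> EdgeScores:
    """Backward-sweep cost increments as link confidences.

    ``score[h, g]`` is the cost increment recorded when regressor h was
    removed for target g, divided by the intercept-only cost of target g
    (removing sensitivity to expression scale).  Genes outside the initial
    active set score 0; self-edges are masked.  ``regulators`` optionally
    restricts the candidate regulator universe (e.g. to known TFs).
    """
    stats = build_regression_stats(series, plans, config)
    n = stats.n_genes
    corr = _pooled_correlations(series)
    cap = min(n - 1, DEFAULT_SIZE_CAP) if size_cap is None else size_cap
    S = np.zeros((n, n))
    universe = set(range(n) if regulators is None else regulators)
    for g in range(n):
        empty_cost = stats.cost(g, [], include_self=False)
        denom = empty_cost if empty_cost > 0 else 1.0
        candidates = sorted(universe - {g})
        if not candidates:
            continue
        active = initial_regressor_set(stats, corr, g, min(cap, len(candidates)))
        active = [h for h in active if h in universe]
        for h, increment in backward_sweep(stats, g, active):
            S[h, g] = max(increment, 0.0) / denom
    if regulators is not None:
        keep = np.zeros(n, dtype=bool)
        keep[list(universe)] = True
        S[~keep, :] = 0.0
    return EdgeScores(
        score=S,
        regulator_names=list(stats.gene_names),
        target_names=list(stats.gene_names),
        self_edges_masked=True,
    )


def signed_edges(model: LinearDriftModel, scores: EdgeScores) -> EdgeScores:
    """Attach activation/inhibition signs from the fitted drift matrix.

    ``sign[h, g] = sign(A[g, h])`` wherever the confidence is positive.  A
    structurally zero drift entry under a positive score keeps sign 0 (an
    inconsistency worth inspecting, reported via a warning).
    """
    S = scores.score
    sign = np.sign(model.A.T).astype(int)
    sign[S <= 0] = 0
    if np.any((S > 0) & (np.sign(model.A.T) == 0)):
        warnings.warn(
            "some positively scored links have a zero drift entry; their sign is 0",
            UserWarning,
            stacklevel=2,
        )
    return EdgeScores(
        score=S.copy(),
        regulator_names=list(scores.regulator_names),
        target_names=list(scores.target_names),
        sign=sign,
        self_edges_masked=scores.self_edges_masked,
    )
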