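"""Scoring of inferred networks and models against ground truth.

Edge predictions are compared to the true adjacency by threshold-free
ranking metrics: AUROC (midrank-tied Mann–Whitney form) and AUPR
(step-interpolated precision–recall area).  Because regulatory networks are
sparse, AUPR is the primary metric; the AUPR-ratio divides it by the network
density so that 1 corresponds to random guessing.  Model recovery is
measured by the squared Frobenius distance between the stacked [A, b]
blocks, and its empirical scaling with the number of cells per snapshot by
an ordinary least-squares slope in log-log coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score

from .data_model import GritValidationError, LinearDriftModel

__all__ = [
    "EvalReport",
    "auroc",
    "aupr",
    "aupr_ratio",
    "evaluate_scores",
    "sign_accuracy",
    "model_error",
    "convergence_slope",
]


@dataclass
class EvalReport:
    """Summary of one network-evaluation run."""

    auroc: float
    aupr: float
    aupr_ratio: float
    n_edges_evaluated: int
    mask_description: str
    sign_accuracy: float | None = None

    def as_dict(self) -> dict:
        out = {
            "auroc": self.auroc,
            "aupr": self.aupr,
            "aupr_ratio": self.aupr_ratio,
            "n_edges_evaluated": self.n_edges_evaluated,
            "mask": self.mask_description,
        }
        if self.sign_accuracy is not None:
            out["sign_accuracy"] = self.sign_accuracy
        return out


def _flatten(scores: np.ndarray, truth: np.ndarray, mask: np.ndarray | None):
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth).astype(bool)
    if scores.shape != truth.shape:
        raise GritValidationError("scores and truth must have identical shape")
    if mask is None:
        mask = np.ones_like(truth, dtype=bool)
        if scores.ndim == 2 and scores.shape[0] == scores.shape[1]:
            np.fill_diagonal(mask, False)
    else:
        mask = np.asarray(mask).astype(bool)
        if mask.shape != truth.shape:
            raise GritValidationError("mask shape must match scores")
    y = truth[mask].ravel()
    s = scores[mask].ravel()
    if not np.all(np.isfinite(s)):
        raise GritValidationError("scores contain non-finite values")
    if y.sum() == 0:
        raise GritValidationError("no positive edges inside the evaluation mask")
    if y.sum() == y.size:
        raise GritValidationError("no negative edges inside the evaluation mask")
    return s, y, mask


def auroc(scores: np.ndarray, truth: np.ndarray, mask: np.ndarray | None = None) -> float:
    """Rank-based AUROC with midrank tie handling (self-edges masked by default)."""
    s, y, _ = _flatten(scores, truth, mask)
    return float(roc_auc_score(y, s))


def aupr(scores: np.ndarray, truth: np.ndarray, mask: np.ndarray | None = None) -> float:
    """Step-interpolated area under the precision–recall curve."""
    s, y, _ = _flatten(scores, truth, mask)
    return float(average_precision_score(y, s))


def aupr_ratio(scores: np.ndarray, truth: np.ndarray, mask: np.ndarray | None = None) -> float:
    """AUPR divided by network density; ~1 for a random-guess scorer."""
    s, y, _ = _flatten(scores, truth, mask)
    density = y.mean()
    return float(average_precision_score(y, s) / density)


def sign_accuracy(
    sign_pred: np.ndarray,
    scores: np.ndarray,
    truth_sign: np.ndarray,
    mask: np.ndarray | None = None,
) -> float:
    """Fraction of correct signs among top-k true positives, k = #true edges.

    Only true edges ranked within the top k by score are sign-checked; this
    separates sign fidelity from ranking quality.
    """
    truth = np.asarray(truth_sign) != 0
    s, y, mask_used = _flatten(scores, truth, mask)
    k = int(y.sum())
    order = np.argsort(-s, kind="stable")
    top = np.zeros_like(y)
    top[order[:k]] = True
    hits = top & y
    if hits.sum() == 0:
        return float("nan")
    sp = np.asarray(sign_pred)[mask_used].ravel()
    st = np.asarray(truth_sign)[mask_used].ravel()
    return float(np.mean(sp[hits] == st[hits]))


def evaluate_scores(
    scores: np.ndarray,
    truth: np.ndarray,
    mask: np.ndarray | None = None,
    sign_pred: np.ndarray | None = None,
    truth_sign: np.ndarray | None = None,
) -> EvalReport:
    """AUROC / AUPR / AUPR-ratio (and optional sign accuracy) in one report."""
    s, y, mask_used = _flatten(scores, truth, mask)
    sa = None
    if sign_pred is not None and truth_sign is not None:
        sa = sign_accuracy(sign_pred, scores, truth_sign, mask_used)
    return EvalReport(
        auroc=float(roc_auc_score(y, s)),
        aupr=float(average_precision_score(y, s)),
        aupr_ratio=float(average_precision_score(y, s) / y.mean()),
        n_edges_evaluated=int(y.size),
        mask_description="self-edges excluded" if mask is None else "custom mask",
        sign_accuracy=sa,
    )


def model_error(model: LinearDriftModel, truth) -> float:
    """Squared Frobenius distance ||[A, b] - [A_true, b_true]||_F^2."""
    est = model.stacked()
    ref = truth.stacked() if hasattr(truth, "stacked") else np.asarray(truth, dtype=float)
    if est.shape != ref.shape:
        raise GritValidationError("model and truth dimensions differ")
    diff = est - ref
    return float(np.sum(diff * diff))


def convergence_slope(cell_counts, errors) -> float:
    """OLS slope of log(error) against log(cells per snapshot).

    An estimator whose squared error decays like m^(-1/2) yields slope -0.5.
    """
    m = np.asarray(cell_counts, dtype=float)
    e = np.asarray(errors, dtype=float)
    if m.shape != e.shape or m.size < 2:
        raise GritValidationError("need matching arrays of at least two points")
    if np.any(m <= 0) or np.any(e <= 0):
        raise GritValidationError("cell counts and errors must be positive")
    x = np.log(m)
    y = np.log(e)
    slope = np.polyfit(x, y, 1)[0]
    return float(slope)
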