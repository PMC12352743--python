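"""Core data containers and I/O for snapshot-resolved single-cell expression data.

The central object is :class:`SnapshotSeries`: an ordered collection of
genes x cells expression matrices ``Y_0 .. Y_N`` measured at strictly
increasing times ``T_0 .. T_N``.  Because single-cell measurements are
destructive, no cell appears in more than one snapshot; each snapshot is an
independent cross-sectional sample of the evolving cell population.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SnapshotSeries",
    "LinearDriftModel",
    "FitConfig",
    "GritValidationError",
    "GritFormatError",
    "LowCellCountWarning",
    "matched_epsilon",
    "read_series",
    "bin_by_pseudotime",
    "write_edge_list",
    "read_edge_list",
]

#: Minimum recommended number of cells per snapshot; below this the snapshot
#: may not span the (possibly reduced-dimension) space used in the transport
#: problem, so a warning is emitted on load.
MIN_RECOMMENDED_CELLS = 120


class GritValidationError(ValueError):
    """Raised when inputs violate the model's structural requirements."""


class GritFormatError(ValueError):
    """Raised when an input file cannot be interpreted."""


class LowCellCountWarning(UserWarning):
    """A snapshot has fewer cells than recommended for a stable transport fit."""


@dataclass
class SnapshotSeries:
    """Time-ordered cross-sectional expression snapshots.

    Parameters
    ----------
    gene_names
        Identifiers of the ``n`` genes (rows of every snapshot).
    snapshots
        List of ``n x m_k`` expression matrices, one per measurement time.
    times
        Strictly increasing measurement times ``T_0 .. T_N``.
    weights
        Optional per-snapshot cell masses ``mu_k`` (each sums to one).
        Defaults to uniform ``1/m_k``.
    branch_labels
        Optional per-snapshot arrays of categorical branch labels, used to
        restrict transport to within-branch couplings.
    branch_origins
        Labels that are allowed to appear for the first time after ``T_0``
        (newly arising sub-lineages).
    """

    gene_names: list[str]
    snapshots: list[np.ndarray]
    times: np.ndarray
    weights: list[np.ndarray] | None = None
    branch_labels: list[np.ndarray] | None = None
    branch_origins: set = field(default_factory=set)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.snapshots = [np.ascontiguousarray(Y, dtype=float) for Y in self.snapshots]
        n = len(self.gene_names)
        if len(self.snapshots) != len(self.times):
            raise GritValidationError("number of snapshots does not match number of times")
        if len(self.snapshots) == 0:
            raise GritValidationError("series must contain at least one snapshot")
        for k, Y in enumerate(self.snapshots):
            if Y.ndim != 2 or Y.shape[0] != n:
                raise GritValidationError(
                    f"snapshot {k} has shape {Y.shape}; expected {n} gene rows"
                )
            if Y.shape[1] == 0:
                raise GritValidationError(f"snapshot {k} contains no cells")
            if np.isnan(Y).any():
                raise GritValidationError(
                    f"snapshot {k} contains NaN expression values; remove or filter "
                    "affected cells upstream (imputation is deliberately not offered)"
                )
        if np.any(np.diff(self.times) <= 0):
            raise GritValidationError("times must be strictly increasing")
        if self.weights is None:
            self.weights = [np.full(Y.shape[1], 1.0 / Y.shape[1]) for Y in self.snapshots]
        else:
            self.weights = [np.asarray(w, dtype=float) for w in self.weights]
            for k, (w, Y) in enumerate(zip(self.weights, self.snapshots)):
                if w.shape != (Y.shape[1],):
                    raise GritValidationError(f"weight vector {k} has wrong length")
                if np.any(w < 0) or not np.isclose(w.sum(), 1.0):
                    raise GritValidationError(
                        f"weights of snapshot {k} must be nonnegative and sum to 1"
                    )
        if self.branch_labels is not None:
            self.branch_labels = [np.asarray(lbl) for lbl in self.branch_labels]
            for k, (lbl, Y) in enumerate(zip(self.branch_labels, self.snapshots)):
                if lbl.shape != (Y.shape[1],):
                    raise GritValidationError(f"branch labels of snapshot {k} have wrong length")
            self._validate_branch_continuity()

    def _validate_branch_continuity(self) -> None:
        assert self.branch_labels is not None
        seen = set(np.unique(self.branch_labels[0])) | set(self.branch_origins)
        for k in range(1, len(self.snapshots)):
            here = set(np.unique(self.branch_labels[k]))
            prev = set(np.unique(self.branch_labels[k - 1])) | set(self.branch_origins)
            orphans = here - prev
            if orphans:
                raise GritValidationError(
                    f"branch label(s) {sorted(map(str, orphans))} appear at time "
                    f"{self.times[k]} without occurring at the previous time and are "
                    "not declared as branch origins"
                )
            seen |= here

    # -- basic descriptors -------------------------------------------------

    @property
    def n_genes(self) -> int:
        return len(self.gene_names)

    @property
    def n_snapshots(self) -> int:
        return len(self.snapshots)

    @property
    def n_transitions(self) -> int:
        return len(self.snapshots) - 1

    @property
    def cell_counts(self) -> list[int]:
        return [Y.shape[1] for Y in self.snapshots]

    def dT(self, k: int) -> float:
        """Time increment of transition ``k`` (1-based: T_k - T_{k-1})."""
        if not 1 <= k <= self.n_transitions:
            raise IndexError(f"transition index {k} out of range")
        return float(self.times[k] - self.times[k - 1])

    @property
    def dTs(self) -> np.ndarray:
        return np.diff(self.times)

    def pooled(self) -> np.ndarray:
        """All cells of all snapshots, concatenated (genes x total cells)."""
        return np.concatenate(self.snapshots, axis=1)

    def map_snapshots(self, fn) -> "SnapshotSeries":
        """Return a copy of the series with ``fn`` applied to every snapshot."""
        return SnapshotSeries(
            gene_names=list(self.gene_names),
            snapshots=[fn(Y) for Y in self.snapshots],
            times=self.times.copy(),
            weights=[w.copy() for w in self.weights],
            branch_labels=None
            if self.branch_labels is None
            else [lbl.copy() for lbl in self.branch_labels],
            branch_origins=set(self.branch_origins),
        )


@dataclass
class LinearDriftModel:
    """Linear drift of the gene-expression SDE  dx = (A x + b) dt + eps dw.

    ``A`` is the n x n drift matrix whose entry ``A[g, h]`` quantifies the
    effect of regulator ``h`` on target ``g``; ``b`` is a constant load and
    ``epsilon`` the (isotropic, constant) noise intensity.
    """

    A: np.ndarray
    b: np.ndarray
    epsilon: float = 0.0

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=float)
        self.b = np.asarray(self.b, dtype=float).ravel()
        if self.A.ndim != 2 or self.A.shape[0] != self.A.shape[1]:
            raise GritValidationError("A must be square")
        if self.b.shape != (self.A.shape[0],):
            raise GritValidationError("b length must match A dimension")
        if not np.isfinite(self.epsilon):
            raise GritValidationError("epsilon must be finite")

    @property
    def n_genes(self) -> int:
        return self.A.shape[0]

    def stacked(self) -> np.ndarray:
        """The n x (n+1) matrix [A, b] used in model-error norms."""
        return np.hstack([self.A, self.b[:, None]])


def matched_epsilon(noise_intensity: float, dT: float = 1.0) -> float:
    """Entropic regularization matched to a given dynamical noise intensity.

    For one Euler step of length ``dT`` the state receives Gaussian noise of
    variance ``noise_intensity**2 * dT`` per coordinate.  With squared
    Euclidean transport cost, the entropic coefficient whose Gibbs kernel
    equals that transition density — i.e. for which entropic transport acts as
    exact noise deconvolution and the generating system is a stationary point
    of the fitting objective — is ``2 * noise_intensity**2 * dT``.
    """
    return 2.0 * float(noise_intensity) ** 2 * float(dT)


@dataclass
class FitConfig:
    """Hyper-parameters of the transport-based model fit.

    Attributes
    ----------
    epsilon
        Entropic regularization strength of the transport cost (> 0).  Should
        be matched to the expected dynamical noise; see
        :func:`matched_epsilon`.
    Lambda_A
        Per-regressor ridge weights (diagonal of the drift penalty); scalar or
        length-n array, all >= 0.
    lambda_b
        Ridge weight on the load vector b (>= 0).
    lambda_pert
        Ridge weight on condition-specific load vectors; defaults to
        ``lambda_b`` when None.
    ot_dim
        Optional dimension of a PCA projection applied (to both point clouds)
        only inside the transport cost; None disables the projection.
    """

    epsilon: float = 0.05
    Lambda_A: float | np.ndarray = 0.0
    lambda_b: float = 0.0
    lambda_pert: float | None = None
    max_outer_iter: int = 200
    outer_tol: float = 1e-6
    sinkhorn_tol: float = 1e-6
    sinkhorn_max_iter: int = 20000
    ot_dim: int | None = None
    ot_dtype: str = "float64"
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.epsilon > 0:
            raise GritValidationError("entropic epsilon must be > 0")
        lam = np.asarray(self.Lambda_A, dtype=float)
        if np.any(lam < 0):
            raise GritValidationError("Lambda_A entries must be >= 0")
        if self.lambda_b < 0:
            raise GritValidationError("lambda_b must be >= 0")
        if self.outer_tol <= 0 or self.sinkhorn_tol <= 0:
            raise GritValidationError("tolerances must be > 0")
        if self.max_outer_iter < 1 or self.sinkhorn_max_iter < 1:
            raise GritValidationError("iteration limits must be >= 1")
        if self.ot_dtype not in {"float32", "float64"}:
            raise GritValidationError("ot_dtype must be 'float32' or 'float64'")

    def lambda_A_vector(self, n: int) -> np.ndarray:
        lam = np.asarray(self.Lambda_A, dtype=float)
        if lam.ndim == 0:
            return np.full(n, float(lam))
        if lam.shape != (n,):
            raise GritValidationError("Lambda_A must be scalar or length-n")
        return lam


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def _read_expression_matrix(path: str | Path, cells_as_rows: bool = False):
    """Read a genes x cells matrix from delimited text or matrix-market.

    Matrix-market input expects sibling files ``<stem>_rows.txt`` (gene names)
    and ``<stem>_cols.txt`` (cell ids), one name per line.
    """
    path = Path(path)
    if path.suffix.lower() == ".mtx":
        from scipy.io import mmread

        raw = mmread(path)
        mat = np.asarray(raw.toarray() if hasattr(raw, "toarray") else raw, dtype=float)
        rows_file = path.with_name(path.stem + "_rows.txt")
        cols_file = path.with_name(path.stem + "_cols.txt")
        if not rows_file.exists() or not cols_file.exists():
            raise GritFormatError(
                f"matrix-market input {path} requires name files {rows_file.name} and {cols_file.name}"
            )
        row_names = rows_file.read_text().split()
        col_names = cols_file.read_text().split()
        df = pd.DataFrame(mat, index=row_names, columns=col_names)
    else:
        sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
        df = pd.read_csv(path, sep=sep, index_col=0)
    if cells_as_rows:
        df = df.T
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise GritFormatError(f"empty expression matrix in {path}")
    return df


def read_series(
    expression_path: str | Path,
    annotation_path: str | Path,
    cells_as_rows: bool = False,
) -> SnapshotSeries:
    """Load an expression matrix plus per-cell annotations into a series.

    The annotation table must contain columns ``cell_id`` and ``time`` and may
    contain ``branch``.  Cells are grouped by time into snapshots sorted by
    time, with uniform weights.  A warning (not an error) is emitted for any
    snapshot with fewer than 120 cells.
    """
    df = _read_expression_matrix(expression_path, cells_as_rows=cells_as_rows)
    ann = pd.read_csv(annotation_path)
    required = {"cell_id", "time"}
    if not required.issubset(ann.columns):
        raise GritFormatError(f"annotation table must contain columns {sorted(required)}")
    ann = ann.copy()
    ann["cell_id"] = ann["cell_id"].astype(str)
    cells = [str(c) for c in df.columns]
    missing = set(cells) - set(ann["cell_id"])
    extra = set(ann["cell_id"]) - set(cells)
    if missing or extra:
        raise GritFormatError(
            f"cell ids differ between matrix and annotation "
            f"({len(missing)} unannotated, {len(extra)} unknown)"
        )
    ann = ann.set_index("cell_id").loc[cells]
    times = np.sort(ann["time"].unique())
    snapshots, labels = [], []
    has_branch = "branch" in ann.columns
    for t in times:
        mask = (ann["time"] == t).to_numpy()
        if mask.sum() == 0:  # pragma: no cover - unique() precludes this
            raise GritValidationError(f"time {t} has no cells")
        block = df.loc[:, mask].to_numpy(dtype=float)
        if block.shape[1] < MIN_RECOMMENDED_CELLS:
            warnings.warn(
                f"snapshot at time {t} has only {block.shape[1]} cells; at least "
                f"{MIN_RECOMMENDED_CELLS} are recommended for a stable transport fit",
                LowCellCountWarning,
                stacklevel=2,
            )
        snapshots.append(block)
        if has_branch:
            labels.append(ann.loc[mask, "branch"].to_numpy())
    if len(times) == 1:
        warnings.warn(
            "series contains a single time point; consider pseudotime binning",
            UserWarning,
            stacklevel=2,
        )
    return SnapshotSeries(
        gene_names=[str(g) for g in df.index],
        snapshots=snapshots,
        times=np.asarray(times, dtype=float),
        branch_labels=labels if has_branch else None,
    )


def bin_by_pseudotime(
    expression: np.ndarray | pd.DataFrame,
    pseudotime: Sequence[float],
    n_bins: int,
    gene_names: Sequence[str] | None = None,
) -> SnapshotSeries:
    """Convert a single pseudotemporally ordered sample into snapshots.

    Cells are sorted by pseudotime (ties broken by original order, so the
    output is deterministic and invariant to any strictly monotone transform
    of the pseudotime) and split into ``n_bins`` contiguous bins of equal cell
    count; the remainder cells are spread over the first bins.  Bin index
    becomes the snapshot time, with unit spacing.
    """
    if isinstance(expression, pd.DataFrame):
        if gene_names is None:
            gene_names = [str(g) for g in expression.index]
        expression = expression.to_numpy(dtype=float)
    expression = np.asarray(expression, dtype=float)
    pt = np.asarray(pseudotime, dtype=float)
    n, m = expression.shape
    if pt.shape != (m,):
        raise GritValidationError("need exactly one pseudotime value per cell")
    if n_bins < 2:
        raise GritValidationError("n_bins must be >= 2")
    if n_bins > m:
        raise GritValidationError(f"n_bins={n_bins} exceeds the number of cells ({m})")
    order = np.argsort(pt, kind="stable")
    base, rem = divmod(m, n_bins)
    sizes = [base + 1 if i < rem else base for i in range(n_bins)]
    snapshots = []
    start = 0
    for size in sizes:
        snapshots.append(expression[:, order[start : start + size]])
        start += size
    if gene_names is None:
        gene_names = [f"g{i}" for i in range(n)]
    return SnapshotSeries(
        gene_names=list(gene_names),
        snapshots=snapshots,
        times=np.arange(n_bins, dtype=float),
    )


def write_edge_list(scores, path: str | Path, signed: bool | None = None) -> None:
    """Write ranked regulator->target confidences as a tab-separated file.

    Columns are ``Gene1`` (regulator), ``Gene2`` (target), ``Score``, plus
    ``Sign`` when sign information is present; rows sorted by descending
    score, ties broken by (regulator, target) order for stability.
    Masked self-edges are omitted.
    """
    rows = []
    S = scores.score
    has_sign = scores.sign is not None and (signed is None or signed)
    if signed and scores.sign is None:
        raise GritValidationError("signed output requested but scores carry no signs")
    for i, reg in enumerate(scores.regulator_names):
        for j, tgt in enumerate(scores.target_names):
            if scores.self_edges_masked and reg == tgt:
                continue
            row = {"Gene1": reg, "Gene2": tgt, "Score": S[i, j]}
            if has_sign:
                row["Sign"] = int(scores.sign[i, j])
            rows.append(row)
    df = pd.DataFrame(rows)
    df = df.sort_values(
        by=["Score", "Gene1", "Gene2"], ascending=[False, True, True], kind="stable"
    )
    df.to_csv(path, sep="\t", index=False)


def read_edge_list(path: str | Path) -> pd.DataFrame:
    """Read back a Gene1/Gene2/Score edge-list TSV."""
    df = pd.read_csv(path, sep="\t")
    if not {"Gene1", "Gene2", "Score"}.issubset(df.columns):
        raise GritFormatError("edge list must contain Gene1, Gene2, Score columns")
    return df
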