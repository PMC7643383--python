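"""Connectivity estimation: group-sparse effective connectivity, Pearson
functional connectivity, pairwise Granger causality, and vectorisation.

Effective connectivity (EC) is estimated with a structural-equation-style
linear model: each ROI's signal is regressed on the signals of all other
ROIs recorded at the same time points.  Estimating the regression jointly
over subjects with an l2,1 (group-LASSO) penalty — one group per directed
connection, pooled across subjects — yields a connection skeleton shared
by the whole cohort while each subject keeps its own connection weights.

Conventions
-----------
EC matrices are ``R x R`` with entry ``(j, r)`` the coefficient of source
ROI ``j`` in the regression of destination ROI ``r``; the diagonal is
structurally zero (no self-connections).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .exceptions import ValidationError
from .signals import RoiTimeSeries

__all__ = [
    "SolverConfig",
    "EcStack",
    "FcMatrix",
    "group_sparse_ec",
    "alpha_max",
    "pearson_fc",
    "granger_ec",
    "vectorize_connectivity",
    "write_matrix",
]


@dataclass
class SolverConfig:
    """Settings for the group-sparse EC solver.

    alpha : regularisation magnitude; ``"auto"`` in the pipeline resolves to
        ``0.1 * median_r alpha_max(r)``.
    max_iter : FISTA iteration cap per destination ROI.
    tol : relative objective-change convergence threshold.
    standardize_inputs : z-score every ROI column per subject before
        solving, so one alpha is comparable across destination ROIs.
    """

    alpha: float = 0.1
    max_iter: int = 1000
    tol: float = 1e-6
    standardize_inputs: bool = True

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ValidationError("alpha must be nonnegative")
        if self.tol <= 0:
            raise ValidationError("tol must be positive")
        if self.max_iter < 1:
            raise ValidationError("max_iter must be positive")


@dataclass
class EcStack:
    """Per-subject directed EC matrices sharing one sparsity support.

    ``matrices[n][j, r]`` is the influence of source ROI ``j`` on
    destination ROI ``r`` for subject ``n``.  ``support_mask`` is the union
    of nonzero off-diagonal entries across subjects; the l2,1 penalty makes
    each subject's support (generically) identical to it.
    """

    matrices: np.ndarray  # (N, R, R)
    alpha: float
    support_mask: np.ndarray = field(default=None)  # (R, R) bool
    subject_ids: list[str] | None = None
    converged: np.ndarray | None = None  # (R,) bool, per destination
    objectives: np.ndarray | None = None  # (R,) final objective values

    def __post_init__(self) -> None:
        self.matrices = np.asarray(self.matrices, dtype=float)
        if self.matrices.ndim != 3 or self.matrices.shape[1] != self.matrices.shape[2]:
            raise ValidationError("matrices must be a (N, R, R) stack")
        if not np.all(np.isfinite(self.matrices)):
            raise ValidationError("EC matrices contain non-finite entries")
        diags = np.einsum("nii->ni", self.matrices)
        if np.any(diags != 0):
            raise ValidationError("EC diagonals must be exactly zero")
        if self.support_mask is None:
            self.support_mask = np.any(self.matrices != 0, axis=0)

    @property
    def n_subjects(self) -> int:
        return self.matrices.shape[0]

    @property
    def n_rois(self) -> int:
        return self.matrices.shape[1]


@dataclass
class FcMatrix:
    """Symmetric Pearson functional-connectivity matrix with unit diagonal."""

    matrix: np.ndarray
    subject_id: str | None = None

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValidationError("FC matrix must be square")
        if not np.allclose(m, m.T, atol=1e-12):
            raise ValidationError("FC matrix must be symmetric")
        if not np.allclose(np.diag(m), 1.0, atol=1e-12):
            raise ValidationError("FC diagonal must be 1")
        self.matrix = m


def _standardized_data(cohort: list[RoiTimeSeries], standardize: bool) -> list[np.ndarray]:
    out = []
    for ts in cohort:
        x = ts.data.astype(float)
        if standardize:
            sd = x.std(axis=0, ddof=1)
            sd = np.where(sd == 0, 1.0, sd)
            x = (x - x.mean(axis=0)) / sd
        out.append(x)
    return out


def _check_cohort(cohort: list[RoiTimeSeries]) -> int:
    if not cohort:
        raise ValidationError("empty cohort")
    rs = {ts.n_rois for ts in cohort}
    if len(rs) != 1:
        raise ValidationError(f"subjects disagree on number of ROIs: {sorted(rs)}")
    return rs.pop()


def alpha_max(
    cohort_series: list[RoiTimeSeries], r: int, standardize_inputs: bool = True
) -> float:
    """Smallest alpha for which the group-sparse solution at destination ``r``
    is identically zero.

    By the subgradient condition at W = 0 this is
    ``max_j sqrt(sum_n (x_n^j . x_n^r)^2)`` over predictor ROIs ``j != r``.
    """
    R = _check_cohort(cohort_series)
    if not (0 <= r < R):
        raise IndexError(f"ROI index {r} out of range for R={R}")
    data = _standardized_data(cohort_series, standardize_inputs)
    sq = np.zeros(R)
    for x in data:
        corr = x.T @ x[:, r]  # (R,)
        sq += corr**2
    sq[r] = 0.0
    return float(np.sqrt(sq.max()))


def _fista_group(
    Xs: list[np.ndarray],
    ys: list[np.ndarray],
    alpha: float,
    max_iter: int,
    tol: float,
) -> tuple[np.ndarray, bool, float, list[float]]:
    """Minimise 0.5*sum_n ||y_n - X_n w_n||^2 + alpha*sum_j ||W_j.||_2.

    W is (P, N): one coefficient column per subject, rows are groups.
    FISTA with group soft-thresholding; step 1/L with L the largest
    per-subject Gram eigenvalue (the smooth part is block diagonal in n).
    """
    N = len(Xs)
    P = Xs[0].shape[1]
    grams = [X.T @ X for X in Xs]
    xtys = np.column_stack([X.T @ y for X, y in zip(Xs, ys)])  # (P, N)
    L = max(
        (float(np.linalg.eigvalsh(G)[-1]) if P else 0.0) for G in grams
    )
    if L <= 0:
        return np.zeros((P, N)), True, 0.5 * sum(float(y @ y) for y in ys), []
    step = 1.0 / L

    def objective(W: np.ndarray) -> float:
        smooth = sum(
            0.5 * float(np.sum((ys[n] - Xs[n] @ W[:, n]) ** 2)) for n in range(N)
        )
        return smooth + alpha * float(np.sum(np.linalg.norm(W, axis=1)))

    def grad(W: np.ndarray) -> np.ndarray:
        return np.column_stack([grams[n] @ W[:, n] for n in range(N)]) - xtys

    def prox(W: np.ndarray, thr: float) -> np.ndarray:
        norms = np.linalg.norm(W, axis=1)
        scale = np.where(norms > thr, 1.0 - thr / np.where(norms > 0, norms, 1.0), 0.0)
        return W * scale[:, None]

    W = np.zeros((P, N))
    Z = W.copy()
    t = 1.0
    obj_prev = objective(W)
    trajectory = [obj_prev]
    converged = False
    for _ in range(max_iter):
        W_new = prox(Z - step * grad(Z), alpha * step)
        obj = objective(W_new)
        # Plain FISTA is not monotone; on an objective increase discard the
        # extrapolated step and take an ISTA step from the previous iterate
        # (non-increasing for step <= 1/L), restarting the momentum.
        if obj > obj_prev:
            W_new = prox(W - step * grad(W), alpha * step)
            obj = objective(W_new)
            t = 1.0
            t_new = 1.0
            Z = W_new.copy()
        else:
            t_new = (1.0 + np.sqrt(1.0 + 4.0 * t * t)) / 2.0
            Z = W_new + ((t - 1.0) / t_new) * (W_new - W)
        W, t = W_new, t_new
        trajectory.append(obj)
        denom = max(abs(obj_prev), 1e-12)
        if abs(obj_prev - obj) / denom < tol:
            converged = True
            break
        obj_prev = obj
    return W, converged, trajectory[-1], trajectory


def group_sparse_ec(
    cohort_series: list[RoiTimeSeries],
    config: SolverConfig | None = None,
    record_trajectories: bool = False,
) -> EcStack:
    """Estimate cohort EC by group-sparse multi-subject regression.

    For each destination ROI ``r`` the solver minimises

        0.5 * sum_n ||x_n^r - X_n^{\\r} w_n^{\\r}||^2  +  alpha * sum_j ||(w_{1,j},...,w_{N,j})||_2

    over the R-1 predictor ROIs ``j``, where the penalty groups one directed
    connection across all subjects.  A connection is therefore either pruned
    for every subject or retained for every subject, with individual weights.
    """
    config = config or SolverConfig()
    R = _check_cohort(cohort_series)
    N = len(cohort_series)
    data = _standardized_data(cohort_series, config.standardize_inputs)
    matrices = np.zeros((N, R, R))
    converged = np.zeros(R, dtype=bool)
    objectives = np.zeros(R)
    trajectories: list[list[float]] = []
    for r in range(R):
        keep = [j for j in range(R) if j != r]
        Xs = [x[:, keep] for x in data]
        ys = [x[:, r] for x in data]
        W, ok, obj, traj = _fista_group(
            Xs, ys, config.alpha, config.max_iter, config.tol
        )
        if not ok:
            warnings.warn(
                f"group-sparse solver did not converge for destination ROI {r}; "
                f"final objective {obj:.6g}",
                RuntimeWarning,
                stacklevel=2,
            )
        converged[r] = ok
        objectives[r] = obj
        if record_trajectories:
            trajectories.append(traj)
        matrices[:, keep, r] = W.T  # subject n's coefficients into column r
    stack = EcStack(
        matrices=matrices,
        alpha=config.alpha,
        subject_ids=[ts.subject_id for ts in cohort_series],
        converged=converged,
        objectives=objectives,
    )
    if record_trajectories:
        stack.trajectories = trajectories
    return stack


def pearson_fc(ts: RoiTimeSeries) -> FcMatrix:
    """Pairwise Pearson correlation matrix between ROI time series."""
    sd = ts.data.std(axis=0)
    constant = np.where(sd == 0)[0]
    if constant.size:
        names = (
            [ts.roi_names[i] for i in constant]
            if ts.roi_names
            else constant.tolist()
        )
        raise ValidationError(f"constant ROI columns cannot be correlated: {names}")
    m = np.corrcoef(ts.data, rowvar=False)
    np.fill_diagonal(m, 1.0)
    m = (m + m.T) / 2.0
    return FcMatrix(matrix=m, subject_id=ts.subject_id)


def granger_ec(ts: RoiTimeSeries, order: int = 1) -> np.ndarray:
    """Pairwise Granger-causality EC matrix.

    Entry ``(j, r)`` is ``ln(RSS_restricted / RSS_full)`` for predicting
    ROI ``r`` at lag order ``p``: the full model regresses ``x^r_t`` on
    lags of both ``x^r`` and ``x^j``; the restricted model drops the
    ``x^j`` lags.  Larger values mean the source's past improves the
    prediction of the destination.  Diagonal is zero by convention.
    """
    if order < 1:
        raise ValidationError("order must be >= 1")
    T, R = ts.data.shape
    if T <= 2 * order + 2:
        raise ValidationError(
            f"T={T} too short for Granger order {order}; need T > {2 * order + 2}"
        )
    x = ts.data
    n_obs = T - order
    lags = np.stack(
        [x[order - 1 - k : T - 1 - k, :] for k in range(order)], axis=2
    )  # (n_obs, R, order)
    intercept = np.ones((n_obs, 1))
    out = np.zeros((R, R))
    for r in range(R):
        y = x[order:, r]
        own = lags[:, r, :]  # (n_obs, order)
        design_r = np.column_stack([own, intercept])
        rss_restricted = _rss(design_r, y)
        for j in range(R):
            if j == r:
                continue
            design_f = np.column_stack([own, lags[:, j, :], intercept])
            rss_full = _rss(design_f, y)
            if rss_full <= 0:
                rss_full = np.finfo(float).tiny
            out[j, r] = max(0.0, float(np.log(rss_restricted / rss_full)))
    return out


def _rss(design: np.ndarray, y: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    return float(resid @ resid)


def vectorize_connectivity(matrix: np.ndarray, kind: str) -> np.ndarray:
    """Flatten a connectivity matrix into the pipeline's feature vector.

    ``kind="ec"`` (also used for Granger matrices): length ``R**2`` —
    destination columns concatenated in order, keeping the structural zero
    at each diagonal position so feature index <-> connection stays a fixed
    bijection.  ``kind="fc"``: length ``R*(R-1)/2`` — strictly upper
    triangular entries in row-major order.
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValidationError("connectivity matrix must be square")
    if kind in ("ec", "gca"):
        return m.flatten(order="F")
    if kind == "fc":
        iu = np.triu_indices(m.shape[0], k=1)
        return m[iu]
    raise ValidationError(f"unknown connectivity kind: {kind!r}")


def feature_matrix(matrices: list[np.ndarray], kind: str) -> np.ndarray:
    """Stack per-subject vectorised connectivity into an ``N x D`` matrix."""
    return np.vstack([vectorize_connectivity(m, kind) for m in matrices])


def write_matrix(
    matrix: np.ndarray,
    path: str | Path,
    subject_id: str | None = None,
    kind: str = "ec",
    alpha: float | None = None,
) -> None:
    """Write an R x R connectivity matrix as TSV with a JSON sidecar."""
    path = Path(path)
    np.savetxt(path, matrix, delimiter="\t", fmt="%.10g")
    sidecar = {
        "subject_id": subject_id,
        "kind": kind,
        "alpha": alpha,
        "convention": "entry[j][r]=source j -> destination r",
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))
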