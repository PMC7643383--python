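"""End-to-end experiment orchestration.

One run performs, per stratified cross-validation fold:

1. connectivity features for every subject (group-sparse EC, Pearson FC,
   or pairwise Granger causality), estimated without any label use;
2. LASSO feature selection fitted on the *training* subjects of the fold;
3. population graph over all subjects from the selected features plus
   (age, gender) phenotypes — intentional transduction: test subjects'
   features shape the graph and the convolutions, their labels never do;
4. GCN training on the labelled training vertices, prediction of the
   held-out fold, and per-fold classification metrics;
5. sensitivity analysis of the fold model over all subjects.

Fold-level relevance scores are scattered back onto the full connectivity
vector, averaged over folds, and thresholded at mu + 1.5 sigma to produce
the discriminant-connection report.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from . import connectivity as conn
from .evaluation import MetricsReport, classification_metrics, stratified_folds
from .exceptions import ValidationError
from .feature_selection import apply_selector, fit_lasso_selector
from .gcn import TrainConfig, cheb_basis, init_gcn, predict, train_gcn
from .interpretation import relevance_scores, select_discriminant
from .population_graph import build_adjacency, spectral_operator
from .signals import CohortManifest, RoiTimeSeries, preprocess_series


@dataclass
class PipelineConfig:
    """All knobs of one experiment; everything downstream derives from seed."""

    feature_kind: str = "ec"  # ec | fc | gca
    alpha: float | str = "auto"  # group-sparse EC regularisation
    lasso_lambda: float | str = "auto"
    sigma: float = 1.0
    gamma: float = 2.0
    hidden_dims: list[int] = field(default_factory=lambda: [16])
    k_order: int = 3
    granger_order: int = 1
    train: TrainConfig = field(default_factory=TrainConfig)
    k_folds: int = 10
    seed: int = 0
    preprocess_band: tuple[float, float] | None = None
    target_class: str = "mdd"

    def __post_init__(self) -> None:
        if self.feature_kind not in ("ec", "fc", "gca"):
            raise ValidationError("feature_kind must be 'ec', 'fc', or 'gca'")
        if self.sigma <= 0 or self.gamma <= 0:
            raise ValidationError("sigma and gamma must be positive")
        if self.k_folds < 2:
            raise ValidationError("k_folds must be >= 2")
        if isinstance(self.train, dict):
            self.train = TrainConfig(**self.train)


def resolve_alpha(series: list[RoiTimeSeries], policy: float | str) -> float:
    """``"auto"`` resolves to 0.1 x the median over ROIs of alpha_max."""
    if policy != "auto":
        return float(policy)
    R = series[0].n_rois
    amax = [conn.alpha_max(series, r) for r in range(R)]
    return 0.1 * float(np.median(amax))


def compute_features(
    series: list[RoiTimeSeries], config: PipelineConfig
) -> tuple[np.ndarray, dict]:
    """N x D connectivity feature matrix for the configured feature kind."""
    meta: dict = {"feature_kind": config.feature_kind}
    if config.feature_kind == "ec":
        alpha = resolve_alpha(series, config.alpha)
        stack = conn.group_sparse_ec(series, conn.SolverConfig(alpha=alpha))
        mats = [stack.matrices[n] for n in range(stack.n_subjects)]
        meta["alpha"] = alpha
        meta["support_edges"] = int(stack.support_mask.sum())
    elif config.feature_kind == "fc":
        mats = [conn.pearson_fc(ts).matrix for ts in series]
    else:
        mats = [conn.granger_ec(ts, order=config.granger_order) for ts in series]
    kind = "fc" if config.feature_kind == "fc" else "ec"
    feats = conn.feature_matrix(mats, kind)
    return feats, meta


def run_pipeline(
    config: PipelineConfig,
    manifest: CohortManifest,
    series: list[RoiTimeSeries],
    atlas: pd.DataFrame | None = None,
    folds: list[tuple[list[int], list[int]]] | None = None,
) -> dict:
    """Run the full cross-validated experiment; returns the report dict.

    ``folds`` overrides the stratified partition with explicit
    (train_indices, test_indices) pairs, e.g. for audits of label isolation.
    """
    if len(series) != len(manifest):
        raise ValidationError("series list does not match manifest length")
    if config.preprocess_band is not None:
        series = [
            preprocess_series(ts, band=config.preprocess_band, standardize=True)
            for ts in series
        ]
    R = series[0].n_rois
    labels = manifest.labels  # 1 = MDD
    n = len(labels)
    vec_kind = "fc" if config.feature_kind == "fc" else "ec"

    features, feat_meta = compute_features(series, config)
    d_full = features.shape[1]

    if folds is None:
        folds = stratified_folds(labels, k=config.k_folds, seed=config.seed)
    report = MetricsReport()
    fold_records = []
    union_indices: set[int] = set()
    relevance_sum = np.zeros((n, d_full))
    predictions = np.full(n, -1, dtype=int)
    mdd_scores = np.full(n, np.nan)

    for fold_id, (train_idx, test_idx) in enumerate(folds):
        train_idx = np.asarray(train_idx, dtype=int)
        test_idx = np.asarray(test_idx, dtype=int)
        fold_seed = (config.seed * 100_003 + fold_id) % (2**31)

        selector = fit_lasso_selector(
            features[train_idx],
            labels[train_idx],
            lam=config.lasso_lambda,
            seed=fold_seed,
        )
        selected = apply_selector(selector, features)
        union_indices.update(selector.selected_indices.tolist())

        graph = build_adjacency(
            selected,
            manifest.table[["age", "gender"]],
            sigma=config.sigma,
            gamma=config.gamma,
        )
        op = spectral_operator(graph)
        basis = cheb_basis(op, config.k_order)

        model = init_gcn(
            selected.shape[1],
            hidden_dims=config.hidden_dims,
            K=config.k_order,
            seed=fold_seed,
        )
        # test labels are masked out before training ever sees the vector
        masked_labels = labels.copy()
        masked_labels[test_idx] = -1
        labeled_mask = np.zeros(n, dtype=bool)
        labeled_mask[train_idx] = True
        train_cfg = TrainConfig(**{**asdict(config.train), "seed": fold_seed})
        model, losses = train_gcn(
            model, basis, selected, masked_labels, labeled_mask, train_cfg
        )

        pred, probs = predict(model, basis, selected)
        predictions[test_idx] = pred[test_idx]
        mdd_scores[test_idx] = probs[test_idx, 1]
        fm = classification_metrics(
            labels[test_idx], pred[test_idx], probs[test_idx, 1]
        )
        report.per_fold.append(fm)

        scores = relevance_scores(model, basis, selected, target_class=config.target_class)
        relevance_sum[:, selector.selected_indices] += scores

        fold_records.append(
            {
                "fold": fold_id,
                "n_selected": selector.n_selected,
                "lambda": selector.lam,
                "final_loss": losses[-1],
                "test_ids": [manifest.subject_ids[i] for i in test_idx],
                "metrics": {
                    "acc": fm.acc,
                    "sen": fm.sen,
                    "spe": fm.spe,
                    "auc": fm.auc,
                },
            }
        )

    union = np.array(sorted(union_indices), dtype=int)
    relevance_mean = relevance_sum[:, union] / config.k_folds
    interpretation = None
    if union.size >= 2:
        rep = select_discriminant(
            relevance_mean,
            feature_indices=union + 1,  # 1-based connectivity indices
            R=R,
            kind=vec_kind,
            atlas=atlas,
        )
        interpretation = {
            "mu": rep.mu,
            "sigma": rep.sigma_rel,
            "threshold": rep.threshold,
            "selected": rep.selected,
        }

    return {
        "config": {
            "feature_kind": config.feature_kind,
            "sigma": config.sigma,
            "gamma": config.gamma,
            "hidden_dims": list(config.hidden_dims),
            "k_order": config.k_order,
            "k_folds": config.k_folds,
            "seed": config.seed,
            "train": asdict(config.train),
        },
        "features": feat_meta,
        "n_subjects": n,
        "n_rois": R,
        "folds": fold_records,
        "metrics": report.summary(),
        "n_selected_union": int(union.size),
        "interpretation": interpretation,
        "predictions": predictions.tolist(),
        "mdd_scores": [float(s) for s in mdd_scores],
    }
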