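"""Gradient sensitivity analysis of a trained GCN and mapping of feature
indices back to directed ROI connections.

For each subject the relevance of feature ``d`` is the absolute partial
derivative of the model's class probability for that subject with respect
to that subject's own input value of the feature (all other subjects'
features held fixed).  Scores are averaged over subjects; features whose
mean score strictly exceeds ``mu + 1.5 * sigma`` (mean and population SD of
the mean scores) are reported as discriminant connections, sorted in
descending score order.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .gcn import GcnModel, cheb_basis, gcn_backward, gcn_forward
from .population_graph import SpectralOperator

MDD_CLASS = 1  # label coding: 1 = MDD (positive), 0 = HC


@dataclass
class RelevanceReport:
    """Per-feature sensitivity scores with the mu + 1.5 sigma selection."""

    per_subject: np.ndarray  # (N, m) nonnegative
    mean_scores: np.ndarray  # (m,)
    mu: float
    sigma_rel: float
    threshold: float
    selected: list[dict]  # feature_index, source, destination, score, ...

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.selected)


def relevance_scores(
    model: GcnModel,
    op: SpectralOperator | list[np.ndarray],
    features: np.ndarray,
    target_class: int | str = "mdd",
) -> np.ndarray:
    """``(N, m)`` matrix of absolute class-probability gradients.

    ``target_class`` is ``"mdd"`` (default), ``"predicted"`` (each subject's
    argmax class), or an explicit class index.  Dropout is never active.
    """
    if not model.trained:
        warnings.warn(
            "computing relevance scores for an untrained model", RuntimeWarning,
            stacklevel=2,
        )
    basis = op if isinstance(op, list) else cheb_basis(op, model.K)
    features = np.asarray(features, dtype=float)
    probs, cache = gcn_forward(model, basis, features, dropout_active=False)
    n = features.shape[0]
    if target_class == "mdd":
        classes = np.full(n, MDD_CLASS)
    elif target_class == "predicted":
        classes = probs.argmax(axis=1)
    else:
        classes = np.full(n, int(target_class))

    scores = np.zeros_like(features)
    for i in range(n):
        c = classes[i]
        # d p_{i,c} / d logits_{i,:} = p_{i,c} * (e_c - p_{i,:}); other rows 0
        d_logits = np.zeros_like(probs)
        d_logits[i] = -probs[i, c] * probs[i]
        d_logits[i, c] += probs[i, c]
        _, d_features = gcn_backward(model, cache, d_logits)
        scores[i] = np.abs(d_features[i])
    return scores


def select_discriminant(
    scores: np.ndarray,
    feature_indices: np.ndarray | None = None,
    R: int | None = None,
    kind: str = "ec",
    atlas: pd.DataFrame | None = None,
    sd_multiplier: float = 1.5,
    population_sd: bool = True,
) -> RelevanceReport:
    """Average scores over subjects and keep features above mu + 1.5 sigma.

    ``feature_indices`` maps score columns back into the full connectivity
    vector (as produced by the LASSO selector); when given together with
    ``R`` the selected entries are annotated with (source, destination) ROI
    pairs.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.ndim != 2 or scores.shape[1] < 2:
        raise ValidationError("need an N x m score matrix with m >= 2")
    mean_scores = scores.mean(axis=0)
    mu = float(mean_scores.mean())
    sigma = float(mean_scores.std(ddof=0 if population_sd else 1))
    threshold = mu + sd_multiplier * sigma
    keep = np.flatnonzero(mean_scores > threshold)
    order = keep[np.argsort(-mean_scores[keep], kind="stable")]

    selected = []
    for col in order:
        entry = {"feature_column": int(col), "score": float(mean_scores[col])}
        if feature_indices is not None:
            full_idx = int(np.asarray(feature_indices)[col])
            entry["feature_index"] = full_idx
            if R is not None:
                src, dst = map_index_to_connection(full_idx, R, kind)
                entry["source"] = src
                entry["destination"] = dst
                if atlas is not None:
                    names = atlas.set_index("index")["roi_name"]
                    entry["source_name"] = str(names.get(src, ""))
                    entry["destination_name"] = str(names.get(dst, ""))
        selected.append(entry)
    return RelevanceReport(
        per_subject=scores,
        mean_scores=mean_scores,
        mu=mu,
        sigma_rel=sigma,
        threshold=threshold,
        selected=selected,
    )


def map_index_to_connection(index: int, R: int, kind: str = "ec") -> tuple[int, int]:
    """Map a 1-based feature-vector index to a 1-based (source, destination).

    EC vectors concatenate destination columns: index ``v`` maps to
    destination ``ceil(v / R)`` and source ``v - (dest - 1) * R``.  FC
    vectors enumerate the strict upper triangle row-major.
    """
    if kind in ("ec", "gca"):
        if not (1 <= index <= R * R):
            raise ValidationError(f"EC index {index} out of range for R={R}")
        dest = (index - 1) // R + 1
        src = index - (dest - 1) * R
        return src, dest
    if kind == "fc":
        total = R * (R - 1) // 2
        if not (1 <= index <= total):
            raise ValidationError(f"FC index {index} out of range for R={R}")
        v = index - 1
        for i in range(1, R):
            row_len = R - i
            if v < row_len:
                return i, i + 1 + v
            v -= row_len
        raise AssertionError("unreachable")
    raise ValidationError(f"unknown kind {kind!r}")


def map_connection_to_index(src: int, dst: int, R: int, kind: str = "ec") -> int:
    """Inverse of :func:`map_index_to_connection` (1-based throughout)."""
    if kind in ("ec", "gca"):
        if src == dst:
            raise ValidationError("self-connections have no feature index")
        return (dst - 1) * R + src
    if kind == "fc":
        i, j = min(src, dst), max(src, dst)
        if i == j:
            raise ValidationError("diagonal has no FC index")
        # rows 1..i-1 contribute R-1, R-2, ... entries
        before = (i - 1) * R - (i - 1) * i // 2
        return before + (j - i)
    raise ValidationError(f"unknown kind {kind!r}")


def map_to_connections(
    indices: list[int], R: int, kind: str = "ec", atlas: pd.DataFrame | None = None
) -> list[dict]:
    """Annotate 1-based feature indices with (source, destination) ROI pairs."""
    out = []
    names = atlas.set_index("index")["roi_name"] if atlas is not None else None
    for v in indices:
        src, dst = map_index_to_connection(v, R, kind)
        entry = {"feature_index": int(v), "source": src, "destination": dst}
        if names is not None:
            entry["source_name"] = str(names.get(src, ""))
            entry["destination_name"] = str(names.get(dst, ""))
        out.append(entry)
    return out


def write_report(report: RelevanceReport, path: str | Path) -> None:
    """TSV of selected connections plus a JSON sidecar with the threshold."""
    path = Path(path)
    report.to_frame().to_csv(path, sep="\t", index=False)
    sidecar = {
        "mu": report.mu,
        "sigma": report.sigma_rel,
        "threshold": report.threshold,
        "n_selected": len(report.selected),
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))
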