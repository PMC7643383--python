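"""Supervised LASSO selection of informative connectivity features.

The connectivity feature vectors are high-dimensional (R**2 for directed EC,
R*(R-1)/2 for FC) against a few dozen subjects, so a sparse linear screen is
fitted on the *training* subjects of each cross-validation fold: an
l1-penalised least-squares regression of the 0/1 diagnostic label on the
column-standardised features.  Features with nonzero coefficients are kept.

Column standardisation parameters (mean/SD) are frozen from the training
subjects and re-applied verbatim to any later matrix, so test subjects never
influence the selection or the scaling.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import Lasso, LassoCV, LinearRegression

from .exceptions import ValidationError


@dataclass
class SelectorModel:
    """A fitted LASSO feature screen.

    selected_indices are positions into the full feature vector, strictly
    increasing; coefficients are the corresponding nonzero LASSO weights.
    """

    lam: float
    selected_indices: np.ndarray
    coefficients: np.ndarray
    column_means: np.ndarray = field(repr=False)
    column_sds: np.ndarray = field(repr=False)
    train_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.selected_indices = np.asarray(self.selected_indices, dtype=int)
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if np.any(np.diff(self.selected_indices) <= 0):
            raise ValidationError("selected_indices must be strictly increasing")
        if np.any(self.coefficients == 0):
            raise ValidationError("stored coefficients must be nonzero")
        if self.selected_indices.size and (
            self.selected_indices.min() < 0
            or self.selected_indices.max() >= self.column_means.size
        ):
            raise ValidationError("selected_indices out of range")

    @property
    def n_selected(self) -> int:
        return int(self.selected_indices.size)

    @property
    def n_features_in(self) -> int:
        return int(self.column_means.size)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "lambda": self.lam,
            "selected_indices": self.selected_indices.tolist(),
            "coefficients": self.coefficients.tolist(),
            "train_ids": self.train_ids,
            "standardization": {
                "means": self.column_means.tolist(),
                "sds": self.column_sds.tolist(),
            },
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "SelectorModel":
        d = json.loads(Path(path).read_text())
        return cls(
            lam=d["lambda"],
            selected_indices=np.asarray(d["selected_indices"], dtype=int),
            coefficients=np.asarray(d["coefficients"], dtype=float),
            column_means=np.asarray(d["standardization"]["means"], dtype=float),
            column_sds=np.asarray(d["standardization"]["sds"], dtype=float),
            train_ids=d.get("train_ids"),
        )


def _standardize(features: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    means = features.mean(axis=0)
    sds = features.std(axis=0)
    safe = np.where(sds == 0, 1.0, sds)
    return (features - means) / safe, means, safe


def fit_lasso_selector(
    features: np.ndarray,
    labels: np.ndarray,
    lam: float | str = "auto",
    train_ids: list[str] | None = None,
    seed: int = 0,
) -> SelectorModel:
    """Fit the LASSO screen on training subjects only.

    ``lam`` follows the scikit-learn scale: the objective is
    ``1/(2N) ||y - Xw||^2 + lam * ||w||_1`` on column-standardised features
    and 0/1 labels.  ``lam="auto"`` picks the value by internal 5-fold
    cross-validation on the training subjects.  ``lam=0`` degenerates to
    ordinary least squares (all features kept when full rank).
    """
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    if features.ndim != 2:
        raise ValidationError("features must be an N x D matrix")
    n, d = features.shape
    if n < 4:
        raise ValidationError("need at least 4 training subjects")
    classes = np.unique(labels)
    if classes.size < 2:
        raise ValidationError("training labels contain a single class")
    y = (labels == classes.max()).astype(float)
    z, means, sds = _standardize(features)
    if np.all(features.std(axis=0) == 0):
        raise ValidationError("all features are constant")

    if lam == "auto":
        cv_model = LassoCV(
            cv=5, random_state=seed, alphas=30, max_iter=5_000, tol=1e-3,
            precompute=True,
        )
        # the screen is deliberately run at loose coordinate-descent
        # tolerance: which features survive is stable long before the
        # coefficients fully converge
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            cv_model.fit(z, y)
            lam_val = float(cv_model.alpha_)
            coef = cv_model.coef_
            if not np.any(coef):
                # uninformative features can drive the CV choice to the null
                # model; keep the screen usable by stepping down the alpha
                # path to the largest value that retains at least one feature
                for alt in np.sort(cv_model.alphas_)[::-1]:
                    if alt >= lam_val:
                        continue
                    coef = (
                        Lasso(alpha=float(alt), max_iter=5_000, tol=1e-3)
                        .fit(z, y)
                        .coef_
                    )
                    if np.any(coef):
                        lam_val = float(alt)
                        break
    elif float(lam) == 0.0:
        lam_val = 0.0
        coef = LinearRegression().fit(z, y).coef_
    else:
        lam_val = float(lam)
        model = Lasso(alpha=lam_val, max_iter=20_000)
        model.fit(z, y)
        coef = model.coef_

    idx = np.flatnonzero(coef)
    return SelectorModel(
        lam=lam_val,
        selected_indices=idx,
        coefficients=coef[idx],
        column_means=means,
        column_sds=sds,
        train_ids=train_ids,
    )


def apply_selector(model: SelectorModel, features: np.ndarray) -> np.ndarray:
    """Standardise with the training parameters and keep the selected columns."""
    features = np.asarray(features, dtype=float)
    if features.ndim != 2 or features.shape[1] != model.n_features_in:
        raise ValidationError(
            f"feature dimension {features.shape} does not match the "
            f"{model.n_features_in} columns the selector was fitted on"
        )
    if model.n_selected == 0:
        raise ValidationError(
            "selector kept no features; lower lambda and refit"
        )
    z = (features - model.column_means) / model.column_sds
    return z[:, model.selected_indices]
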