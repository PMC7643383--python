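"""Cross-validation, classification metrics, and the statistical utilities
used to characterise the classifier and the cohort.

The positive class throughout is MDD: sensitivity is the fraction of MDD
patients correctly flagged, specificity the fraction of healthy controls
correctly cleared.  AUC is the Mann-Whitney rank statistic on the
MDD-probability scores (ties averaged).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.model_selection import StratifiedKFold

from .exceptions import ValidationError
from .signals import CohortManifest


@dataclass
class FoldMetrics:
    acc: float
    sen: float
    spe: float
    auc: float
    tp: int
    tn: int
    fp: int
    fn: int


@dataclass
class MetricsReport:
    """Per-fold metrics plus mean and SD over folds."""

    per_fold: list[FoldMetrics] = field(default_factory=list)

    def _collect(self, name: str) -> np.ndarray:
        return np.array(
            [getattr(f, name) for f in self.per_fold if getattr(f, name) is not None],
            dtype=float,
        )

    def mean(self, name: str) -> float:
        vals = self._collect(name)
        return float(vals.mean()) if vals.size else float("nan")

    def sd(self, name: str) -> float:
        vals = self._collect(name)
        return float(vals.std(ddof=1)) if vals.size > 1 else 0.0

    def summary(self) -> dict:
        out = {}
        for m in ("acc", "sen", "spe", "auc"):
            out[m] = {"mean": self.mean(m), "sd": self.sd(m)}
        return out


@dataclass
class SensitivityCi:
    """Normal-approximation confidence interval from summary statistics."""

    mean: float
    sd: float
    n: int
    z: float
    marginal_error: float
    ci: tuple[float, float]


def stratified_folds(
    manifest_or_labels, k: int = 10, seed: int = 0
) -> list[tuple[list, list]]:
    """K-fold stratified partition; returns (train_ids, test_ids) per fold.

    Accepts a :class:`CohortManifest` (ids are subject ids) or a plain label
    vector (ids are positional indices).  Per-fold class counts differ from
    the proportional share by at most one subject; reproducible from seed.
    """
    if isinstance(manifest_or_labels, CohortManifest):
        ids = np.asarray(manifest_or_labels.subject_ids, dtype=object)
        labels = manifest_or_labels.labels
    else:
        labels = np.asarray(manifest_or_labels)
        ids = np.arange(len(labels))
    counts = np.unique(labels, return_counts=True)[1]
    if counts.min() < k:
        raise ValidationError(
            f"smallest class has {counts.min()} members; cannot stratify into {k} folds"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [
        (ids[tr].tolist(), ids[te].tolist())
        for tr, te in skf.split(np.zeros(len(labels)), labels)
    ]


def classification_metrics(
    y_true: np.ndarray, y_pred: np.ndarray, scores: np.ndarray | None = None
) -> FoldMetrics:
    """ACC, SEN, SPE from the confusion matrix and rank-statistic AUC.

    Labels are 0/1 with 1 = MDD (positive).  With a single-class truth the
    undefined metric (SEN or SPE) is reported as None with a warning.
    """
    y_true = np.asarray(y_true).astype(int)
    y_pred = np.asarray(y_pred).astype(int)
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    acc = (tp + tn) / len(y_true)
    sen = tp / (tp + fn) if (tp + fn) > 0 else None
    spe = tn / (tn + fp) if (tn + fp) > 0 else None
    if sen is None or spe is None:
        warnings.warn(
            "single-class truth: SEN or SPE undefined for this fold",
            RuntimeWarning,
            stacklevel=2,
        )
    auc = None
    if scores is not None and sen is not None and spe is not None:
        auc = _rank_auc(y_true, np.asarray(scores, dtype=float))
    return FoldMetrics(acc=acc, sen=sen, spe=spe, auc=auc, tp=tp, tn=tn, fp=fp, fn=fn)


def _rank_auc(y_true: np.ndarray, scores: np.ndarray) -> float:
    """AUC as the normalised Mann-Whitney U statistic with averaged ties."""
    pos = scores[y_true == 1]
    neg = scores[y_true == 0]
    ranks = stats.rankdata(scores)
    u = ranks[y_true == 1].sum() - len(pos) * (len(pos) + 1) / 2
    return float(u / (len(pos) * len(neg)))


def mcnemar_test(
    y_true: np.ndarray,
    pred_a: np.ndarray,
    pred_b: np.ndarray,
    exact_threshold: int = 25,
) -> tuple[float, float]:
    """Paired comparison of two classifiers on the same subjects.

    Discordant counts: ``b`` = A right & B wrong, ``c`` = A wrong & B right.
    For ``b + c >= exact_threshold`` the continuity-corrected chi-square
    ``(|b - c| - 1)^2 / (b + c)`` is used; otherwise the exact two-sided
    binomial test on ``min(b, c)`` of ``b + c`` tosses.
    Returns ``(statistic, p)``; the statistic is the chi-square value in the
    large-sample branch and ``min(b, c)`` in the exact branch.
    """
    y_true = np.asarray(y_true)
    pred_a = np.asarray(pred_a)
    pred_b = np.asarray(pred_b)
    if not (len(y_true) == len(pred_a) == len(pred_b)):
        raise ValidationError("prediction vectors must have equal length")
    right_a = pred_a == y_true
    right_b = pred_b == y_true
    b = int(np.sum(right_a & ~right_b))
    c = int(np.sum(~right_a & right_b))
    n_disc = b + c
    if n_disc == 0:
        return 0.0, 1.0
    if n_disc >= exact_threshold:
        statistic = (abs(b - c) - 1) ** 2 / n_disc
        p = float(stats.chi2.sf(statistic, df=1))
        return float(statistic), p
    k = min(b, c)
    p = float(min(1.0, 2.0 * stats.binom.cdf(k, n_disc, 0.5)))
    return float(k), p


def pearson_chi_square(table: np.ndarray) -> tuple[float, int]:
    """Pearson chi-square of independence (no continuity correction)."""
    table = np.asarray(table, dtype=float)
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValidationError("contingency table has a zero marginal")
    stat, _, dof, expected = stats.chi2_contingency(table, correction=False)
    if np.any(expected <= 0):
        raise ValidationError("expected counts must be positive")
    return float(stat), int(dof)


def two_sample_t(
    mean1: float,
    sd1: float,
    n1: int,
    mean2: float,
    sd2: float,
    n2: int,
    variant: str = "pooled",
) -> float:
    """Two-sample t statistic from summary statistics (pooled or Welch)."""
    if n1 < 2 or n2 < 2:
        raise ValidationError("need n >= 2 per group")
    if sd1 < 0 or sd2 < 0:
        raise ValidationError("standard deviations must be nonnegative")
    diff = mean1 - mean2
    if sd1 == 0 and sd2 == 0:
        if diff == 0:
            return 0.0
        raise ValidationError("zero variance with unequal means: t undefined")
    if variant == "pooled":
        sp2 = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / (n1 + n2 - 2)
        return float(diff / np.sqrt(sp2 * (1 / n1 + 1 / n2)))
    if variant == "welch":
        return float(diff / np.sqrt(sd1**2 / n1 + sd2**2 / n2))
    raise ValidationError("variant must be 'pooled' or 'welch'")


def sensitivity_ci(mean: float, sd: float, n: int, z: float = 1.96) -> SensitivityCi:
    """Confidence interval ``mean +- z * sd / sqrt(n)`` from fold summaries."""
    if n < 1:
        raise ValidationError("n must be >= 1")
    if sd < 0:
        raise ValidationError("sd must be nonnegative")
    me = z * sd / np.sqrt(n)
    return SensitivityCi(
        mean=mean, sd=sd, n=n, z=z, marginal_error=float(me),
        ci=(float(mean - me), float(mean + me)),
    )
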