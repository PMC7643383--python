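"""Seeded synthetic rs-fMRI cohorts with the statistical structure the
pipeline assumes.

The generator emulates a two-group (MDD vs healthy-control) cohort at the
scale of a typical single-site clinical study: 29 patients and 44 controls
by default, each with a ``T x R`` ROI time-series.  Signals come from an
instantaneous linear structural-equation model

    x_t = A_n^T x_t + eps_t   =>   x_t = (I - A_n^T)^{-1} eps_t,

where ``A_n[j, r]`` is the directed influence of ROI ``j`` on ROI ``r`` for
subject ``n`` and ``eps_t ~ N(0, noise_sd^2 I)`` i.i.d. over time.  The
contemporaneous (rather than lagged) model matches the regression the EC
estimator fits.  All subjects share one sparse connection skeleton; weights
get per-subject jitter, and patients additionally have the weights of a
designated edge subset shifted by ``effect_size`` — the class signal the
classifier must find.  A VAR(1) mode generating lagged dependence is
provided for exercising Granger causality.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .signals import CohortManifest, RoiTimeSeries, write_manifest, write_timeseries

SPECTRAL_RADIUS_CAP = 0.9


@dataclass
class SimulationGroundTruth:
    """Everything the generator knows: skeleton, weights, and the class effect."""

    support: np.ndarray  # (R, R) bool, zero diagonal
    base_weights: np.ndarray  # (R, R)
    class_effect_edges: list[tuple[int, int]]  # (source, destination), 0-based
    effect_size: float
    subject_weights: np.ndarray  # (N, R, R)
    phenotype_rule: str


def _stabilize(a: np.ndarray) -> np.ndarray:
    """Rescale so the spectral radius is at most SPECTRAL_RADIUS_CAP."""
    radius = float(np.max(np.abs(np.linalg.eigvals(a))))
    if radius > SPECTRAL_RADIUS_CAP:
        a = a * (SPECTRAL_RADIUS_CAP / radius)
    return a


def simulate_cohort(
    n_mdd: int = 29,
    n_hc: int = 44,
    R: int = 114,
    T: int = 170,
    density: float = 0.1,
    effect_size: float = 1.0,
    noise_sd: float = 1.0,
    seed: int = 0,
    tr_seconds: float = 2.0,
    model: str = "sem",
    jitter_sd: float = 0.1,
    effect_edge_fraction: float = 0.2,
    age_shift: float = 0.0,
) -> tuple[CohortManifest, list[RoiTimeSeries], SimulationGroundTruth]:
    """Generate a labelled synthetic cohort; fully reproducible from the seed.

    Parameters
    ----------
    density
        Fraction of the ``R * (R - 1)`` possible directed edges present in
        the shared skeleton.
    effect_size
        Additive shift applied to patients' weights on the class-effect
        edges (a random 20% of skeleton edges by default); 0 means the two
        groups are statistically identical.
    model
        ``"sem"`` for the instantaneous model (default) or ``"var"`` for a
        VAR(1) process with the same coefficient matrix (for testing
        lag-based estimators).
    age_shift
        Optional mean age difference (years) added to the MDD group, making
        the phenotypes class-informative.
    """
    if not (0 < density < 1):
        raise ValidationError("density must be in (0, 1)")
    n_possible = R * (R - 1)
    n_edges = int(round(density * n_possible))
    if n_edges < 1:
        raise ValidationError("density too low: no edges in the skeleton")
    if noise_sd <= 0:
        raise ValidationError("noise_sd must be positive")
    if model not in ("sem", "var"):
        raise ValidationError("model must be 'sem' or 'var'")

    rng = np.random.default_rng(seed)
    n_total = n_mdd + n_hc

    # Shared skeleton: reciprocal connections.  Cortico-cortical projections
    # are predominantly bidirectional, and an instantaneous Gaussian model
    # cannot identify edge orientation anyway (the precision matrix is
    # symmetric), so the skeleton is drawn as undirected pairs with both
    # directions present: shared sign, independent magnitudes per direction.
    pairs = [(i, j) for i in range(R) for j in range(i + 1, R)]
    n_pairs = max(1, n_edges // 2)
    chosen = rng.choice(len(pairs), size=n_pairs, replace=False)
    support = np.zeros((R, R), dtype=bool)
    base = np.zeros((R, R))
    for c in chosen:
        i, j = pairs[c]
        sign = rng.choice([-1.0, 1.0])
        base[i, j] = sign * rng.uniform(0.2, 0.5)
        base[j, i] = sign * rng.uniform(0.2, 0.5)
        support[i, j] = support[j, i] = True
    n_edges = int(support.sum())
    base = _stabilize(base)

    n_effect = max(1, int(round(effect_edge_fraction * n_edges)))
    support_edges = [tuple(e) for e in np.argwhere(support)]
    effect_idx = rng.choice(len(support_edges), size=n_effect, replace=False)
    effect_edges = [support_edges[i] for i in effect_idx]

    labels = np.array(["MDD"] * n_mdd + ["HC"] * n_hc)
    subject_weights = np.zeros((n_total, R, R))
    series: list[RoiTimeSeries] = []
    for n in range(n_total):
        a = base.copy()
        a[support] += rng.normal(0.0, jitter_sd, size=n_edges)
        a[~support] = 0.0
        if labels[n] == "MDD" and effect_size != 0:
            for (j, r) in effect_edges:
                a[j, r] += effect_size
        a = _stabilize(a)
        radius = float(np.max(np.abs(np.linalg.eigvals(a))))
        if radius > SPECTRAL_RADIUS_CAP + 1e-9:
            raise RuntimeError("internal error: unstable mixing matrix after rescaling")
        subject_weights[n] = a

        eps = rng.normal(0.0, noise_sd, size=(T, R))
        if model == "sem":
            # x_t = A^T x_t + eps_t  (A[j, r]: source j -> destination r)
            mix = np.linalg.inv(np.eye(R) - a.T)
            data = eps @ mix.T
        else:
            data = np.zeros((T, R))
            data[0] = eps[0]
            for t in range(1, T):
                data[t] = a.T @ data[t - 1] + eps[t]
        series.append(
            RoiTimeSeries(subject_id=f"s{n + 1:03d}", data=data, tr_seconds=tr_seconds)
        )

    ages = rng.integers(20, 61, size=n_total).astype(float)
    if age_shift:
        ages[: n_mdd] += age_shift
    genders = np.where(rng.random(n_total) < 0.6, "F", "M")
    manifest = CohortManifest(
        pd.DataFrame(
            {
                "subject_id": [ts.subject_id for ts in series],
                "label": labels,
                "age": ages.astype(int),
                "gender": genders,
                "series_path": [f"{ts.subject_id}.tsv" for ts in series],
            }
        )
    )
    truth = SimulationGroundTruth(
        support=support,
        base_weights=base,
        class_effect_edges=effect_edges,
        effect_size=effect_size,
        subject_weights=subject_weights,
        phenotype_rule=(
            f"age ~ uniform integers 20-60 (+{age_shift} for MDD); "
            "gender ~ Bernoulli(0.6 female)"
        ),
    )
    return manifest, series, truth


def simulate_regression_fixture(
    T: int = 100,
    R: int = 10,
    sparsity: int = 3,
    noise_sd: float = 0.0,
    n_subjects: int = 2,
    seed: int = 0,
    tr_seconds: float = 2.0,
) -> tuple[list[RoiTimeSeries], np.ndarray]:
    """Exact single-destination fixture for the group-sparse solver.

    ROI 0 is the destination: its signal is a sparse linear combination of
    the other R-1 ROIs (i.i.d. standard normal) plus optional Gaussian
    noise.  The support (which predictors matter) is shared across subjects;
    the weights differ per subject.  Returns the series and the true
    coefficient matrix of shape ``(n_subjects, R)`` (entry 0 is the
    structural zero at the destination itself).
    """
    if sparsity >= R:
        raise ValidationError("sparsity must be < R")
    rng = np.random.default_rng(seed)
    support = rng.choice(np.arange(1, R), size=sparsity, replace=False)
    coefs = np.zeros((n_subjects, R))
    series = []
    for n in range(n_subjects):
        w = np.zeros(R)
        w[support] = rng.uniform(0.5, 1.5, size=sparsity) * rng.choice(
            [-1, 1], size=sparsity
        )
        coefs[n] = w
        x = rng.standard_normal((T, R))
        x[:, 0] = x[:, 1:] @ w[1:]
        if noise_sd > 0:
            x[:, 0] += rng.normal(0.0, noise_sd, size=T)
        series.append(
            RoiTimeSeries(subject_id=f"s{n + 1:03d}", data=x, tr_seconds=tr_seconds)
        )
    return series, coefs


def write_cohort(
    manifest: CohortManifest,
    series: list[RoiTimeSeries],
    truth: SimulationGroundTruth,
    out_dir: str | Path,
) -> None:
    """Write manifest CSV, per-subject series TSVs, and ground-truth JSON."""
    import json

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_manifest(manifest, out_dir / "manifest.csv")
    for ts in series:
        write_timeseries(ts, out_dir / f"{ts.subject_id}.tsv")
    payload = {
        "support": truth.support.astype(int).tolist(),
        "base_weights": truth.base_weights.tolist(),
        "class_effect_edges": [list(map(int, e)) for e in truth.class_effect_edges],
        "effect_size": truth.effect_size,
        "phenotype_rule": truth.phenotype_rule,
    }
    (out_dir / "ground_truth.json").write_text(json.dumps(payload))
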