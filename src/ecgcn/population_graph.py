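"""Subject-similarity population graph and its spectral operators.

Vertices are subjects; an edge weight combines a Gaussian kernel on the
imaging feature vectors with an integer count of phenotype agreements:

    W_ij = exp(-||f_i - f_j||^2 / (2 sigma^2)) * sum_h delta_h(p_i, p_j)

with delta an exact-match indicator for categorical measures (gender) and
the indicator of |age_i - age_j| < gamma for age.  Entries are therefore
nonnegative and bounded by the number of phenotypic measures H.  Graph
convolution uses the symmetric normalised Laplacian, whose spectrum lies in
[0, 2]; Chebyshev filters operate on the rescaled operator
(2 / lambda_max) L - I, whose spectrum lies in [-1, 1].
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ValidationError


@dataclass
class PopulationGraph:
    """N x N nonnegative symmetric subject-affinity graph with phenotypes."""

    adjacency: np.ndarray
    sigma: float
    gamma: float
    phenotypes: pd.DataFrame = field(repr=False)
    feature_matrix: np.ndarray = field(repr=False)
    n_phenotypes: int = 2

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency, dtype=float)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValidationError("adjacency must be square")
        if not np.allclose(a, a.T, atol=1e-12):
            raise ValidationError("adjacency must be symmetric")
        if np.any(a < 0):
            raise ValidationError("adjacency entries must be nonnegative")
        if np.any(np.diag(a) != 0):
            raise ValidationError("adjacency diagonal must be zero")
        self.adjacency = a

    @property
    def n_subjects(self) -> int:
        return self.adjacency.shape[0]


@dataclass
class SpectralOperator:
    """Normalised Laplacian of a population graph and its Chebyshev rescaling."""

    laplacian_normalized: np.ndarray
    lambda_max: float
    laplacian_scaled: np.ndarray

    @property
    def n(self) -> int:
        return self.laplacian_normalized.shape[0]


def build_adjacency(
    feature_matrix: np.ndarray,
    phenotypes: pd.DataFrame,
    sigma: float = 1.0,
    gamma: float = 2.0,
) -> PopulationGraph:
    """Build the population graph from features and (age, gender) phenotypes.

    Defaults sigma=1, gamma=2 (kernel width and age-agreement threshold).
    Self-weights are set to zero: self-similarity carries no information for
    between-subject convolution.
    """
    if sigma <= 0:
        raise ValidationError("sigma must be positive")
    if gamma <= 0:
        raise ValidationError("gamma must be positive")
    f = np.asarray(feature_matrix, dtype=float)
    if f.ndim != 2:
        raise ValidationError("feature_matrix must be N x m")
    n = f.shape[0]
    if n < 2:
        raise ValidationError("need at least 2 subjects")
    for col in ("age", "gender"):
        if col not in phenotypes.columns:
            raise ValidationError(f"phenotypes table is missing column {col!r}")
    if len(phenotypes) != n:
        raise ValidationError("phenotype rows must match feature rows")

    sq_dists = np.sum((f[:, None, :] - f[None, :, :]) ** 2, axis=2)
    kernel = np.exp(-sq_dists / (2.0 * sigma**2))

    age = phenotypes["age"].to_numpy(dtype=float)
    gender = phenotypes["gender"].to_numpy()
    agree = (np.abs(age[:, None] - age[None, :]) < gamma).astype(float)
    agree += (gender[:, None] == gender[None, :]).astype(float)
    n_ph = 2
    if "education" in phenotypes.columns:
        edu = phenotypes["education"].to_numpy()
        agree += (edu[:, None] == edu[None, :]).astype(float)
        n_ph = 3

    w = kernel * agree
    np.fill_diagonal(w, 0.0)
    w = (w + w.T) / 2.0
    return PopulationGraph(
        adjacency=w,
        sigma=sigma,
        gamma=gamma,
        phenotypes=phenotypes.reset_index(drop=True),
        feature_matrix=f,
        n_phenotypes=n_ph,
    )


def spectral_operator(graph: PopulationGraph) -> SpectralOperator:
    """Symmetric normalised Laplacian and its [-1, 1]-rescaled version.

    Zero-degree (isolated) vertices get identity rows in L_norm, which keeps
    them fixed points of the convolution instead of dividing by zero.
    """
    w = graph.adjacency
    n = w.shape[0]
    deg = w.sum(axis=1)
    inv_sqrt = np.zeros(n)
    pos = deg > 0
    inv_sqrt[pos] = 1.0 / np.sqrt(deg[pos])
    norm_w = (inv_sqrt[:, None] * w) * inv_sqrt[None, :]
    lap = np.eye(n) - norm_w
    # isolated vertices: row is already e_i (identity), matching the convention
    lap = (lap + lap.T) / 2.0
    eigvals = np.linalg.eigvalsh(lap)
    lam_max = float(eigvals[-1])
    if lam_max <= 0:
        lam_max = 2.0  # fully disconnected graph: L = I, pick the generic bound
    scaled = (2.0 / lam_max) * lap - np.eye(n)
    return SpectralOperator(
        laplacian_normalized=lap, lambda_max=lam_max, laplacian_scaled=scaled
    )


def write_graph(graph: PopulationGraph, op: SpectralOperator | None, path: str | Path) -> None:
    """Write the adjacency as a delimited matrix plus a JSON sidecar."""
    path = Path(path)
    np.savetxt(path, graph.adjacency, delimiter="\t", fmt="%.10g")
    sidecar = {
        "sigma": graph.sigma,
        "gamma": graph.gamma,
        "phenotype_measures": ["age", "gender"]
        + (["education"] if graph.n_phenotypes == 3 else []),
        "lambda_max": op.lambda_max if op is not None else None,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))
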