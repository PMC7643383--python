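"""Chebyshev spectral graph convolutional network over the population graph.

The classifier is a small spectral GCN: each layer filters the N-subject
vertex-feature matrix H with a K-th order Chebyshev polynomial of the
rescaled normalised Laplacian L~ (spectrum in [-1, 1]),

    H_out = act( sum_{k=0..K} T_k(L~) @ H @ theta_k + b ),

with the recurrence T_0 = I, T_1 = L~, T_k = 2 L~ T_{k-1} - T_{k-2}.
Hidden layers use ReLU, the output layer a row-wise softmax over the two
diagnostic classes.  Training is transductive and full-batch: every subject
(labelled or not) participates in the convolutions, while the mean
cross-entropy loss is evaluated only on the labelled (training) vertices,
plus an l2 penalty ``weight_decay * sum(theta**2)`` on filter weights (not
biases).  All gradients are computed by hand-written reverse-mode
differentiation of this forward graph.

The cohort is small, so the K+1 dense ``T_k(L~)`` matrices are materialised
once and reused for the forward pass, backpropagation, and the sensitivity
analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import ValidationError
from .population_graph import SpectralOperator

__all__ = [
    "GcnLayer",
    "GcnModel",
    "TrainConfig",
    "init_gcn",
    "cheb_basis",
    "gcn_forward",
    "gcn_backward",
    "loss_and_gradients",
    "train_gcn",
    "predict",
    "gradient_check",
]


@dataclass
class GcnLayer:
    theta: np.ndarray  # (K+1, F_in, F_out)
    bias: np.ndarray  # (F_out,)


@dataclass
class GcnModel:
    """Layer parameters and architecture of the spectral GCN."""

    layers: list[GcnLayer]
    K: int
    hidden_dims: list[int]
    n_classes: int = 2
    trained: bool = False

    @property
    def f_in(self) -> int:
        return self.layers[0].theta.shape[1]

    def copy(self) -> "GcnModel":
        return GcnModel(
            layers=[GcnLayer(l.theta.copy(), l.bias.copy()) for l in self.layers],
            K=self.K,
            hidden_dims=list(self.hidden_dims),
            n_classes=self.n_classes,
            trained=self.trained,
        )


@dataclass
class TrainConfig:
    """Training hyperparameters.

    Defaults: full-batch gradient descent, learning rate 0.05, dropout 0.3
    on input and hidden activations, l2 weight decay 5e-4 on filter
    weights, 200 epochs.
    """

    learning_rate: float = 0.05
    dropout: float = 0.3
    weight_decay: float = 5e-4
    epochs: int = 200
    seed: int = 0
    optimizer: str = "gd"

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValidationError("learning_rate must be positive")
        if not (0 <= self.dropout < 1):
            raise ValidationError("dropout must be in [0, 1)")
        if self.weight_decay < 0:
            raise ValidationError("weight_decay must be nonnegative")
        if self.epochs < 1:
            raise ValidationError("epochs must be positive")
        if self.optimizer not in ("gd", "adam"):
            raise ValidationError("optimizer must be 'gd' or 'adam'")


def init_gcn(
    f_in: int,
    hidden_dims: list[int] | None = None,
    K: int = 3,
    seed: int = 0,
    n_classes: int = 2,
) -> GcnModel:
    """Glorot-uniform initialised GCN, reproducible from the seed.

    ``hidden_dims=[]`` yields a single-layer model (graph-filtered softmax
    regression).  Each layer holds a ``(K+1, F_in, F_out)`` weight tensor
    and a zero bias.
    """
    if f_in < 1:
        raise ValidationError("f_in must be >= 1")
    if K < 0:
        raise ValidationError("Chebyshev order K must be nonnegative")
    hidden_dims = [16] if hidden_dims is None else list(hidden_dims)
    rng = np.random.default_rng(seed)
    dims = [f_in] + hidden_dims + [n_classes]
    layers = []
    for d_in, d_out in zip(dims[:-1], dims[1:]):
        limit = np.sqrt(6.0 / (d_in * (K + 1) + d_out))
        theta = rng.uniform(-limit, limit, size=(K + 1, d_in, d_out))
        layers.append(GcnLayer(theta=theta, bias=np.zeros(d_out)))
    return GcnModel(layers=layers, K=K, hidden_dims=hidden_dims, n_classes=n_classes)


def cheb_basis(op: SpectralOperator, K: int) -> list[np.ndarray]:
    """Dense Chebyshev polynomials ``T_0..T_K`` of the rescaled Laplacian."""
    L = op.laplacian_scaled
    n = L.shape[0]
    basis = [np.eye(n)]
    if K >= 1:
        basis.append(L.copy())
    for _ in range(2, K + 1):
        basis.append(2.0 * L @ basis[-1] - basis[-2])
    return basis


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def gcn_forward(
    model: GcnModel,
    op: SpectralOperator | list[np.ndarray],
    features: np.ndarray,
    dropout: float = 0.0,
    dropout_active: bool = False,
    rng: np.random.Generator | None = None,
):
    """Forward pass; returns ``(probabilities, cache)``.

    Inverted dropout is applied to the input features and each hidden
    activation only when ``dropout_active`` (training); never to the softmax
    output, and never at inference.
    """
    basis = op if isinstance(op, list) else cheb_basis(op, model.K)
    features = np.asarray(features, dtype=float)
    if features.ndim != 2:
        raise ValidationError("features must be N x F_in")
    if features.shape[0] != basis[0].shape[0]:
        raise ValidationError(
            f"operator is over {basis[0].shape[0]} vertices but features have "
            f"{features.shape[0]} rows"
        )
    if features.shape[1] != model.f_in:
        raise ValidationError(
            f"model expects F_in={model.f_in}, features have {features.shape[1]}"
        )
    use_dropout = dropout_active and dropout > 0
    if use_dropout and rng is None:
        rng = np.random.default_rng(0)

    h = features
    cache = {"basis": basis, "layers": [], "features": features}
    n_layers = len(model.layers)
    for li, layer in enumerate(model.layers):
        mask = None
        if use_dropout:  # input (li=0) and hidden activations (li>0)
            mask = (rng.random(h.shape) >= dropout) / (1.0 - dropout)
            h = h * mask
        tkh = [tk @ h for tk in basis]  # (K+1) x (N, F_in)
        z = sum(t @ layer.theta[k] for k, t in enumerate(tkh)) + layer.bias
        cache["layers"].append({"h_in": h, "tkh": tkh, "z": z, "mask": mask})
        h = np.maximum(z, 0.0) if li < n_layers - 1 else z
    probs = _softmax(h)
    cache["probs"] = probs
    return probs, cache


def gcn_backward(model: GcnModel, cache: dict, d_logits: np.ndarray):
    """Reverse-mode pass from an output-logit seed.

    Returns ``(grads, d_features)`` where grads is a list of
    ``(d_theta, d_bias)`` per layer and ``d_features`` is the gradient with
    respect to the (pre-dropout) input feature matrix.
    """
    basis = cache["basis"]
    grads: list[tuple[np.ndarray, np.ndarray]] = [None] * len(model.layers)
    dz = d_logits
    for li in range(len(model.layers) - 1, -1, -1):
        layer = model.layers[li]
        lc = cache["layers"][li]
        d_theta = np.stack([t.T @ dz for t in lc["tkh"]])  # (K+1, F_in, F_out)
        d_bias = dz.sum(axis=0)
        grads[li] = (d_theta, d_bias)
        # d wrt layer input: sum_k T_k^T (dz theta_k^T); T_k symmetric
        dh = np.zeros_like(lc["h_in"])
        for k, tk in enumerate(basis):
            dh += tk @ (dz @ layer.theta[k].T)
        if lc["mask"] is not None:
            dh = dh * lc["mask"]
        if li > 0:
            dz = dh * (cache["layers"][li - 1]["z"] > 0)
        else:
            d_features = dh
    return grads, d_features


def loss_and_gradients(
    model: GcnModel,
    op: SpectralOperator | list[np.ndarray],
    features: np.ndarray,
    labels: np.ndarray,
    labeled_mask: np.ndarray,
    weight_decay: float = 0.0,
    dropout: float = 0.0,
    dropout_active: bool = False,
    rng: np.random.Generator | None = None,
):
    """Mean cross-entropy over labelled vertices plus l2 penalty; gradients."""
    labeled_mask = np.asarray(labeled_mask, dtype=bool)
    if not labeled_mask.any():
        raise ValidationError("labelled mask is empty")
    labels = np.asarray(labels)
    probs, cache = gcn_forward(
        model, op, features, dropout=dropout, dropout_active=dropout_active, rng=rng
    )
    n_lab = int(labeled_mask.sum())
    onehot = np.zeros_like(probs)
    onehot[np.arange(len(labels)), labels.clip(min=0)] = 1.0
    eps = 1e-12
    ce = -np.sum(
        onehot[labeled_mask] * np.log(probs[labeled_mask] + eps)
    ) / n_lab
    penalty = weight_decay * sum(float(np.sum(l.theta**2)) for l in model.layers)
    loss = ce + penalty

    d_logits = (probs - onehot) / n_lab
    d_logits[~labeled_mask] = 0.0
    grads, _ = gcn_backward(model, cache, d_logits)
    if weight_decay:
        grads = [
            (dt + 2.0 * weight_decay * layer.theta, db)
            for (dt, db), layer in zip(grads, model.layers)
        ]
    return loss, grads, probs


def train_gcn(
    model: GcnModel,
    op: SpectralOperator | list[np.ndarray],
    features: np.ndarray,
    labels: np.ndarray,
    labeled_mask: np.ndarray,
    config: TrainConfig | None = None,
):
    """Transductive full-batch training; returns ``(trained model, losses)``.

    All vertices participate in the convolutions; the loss sees only the
    labelled (training) vertices.  The returned loss trajectory is the
    per-epoch training loss (cross-entropy plus weight penalty) evaluated
    with the dropout draw of that epoch.
    """
    config = config or TrainConfig()
    labeled_mask = np.asarray(labeled_mask, dtype=bool)
    lab_classes = np.unique(np.asarray(labels)[labeled_mask])
    if lab_classes.size < 2:
        raise ValidationError("labelled subset must contain both classes")
    basis = op if isinstance(op, list) else cheb_basis(op, model.K)
    model = model.copy()
    rng = np.random.default_rng(config.seed)
    losses = []

    if config.optimizer == "adam":
        m_state = [
            (np.zeros_like(l.theta), np.zeros_like(l.bias)) for l in model.layers
        ]
        v_state = [
            (np.zeros_like(l.theta), np.zeros_like(l.bias)) for l in model.layers
        ]
        b1, b2, adam_eps = 0.9, 0.999, 1e-8

    for epoch in range(config.epochs):
        loss, grads, _ = loss_and_gradients(
            model,
            basis,
            features,
            labels,
            labeled_mask,
            weight_decay=config.weight_decay,
            dropout=config.dropout,
            dropout_active=config.dropout > 0,
            rng=rng,
        )
        if not np.isfinite(loss):
            raise RuntimeError(
                f"non-finite loss {loss!r} at epoch {epoch}; learning rate "
                f"{config.learning_rate} likely too large for this instance"
            )
        losses.append(float(loss))
        if config.optimizer == "gd":
            for layer, (dt, db) in zip(model.layers, grads):
                layer.theta -= config.learning_rate * dt
                layer.bias -= config.learning_rate * db
        else:
            t = epoch + 1
            for i, (layer, (dt, db)) in enumerate(zip(model.layers, grads)):
                mt, mb = m_state[i]
                vt, vb = v_state[i]
                mt[:] = b1 * mt + (1 - b1) * dt
                mb[:] = b1 * mb + (1 - b1) * db
                vt[:] = b2 * vt + (1 - b2) * dt**2
                vb[:] = b2 * vb + (1 - b2) * db**2
                mt_hat = mt / (1 - b1**t)
                mb_hat = mb / (1 - b1**t)
                vt_hat = vt / (1 - b2**t)
                vb_hat = vb / (1 - b2**t)
                layer.theta -= config.learning_rate * mt_hat / (np.sqrt(vt_hat) + adam_eps)
                layer.bias -= config.learning_rate * mb_hat / (np.sqrt(vb_hat) + adam_eps)
    model.trained = True
    return model, losses


def predict(
    model: GcnModel,
    op: SpectralOperator | list[np.ndarray],
    features: np.ndarray,
    subject_mask: np.ndarray | None = None,
):
    """Deterministic inference: argmax class labels and softmax probabilities.

    ``subject_mask`` restricts the *returned* rows (e.g. the test fold);
    the convolution always runs over the whole graph.
    """
    probs, _ = gcn_forward(model, op, features, dropout_active=False)
    labels = probs.argmax(axis=1)
    if subject_mask is not None:
        subject_mask = np.asarray(subject_mask, dtype=bool)
        return labels[subject_mask], probs[subject_mask]
    return labels, probs


def gradient_check(
    model: GcnModel,
    op: SpectralOperator | list[np.ndarray],
    features: np.ndarray,
    labels: np.ndarray,
    labeled_mask: np.ndarray | None = None,
    epsilon: float = 1e-5,
    weight_decay: float = 0.0,
) -> float:
    """Max relative error of analytic parameter gradients vs central differences."""
    if labeled_mask is None:
        labeled_mask = np.ones(len(labels), dtype=bool)
    basis = op if isinstance(op, list) else cheb_basis(op, model.K)

    def loss_only(m: GcnModel) -> float:
        loss, _, _ = loss_and_gradients(
            m, basis, features, labels, labeled_mask, weight_decay=weight_decay
        )
        return loss

    _, grads, _ = loss_and_gradients(
        model, basis, features, labels, labeled_mask, weight_decay=weight_decay
    )
    max_rel = 0.0
    for li, layer in enumerate(model.layers):
        for arr, grad in ((layer.theta, grads[li][0]), (layer.bias, grads[li][1])):
            it = np.nditer(arr, flags=["multi_index"])
            for _ in it:
                idx = it.multi_index
                orig = arr[idx]
                arr[idx] = orig + epsilon
                up = loss_only(model)
                arr[idx] = orig - epsilon
                down = loss_only(model)
                arr[idx] = orig
                numeric = (up - down) / (2 * epsilon)
                denom = max(abs(numeric), abs(grad[idx]), 1e-8)
                max_rel = max(max_rel, abs(numeric - grad[idx]) / denom)
    return max_rel
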