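"""The two predictors: kNN mean-of-neighbors regression and a BP network.

kNN regression finds the ``k`` training samples nearest the query in
Euclidean distance over the condition attributes and predicts the unweighted
mean of their targets.  Distance ties are broken by ascending training-sample
index (stable sort on distance).

The backpropagation network is a small multi-layer perceptron trained by
full-batch steepest descent on mean squared error: logistic hidden units,
a linear output unit, seeded weight initialisation.  Inputs are min–max
scaled and the target is z-scored internally (chlorophyll quantities span
thousands of units; raw-scale gradients diverge at any sensible learning
rate); predictions are transformed back to the original scale.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .data_model import MinMaxParams, SampleTable, apply_min_max, fit_min_max

__all__ = [
    "KNNConfig",
    "NeighborModel",
    "fit_knn",
    "knn_predict",
    "MLPConfig",
    "MLPModel",
    "mlp_train",
    "mlp_predict",
    "loss_and_gradients",
    "model_to_json",
    "model_from_json",
]

DEFAULT_K_GRID: tuple[int, ...] = (1, 3, 5, 7, 9, 11, 13, 15)


@dataclass(frozen=True)
class KNNConfig:
    """kNN hyperparameters; the grid mirrors the usual odd-k sweep 1..15."""

    k: int = 3
    k_grid: tuple[int, ...] = DEFAULT_K_GRID
    normalize: bool = True


@dataclass
class NeighborModel:
    training_matrix: np.ndarray
    training_targets: np.ndarray
    k: int
    scaling: MinMaxParams | None = None


def fit_knn(table: SampleTable, k: int, normalize: bool = True) -> NeighborModel:
    if not 1 <= k <= table.n:
        raise ValueError(f"k must satisfy 1 <= k <= n (got k={k}, n={table.n})")
    scaling = fit_min_max(table.values) if normalize else None
    X = apply_min_max(table.values, scaling) if scaling is not None else table.values.copy()
    return NeighborModel(
        training_matrix=X, training_targets=table.target.copy(), k=k, scaling=scaling
    )


def knn_predict(model: NeighborModel, query: np.ndarray) -> np.ndarray | float:
    """Predict one query vector or a batch of query rows.

    Returns a scalar for a single d-vector, an array for a 2-D batch.
    """
    q = np.asarray(query, dtype=float)
    single = q.ndim == 1
    q = np.atleast_2d(q)
    if q.shape[1] != model.training_matrix.shape[1]:
        raise ValueError(
            f"query has {q.shape[1]} attributes, model expects "
            f"{model.training_matrix.shape[1]}"
        )
    if model.scaling is not None:
        q = apply_min_max(q, model.scaling)
    # (queries, training) distance matrix; stable sort breaks ties by index
    d = np.linalg.norm(q[:, None, :] - model.training_matrix[None, :, :], axis=2)
    nearest = np.argsort(d, axis=1, kind="stable")[:, : model.k]
    preds = model.training_targets[nearest].mean(axis=1)
    return float(preds[0]) if single else preds


@dataclass(frozen=True)
class MLPConfig:
    """BP-network hyperparameters.

    ``hidden_sizes=None`` selects one hidden layer of width ``max(8, 2d)``.
    """

    hidden_sizes: tuple[int, ...] | None = None
    learning_rate: float = 0.01
    epochs: int = 2000
    seed: int = 0
    normalize: bool = True


@dataclass
class MLPModel:
    weights: list[np.ndarray]
    biases: list[np.ndarray]
    x_scaling: MinMaxParams | None
    y_mean: float
    y_sd: float
    loss_trace: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def layer_sizes(self) -> list[int]:
        return [self.weights[0].shape[0]] + [w.shape[1] for w in self.weights]


def _logistic(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _forward(weights: list[np.ndarray], biases: list[np.ndarray], X: np.ndarray) -> list[np.ndarray]:
    """Activations a^(0)..a^(L); logistic hidden layers, linear output."""
    acts = [X]
    a = X
    last = len(weights) - 1
    for l, (W, b) in enumerate(zip(weights, biases)):
        z = a @ W + b
        a = z if l == last else _logistic(z)
        acts.append(a)
    return acts


def loss_and_gradients(
    weights: list[np.ndarray], biases: list[np.ndarray], X: np.ndarray, y: np.ndarray
) -> tuple[float, list[np.ndarray], list[np.ndarray]]:
    """Mean-squared-error loss and its analytic backprop gradients."""
    n = X.shape[0]
    acts = _forward(weights, biases, X)
    pred = acts[-1][:, 0]
    resid = pred - y
    loss = float(np.mean(resid**2))
    delta = (2.0 / n) * resid[:, None]  # dLoss/dz at the linear output
    dWs: list[np.ndarray] = [None] * len(weights)  # type: ignore[list-item]
    dbs: list[np.ndarray] = [None] * len(biases)  # type: ignore[list-item]
    for l in range(len(weights) - 1, -1, -1):
        dWs[l] = acts[l].T @ delta
        dbs[l] = delta.sum(axis=0)
        if l > 0:
            a_prev = acts[l]
            delta = (delta @ weights[l].T) * a_prev * (1.0 - a_prev)
    return loss, dWs, dbs


def mlp_train(table: SampleTable, config: MLPConfig | None = None) -> MLPModel:
    """Train the BP network by full-batch gradient descent; deterministic per seed.

    Raises ``RuntimeError`` naming the epoch if the loss becomes non-finite
    (learning rate too high for the data).
    """
    if table.n < 2:
        raise ValueError("mlp_train requires at least 2 samples")
    config = config or MLPConfig()
    hidden = config.hidden_sizes
    if hidden is None:
        hidden = (max(8, 2 * table.d),)
    x_scaling = fit_min_max(table.values) if config.normalize else None
    X = apply_min_max(table.values, x_scaling) if x_scaling is not None else table.values.copy()
    y_mean = float(table.target.mean())
    y_sd = float(table.target.std())
    if y_sd == 0.0:
        y_sd = 1.0
    y = (table.target - y_mean) / y_sd

    sizes = [table.d, *hidden, 1]
    rng = np.random.default_rng(config.seed)
    weights = [
        rng.normal(0.0, 1.0 / np.sqrt(sizes[l]), size=(sizes[l], sizes[l + 1]))
        for l in range(len(sizes) - 1)
    ]
    biases = [np.zeros(sizes[l + 1]) for l in range(len(sizes) - 1)]

    trace = np.empty(config.epochs)
    for epoch in range(config.epochs):
        loss, dWs, dbs = loss_and_gradients(weights, biases, X, y)
        if not np.isfinite(loss):
            raise RuntimeError(f"non-finite training loss at epoch {epoch}; lower the learning rate")
        trace[epoch] = loss
        for l in range(len(weights)):
            weights[l] -= config.learning_rate * dWs[l]
            biases[l] -= config.learning_rate * dbs[l]
    return MLPModel(
        weights=weights,
        biases=biases,
        x_scaling=x_scaling,
        y_mean=y_mean,
        y_sd=y_sd,
        loss_trace=trace,
    )


def mlp_predict(model: MLPModel, query: np.ndarray) -> np.ndarray | float:
    """Layer-by-layer forward pass; returns predictions on the original target scale."""
    q = np.asarray(query, dtype=float)
    single = q.ndim == 1
    q = np.atleast_2d(q)
    if q.shape[1] != model.weights[0].shape[0]:
        raise ValueError(
            f"query has {q.shape[1]} attributes, model expects {model.weights[0].shape[0]}"
        )
    if model.x_scaling is not None:
        q = apply_min_max(q, model.x_scaling)
    out = _forward(model.weights, model.biases, q)[-1][:, 0]
    out = out * model.y_sd + model.y_mean
    return float(out[0]) if single else out


def _scaling_to_dict(s: MinMaxParams | None) -> dict | None:
    if s is None:
        return None
    return {"minimum": s.minimum.tolist(), "span": s.span.tolist()}


def _scaling_from_dict(d: dict | None) -> MinMaxParams | None:
    if d is None:
        return None
    return MinMaxParams(minimum=np.asarray(d["minimum"]), span=np.asarray(d["span"]))


def model_to_json(model: NeighborModel | MLPModel, path: str | Path | None = None) -> str:
    """Serialise either model (weights, scaling, hyperparameters) as JSON."""
    if isinstance(model, NeighborModel):
        payload = {
            "kind": "knn",
            "k": model.k,
            "training_matrix": model.training_matrix.tolist(),
            "training_targets": model.training_targets.tolist(),
            "scaling": _scaling_to_dict(model.scaling),
        }
    else:
        payload = {
            "kind": "mlp",
            "weights": [w.tolist() for w in model.weights],
            "biases": [b.tolist() for b in model.biases],
            "x_scaling": _scaling_to_dict(model.x_scaling),
            "y_mean": model.y_mean,
            "y_sd": model.y_sd,
        }
    text = json.dumps(payload)
    if path is not None:
        Path(path).write_text(text)
    return text


def model_from_json(source: str | Path) -> NeighborModel | MLPModel:
    text = str(source)
    if not text.lstrip().startswith("{"):
        text = Path(source).read_text()
    payload = json.loads(text)
    if payload["kind"] == "knn":
        return NeighborModel(
            training_matrix=np.asarray(payload["training_matrix"], dtype=float),
            training_targets=np.asarray(payload["training_targets"], dtype=float),
            k=int(payload["k"]),
            scaling=_scaling_from_dict(payload["scaling"]),
        )
    return MLPModel(
        weights=[np.asarray(w, dtype=float) for w in payload["weights"]],
        biases=[np.asarray(b, dtype=float) for b in payload["biases"]],
        x_scaling=_scaling_from_dict(payload["x_scaling"]),
        y_mean=float(payload["y_mean"]),
        y_sd=float(payload["y_sd"]),
    )
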