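"""Extreme Learning Machine: random hidden layer, least-squares output weights.

A single-hidden-layer feed-forward network in which the input-to-hidden
weights ``omega`` (d x L) and hidden biases ``b`` (L) are either drawn
uniformly from a fixed box or supplied externally (the hook used by the
metaheuristic optimizers), the hidden layer is sigmoid, and the hidden-to-
output weights ``beta`` (L x K) solve the least-squares problem
``H beta = T`` via the Moore-Penrose pseudo-inverse, with T the one-hot
target matrix. Prediction is the argmax over output scores, ties broken
toward the lowest class index.

``pack_position`` / ``unpack_position`` define the flat layout the
optimizers search over: omega column-major, then the biases.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit


@dataclass(frozen=True)
class ELMConfig:
    """Hidden-layer size, activation, random-weight box and seed."""

    n_hidden: int = 120
    activation: str = "sigmoid"
    weight_low: float = -1.0
    weight_high: float = 1.0
    seed: int = 0
    ridge: float = 0.0  # optional Tikhonov term for near-singular H

    def validate(self) -> None:
        if self.n_hidden < 1:
            raise ValueError("n_hidden must be at least 1")
        if self.activation != "sigmoid":
            raise ValueError(f"unsupported activation {self.activation!r}")
        if not self.weight_low < self.weight_high:
            raise ValueError("weight_low must be below weight_high")
        if self.ridge < 0:
            raise ValueError("ridge must be non-negative")


@dataclass
class ELMModel:
    omega: np.ndarray  # d x L input-to-hidden weights
    bias: np.ndarray  # L hidden thresholds
    beta: np.ndarray  # L x K output weights
    class_labels: np.ndarray  # ordered class values, length K
    activation: str = "sigmoid"

    def __post_init__(self) -> None:
        self.omega = np.asarray(self.omega, dtype=float)
        self.bias = np.asarray(self.bias, dtype=float)
        self.beta = np.asarray(self.beta, dtype=float)
        self.class_labels = np.asarray(self.class_labels)
        d, L = self.omega.shape
        if self.bias.shape != (L,):
            raise ValueError("bias length must equal hidden size")
        if self.beta.shape[0] != L or self.beta.shape[1] != self.class_labels.shape[0]:
            raise ValueError("beta shape inconsistent with hidden size / classes")
        for a in (self.omega, self.bias, self.beta):
            if not np.all(np.isfinite(a)):
                raise ValueError("model parameters must be finite")

    @property
    def n_features(self) -> int:
        return self.omega.shape[0]

    @property
    def n_hidden(self) -> int:
        return self.omega.shape[1]

    def to_json(self, path) -> None:
        payload = {
            "activation": self.activation,
            "omega": self.omega.tolist(),
            "bias": self.bias.tolist(),
            "beta": self.beta.tolist(),
            "class_labels": self.class_labels.tolist(),
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "ELMModel":
        with open(path, encoding="utf-8") as fh:
            p = json.load(fh)
        return cls(
            omega=np.array(p["omega"], dtype=float),
            bias=np.array(p["bias"], dtype=float),
            beta=np.array(p["beta"], dtype=float),
            class_labels=np.array(p["class_labels"]),
            activation=p["activation"],
        )


def hidden_activations(X: np.ndarray, omega: np.ndarray, bias: np.ndarray) -> np.ndarray:
    """Hidden-layer output H[i, j] = sigmoid(x_i . omega_j + b_j)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    omega = np.asarray(omega, dtype=float)
    bias = np.asarray(bias, dtype=float)
    if X.shape[1] != omega.shape[0]:
        raise ValueError(f"feature count {X.shape[1]} != omega rows {omega.shape[0]}")
    if bias.shape != (omega.shape[1],):
        raise ValueError("bias length must equal number of hidden units")
    return expit(X @ omega + bias)


def one_hot(labels: np.ndarray, classes: np.ndarray) -> np.ndarray:
    """n x K target matrix with 1 at the true class column, 0 elsewhere."""
    idx = np.searchsorted(classes, labels)
    if np.any(classes[idx] != labels):
        raise ValueError("labels contain values outside the class set")
    T = np.zeros((labels.shape[0], classes.shape[0]))
    T[np.arange(labels.shape[0]), idx] = 1.0
    return T


def random_hidden_params(
    d: int, config: ELMConfig, rng: np.random.Generator | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Draw omega ~ U(low, high)^(d x L) and bias ~ U(low, high)^L."""
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    L = config.n_hidden
    omega = rng.uniform(config.weight_low, config.weight_high, size=(d, L))
    bias = rng.uniform(config.weight_low, config.weight_high, size=L)
    return omega, bias


def elm_train(
    X: np.ndarray,
    labels: np.ndarray,
    config: ELMConfig,
    omega: np.ndarray | None = None,
    bias: np.ndarray | None = None,
) -> ELMModel:
    """Fit output weights by least squares; hidden parameters random or supplied.

    Supplying ``omega``/``bias`` overrides the random draw — this is the hook
    through which the optimizers inject candidate hidden layers.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    labels = np.asarray(labels)
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite training features")
    classes = np.unique(labels)
    if classes.shape[0] < 2:
        raise ValueError("need at least 2 classes")
    if X.shape[0] < classes.shape[0]:
        raise ValueError("need at least as many samples as classes")
    if omega is None or bias is None:
        omega, bias = random_hidden_params(X.shape[1], config)
    omega = np.asarray(omega, dtype=float)
    bias = np.asarray(bias, dtype=float)
    H = hidden_activations(X, omega, bias)
    T = one_hot(labels, classes)
    if config.ridge > 0:
        L = H.shape[1]
        beta = np.linalg.solve(H.T @ H + config.ridge * np.eye(L), H.T @ T)
    else:
        beta = np.linalg.pinv(H) @ T
    return ELMModel(omega=omega, bias=bias, beta=beta, class_labels=classes,
                    activation=config.activation)


def elm_scores(model: ELMModel, X: np.ndarray) -> np.ndarray:
    return hidden_activations(X, model.omega, model.bias) @ model.beta


def elm_predict(model: ELMModel, X: np.ndarray) -> np.ndarray:
    """Predicted class = argmax of output scores (ties -> lowest class index)."""
    return model.class_labels[np.argmax(elm_scores(model, X), axis=1)]


def pack_position(omega: np.ndarray, bias: np.ndarray) -> np.ndarray:
    """Flatten (omega, bias) into one search vector: omega column-major, then bias."""
    return np.concatenate([np.asarray(omega, dtype=float).ravel(order="F"),
                           np.asarray(bias, dtype=float)])


def unpack_position(position: np.ndarray, d: int, L: int) -> tuple[np.ndarray, np.ndarray]:
    """Inverse of :func:`pack_position`; requires length d*L + L."""
    position = np.asarray(position, dtype=float)
    if position.shape != (d * L + L,):
        raise ValueError(f"position length {position.shape[0]} != d*L + L = {d * L + L}")
    omega = position[: d * L].reshape((d, L), order="F")
    bias = position[d * L :]
    return omega, bias
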