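"""The two probability sources: an MLP over texture features and a CNN over
images, behind one contract — labelled inputs in, normalized probability
triples over (benign, malignant, ignorant) out.

The MLP is the classic fully-connected sigmoid network trained by
backpropagation (gradient descent with momentum on a mean-squared-error
loss against one-hot targets).  Its sigmoid outputs are renormalized to sum
to 1, giving the probability triple the fusion stage consumes.  The network
is written directly in numpy so the backward pass is an explicit, testable
implementation of the chain rule.

The CNN lives in :mod:`mldstnet.cnn`; both expose ``predict_proba`` and are
interchangeable as evidence sources.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .errors import EncodingError, ParameterError, StateError, TrainingError
from .phantom import CLASSES

__all__ = [
    "one_hot_encode",
    "one_hot_decode",
    "MLPConfig",
    "MLPSource",
    "predict_proba",
]


def one_hot_encode(label: str) -> np.ndarray:
    """Class label -> 0/1 vector in (benign, malignant, ignorant) order."""
    if label not in CLASSES:
        raise EncodingError(f"unknown label {label!r}; expected one of {CLASSES}")
    vec = np.zeros(len(CLASSES), dtype=np.int64)
    vec[CLASSES.index(label)] = 1
    return vec


def one_hot_decode(vector) -> str:
    """0/1 vector with exactly one 1 -> class label."""
    v = np.asarray(vector)
    if v.shape != (len(CLASSES),) or not np.all(np.isin(v, (0, 1))) or v.sum() != 1:
        raise EncodingError(f"not a one-hot vector: {vector!r}")
    return CLASSES[int(np.argmax(v))]


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


@dataclass(frozen=True)
class MLPConfig:
    """Configuration of the texture-feature MLP.

    Two hidden layers of 10 sigmoid units each; trained full-batch by
    backpropagation with momentum.  ``input_dim`` may be left at 0 to be
    inferred from the training table.
    """

    input_dim: int = 0
    hidden_layers: tuple[int, ...] = (10, 10)
    epochs: int = 300
    learning_rate: float = 0.5
    momentum: float = 0.9
    standardize: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if any(h < 1 for h in self.hidden_layers):
            raise ParameterError("hidden layer sizes must be >= 1")
        if self.epochs < 1:
            raise ParameterError("epochs must be >= 1")
        if self.learning_rate <= 0:
            raise ParameterError("learning_rate must be positive")


class MLPSource:
    """Sigmoid multilayer perceptron over texture features.

    Use :meth:`fit` then :meth:`predict_proba`.  All randomness flows from
    ``config.seed``; training is bit-reproducible.
    """

    def __init__(self, config: MLPConfig = MLPConfig()):
        self.config = config
        self.weights: list[np.ndarray] | None = None
        self.biases: list[np.ndarray] | None = None
        self._mu: np.ndarray | None = None
        self._sd: np.ndarray | None = None
        self.loss_history: list[float] = []

    # -- parameter plumbing -------------------------------------------------

    def _init_params(self, input_dim: int, rng: np.random.Generator) -> None:
        sizes = [input_dim, *self.config.hidden_layers, len(CLASSES)]
        self.weights = [
            rng.normal(0.0, 1.0 / np.sqrt(fan_in), size=(fan_in, fan_out))
            for fan_in, fan_out in zip(sizes[:-1], sizes[1:])
        ]
        self.biases = [np.zeros(fan_out) for fan_out in sizes[1:]]

    def get_params_vector(self) -> np.ndarray:
        self._require_fitted()
        return np.concatenate(
            [w.ravel() for w in self.weights] + [b.ravel() for b in self.biases]
        )

    def set_params_vector(self, vec: np.ndarray) -> None:
        self._require_fitted()
        pos = 0
        for w in self.weights:
            w[...] = vec[pos : pos + w.size].reshape(w.shape)
            pos += w.size
        for b in self.biases:
            b[...] = vec[pos : pos + b.size]
            pos += b.size

    def _require_fitted(self) -> None:
        if self.weights is None:
            raise StateError("MLP source is untrained; call fit() first")

    # -- forward / backward -------------------------------------------------

    def _standardize(self, X: np.ndarray) -> np.ndarray:
        if self._mu is None:
            return X
        return (X - self._mu) / self._sd

    def _forward(self, Xs: np.ndarray) -> list[np.ndarray]:
        """Activations per layer (input first, sigmoid everywhere)."""
        acts = [Xs]
        for w, b in zip(self.weights, self.biases):
            acts.append(_sigmoid(acts[-1] @ w + b))
        return acts

    def loss_and_gradient(self, X, labels) -> tuple[float, np.ndarray]:
        """MSE loss and its gradient w.r.t. the flattened parameter vector.

        The backward pass is plain backpropagation through the sigmoid
        layers; this is the quantity checked against finite differences.
        """
        self._require_fitted()
        X = np.asarray(X, dtype=float)
        T = np.stack([one_hot_encode(l) for l in labels]).astype(float)
        acts = self._forward(self._standardize(X))
        n = X.shape[0]
        Y = acts[-1]
        loss = float(0.5 * np.sum((Y - T) ** 2) / n)

        grads_w = [np.zeros_like(w) for w in self.weights]
        grads_b = [np.zeros_like(b) for b in self.biases]
        delta = (Y - T) * Y * (1.0 - Y) / n
        for layer in range(len(self.weights) - 1, -1, -1):
            grads_w[layer] = acts[layer].T @ delta
            grads_b[layer] = delta.sum(axis=0)
            if layer > 0:
                a = acts[layer]
                delta = (delta @ self.weights[layer].T) * a * (1.0 - a)
        flat = np.concatenate(
            [g.ravel() for g in grads_w] + [g.ravel() for g in grads_b]
        )
        return loss, flat

    # -- public API ---------------------------------------------------------

    def fit(self, X, labels) -> "MLPSource":
        """Train by full-batch backpropagation with momentum.

        Raises
        ------
        TrainingError
            If the training set contains fewer than two distinct classes.
        """
        X = np.asarray(X, dtype=float)
        labels = list(labels)
        if X.ndim != 2 or X.shape[0] != len(labels):
            raise ParameterError(f"bad feature table shape {X.shape} for {len(labels)} labels")
        if not np.all(np.isfinite(X)):
            raise ParameterError("features must be finite")
        if len(set(labels)) < 2:
            raise TrainingError("training set has a single class; nothing to separate")

        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        input_dim = cfg.input_dim or X.shape[1]
        if input_dim != X.shape[1]:
            raise ParameterError(
                f"config.input_dim={cfg.input_dim} but features have {X.shape[1]} columns"
            )
        if cfg.standardize:
            self._mu = X.mean(axis=0)
            sd = X.std(axis=0)
            self._sd = np.where(sd > 1e-12, sd, 1.0)
        self._init_params(input_dim, rng)

        velocity = np.zeros(self.get_params_vector().size)
        self.loss_history = []
        for _ in range(cfg.epochs):
            loss, grad = self.loss_and_gradient(X, labels)
            self.loss_history.append(loss)
            velocity = cfg.momentum * velocity - cfg.learning_rate * grad
            self.set_params_vector(self.get_params_vector() + velocity)
        return self

    def predict_proba(self, X) -> np.ndarray:
        """(n, 3) probability triples: renormalized sigmoid outputs."""
        self._require_fitted()
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ParameterError(f"expected 2-D feature array, got shape {X.shape}")
        if X.shape[0] == 0:
            return np.empty((0, len(CLASSES)))
        Y = self._forward(self._standardize(X))[-1]
        return Y / Y.sum(axis=1, keepdims=True)

    def predict(self, X) -> np.ndarray:
        p = self.predict_proba(X)
        return np.array([CLASSES[i] for i in np.argmax(p, axis=1)])

    # -- persistence --------------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Checkpoint: npz parameter file + JSON sidecar with the config."""
        self._require_fitted()
        path = Path(path)
        arrays = {f"w{i}": w for i, w in enumerate(self.weights)}
        arrays |= {f"b{i}": b for i, b in enumerate(self.biases)}
        if self._mu is not None:
            arrays |= {"mu": self._mu, "sd": self._sd}
        np.savez(path, **arrays)
        sidecar = {"format": "mldstnet-mlp-v1", "config": asdict(self.config)}
        Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "MLPSource":
        sidecar = json.loads(Path(str(path) + ".json").read_text())
        cfg_dict = sidecar["config"]
        cfg_dict["hidden_layers"] = tuple(cfg_dict["hidden_layers"])
        model = cls(MLPConfig(**cfg_dict))
        data = np.load(path if str(path).endswith(".npz") else str(path) + ".npz")
        n_layers = len(model.config.hidden_layers) + 1
        model.weights = [data[f"w{i}"] for i in range(n_layers)]
        model.biases = [data[f"b{i}"] for i in range(n_layers)]
        if "mu" in data:
            model._mu, model._sd = data["mu"], data["sd"]
        return model


def predict_proba(source, inputs) -> np.ndarray:
    """Source-agnostic prediction: any trained source -> (n, 3) triples."""
    if not hasattr(source, "predict_proba"):
        raise StateError(f"{source!r} does not expose predict_proba")
    return source.predict_proba(inputs)
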