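"""A small convolutional network over phantom images, written in numpy.

The default architecture is a four-block pyramid — conv / batch-norm / ReLU /
2x2 pooling with filter counts (16, 32, 32, 64) — followed by a 100-unit
fully-connected layer, a 3-unit output layer and a softmax, trained with
cross-entropy by mini-batch gradient descent with momentum.  Blocks 1-3 use
max pooling; block 4 uses average pooling.  Convolutions are stride 1 with
'same' padding, pooling is 2x2 stride 2, so the input side must be divisible
by 16.

Grayscale input images are resized to ``input_size`` and replicated to three
channels.  Every forward/backward pass is explicit numpy; with a fixed seed,
training is bit-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
from skimage.transform import resize

from .errors import ConfigurationError, ParameterError, StateError, TrainingError
from .image import GrayImage
from .phantom import CLASSES

__all__ = ["CNNConfig", "CNNSource"]

_BN_EPS = 1e-5


@dataclass(frozen=True)
class CNNConfig:
    """Architecture and training configuration of the image CNN.

    The defaults mirror the reference four-block design (input 128 px on the
    desk scale, kernel sizes 28/14/7/4, filters 16/32/32/64, FC 100).  For
    quick experiments a smaller ``input_size`` with proportionally smaller
    kernels trains orders of magnitude faster with the same block structure.

    ``augment`` enables random flips and 90-degree rotations of each training
    batch — the phantom phenotypes are rotation/reflection invariant, and with
    ~100 training images this markedly reduces overfitting.
    """

    input_size: int = 128
    channels: int = 3
    filters: tuple[int, int, int, int] = (16, 32, 32, 64)
    kernel_sizes: tuple[int, int, int, int] = (28, 14, 7, 4)
    fc_units: int = 100
    epochs: int = 20
    learning_rate: float = 0.01
    momentum: float = 0.9
    batch_size: int = 8
    augment: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.filters) != 4 or len(self.kernel_sizes) != 4:
            raise ConfigurationError("exactly 4 conv blocks are required")
        if self.input_size % 16 != 0 or self.input_size < 16:
            raise ConfigurationError(
                f"input_size must be a positive multiple of 16 (four 2x2 pooling "
                f"stages), got {self.input_size}"
            )
        if any(k < 1 for k in self.kernel_sizes) or any(f < 1 for f in self.filters):
            raise ConfigurationError("kernel sizes and filter counts must be >= 1")
        if self.epochs < 1 or self.batch_size < 1:
            raise ConfigurationError("epochs and batch_size must be >= 1")


# --------------------------------------------------------------------------
# layers; each stores its cache on forward(training=True)


class _Conv:
    """2-D convolution, stride 1, 'same' padding, via im2col + GEMM."""

    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator):
        fan_in = cin * k * k
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(cout, fan_in))
        self.b = np.zeros(cout)
        self.k, self.cin, self.cout = k, cin, cout

    def describe(self) -> str:
        return f"conv {self.cout}@{self.k}x{self.k} stride 1 padding same"

    def _pad(self, x: np.ndarray) -> np.ndarray:
        lo, hi = (self.k - 1) // 2, self.k // 2
        return np.pad(x, ((0, 0), (0, 0), (lo, hi), (lo, hi)))

    def _im2col(self, xp: np.ndarray, h: int, w: int) -> np.ndarray:
        # (n, cin, h+k-1, w+k-1) -> (n, cin*k*k, h*w)
        view = np.lib.stride_tricks.sliding_window_view(xp, (self.k, self.k), axis=(2, 3))
        return view.transpose(0, 1, 4, 5, 2, 3).reshape(
            xp.shape[0], self.cin * self.k * self.k, h * w
        )

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        n, _, h, w = x.shape
        cols = self._im2col(self._pad(x), h, w)
        out = np.einsum("of,nfp->nop", self.W, cols) + self.b[None, :, None]
        if training:
            self._cache = (cols, x.shape)
        return out.reshape(n, self.cout, h, w)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        cols, xshape = self._cache
        n, _, h, w = xshape
        g = grad.reshape(n, self.cout, h * w)
        self.dW = np.einsum("nop,nfp->of", g, cols)
        self.db = g.sum(axis=(0, 2))
        dcols = np.einsum("of,nop->nfp", self.W, g)
        # col2im: scatter-add each kernel offset back onto the padded grid
        lo = (self.k - 1) // 2
        hp, wp = h + self.k - 1, w + self.k - 1
        dxp = np.zeros((n, self.cin, hp, wp))
        dcols = dcols.reshape(n, self.cin, self.k, self.k, h, w)
        for di in range(self.k):
            for dj in range(self.k):
                dxp[:, :, di : di + h, dj : dj + w] += dcols[:, :, di, dj]
        return dxp[:, :, lo : lo + h, lo : lo + w]


class _BatchNorm:
    """Per-channel batch normalization with running statistics."""

    def __init__(self, c: int, momentum: float = 0.9):
        self.gamma = np.ones(c)
        self.beta = np.zeros(c)
        self.run_mean = np.zeros(c)
        self.run_var = np.ones(c)
        self.momentum = momentum

    def describe(self) -> str:
        return "batchnorm"

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if training:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.run_mean = self.momentum * self.run_mean + (1 - self.momentum) * mean
            self.run_var = self.momentum * self.run_var + (1 - self.momentum) * var
        else:
            mean, var = self.run_mean, self.run_var
        inv = 1.0 / np.sqrt(var + _BN_EPS)
        xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
        if training:
            self._cache = (xhat, inv, x.shape)
        return self.gamma[None, :, None, None] * xhat + self.beta[None, :, None, None]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        xhat, inv, shape = self._cache
        m = shape[0] * shape[2] * shape[3]
        self.dgamma = (grad * xhat).sum(axis=(0, 2, 3))
        self.dbeta = grad.sum(axis=(0, 2, 3))
        g = grad * self.gamma[None, :, None, None]
        return (
            inv[None, :, None, None]
            / m
            * (
                m * g
                - g.sum(axis=(0, 2, 3), keepdims=True)
                - xhat * (g * xhat).sum(axis=(0, 2, 3))[None, :, None, None]
            )
        )


class _ReLU:
    def describe(self) -> str:
        return "relu"

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if training:
            self._mask = x > 0
        return np.maximum(x, 0.0)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * self._mask


class _Pool:
    """2x2 pooling, stride 2; ``kind`` is 'max' or 'avg'."""

    def __init__(self, kind: str):
        self.kind = kind

    def describe(self) -> str:
        return f"{self.kind}pool 2x2 stride 2"

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        n, c, h, w = x.shape
        blocks = x.reshape(n, c, h // 2, 2, w // 2, 2)
        if self.kind == "avg":
            out = blocks.mean(axis=(3, 5))
            if training:
                self._shape = x.shape
            return out
        out = blocks.max(axis=(3, 5))
        if training:
            mask = blocks == out[:, :, :, None, :, None]
            # split gradient among tied maxima to keep backward deterministic
            self._mask = mask / mask.sum(axis=(3, 5), keepdims=True)
            self._shape = x.shape
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        g = grad[:, :, :, None, :, None]
        if self.kind == "avg":
            return np.broadcast_to(g / 4.0, (n, c, h // 2, 2, w // 2, 2)).reshape(
                n, c, h, w
            )
        return (self._mask * g).reshape(n, c, h, w)


class _Flatten:
    def describe(self) -> str:
        return "flatten"

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if training:
            self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad.reshape(self._shape)


class _Dense:
    def __init__(self, fan_in: int, fan_out: int, rng: np.random.Generator):
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, fan_out))
        self.b = np.zeros(fan_out)

    def describe(self) -> str:
        return f"fc {self.W.shape[1]}"

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if training:
            self._x = x
        return x @ self.W + self.b

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.dW = self._x.T @ grad
        self.db = grad.sum(axis=0)
        return grad @ self.W.T


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


# --------------------------------------------------------------------------


class CNNSource:
    """Image classifier with the four-block conv/BN/ReLU/pool architecture."""

    def __init__(self, config: CNNConfig = CNNConfig()):
        self.config = config
        self._trained = False
        rng = np.random.default_rng(config.seed)
        self._rng = rng
        c = config.channels
        side = config.input_size
        layers: list = []
        pool_kinds = ("max", "max", "max", "avg")
        for f, k, kind in zip(config.filters, config.kernel_sizes, pool_kinds):
            layers += [_Conv(c, f, k, rng), _BatchNorm(f), _ReLU(), _Pool(kind)]
            c = f
            side //= 2
        layers.append(_Flatten())
        layers.append(_Dense(c * side * side, config.fc_units, rng))
        layers.append(_ReLU())
        layers.append(_Dense(config.fc_units, len(CLASSES), rng))
        self.layers = layers
        self.loss_history: list[float] = []

    # -- input handling -----------------------------------------------------

    def architecture(self) -> list[str]:
        """Layer walk, input first, softmax output last."""
        s = self.config.input_size
        walk = [f"input {s}x{s}x{self.config.channels}"]
        walk += [layer.describe() for layer in self.layers]
        walk.append("softmax")
        return walk

    def _to_tensor(self, images: list[GrayImage]) -> np.ndarray:
        """Resize, scale to [0,1], replicate gray to ``channels`` channels."""
        size = self.config.input_size
        out = np.empty((len(images), self.config.channels, size, size))
        for i, img in enumerate(images):
            arr = img.pixels.astype(float) / (img.levels - 1)
            if arr.shape != (size, size):
                arr = resize(arr, (size, size), anti_aliasing=True)
            out[i] = arr[None, :, :]
        return out

    # -- forward / training -------------------------------------------------

    def _forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, training)
        return x

    def _backward(self, grad: np.ndarray) -> None:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)

    def _step(self, velocities: dict, lr: float, mom: float) -> None:
        for i, layer in enumerate(self.layers):
            for name, gname in (("W", "dW"), ("b", "db"), ("gamma", "dgamma"),
                                ("beta", "dbeta")):
                if hasattr(layer, gname):
                    key = (i, name)
                    v = velocities.get(key, 0.0)
                    v = mom * v - lr * getattr(layer, gname)
                    velocities[key] = v
                    setattr(layer, name, getattr(layer, name) + v)

    def fit(self, images: list[GrayImage], labels: list[str]) -> "CNNSource":
        """Mini-batch SGD with momentum on softmax cross-entropy."""
        if len(images) != len(labels):
            raise ParameterError(f"{len(images)} images vs {len(labels)} labels")
        if len(set(labels)) < 2:
            raise TrainingError("training set has a single class; nothing to separate")
        X = self._to_tensor(images)
        T = np.zeros((len(labels), len(CLASSES)))
        for i, lab in enumerate(labels):
            if lab not in CLASSES:
                raise ParameterError(f"unknown label {lab!r}")
            T[i, CLASSES.index(lab)] = 1.0

        cfg = self.config
        rng = np.random.default_rng(cfg.seed + 1)  # shuffling stream
        velocities: dict = {}
        self.loss_history = []
        n = len(images)
        for _ in range(cfg.epochs):
            order = rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, cfg.batch_size):
                idx = order[start : start + cfg.batch_size]
                batch = X[idx]
                if cfg.augment:
                    batch = batch.copy()
                    for b in range(batch.shape[0]):
                        rot = rng.integers(4)
                        if rot:
                            batch[b] = np.rot90(batch[b], rot, axes=(1, 2))
                        if rng.random() < 0.5:
                            batch[b] = batch[b][:, :, ::-1]
                logits = self._forward(batch, training=True)
                probs = _softmax(logits)
                batch_t = T[idx]
                loss = -np.sum(batch_t * np.log(probs + 1e-12)) / len(idx)
                epoch_loss += loss * len(idx)
                self._backward((probs - batch_t) / len(idx))
                self._step(velocities, cfg.learning_rate, cfg.momentum)
            self.loss_history.append(epoch_loss / n)
        self._trained = True
        return self

    def predict_proba(self, images: list[GrayImage]) -> np.ndarray:
        """(n, 3) softmax probability triples (inference mode batch norm)."""
        if not self._trained:
            raise StateError("CNN source is untrained; call fit() first")
        if len(images) == 0:
            return np.empty((0, len(CLASSES)))
        return _softmax(self._forward(self._to_tensor(images), training=False))

    def predict(self, images: list[GrayImage]) -> np.ndarray:
        p = self.predict_proba(images)
        return np.array([CLASSES[i] for i in np.argmax(p, axis=1)])

    # -- persistence --------------------------------------------------------

    def save(self, path: str | Path) -> None:
        if not self._trained:
            raise StateError("refusing to checkpoint an untrained CNN")
        arrays = {}
        for i, layer in enumerate(self.layers):
            for name in ("W", "b", "gamma", "beta", "run_mean", "run_var"):
                if hasattr(layer, name):
                    arrays[f"l{i}_{name}"] = getattr(layer, name)
        np.savez(path, **arrays)
        sidecar = {"format": "mldstnet-cnn-v1", "config": asdict(self.config)}
        Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "CNNSource":
        sidecar = json.loads(Path(str(path) + ".json").read_text())
        cfg = sidecar["config"]
        for key in ("filters", "kernel_sizes"):
            cfg[key] = tuple(cfg[key])
        model = cls(CNNConfig(**cfg))
        data = np.load(path if str(path).endswith(".npz") else str(path) + ".npz")
        for i, layer in enumerate(model.layers):
            for name in ("W", "b", "gamma", "beta", "run_mean", "run_var"):
                key = f"l{i}_{name}"
                if key in data:
                    setattr(layer, name, data[key])
        model._trained = True
        return model
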