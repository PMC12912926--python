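"""1D convolutional classifier for aligned barcode fragments.

A compact NumPy implementation of the standard sequence-CNN recipe: three
convolutional blocks (1D convolution -> batch normalization -> size-2 max
pooling -> ReLU -> dropout) with 64/128/128 channels, global average pooling
to a 128-dimensional feature vector, and three fully connected layers
producing per-species logits. Training uses Adam with cross-entropy loss
(batch size 16, learning rate 0.001). Forward and backward passes are
written out explicitly, which keeps inference deterministic and makes the
gradients needed by the attribution module (class scores and energy scores
backpropagated to the last convolutional feature maps) directly available.

Inputs whose length is not a multiple of 8 are right-padded with all-zero
one-hot rows so that the three pooling stages divide evenly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from ._seeds import rng_for
from .dataset import SequenceRecord
from .seqprep import encode_one_hot

__all__ = ["CnnSpec", "CnnClassifier", "build_model", "train", "accuracy"]


@dataclass
class CnnSpec:
    """Architecture hyperparameters.

    ``fc_hidden`` gives the widths of the two hidden fully connected layers;
    the second one (64 units by default) is the penultimate representation
    used for Mahalanobis scoring. ``kernel_size`` defaults to 3, which with
    the stated channel widths puts the trainable parameter count at the
    ~1e5 scale of the published architecture.
    """

    n_classes: int
    input_length: int
    conv_channels: tuple[int, int, int] = (64, 128, 128)
    kernel_size: int = 3
    conv_dropout: float = 0.15
    fc_dropout: float = 0.25
    fc_hidden: tuple[int, int] = (128, 64)

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if self.input_length < 8:
            raise ValueError("input_length must be >= 8 (three pooling stages)")

    @property
    def padded_length(self) -> int:
        return -(-self.input_length // 8) * 8

    @property
    def feature_dim(self) -> int:
        return self.conv_channels[-1]


# ---------------------------------------------------------------------------
# Layers (forward caches what backward needs; inference mode caches too, so
# attribution can backpropagate through a deterministic forward pass)
# ---------------------------------------------------------------------------

class _Layer:
    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self) -> None:
        self.params, self.grads = [], []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, g: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class _Conv1d(_Layer):
    """Same-padding, stride-1 1D convolution via an im2col matmul."""

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator):
        super().__init__()
        scale = math.sqrt(2.0 / (c_in * k))
        self.w = (rng.standard_normal((c_out, c_in * k)) * scale).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.k = k
        self.c_in = c_in
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, c, length = x.shape
        pad = self.k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (pad, pad)))
        cols = np.lib.stride_tricks.sliding_window_view(xp, self.k, axis=2)
        # (n, c, L, k) -> (n, L, c*k)
        cols = np.ascontiguousarray(cols.transpose(0, 2, 1, 3)).reshape(
            n, length, c * self.k
        )
        self._cols, self._shape = cols, (n, c, length)
        y = cols @ self.w.T + self.b
        return np.ascontiguousarray(y.transpose(0, 2, 1))

    def backward(self, g: np.ndarray) -> np.ndarray:
        n, c, length = self._shape
        g2 = np.ascontiguousarray(g.transpose(0, 2, 1))  # (n, L, c_out)
        self.grads[0][...] = np.einsum("nlo,nlc->oc", g2, self._cols)
        self.grads[1][...] = g2.sum(axis=(0, 1))
        dcols = (g2 @ self.w).reshape(n, length, c, self.k)
        pad = self.k // 2
        dxp = np.zeros((n, c, length + 2 * pad), dtype=np.float32)
        for kk in range(self.k):
            dxp[:, :, kk:kk + length] += dcols[:, :, :, kk].transpose(0, 2, 1)
        return dxp[:, :, pad:pad + length]


class _BatchNorm1d(_Layer):
    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.gamma = np.ones(channels, dtype=np.float32)
        self.beta = np.zeros(channels, dtype=np.float32)
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self.momentum, self.eps = momentum, eps
        self.params = [self.gamma, self.beta]
        self.grads = [np.zeros_like(self.gamma), np.zeros_like(self.beta)]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        invstd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[:, None]) * invstd[:, None]
        self._xhat, self._invstd, self._train = xhat.astype(np.float32), invstd, train
        return self.gamma[:, None] * self._xhat + self.beta[:, None]

    def backward(self, g: np.ndarray) -> np.ndarray:
        xhat, invstd = self._xhat, self._invstd
        self.grads[0][...] = (g * xhat).sum(axis=(0, 2))
        self.grads[1][...] = g.sum(axis=(0, 2))
        gx = g * self.gamma[:, None]
        if not self._train:
            return (gx * invstd[:, None]).astype(np.float32)
        m = g.shape[0] * g.shape[2]
        term = (
            gx
            - gx.mean(axis=(0, 2), keepdims=True)
            - xhat * (gx * xhat).mean(axis=(0, 2), keepdims=True)
        )
        return (term * invstd[:, None]).astype(np.float32)


class _MaxPool2(_Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, c, length = x.shape
        xr = x.reshape(n, c, length // 2, 2)
        self._argmax = xr.argmax(axis=3)
        self._shape = x.shape
        return xr.max(axis=3)

    def backward(self, g: np.ndarray) -> np.ndarray:
        n, c, length = self._shape
        dxr = np.zeros((n, c, length // 2, 2), dtype=np.float32)
        np.put_along_axis(dxr, self._argmax[..., None], g[..., None], axis=3)
        return dxr.reshape(n, c, length)


class _ReLU(_Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, g: np.ndarray) -> np.ndarray:
        return g * self._mask


class _Dropout(_Layer):
    def __init__(self, rate: float, rng: np.random.Generator):
        super().__init__()
        self.rate, self.rng = rate, rng

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(np.float32) / keep
        return x * self._mask

    def backward(self, g: np.ndarray) -> np.ndarray:
        return g if self._mask is None else g * self._mask


class _GlobalAvgPool(_Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._length = x.shape[2]
        return x.mean(axis=2)

    def backward(self, g: np.ndarray) -> np.ndarray:
        return np.repeat(g[:, :, None], self._length, axis=2) / self._length


class _Dense(_Layer):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        super().__init__()
        scale = math.sqrt(2.0 / d_in)
        self.w = (rng.standard_normal((d_out, d_in)) * scale).astype(np.float32)
        self.b = np.zeros(d_out, dtype=np.float32)
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._x = x
        return x @ self.w.T + self.b

    def backward(self, g: np.ndarray) -> np.ndarray:
        self.grads[0][...] = g.T @ self._x
        self.grads[1][...] = g.sum(axis=0)
        return g @ self.w


# ---------------------------------------------------------------------------
# Model
# ---------------------------------------------------------------------------

class CnnClassifier:
    """The fitted (or fittable) classifier.

    Exposes softmax probabilities, raw logits and penultimate-layer feature
    vectors per input, plus the partial backward pass from an arbitrary
    logit-space gradient to the last convolutional feature maps used by
    gradient attribution.
    """

    def __init__(self, spec: CnnSpec, classes: list[str], seed: int = 0):
        if len(classes) != spec.n_classes:
            raise ValueError("class list length must equal spec.n_classes")
        self.spec = spec
        self.classes = list(classes)
        self.seed = seed
        init_rng = rng_for(seed, "init")
        self._dropout_rng = rng_for(seed, "dropout")
        k = spec.kernel_size
        ch = spec.conv_channels
        self.features: list[_Layer] = []
        c_in = 4
        for c_out in ch:
            self.features += [
                _Conv1d(c_in, c_out, k, init_rng),
                _BatchNorm1d(c_out),
                _MaxPool2(),
                _ReLU(),
                _Dropout(spec.conv_dropout, self._dropout_rng),
            ]
            c_in = c_out
        h1, h2 = spec.fc_hidden
        self.head: list[_Layer] = [
            _GlobalAvgPool(),
            _Dense(spec.feature_dim, h1, init_rng),
            _ReLU(),
            _Dropout(spec.fc_dropout, self._dropout_rng),
            _Dense(h1, h2, init_rng),
            _ReLU(),
            _Dropout(spec.fc_dropout, self._dropout_rng),
            _Dense(h2, spec.n_classes, init_rng),
        ]
        self.history: dict[str, list[float]] = {"loss": []}
        self.trained = False

    # -- plumbing ----------------------------------------------------------
    @property
    def layers(self) -> list[_Layer]:
        return self.features + self.head

    def n_parameters(self) -> int:
        return sum(p.size for layer in self.layers for p in layer.params)

    def _prepare(self, x) -> np.ndarray:
        """Accept records or one-hot arrays; transpose to (n, 4, L) and pad."""
        if isinstance(x, np.ndarray):
            arr = x.astype(np.float32)
        else:
            arr = encode_one_hot(list(x))
        if arr.ndim == 2:
            arr = arr[None]
        if arr.shape[1] == 4 and arr.shape[2] != 4:
            pass  # already channel-first
        else:
            arr = arr.transpose(0, 2, 1)
        length = arr.shape[2]
        if length != self.spec.input_length:
            raise ValueError(
                f"input length {length} != model input length {self.spec.input_length}"
            )
        pad = self.spec.padded_length - length
        if pad:
            arr = np.pad(arr, ((0, 0), (0, 0), (0, pad)))
        return np.ascontiguousarray(arr, dtype=np.float32)

    def _forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        for layer in self.features:
            x = layer.forward(x, train)
        self._feature_maps = x
        for layer in self.head:
            x = layer.forward(x, train)
            if isinstance(layer, _ReLU) and layer is self.head[-3]:
                self._penultimate = x
        return x

    def _backward(self, dlogits: np.ndarray, through_features: bool = True):
        g = dlogits
        for layer in reversed(self.head):
            g = layer.backward(g)
        dmaps = g
        if through_features:
            for layer in reversed(self.features):
                g = layer.backward(g)
        return dmaps

    # -- inference ---------------------------------------------------------
    def _batched_forward(self, x, batch: int = 256) -> np.ndarray:
        arr = self._prepare(x)
        outs = [
            self._forward(arr[i:i + batch], train=False)
            for i in range(0, arr.shape[0], batch)
        ]
        return np.concatenate(outs) if outs else np.empty((0, self.spec.n_classes))

    def logits(self, x) -> np.ndarray:
        return self._batched_forward(x)

    def predict_proba(self, x) -> np.ndarray:
        return _softmax(self.logits(x))

    def predict(self, x) -> np.ndarray:
        proba = self.predict_proba(x)
        return np.array([self.classes[i] for i in proba.argmax(axis=1)])

    def penultimate_features(self, x, batch: int = 256) -> np.ndarray:
        arr = self._prepare(x)
        feats = []
        for i in range(0, arr.shape[0], batch):
            self._forward(arr[i:i + batch], train=False)
            feats.append(self._penultimate)
        return np.concatenate(feats)

    def feature_maps_and_logits(self, x) -> tuple[np.ndarray, np.ndarray]:
        """Inference forward pass exposing the last conv block's output."""
        arr = self._prepare(x)
        logits = self._forward(arr, train=False)
        return self._feature_maps, logits

    def backprop_to_feature_maps(self, dlogits: np.ndarray) -> np.ndarray:
        """Gradient of a scalar (given as d/dlogits) w.r.t. the conv feature maps.

        Must follow a :meth:`feature_maps_and_logits` call on the same batch.
        """
        return self._backward(dlogits.astype(np.float32), through_features=False)


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def build_model(spec: CnnSpec, classes: list[str], seed: int = 0) -> CnnClassifier:
    """Freshly initialized classifier; identical seeds give identical parameters."""
    return CnnClassifier(spec, classes, seed=seed)


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

class _Adam:
    def __init__(self, layers, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-7):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.slots = [
            (p, g, np.zeros_like(p), np.zeros_like(p))
            for layer in layers
            for p, g in zip(layer.params, layer.grads)
        ]

    def step(self) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for p, g, m, v in self.slots:
            m += (1.0 - self.b1) * (g - m)
            v += (1.0 - self.b2) * (g * g - v)
            p -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)


def train(
    model: CnnClassifier,
    records: list[SequenceRecord],
    epochs: int = 200,
    batch_size: int = 16,
    lr: float = 1e-3,
    seed: int | None = None,
    patience: int = 10,
    min_delta: float = 1e-4,
) -> CnnClassifier:
    """Fit with Adam + cross-entropy; stops early on a training-loss plateau.

    The plateau rule automates the usual visual convergence check: training
    stops when the best epoch loss has not improved by ``min_delta`` for
    ``patience`` consecutive epochs (or at ``epochs``, whichever is first).
    """
    label_index = {c: i for i, c in enumerate(model.classes)}
    unknown = {r.species for r in records} - set(label_index)
    if unknown:
        raise ValueError(f"records contain species outside the class list: {unknown}")
    x = model._prepare(records)
    y = np.array([label_index[r.species] for r in records])
    n = x.shape[0]
    rng = rng_for(model.seed if seed is None else seed, "train")
    opt = _Adam(model.layers, lr=lr)
    best = np.inf
    stall = 0
    for epoch in range(epochs):
        order = rng.permutation(n)
        total = 0.0
        for start in range(0, n, batch_size):
            idx = order[start:start + batch_size]
            logits = model._forward(x[idx], train=True)
            proba = _softmax(logits)
            eps = 1e-12
            loss = -np.log(proba[np.arange(len(idx)), y[idx]] + eps).mean()
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch}; "
                    "inspect inputs/learning rate"
                )
            total += loss * len(idx)
            dlogits = proba
            dlogits[np.arange(len(idx)), y[idx]] -= 1.0
            dlogits /= len(idx)
            model._backward(dlogits.astype(np.float32))
            opt.step()
        epoch_loss = total / n
        model.history["loss"].append(float(epoch_loss))
        if epoch_loss < best - min_delta:
            best = epoch_loss
            stall = 0
        else:
            stall += 1
            if stall >= patience:
                break
    model.trained = True
    return model


def accuracy(predictions, truth) -> float:
    """Fraction of correct identifications."""
    predictions = np.asarray(predictions)
    truth = np.asarray(truth)
    if predictions.size == 0:
        raise ValueError("empty input")
    if predictions.shape != truth.shape:
        raise ValueError("predictions and truth must have equal length")
    return float((predictions == truth).mean())
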