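"""A small, deterministic 1-D convolutional network engine in NumPy.

The package's two per-beat classifiers are modest stacks of conv / pooling /
dense layers over short windows, so the trainable network is implemented
directly on NumPy: forward and backward passes are expressed as batched
GEMMs (a kernel-position loop of ``(N·L_out, C_in) @ (C_in, C_out)``
products), which keeps single-core training of the full five-class model on
tens of thousands of beats in the minutes range.  Everything is float32 and
driven by explicit integer seeds, so two builds/trainings with the same
seeds produce bit-identical parameters and loss curves.

Conventions: activations flow as ``(batch, length, channels)`` until the
first flatten/global pool, then ``(batch, features)``.  The final dense
layer's softmax/sigmoid is *not* applied inside ``forward`` — training uses
fused logit losses for numerical stability; ``predict`` applies it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .arch import ArchitectureSpec, LayerSpec, propagate_shapes
from .errors import InputShapeError, TrainingError


# --------------------------------------------------------------------------
# layers
# --------------------------------------------------------------------------

class _Layer:
    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self) -> None:
        self.params, self.grads = [], []

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class _Conv1D(_Layer):
    def __init__(self, c_in, c_out, kernel, padding, relu, rng):
        super().__init__()
        self.k, self.padding, self.relu = kernel, padding, relu
        limit = np.sqrt(6.0 / (kernel * c_in + kernel * c_out))
        self.W = rng.uniform(-limit, limit, size=(kernel, c_in, c_out)).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self.params, self.grads = [self.W, self.b], [self.dW, self.db]

    def forward(self, x, training):
        k = self.k
        if self.padding == "same":
            left = (k - 1) // 2
            x = np.pad(x, ((0, 0), (left, k - 1 - left), (0, 0)))
            self._left = left
        else:
            self._left = 0
        n, l_pad, _ = x.shape
        l_out = l_pad - k + 1
        y = np.broadcast_to(self.b, (n, l_out, self.b.size)).copy()
        for i in range(k):
            y += x[:, i : i + l_out, :] @ self.W[i]
        self._x_pad, self._l_out = x, l_out
        if self.relu:
            self._mask = y > 0
            y *= self._mask
        return y

    def backward(self, dy):
        if self.relu:
            dy = dy * self._mask
        x, l_out, k = self._x_pad, self._l_out, self.k
        n, _, c_out = dy.shape
        dy2 = dy.reshape(-1, c_out)
        self.db[...] = dy2.sum(axis=0)
        dx = np.zeros_like(x)
        for i in range(k):
            xi = x[:, i : i + l_out, :]
            self.dW[i] = xi.reshape(-1, xi.shape[2]).T @ dy2
            dx[:, i : i + l_out, :] += dy @ self.W[i].T
        left = self._left
        L = x.shape[1] - (k - 1) if self.padding == "same" else x.shape[1]
        return dx[:, left : left + L, :] if self.padding == "same" else dx


class _Pool1D(_Layer):
    def __init__(self, pool, stride, mode):
        super().__init__()
        self.p, self.s, self.mode = pool, stride, mode

    def forward(self, x, training):
        p, s = self.p, self.s
        win = np.lib.stride_tricks.sliding_window_view(x, p, axis=1)[:, ::s]
        self._in_shape = x.shape
        if self.mode == "avg":
            return win.mean(axis=-1)
        self._idx = win.argmax(axis=-1)
        return win.max(axis=-1)

    def backward(self, dy):
        p, s = self.p, self.s
        l_out = dy.shape[1]
        dx = np.zeros(self._in_shape, dtype=dy.dtype)
        end = s * (l_out - 1) + 1
        if self.mode == "avg":
            share = dy / p
            for i in range(p):
                dx[:, i : i + end : s, :] += share
        else:
            for i in range(p):
                dx[:, i : i + end : s, :] += dy * (self._idx == i)
        return dx


class _GlobalMaxPool(_Layer):
    def forward(self, x, training):
        self._in_shape = x.shape
        self._idx = x.argmax(axis=1)
        return x.max(axis=1)

    def backward(self, dy):
        dx = np.zeros(self._in_shape, dtype=dy.dtype)
        np.put_along_axis(dx, self._idx[:, None, :], dy[:, None, :], axis=1)
        return dx


class _Flatten(_Layer):
    def forward(self, x, training):
        self._in_shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._in_shape)


class _Dropout(_Layer):
    def __init__(self, rate):
        super().__init__()
        self.rate = rate
        self.rng = np.random.default_rng(0)  # reseeded by train()

    def forward(self, x, training):
        if not training or self.rate == 0.0:
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class _Dense(_Layer):
    def __init__(self, n_in, n_out, relu, rng):
        super().__init__()
        self.relu = relu
        limit = np.sqrt(6.0 / (n_in + n_out))
        self.W = rng.uniform(-limit, limit, size=(n_in, n_out)).astype(np.float32)
        self.b = np.zeros(n_out, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self.params, self.grads = [self.W, self.b], [self.dW, self.db]

    def forward(self, x, training):
        self._x = x
        y = x @ self.W + self.b
        if self.relu:
            self._mask = y > 0
            y *= self._mask
        return y

    def backward(self, dy):
        if self.relu:
            dy = dy * self._mask
        self.dW[...] = self._x.T @ dy
        self.db[...] = dy.sum(axis=0)
        return dy @ self.W.T


# --------------------------------------------------------------------------
# model
# --------------------------------------------------------------------------

class Model:
    """A built, trainable network for one :class:`ArchitectureSpec`."""

    def __init__(self, spec: ArchitectureSpec, seed: int):
        self.spec = spec
        self.seed = seed
        rng = np.random.default_rng(seed)
        shapes = propagate_shapes(spec)
        self.layers: list[_Layer] = []
        c_in = spec.input_channels
        feat_in: int | None = None
        for layer, shape in zip(spec.layers, shapes):
            if layer.kind == "conv1d":
                relu = layer.activation == "relu"
                self.layers.append(
                    _Conv1D(c_in, layer.filters, layer.kernel_size, layer.padding, relu, rng)
                )
                c_in = layer.filters
            elif layer.kind == "avgpool1d":
                self.layers.append(_Pool1D(layer.pool_size, layer.stride or 1, "avg"))
            elif layer.kind == "maxpool1d":
                self.layers.append(_Pool1D(layer.pool_size, layer.stride or 1, "max"))
            elif layer.kind == "globalmaxpool1d":
                self.layers.append(_GlobalMaxPool())
                feat_in = shape.features
            elif layer.kind == "flatten":
                self.layers.append(_Flatten())
                feat_in = shape.features
            elif layer.kind == "dropout":
                self.layers.append(_Dropout(layer.dropout_rate or 0.0))
            elif layer.kind == "dense":
                relu = layer.activation == "relu"
                self.layers.append(_Dense(feat_in, layer.filters, relu, rng))
                feat_in = layer.filters
        self.output_activation = spec.layers[-1].activation  # softmax | sigmoid

    # -- passes ------------------------------------------------------------

    def _check_input(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=np.float32)
        if x.ndim == 2:
            x = x[:, :, None]
        if x.ndim != 3 or x.shape[1] != self.spec.input_length or x.shape[2] != self.spec.input_channels:
            raise InputShapeError(
                f"expected (n, {self.spec.input_length}, {self.spec.input_channels}), "
                f"got {x.shape}"
            )
        return x

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        """Logits of shape (n, n_outputs)."""
        a = self._check_input(x)
        for layer in self.layers:
            a = layer.forward(a, training)
        return a

    def backward(self, dlogits: np.ndarray) -> None:
        d = dlogits
        for layer in reversed(self.layers):
            d = layer.backward(d)

    def predict_proba(self, x: np.ndarray, batch_size: int = 512) -> np.ndarray:
        """Class probabilities (softmax rows / sigmoid values)."""
        x = self._check_input(x)
        chunks = []
        for lo in range(0, len(x), batch_size):
            z = self.forward(x[lo : lo + batch_size], training=False)
            chunks.append(_activate(z, self.output_activation))
        return np.concatenate(chunks) if chunks else np.empty((0, self.spec.n_outputs))

    def activation_shapes(self, batch: int = 2) -> list[tuple[int, ...]]:
        """Actual per-layer output shapes (without the batch axis) of a run."""
        x = np.zeros((batch, self.spec.input_length, self.spec.input_channels), np.float32)
        shapes = []
        for layer in self.layers:
            x = layer.forward(x, training=False)
            shapes.append(x.shape[1:])
        return shapes

    def parameter_count(self) -> int:
        return sum(p.size for layer in self.layers for p in layer.params)

    # -- persistence -------------------------------------------------------

    def save(self, path: str) -> None:
        arrays = {
            f"p{i}_{j}": p
            for i, layer in enumerate(self.layers)
            for j, p in enumerate(layer.params)
        }
        np.savez(path, spec=self.spec.to_json(), seed=self.seed, **arrays)

    @staticmethod
    def load(path: str) -> "Model":
        data = np.load(path, allow_pickle=False)
        spec = ArchitectureSpec.from_json(str(data["spec"]))
        model = Model(spec, seed=int(data["seed"]))
        for i, layer in enumerate(model.layers):
            for j in range(len(layer.params)):
                layer.params[j][...] = data[f"p{i}_{j}"]
        return model


def build_network(spec: ArchitectureSpec, seed: int = 0) -> Model:
    """Instantiate a trainable network with seeded Glorot-uniform weights."""
    return Model(spec, seed)


def _activate(z: np.ndarray, activation: str | None) -> np.ndarray:
    if activation == "softmax":
        m = z.max(axis=1, keepdims=True)
        e = np.exp(z - m)
        return e / e.sum(axis=1, keepdims=True)
    if activation == "sigmoid":
        return 1.0 / (1.0 + np.exp(-z))
    return z


def labels_from_probs(probs: np.ndarray) -> np.ndarray:
    """argmax labels for softmax rows; 0.5-threshold labels for a sigmoid column."""
    if probs.shape[1] == 1:
        return (probs[:, 0] >= 0.5).astype(np.int64)
    return probs.argmax(axis=1).astype(np.int64)


def predict(model: Model, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(probabilities, hard labels) for a batch of windows."""
    probs = model.predict_proba(x)
    return probs, labels_from_probs(probs)


# --------------------------------------------------------------------------
# training
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings.

    The published pipeline trains 80 epochs (five-class) / 30 epochs
    (binary); optimizer, learning rate, batch size and loss are not stated
    there, so the declared defaults are Adam(1e-3), batch 32, cross-entropy
    matched to the output head.  ``stop_at_accuracy`` optionally ends
    training once the monitor accuracy reaches a convergence bar.
    """

    epochs: int = 10
    batch_size: int = 32
    learning_rate: float = 1e-3
    seed: int = 0
    stop_at_accuracy: float | None = None

    def __post_init__(self) -> None:
        if self.epochs < 1 or self.batch_size < 1 or self.learning_rate <= 0:
            raise TrainingError("epochs, batch_size >= 1 and learning_rate > 0 required")


@dataclass
class TrainHistory:
    """Per-epoch curves (monitor = the data passed as ``monitor_data``)."""

    train_accuracy: list[float] = field(default_factory=list)
    train_loss: list[float] = field(default_factory=list)
    test_accuracy: list[float] = field(default_factory=list)
    test_loss: list[float] = field(default_factory=list)

    @property
    def epochs_run(self) -> int:
        return len(self.train_loss)


class _Adam:
    def __init__(self, model: Model, lr: float):
        self.lr = lr
        self.beta1, self.beta2, self.eps = 0.9, 0.999, 1e-7
        self.t = 0
        self.slots = [
            (p, g, np.zeros_like(p), np.zeros_like(p))
            for layer in model.layers
            for p, g in zip(layer.params, layer.grads)
        ]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        corr = self.lr * np.sqrt(1 - b2**self.t) / (1 - b1**self.t)
        for p, g, m, v in self.slots:
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p -= corr * m / (np.sqrt(v) + self.eps)


def _loss_and_grad(
    logits: np.ndarray, y: np.ndarray, activation: str | None
) -> tuple[float, np.ndarray, np.ndarray]:
    """Fused cross-entropy on logits → (mean loss, dlogits, hard predictions)."""
    n = len(logits)
    if activation == "softmax":
        m = logits.max(axis=1, keepdims=True)
        z = logits - m
        lse = np.log(np.exp(z).sum(axis=1, keepdims=True))
        logp = z - lse
        loss = float(-(y * logp).sum() / n)
        p = np.exp(logp)
        return loss, (p - y).astype(np.float32) / n, logits.argmax(axis=1)
    # sigmoid / binary cross-entropy; y is an (n, 1) 0/1 column
    z = logits
    loss = float(np.mean(np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z)))))
    p = 1.0 / (1.0 + np.exp(-z))
    return loss, (p - y).astype(np.float32) / n, (z[:, 0] >= 0).astype(np.int64)


def _hard(y: np.ndarray) -> np.ndarray:
    return y.argmax(axis=1) if y.shape[1] > 1 else y[:, 0].astype(np.int64)


def evaluate(
    model: Model, x: np.ndarray, y: np.ndarray, batch_size: int = 512
) -> tuple[float, float]:
    """(loss, accuracy) of the model on encoded labels ``y``, dropout inert."""
    x = model._check_input(x)
    y = np.asarray(y, dtype=np.float32)
    total_loss, correct = 0.0, 0
    for lo in range(0, len(x), batch_size):
        xb, yb = x[lo : lo + batch_size], y[lo : lo + batch_size]
        logits = model.forward(xb, training=False)
        loss, _, pred = _loss_and_grad(logits, yb, model.output_activation)
        total_loss += loss * len(xb)
        correct += int((pred == _hard(yb)).sum())
    n = len(x)
    return total_loss / n, correct / n


def train(
    model: Model,
    train_data: tuple[np.ndarray, np.ndarray],
    monitor_data: tuple[np.ndarray, np.ndarray] | None,
    config: TrainConfig = TrainConfig(),
) -> TrainHistory:
    """Mini-batch Adam training; returns per-epoch accuracy/loss curves.

    ``train_data`` and ``monitor_data`` are (windows, encoded labels) pairs:
    one-hot rows for the softmax head, a 0/1 column for the sigmoid head.
    Train-set accuracy/loss are the running mini-batch averages of the epoch
    (the dropout-active pass), monitor metrics a full inert pass after it.
    Raises :class:`TrainingError` on a non-finite loss.
    """
    x = model._check_input(train_data[0])
    y = np.asarray(train_data[1], dtype=np.float32)
    if y.ndim != 2 or y.shape[0] != x.shape[0] or y.shape[1] != model.spec.n_outputs:
        raise InputShapeError(
            f"encoded labels {y.shape} do not match inputs {x.shape} / "
            f"{model.spec.n_outputs} outputs"
        )
    rng = np.random.default_rng(config.seed)
    for layer in model.layers:
        if isinstance(layer, _Dropout):
            layer.rng = np.random.default_rng(rng.integers(2**31))
    opt = _Adam(model, config.learning_rate)
    history = TrainHistory()
    n = len(x)
    for _epoch in range(config.epochs):
        order = rng.permutation(n)
        running_loss, running_correct = 0.0, 0
        for lo in range(0, n, config.batch_size):
            idx = order[lo : lo + config.batch_size]
            xb, yb = x[idx], y[idx]
            logits = model.forward(xb, training=True)
            loss, dlogits, pred = _loss_and_grad(logits, yb, model.output_activation)
            if not np.isfinite(loss):
                raise TrainingError(f"non-finite loss at epoch {_epoch}")
            model.backward(dlogits)
            opt.step()
            running_loss += loss * len(idx)
            running_correct += int((pred == _hard(yb)).sum())
        history.train_loss.append(running_loss / n)
        history.train_accuracy.append(running_correct / n)
        if monitor_data is not None:
            mloss, macc = evaluate(model, monitor_data[0], monitor_data[1])
            history.test_loss.append(mloss)
            history.test_accuracy.append(macc)
            if config.stop_at_accuracy is not None and macc >= config.stop_at_accuracy:
                break
    return history
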