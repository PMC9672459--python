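"""1-D convolutional promoter classifier (pure numpy).

Architecture, in order: two [Conv1D -> MaxPool -> Dropout] blocks, Flatten,
Dense(64, ReLU), Dropout, Dense(1, sigmoid). Both convolutions have 16
filters of kernel size 5 with ReLU; both poolings use size 4 with stride 2;
all dropouts are 0.5. Kernel and bias L2 regularization (1e-4 each) is
applied to the convolutional and dense layers. Training minimises binary
cross-entropy with Adam at batch size 20 for 85 epochs. All of these are the
model's defaults and are exposed through :class:`CNNConfig`.

The implementation is deliberately small and fully deterministic given the
config seed (single-threaded numpy): forward/backward passes use an
im2col-style lowering of the convolutions to matrix products.
"""

from __future__ import annotations

import io
import json
import zipfile
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .sequence_io import DataError

SCHEMA_VERSION = 1


def sigmoid(p):
    """Logistic function S(p) = 1 / (1 + exp(-p)), stable for large |p|."""
    p = np.asarray(p, dtype=float)
    out = np.empty_like(p)
    pos = p >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-p[pos]))
    ep = np.exp(p[~pos])
    out[~pos] = ep / (1.0 + ep)
    if out.ndim == 0:
        return float(out)
    return out


@dataclass(frozen=True)
class CNNConfig:
    """Every architecture/training hyperparameter of the promoter CNN."""

    conv_filters: int = 16
    conv_kernel: int = 5
    n_conv_blocks: int = 2
    pool_size: int = 4
    pool_stride: int = 2
    dropout: float = 0.5
    dense_units: int = 64
    l2: float = 0.0001
    bias_l2: float = 0.0001
    loss: str = "binary_cross_entropy"
    optimizer: str = "adam"
    batch_size: int = 20
    epochs: int = 85
    activation: str = "relu"
    output_activation: str = "sigmoid"
    learning_rate: float = 0.001
    padding: str = "same"
    seed: int = 0

    def __post_init__(self) -> None:
        problems = []
        if not 0 <= self.dropout < 1:
            problems.append(f"dropout={self.dropout} not in [0, 1)")
        if self.epochs < 1:
            problems.append(f"epochs={self.epochs} < 1")
        if self.batch_size < 1:
            problems.append(f"batch_size={self.batch_size} < 1")
        if self.loss != "binary_cross_entropy":
            problems.append(f"unsupported loss {self.loss!r}")
        if self.optimizer != "adam":
            problems.append(f"unsupported optimizer {self.optimizer!r}")
        if self.activation != "relu" or self.output_activation != "sigmoid":
            problems.append("activations must be relu / sigmoid")
        if self.padding != "same":
            problems.append(f"unsupported padding {self.padding!r}")
        if problems:
            raise DataError("invalid CNNConfig: " + "; ".join(problems))


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------

class Conv1D:
    """Same-padded stride-1 1-D convolution with ReLU."""

    def __init__(self, in_ch: int, filters: int, kernel: int,
                 rng: np.random.Generator):
        limit = np.sqrt(6.0 / (kernel * in_ch + kernel * filters))  # Glorot
        self.W = rng.uniform(-limit, limit, size=(kernel * in_ch, filters))
        self.b = np.zeros(filters)
        self.kernel = kernel
        self.in_ch = in_ch
        self.filters = filters
        self.regularized = True

    @property
    def n_params(self) -> int:
        return self.W.size + self.b.size

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        B, L, C = x.shape
        k = self.kernel
        left = (k - 1) // 2
        xp = np.zeros((B, L + k - 1, C))
        xp[:, left : left + L] = x
        idx = np.arange(L)[:, None] + np.arange(k)[None, :]
        return xp[:, idx, :].reshape(B, L, k * C)

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._xcol = self._im2col(x)
        self._L_in = x.shape[1]
        z = self._xcol @ self.W + self.b
        self._mask = z > 0
        return np.where(self._mask, z, 0.0)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dy = dy * self._mask
        self.dW = np.einsum("blk,blf->kf", self._xcol, dy)
        self.db = dy.sum(axis=(0, 1))
        dxcol = (dy @ self.W.T).reshape(
            dy.shape[0], dy.shape[1], self.kernel, self.in_ch
        )
        B, L = dy.shape[0], self._L_in
        k = self.kernel
        left = (k - 1) // 2
        dxp = np.zeros((B, L + k - 1, self.in_ch))
        for o in range(k):
            dxp[:, o : o + L] += dxcol[:, :, o, :]
        return dxp[:, left : left + L]

    def params(self):
        return [("W", self.W), ("b", self.b)]

    def grads(self):
        return [self.dW, self.db]


class MaxPool1D:
    """Valid max pooling (size 4, stride 2 by default)."""

    def __init__(self, size: int, stride: int):
        self.size = size
        self.stride = stride
        self.regularized = False

    def out_len(self, L: int) -> int:
        if L < self.size:
            raise DataError(f"input length {L} < pool size {self.size}")
        return (L - self.size) // self.stride + 1

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        B, L, C = x.shape
        n_out = self.out_len(L)
        idx = np.arange(n_out)[:, None] * self.stride + np.arange(self.size)
        win = x[:, idx, :]  # (B, n_out, size, C)
        self._argmax = win.argmax(axis=2)
        self._in_shape = x.shape
        return win.max(axis=2)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        B, n_out, C = dy.shape
        dx = np.zeros(self._in_shape)
        onehot = (
            np.arange(self.size)[None, None, :, None] == self._argmax[:, :, None, :]
        )
        dwin = dy[:, :, None, :] * onehot
        for o in range(self.size):
            cols = np.arange(n_out) * self.stride + o
            dx[:, cols, :] += dwin[:, :, o, :]
        return dx

    def params(self):
        return []

    def grads(self):
        return []


class Dropout:
    def __init__(self, rate: float, rng: np.random.Generator):
        self.rate = rate
        self.rng = rng
        self.regularized = False

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if not training or self.rate == 0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.rate) / (1 - self.rate)
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy if self._mask is None else dy * self._mask

    def params(self):
        return []

    def grads(self):
        return []


class Flatten:
    def __init__(self):
        self.regularized = False

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy.reshape(self._shape)

    def params(self):
        return []

    def grads(self):
        return []


class Dense:
    """Fully connected layer; activation 'relu', 'sigmoid' or None (logits)."""

    def __init__(self, in_dim: int, units: int, activation: str | None,
                 rng: np.random.Generator):
        limit = np.sqrt(6.0 / (in_dim + units))
        self.W = rng.uniform(-limit, limit, size=(in_dim, units))
        self.b = np.zeros(units)
        self.activation = activation
        self.regularized = True

    @property
    def n_params(self) -> int:
        return self.W.size + self.b.size

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._x = x
        z = x @ self.W + self.b
        if self.activation == "relu":
            self._mask = z > 0
            return np.where(self._mask, z, 0.0)
        self._z = z
        return z  # sigmoid head fused with the loss; see PromoterCNN

    def backward(self, dy: np.ndarray) -> np.ndarray:
        if self.activation == "relu":
            dy = dy * self._mask
        self.dW = self._x.T @ dy
        self.db = dy.sum(axis=0)
        return dy @ self.W.T

    def params(self):
        return [("W", self.W), ("b", self.b)]

    def grads(self):
        return [self.dW, self.db]


class Adam:
    def __init__(self, lr: float, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-7):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m: list[np.ndarray] | None = None
        self.v: list[np.ndarray] | None = None

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        if self.m is None:
            self.m = [np.zeros_like(p) for p in params]
            self.v = [np.zeros_like(p) for p in params]
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------

class PromoterCNN:
    """The promoter CNN with Keras-like fit/predict_proba semantics."""

    def __init__(self, config: CNNConfig, input_shape: tuple[int, int]):
        if input_shape[0] != 99:
            raise DataError(
                f"model input must have 99 rows, got {input_shape[0]}"
            )
        self.config = config
        self.input_shape = tuple(input_shape)
        self.training_log: list[dict] = []
        self.rng = np.random.default_rng(config.seed)
        self._build()

    def _build(self) -> None:
        cfg = self.config
        L, C = self.input_shape
        layers: list = []
        ch = C
        for _ in range(cfg.n_conv_blocks):
            layers.append(Conv1D(ch, cfg.conv_filters, cfg.conv_kernel, self.rng))
            pool = MaxPool1D(cfg.pool_size, cfg.pool_stride)
            L = pool.out_len(L)
            layers.append(pool)
            layers.append(Dropout(cfg.dropout, self.rng))
            ch = cfg.conv_filters
        layers.append(Flatten())
        layers.append(Dense(L * ch, cfg.dense_units, "relu", self.rng))
        layers.append(Dropout(cfg.dropout, self.rng))
        layers.append(Dense(cfg.dense_units, 1, "sigmoid", self.rng))
        self.layers = layers

    # -- forward / backward -------------------------------------------------

    def _forward(self, X: np.ndarray, training: bool) -> np.ndarray:
        out = X
        for layer in self.layers:
            out = layer.forward(out, training)
        return out[:, 0]  # logits

    def _reg_loss(self) -> float:
        cfg = self.config
        total = 0.0
        for layer in self.layers:
            if layer.regularized:
                total += cfg.l2 * float((layer.W**2).sum())
                total += cfg.bias_l2 * float((layer.b**2).sum())
        return total

    def _train_step(self, X: np.ndarray, y: np.ndarray, opt: Adam) -> tuple:
        cfg = self.config
        logits = self._forward(X, training=True)
        p = sigmoid(logits)
        eps = 1e-12
        data_loss = -float(
            np.mean(y * np.log(p + eps) + (1 - y) * np.log(1 - p + eps))
        )
        loss = data_loss + self._reg_loss()
        if not np.isfinite(loss):
            raise DataError(
                f"training diverged: loss={loss} at Adam step {opt.t + 1}"
            )
        # fused sigmoid + BCE gradient
        dlogits = (p - y)[:, None] / len(y)
        grad = dlogits
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        params, grads = [], []
        for layer in self.layers:
            for (name, p_arr), g in zip(layer.params(), layer.grads()):
                if layer.regularized:
                    lam = cfg.l2 if name == "W" else cfg.bias_l2
                    g = g + 2.0 * lam * p_arr
                params.append(p_arr)
                grads.append(g)
        opt.step(params, grads)
        acc = float(np.mean((p >= 0.5) == (y == 1)))
        return loss, acc, len(y)

    # -- public API ---------------------------------------------------------

    def fit(self, X: np.ndarray, y) -> "PromoterCNN":
        """Train for ``config.epochs`` epochs at ``config.batch_size``.

        ``X``: (n, 99, channels) positional encodings; ``y``: binary labels.
        Appends one entry per epoch to :attr:`training_log`. Deterministic
        given the config seed.
        """
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 3 or X.shape[1:] != self.input_shape:
            raise DataError(
                f"X shape {X.shape} incompatible with input {self.input_shape}"
            )
        if len(X) != len(y):
            raise DataError(f"{len(X)} inputs but {len(y)} labels")
        classes = np.unique(y)
        if classes.size < 2:
            raise DataError(
                f"training labels contain a single class {classes.tolist()}"
            )
        cfg = self.config
        opt = Adam(cfg.learning_rate)
        n = len(X)
        for epoch in range(cfg.epochs):
            order = self.rng.permutation(n)
            tot_loss = tot_acc = tot_n = 0.0
            for start in range(0, n, cfg.batch_size):
                sel = order[start : start + cfg.batch_size]
                loss, acc, bs = self._train_step(X[sel], y[sel], opt)
                tot_loss += loss * bs
                tot_acc += acc * bs
                tot_n += bs
            self.training_log.append(
                {
                    "epoch": epoch + 1,
                    "loss": tot_loss / tot_n,
                    "accuracy": tot_acc / tot_n,
                }
            )
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Probability of the positive class for each input row, in [0, 1]."""
        X = np.asarray(X, dtype=float)
        if X.ndim != 3 or X.shape[1:] != self.input_shape:
            raise DataError(
                f"X shape {X.shape} incompatible with input {self.input_shape}"
            )
        return sigmoid(self._forward(X, training=False))

    def predict(self, X: np.ndarray, threshold: float = 0.5) -> np.ndarray:
        return (self.predict_proba(X) >= threshold).astype(int)

    # -- persistence --------------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Single-file archive: config JSON + weight tensors."""
        weights = {}
        for i, layer in enumerate(self.layers):
            for name, arr in layer.params():
                weights[f"layer{i}_{name}"] = arr
        buf = io.BytesIO()
        np.savez(buf, **weights)
        meta = {
            "schema_version": SCHEMA_VERSION,
            "config": asdict(self.config),
            "input_shape": list(self.input_shape),
            "training_log": self.training_log,
        }
        with zipfile.ZipFile(path, "w") as zf:
            zf.writestr("config.json", json.dumps(meta, indent=1))
            zf.writestr("weights.npz", buf.getvalue())

    @classmethod
    def load(cls, path: str | Path) -> "PromoterCNN":
        try:
            with zipfile.ZipFile(path) as zf:
                meta = json.loads(zf.read("config.json"))
                weights = np.load(io.BytesIO(zf.read("weights.npz")))
                if meta.get("schema_version") != SCHEMA_VERSION:
                    raise DataError(
                        f"model file schema version {meta.get('schema_version')} "
                        f"!= supported {SCHEMA_VERSION}"
                    )
                model = cls(CNNConfig(**meta["config"]),
                            tuple(meta["input_shape"]))
                model.training_log = meta["training_log"]
                for i, layer in enumerate(model.layers):
                    for name, arr in layer.params():
                        arr[...] = weights[f"layer{i}_{name}"]
                return model
        except (zipfile.BadZipFile, KeyError) as exc:
            raise DataError(f"corrupt or incompatible model file {path}: {exc}")


def build_model(cfg: CNNConfig | None = None,
                input_shape: tuple[int, int] = (99, 4)) -> PromoterCNN:
    """Construct the untrained CNN for a given positional input shape."""
    return PromoterCNN(cfg or CNNConfig(), input_shape)


def train(model: PromoterCNN, X: np.ndarray, y) -> PromoterCNN:
    """Functional alias for :meth:`PromoterCNN.fit`."""
    return model.fit(X, y)


def save_model(model: PromoterCNN, path: str | Path) -> None:
    """Functional alias for :meth:`PromoterCNN.save`."""
    model.save(path)


def load_model(path: str | Path) -> PromoterCNN:
    """Functional alias for :meth:`PromoterCNN.load`."""
    return PromoterCNN.load(path)
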