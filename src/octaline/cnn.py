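"""1-D convolutional network for A-line classification and feature extraction.

The network classifies single pre-processed A-lines (200-px ROI padded to 210
samples) as fibrolipidic / fibrocalcific / other.  Architecture: three
convolution blocks (32, 64, 96 filters; kernels 11, 9, 7; stride 2; each with
batch normalization and ReLU), max pooling (size 2) after the first two
blocks, then three fully connected layers (100, 100, 3) with ReLU + dropout
on the first two and softmax on the last.  Training minimizes a softmax
cross-entropy loss weighted by inverse-median class frequency, with the Adam
optimizer, a step learning-rate schedule, and early stopping on validation
loss.

After training, the last fully connected layer is removed and the 100
activations of the penultimate layer serve as convolutional features for the
downstream hybrid random-forest classifier; :meth:`ALineCNN.transform`
exposes exactly that truncated forward pass.

The implementation is pure numpy (im2col convolutions with explicit
backward passes); at A-line scale this trains in seconds to minutes on one
CPU core.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin

from .preprocess import KEEP_LENGTH, PAD_SOURCE_LENGTH, ROI_LENGTH

__all__ = [
    "pad_aline",
    "pad_alines",
    "inverse_median_frequency_weights",
    "ALineCNN",
    "PADDED_LENGTH",
    "N_FEATURES",
]

#: CNN input length: 5 zero pad + 200 ROI + 5 tissue pad.
PADDED_LENGTH = ROI_LENGTH + 2 * PAD_SOURCE_LENGTH
#: Width of the penultimate fully connected layer = feature vector length.
N_FEATURES = 100


def pad_aline(roi: np.ndarray, pad_source: np.ndarray) -> np.ndarray:
    """Pad one A-line for the CNN: 5 zeros on the left (lumen side), the ROI,
    then the five post-ROI tissue samples on the right."""
    roi = np.asarray(roi).ravel()
    pad_source = np.asarray(pad_source).ravel()
    if roi.size != ROI_LENGTH:
        raise ValueError(f"ROI must have {ROI_LENGTH} samples, got {roi.size}")
    if pad_source.size != PAD_SOURCE_LENGTH:
        raise ValueError(
            f"pad source must have {PAD_SOURCE_LENGTH} samples, got {pad_source.size}"
        )
    return np.concatenate([np.zeros(PAD_SOURCE_LENGTH), roi, pad_source])


def pad_alines(alines: np.ndarray) -> np.ndarray:
    """Vectorized :func:`pad_aline` over an (N, 205) array of ROI+pad rows."""
    alines = np.atleast_2d(np.asarray(alines))
    if alines.shape[1] != KEEP_LENGTH:
        raise ValueError(f"expected {KEEP_LENGTH} samples per A-line, got {alines.shape[1]}")
    left = np.zeros((alines.shape[0], PAD_SOURCE_LENGTH))
    return np.concatenate([left, alines], axis=1)


def inverse_median_frequency_weights(y: np.ndarray, n_classes: int = 3) -> np.ndarray:
    """Per-class loss weights w_c = median(freq) / freq_c.

    Raises if a class is absent (its weight would be undefined).
    """
    y = np.asarray(y)
    counts = np.bincount(y, minlength=n_classes).astype(float)
    if np.any(counts[:n_classes] == 0):
        missing = np.flatnonzero(counts[:n_classes] == 0)
        raise ValueError(f"classes {missing.tolist()} absent from training data")
    freqs = counts[:n_classes] / counts[:n_classes].sum()
    return np.median(freqs) / freqs


# ---------------------------------------------------------------------------
# layers (float32, explicit forward/backward)


class _Conv1d:
    def __init__(self, c_in: int, c_out: int, kernel: int, stride: int, rng):
        scale = np.sqrt(2.0 / (c_in * kernel))
        self.W = rng.normal(0.0, scale, size=(c_out, c_in, kernel)).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.stride = stride
        self.kernel = kernel

    def out_length(self, length: int) -> int:
        return -(-length // self.stride)  # ceil, "same" padding

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, c, length = x.shape
        l_out = self.out_length(length)
        total_pad = max((l_out - 1) * self.stride + self.kernel - length, 0)
        left = total_pad // 2
        xp = np.pad(x, ((0, 0), (0, 0), (left, total_pad - left)))
        windows = np.lib.stride_tricks.sliding_window_view(xp, self.kernel, axis=2)
        cols = windows[:, :, :: self.stride][:, :, :l_out]  # (n, c, l_out, k)
        self._cache = (cols, x.shape, left, xp.shape[2])
        return np.einsum("nclk,ock->nol", cols, self.W, optimize=True) + self.b[None, :, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        cols, x_shape, left, lp = self._cache
        self.dW = np.einsum("nol,nclk->ock", dy, cols, optimize=True)
        self.db = dy.sum(axis=(0, 2))
        dcols = np.einsum("nol,ock->nclk", dy, self.W, optimize=True)
        n, c, length = x_shape
        l_out = dy.shape[2]
        dxp = np.zeros((n, c, lp), dtype=np.float32)
        for i in range(self.kernel):
            dxp[:, :, i : i + self.stride * l_out : self.stride] += dcols[:, :, :, i]
        return dxp[:, :, left : left + length]

    def params(self):
        return [("W", self), ("b", self)]


class _BatchNorm1d:
    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = np.ones(channels, dtype=np.float32)
        self.beta = np.zeros(channels, dtype=np.float32)
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mean, var = self.running_mean, self.running_var
        invstd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None]) * invstd[None, :, None]
        self._cache = (xhat, invstd)
        return self.gamma[None, :, None] * xhat + self.beta[None, :, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, invstd = self._cache
        m = dy.shape[0] * dy.shape[2]
        self.dgamma = (dy * xhat).sum(axis=(0, 2))
        self.dbeta = dy.sum(axis=(0, 2))
        g = self.gamma[None, :, None] * invstd[None, :, None]
        return g * (
            dy
            - self.dbeta[None, :, None] / m
            - xhat * self.dgamma[None, :, None] / m
        )


class _ReLU:
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dy, 0.0)


class _MaxPool1d:
    def __init__(self, size: int = 2):
        self.size = size

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, c, length = x.shape
        l_out = length // self.size
        trimmed = x[:, :, : l_out * self.size].reshape(n, c, l_out, self.size)
        self._arg = trimmed.argmax(axis=3)
        self._in_shape = x.shape
        return trimmed.max(axis=3)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, length = self._in_shape
        l_out = dy.shape[2]
        dx = np.zeros((n, c, l_out, self.size), dtype=np.float32)
        np.put_along_axis(dx, self._arg[..., None], dy[..., None], axis=3)
        out = np.zeros((n, c, length), dtype=np.float32)
        out[:, :, : l_out * self.size] = dx.reshape(n, c, l_out * self.size)
        return out


class _Flatten:
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy.reshape(self._shape)


class _Dense:
    def __init__(self, n_in: int, n_out: int, rng):
        scale = np.sqrt(2.0 / n_in)
        self.W = rng.normal(0.0, scale, size=(n_in, n_out)).astype(np.float32)
        self.b = np.zeros(n_out, dtype=np.float32)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._x = x
        return x @ self.W + self.b

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.dW = self._x.T @ dy
        self.db = dy.sum(axis=0)
        return dy @ self.W.T


class _Dropout:
    def __init__(self, rate: float, rng):
        self.rate = rate
        self.rng = rng

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if not train or self.rate <= 0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(np.float32) / keep
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy if self._mask is None else dy * self._mask


def _trainable_arrays(layers) -> list[tuple[object, str]]:
    out = []
    for layer in layers:
        if isinstance(layer, _Conv1d):
            out += [(layer, "W"), (layer, "b")]
        elif isinstance(layer, _Dense):
            out += [(layer, "W"), (layer, "b")]
        elif isinstance(layer, _BatchNorm1d):
            out += [(layer, "gamma"), (layer, "beta")]
    return out


_GRAD_NAME = {"W": "dW", "b": "db", "gamma": "dgamma", "beta": "dbeta"}


@dataclass
class _TrainingLogRow:
    epoch: int
    train_loss: float
    val_loss: float
    learning_rate: float


class ALineCNN(TransformerMixin, ClassifierMixin, BaseEstimator):
    """A-line CNN classifier / convolutional feature extractor.

    Parameters follow the published training recipe: batch size 30, up to 50
    epochs, Adam with base learning rate 1e-3, first-moment decay 0.9, step
    decay by 0.2 every 5 epochs, early stopping after 5 epochs without
    validation-loss improvement, and inverse-median-frequency class weights.

    ``fit`` accepts A-lines of length 205 (ROI + pad source, padded
    internally) or 210 (already padded).  ``transform`` returns the 100
    penultimate-layer activations (post-ReLU, dropout disabled); ``predict``
    and ``predict_proba`` use the full softmax head.
    """

    def __init__(
        self,
        conv_filters: tuple = (32, 64, 96),
        conv_kernels: tuple = (11, 9, 7),
        conv_stride: int = 2,
        pool_size: int = 2,
        fc_widths: tuple = (100, 100, 3),
        dropout_rate: float = 0.5,
        batch_size: int = 30,
        max_epochs: int = 50,
        patience: int = 5,
        learning_rate: float = 1e-3,
        lr_drop_factor: float = 0.2,
        lr_drop_period: int = 5,
        adam_beta1: float = 0.9,
        adam_beta2: float = 0.999,
        input_scale: float = 65535.0,
        validation_fraction: float = 0.15,
        random_state: int = 0,
    ):
        self.conv_filters = conv_filters
        self.conv_kernels = conv_kernels
        self.conv_stride = conv_stride
        self.pool_size = pool_size
        self.fc_widths = fc_widths
        self.dropout_rate = dropout_rate
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.patience = patience
        self.learning_rate = learning_rate
        self.lr_drop_factor = lr_drop_factor
        self.lr_drop_period = lr_drop_period
        self.adam_beta1 = adam_beta1
        self.adam_beta2 = adam_beta2
        self.input_scale = input_scale
        self.validation_fraction = validation_fraction
        self.random_state = random_state

    # -- construction ------------------------------------------------------

    def _build(self, rng) -> list:
        layers: list = []
        c_in = 1
        length = PADDED_LENGTH
        n_pools = 0
        for i, (c_out, k) in enumerate(zip(self.conv_filters, self.conv_kernels)):
            conv = _Conv1d(c_in, c_out, k, self.conv_stride, rng)
            layers += [conv, _BatchNorm1d(c_out), _ReLU()]
            length = conv.out_length(length)
            c_in = c_out
            if n_pools < 2 and i < len(self.conv_filters) - 1:
                layers.append(_MaxPool1d(self.pool_size))
                length //= self.pool_size
                n_pools += 1
        layers.append(_Flatten())
        n_in = c_in * length
        self._dropout_rng = np.random.default_rng(self.random_state + 1)
        for j, width in enumerate(self.fc_widths):
            layers.append(_Dense(n_in, width, rng))
            if j < len(self.fc_widths) - 1:
                layers += [_ReLU(), _Dropout(self.dropout_rate, self._dropout_rng)]
            n_in = width
        return layers

    @staticmethod
    def _receptive_field(kernels, conv_stride, pool_size, n_pools=2) -> int:
        rf, jump = 1, 1
        specs = []
        for i, k in enumerate(kernels):
            specs.append((k, conv_stride))
            if i < n_pools:
                specs.append((pool_size, pool_size))
        for k, s in specs:
            rf += (k - 1) * jump
            jump *= s
        return rf

    # -- data plumbing -----------------------------------------------------

    def _prepare(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        if X.shape[1] == KEEP_LENGTH:
            X = pad_alines(X)
        if X.shape[1] != PADDED_LENGTH:
            raise ValueError(
                f"expected {KEEP_LENGTH} or {PADDED_LENGTH} samples per A-line, "
                f"got {X.shape[1]}"
            )
        return (X / self.input_scale).astype(np.float32)[:, None, :]

    def _forward(self, x: np.ndarray, train: bool, stop_at: int | None = None) -> np.ndarray:
        layers = self.layers_ if stop_at is None else self.layers_[:stop_at]
        for layer in layers:
            x = layer.forward(x, train)
        return x

    def _loss_and_grad(self, logits: np.ndarray, y: np.ndarray):
        n = logits.shape[0]
        shifted = logits - logits.max(axis=1, keepdims=True)
        logp = shifted - np.log(np.exp(shifted).sum(axis=1, keepdims=True))
        w = self.class_weights_[y].astype(np.float32)
        loss = float(-(w * logp[np.arange(n), y]).sum() / n)
        probs = np.exp(logp)
        grad = probs
        grad[np.arange(n), y] -= 1.0
        grad *= w[:, None] / n
        return loss, grad.astype(np.float32)

    def _eval_loss(self, x: np.ndarray, y: np.ndarray) -> float:
        total, n = 0.0, x.shape[0]
        for i in range(0, n, 512):
            logits = self._forward(x[i : i + 512], train=False)
            loss, _ = self._loss_and_grad(logits, y[i : i + 512])
            total += loss * logits.shape[0]
        return total / n

    # -- estimator API -----------------------------------------------------

    def fit(self, X, y, validation_data: tuple | None = None):
        """Train on labeled A-lines.

        ``validation_data=(X_val, y_val)`` should be a VOI-level split; when
        omitted, a random ``validation_fraction`` of rows is held out (rows,
        not VOIs — fine for unit-scale fixtures, not for real evaluation).
        """
        rng = np.random.default_rng(self.random_state)
        y = np.asarray(y, dtype=int)
        x = self._prepare(X)
        self.classes_ = np.arange(int(self.fc_widths[-1]))
        self.class_weights_ = inverse_median_frequency_weights(
            y, n_classes=len(self.classes_)
        ).astype(np.float32)

        if validation_data is not None:
            xv = self._prepare(validation_data[0])
            yv = np.asarray(validation_data[1], dtype=int)
        else:
            n_val = max(int(round(self.validation_fraction * x.shape[0])), 1)
            perm = rng.permutation(x.shape[0])
            val_idx, train_idx = perm[:n_val], perm[n_val:]
            xv, yv = x[val_idx], y[val_idx]
            x, y = x[train_idx], y[train_idx]

        self.layers_ = self._build(rng)
        arrays = _trainable_arrays(self.layers_)
        m_state = [np.zeros_like(getattr(obj, name)) for obj, name in arrays]
        v_state = [np.zeros_like(getattr(obj, name)) for obj, name in arrays]
        step = 0

        self.history_: list[_TrainingLogRow] = []
        best_val = np.inf
        best_state = None
        stale = 0
        n = x.shape[0]
        for epoch in range(self.max_epochs):
            lr = self.learning_rate * self.lr_drop_factor ** (epoch // self.lr_drop_period)
            order = rng.permutation(n)
            epoch_loss = 0.0
            for i in range(0, n, self.batch_size):
                idx = order[i : i + self.batch_size]
                logits = self._forward(x[idx], train=True)
                loss, grad = self._loss_and_grad(logits, y[idx])
                epoch_loss += loss * idx.size
                for layer in reversed(self.layers_):
                    grad = layer.backward(grad)
                step += 1
                b1, b2 = self.adam_beta1, self.adam_beta2
                for j, (obj, name) in enumerate(arrays):
                    g = getattr(obj, _GRAD_NAME[name])
                    m_state[j] = b1 * m_state[j] + (1 - b1) * g
                    v_state[j] = b2 * v_state[j] + (1 - b2) * g * g
                    mhat = m_state[j] / (1 - b1**step)
                    vhat = v_state[j] / (1 - b2**step)
                    arr = getattr(obj, name)
                    arr -= (lr * mhat / (np.sqrt(vhat) + 1e-8)).astype(np.float32)

            val_loss = self._eval_loss(xv, yv)
            self.history_.append(
                _TrainingLogRow(epoch, epoch_loss / n, val_loss, lr)
            )
            if val_loss < best_val - 1e-6:
                best_val = val_loss
                best_state = copy.deepcopy(self.layers_)
                stale = 0
            else:
                stale += 1
                if stale >= self.patience:
                    break
        if best_state is not None:
            self.layers_ = best_state
        self.n_epochs_run_ = len(self.history_)
        self.best_val_loss_ = best_val
        self.receptive_field_ = self._receptive_field(
            self.conv_kernels, self.conv_stride, self.pool_size
        )
        return self

    def _check_fitted(self):
        if not hasattr(self, "layers_"):
            raise RuntimeError("ALineCNN is not fitted")

    def predict_proba(self, X) -> np.ndarray:
        self._check_fitted()
        x = self._prepare(X)
        out = []
        for i in range(0, x.shape[0], 1024):
            logits = self._forward(x[i : i + 1024], train=False)
            shifted = logits - logits.max(axis=1, keepdims=True)
            e = np.exp(shifted)
            out.append(e / e.sum(axis=1, keepdims=True))
        return np.concatenate(out).astype(float)

    def predict(self, X) -> np.ndarray:
        return np.argmax(self.predict_proba(X), axis=1)

    def transform(self, X) -> np.ndarray:
        """100 convolutional features: penultimate FC activations post-ReLU,
        dropout disabled, batch-norm statistics frozen."""
        self._check_fitted()
        x = self._prepare(X)
        # stop after the ReLU that follows the second 100-unit dense layer
        stop = len(self.layers_) - 2  # drop final Dense; its preceding Dropout is idle
        out = []
        for i in range(0, x.shape[0], 1024):
            h = x[i : i + 1024]
            for layer in self.layers_[:stop]:
                if isinstance(layer, _Dropout):
                    continue
                h = layer.forward(h, train=False)
            out.append(h)
        return np.concatenate(out).astype(float)

    def score(self, X, y) -> float:
        return float(np.mean(self.predict(X) == np.asarray(y)))

    def manifest(self) -> dict:
        """JSON-serializable description of the trained network."""
        self._check_fitted()
        return {
            "conv_filters": list(self.conv_filters),
            "conv_kernels": list(self.conv_kernels),
            "conv_stride": self.conv_stride,
            "pool_size": self.pool_size,
            "fc_widths": list(self.fc_widths),
            "dropout_rate": self.dropout_rate,
            "receptive_field_px": int(self.receptive_field_),
            "class_weights": [float(w) for w in self.class_weights_],
            "epochs_run": self.n_epochs_run_,
            "best_val_loss": float(self.best_val_loss_),
            "random_state": self.random_state,
        }
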