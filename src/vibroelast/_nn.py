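"""Minimal feed-forward neural-net engine (numpy, NHWC layout).

Implements exactly the layers the classifier needs — valid-mode 2-D
convolution, ReLU, batch normalization, 2×2 max pooling, dense layers,
inverted dropout, softmax cross-entropy — with hand-written backprop and an
Adam optimizer. Layers expose ``forward(x, training)`` / ``backward(dout)``
and hold parameters and their gradients in name-keyed dicts so the
optimizer can freeze arbitrary subsets (needed for the fine-tuning
protocol, where the conv block must stay bit-identical).
"""

from __future__ import annotations

import numpy as np

#: working precision of the engine; single precision halves memory traffic
#: and is ample for a classifier of this size
DTYPE = np.float32


class Layer:
    """Base layer; parameter-free unless overridden."""

    name = "layer"

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def params(self) -> dict[str, np.ndarray]:
        return {}

    def grads(self) -> dict[str, np.ndarray]:
        return {}

    def buffers(self) -> dict[str, np.ndarray]:
        return {}


class Conv2D(Layer):
    """Valid-mode convolution, stride 1, square kernel, NHWC tensors."""

    def __init__(self, in_channels: int, out_channels: int, kernel: int,
                 rng: np.random.Generator, name: str = "conv"):
        self.name = name
        self.kernel = kernel
        fan_in = kernel * kernel * in_channels
        self.W = (rng.standard_normal(
            (kernel, kernel, in_channels, out_channels)
        ) * np.sqrt(2.0 / fan_in)).astype(DTYPE)
        self.b = np.zeros(out_channels, dtype=DTYPE)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._x: np.ndarray | None = None

    def forward(self, x, training=False):
        kh = kw = self.kernel
        n, h, w, c = x.shape
        if h < kh or w < kw:
            raise ValueError(
                f"input spatial size {h}×{w} smaller than {kh}×{kw} kernel"
            )
        self._x = x
        oh, ow = h - kh + 1, w - kw + 1
        cols = np.lib.stride_tricks.sliding_window_view(x, (kh, kw), axis=(1, 2))
        # cols: (n, oh, ow, c, kh, kw) -> (n*oh*ow, kh*kw*c)
        cols = cols.transpose(0, 1, 2, 4, 5, 3).reshape(n * oh * ow, kh * kw * c)
        self._cols = cols
        out = cols @ self.W.reshape(kh * kw * c, -1) + self.b
        return out.reshape(n, oh, ow, -1)

    def backward(self, dout):
        x = self._x
        kh = kw = self.kernel
        n, h, w, c = x.shape
        oh, ow, f = dout.shape[1], dout.shape[2], dout.shape[3]
        dflat = dout.reshape(n * oh * ow, f)
        dW = (self._cols.T @ dflat).reshape(kh, kw, c, f)
        self.dW = dW
        self.db = dflat.sum(axis=0)
        dx = np.zeros_like(x)
        for i in range(kh):
            for j in range(kw):
                dx[:, i:i + oh, j:j + ow, :] += dout @ self.W[i, j].T
        return dx

    def params(self):
        return {f"{self.name}.W": self.W, f"{self.name}.b": self.b}

    def grads(self):
        return {f"{self.name}.W": self.dW, f"{self.name}.b": self.db}


class ReLU(Layer):
    def __init__(self, name: str = "relu"):
        self.name = name

    def forward(self, x, training=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class BatchNorm(Layer):
    """Per-channel batch normalization over the (N, H, W) axes.

    In training mode uses batch statistics and updates running estimates;
    in inference mode uses the running estimates, making the output
    independent of batch composition. ``frozen`` forces inference-mode
    statistics even during training (fine-tuning contract).
    """

    def __init__(self, channels: int, momentum: float = 0.99, eps: float = 1e-3,
                 name: str = "bn"):
        self.name = name
        self.momentum = momentum
        self.eps = eps
        self.gamma = np.ones(channels, dtype=DTYPE)
        self.beta = np.zeros(channels, dtype=DTYPE)
        self.running_mean = np.zeros(channels, dtype=DTYPE)
        self.running_var = np.ones(channels, dtype=DTYPE)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.frozen = False

    def forward(self, x, training=False):
        axes = tuple(range(x.ndim - 1))
        if training and not self.frozen:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = (self.momentum * self.running_mean
                                 + (1 - self.momentum) * mean).astype(DTYPE)
            self.running_var = (self.momentum * self.running_var
                                + (1 - self.momentum) * var).astype(DTYPE)
        else:
            mean = self.running_mean
            var = self.running_var
        self._axes = axes
        self._m = x.size // x.shape[-1]
        self._inv_std = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mean) * self._inv_std
        self._batch_stats = training and not self.frozen
        return self.gamma * self._xhat + self.beta

    def backward(self, dout):
        axes = self._axes
        self.dgamma = (dout * self._xhat).sum(axis=axes)
        self.dbeta = dout.sum(axis=axes)
        if not self._batch_stats:
            return dout * self.gamma * self._inv_std
        m = self._m
        dxhat = dout * self.gamma
        dx = (self._inv_std / m) * (
            m * dxhat
            - dxhat.sum(axis=axes)
            - self._xhat * (dxhat * self._xhat).sum(axis=axes)
        )
        return dx

    def params(self):
        return {f"{self.name}.gamma": self.gamma, f"{self.name}.beta": self.beta}

    def grads(self):
        return {f"{self.name}.gamma": self.dgamma, f"{self.name}.beta": self.dbeta}

    def buffers(self):
        return {f"{self.name}.running_mean": self.running_mean,
                f"{self.name}.running_var": self.running_var}


class MaxPool2(Layer):
    """2×2 max pooling, stride 2; odd trailing rows/columns are dropped."""

    def __init__(self, name: str = "pool"):
        self.name = name

    def forward(self, x, training=False):
        n, h, w, c = x.shape
        oh, ow = h // 2, w // 2
        self._in_shape = x.shape
        xr = x[:, :2 * oh, :2 * ow, :].reshape(n, oh, 2, ow, 2, c)
        xr = xr.transpose(0, 1, 3, 2, 4, 5).reshape(n, oh, ow, 4, c)
        self._argmax = xr.argmax(axis=3)
        out = np.take_along_axis(xr, self._argmax[:, :, :, None, :], axis=3)
        return out[:, :, :, 0, :]

    def backward(self, dout):
        n, h, w, c = self._in_shape
        oh, ow = h // 2, w // 2
        dxr = np.zeros((n, oh, ow, 4, c), dtype=dout.dtype)
        np.put_along_axis(dxr, self._argmax[:, :, :, None, :],
                          dout[:, :, :, None, :], axis=3)
        dxr = dxr.reshape(n, oh, ow, 2, 2, c).transpose(0, 1, 3, 2, 4, 5)
        dx = np.zeros(self._in_shape, dtype=dout.dtype)
        dx[:, :2 * oh, :2 * ow, :] = dxr.reshape(n, 2 * oh, 2 * ow, c)
        return dx


class Flatten(Layer):
    def __init__(self, name: str = "flatten"):
        self.name = name

    def forward(self, x, training=False):
        self._in_shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._in_shape)


class Dense(Layer):
    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator, name: str = "dense"):
        self.name = name
        self.W = (rng.standard_normal((in_features, out_features))
                  * np.sqrt(2.0 / in_features)).astype(DTYPE)
        self.b = np.zeros(out_features, dtype=DTYPE)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x, training=False):
        self._x = x
        return x @ self.W + self.b

    def backward(self, dout):
        self.dW = self._x.T @ dout
        self.db = dout.sum(axis=0)
        return dout @ self.W.T

    def params(self):
        return {f"{self.name}.W": self.W, f"{self.name}.b": self.b}

    def grads(self):
        return {f"{self.name}.W": self.dW, f"{self.name}.b": self.db}


class Dropout(Layer):
    """Inverted dropout; identity outside training mode."""

    def __init__(self, rate: float, name: str = "dropout"):
        self.name = name
        self.rate = rate
        self.rng = np.random.default_rng(0)

    def forward(self, x, training=False):
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = ((self.rng.uniform(size=x.shape) < keep) / keep).astype(DTYPE)
        return x * self._mask

    def backward(self, dout):
        if self._mask is None:
            return dout
        return dout * self._mask


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy(probs: np.ndarray, labels: np.ndarray) -> float:
    """Mean negative log-likelihood; for a two-class softmax this equals
    binary cross-entropy on the positive-class probability."""
    p = np.clip(probs[np.arange(len(labels)), labels], 1e-12, None)
    return float(-np.mean(np.log(p)))


def cross_entropy_grad(probs: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Gradient of mean cross-entropy w.r.t. the logits of a softmax."""
    g = probs.copy()
    g[np.arange(len(labels)), labels] -= 1.0
    return g / len(labels)


try:  # fused single-pass update: Adam is memory-bound at this size
    from numba import njit

    @njit(cache=True, fastmath=True)
    def _adam_update(p, g, m, v, b1, b2, lr, eps, bias1, bias2):
        scale = lr / bias1
        eps2 = eps * np.sqrt(bias2)
        sq_bias2 = np.sqrt(bias2)
        for i in range(p.size):
            m[i] = b1 * m[i] + (1.0 - b1) * g[i]
            v[i] = b2 * v[i] + (1.0 - b2) * g[i] * g[i]
            p[i] -= scale * m[i] * sq_bias2 / (np.sqrt(v[i]) + eps2)

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False


class Adam:
    """Adam with a name-keyed parameter dict and optional freezing."""

    def __init__(self, params: dict[str, np.ndarray], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8,
                 trainable: set[str] | None = None):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.trainable = set(params) if trainable is None else set(trainable)
        unknown = self.trainable - set(params)
        if unknown:
            raise KeyError(f"trainable names not in params: {sorted(unknown)}")
        self.m = {k: np.zeros_like(params[k]) for k in self.trainable}
        self.v = {k: np.zeros_like(params[k]) for k in self.trainable}
        self.t = 0

    def step(self, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = DTYPE(1 - b1 ** self.t)
        bias2 = DTYPE(1 - b2 ** self.t)
        for k in self.trainable:
            g = grads[k]
            m, v = self.m[k], self.v[k]
            p = self.params[k]
            if _HAVE_NUMBA:
                _adam_update(
                    p.reshape(-1), np.ascontiguousarray(g).reshape(-1),
                    m.reshape(-1), v.reshape(-1),
                    DTYPE(b1), DTYPE(b2), DTYPE(self.lr), DTYPE(self.eps),
                    bias1, bias2,
                )
            else:  # pragma: no cover
                m *= DTYPE(b1)
                m += DTYPE(1 - b1) * g
                v *= DTYPE(b2)
                v += DTYPE(1 - b2) * (g * g)
                update = m / bias1
                update /= np.sqrt(v / bias2) + DTYPE(self.eps)
                update *= DTYPE(self.lr)
                p -= update
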