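"""A compact NumPy convolutional network with explicit backpropagation.

The pathway images this package classifies are tiny (hundreds of rows, a
handful of columns), so a vectorized im2col implementation on one CPU is
entirely adequate.  Writing the network explicitly also gives exact input
gradients in eval mode, which the gradient-SHAP attributor consumes.

Layout convention: NCHW.  All layers cache what their backward pass needs
from the most recent forward pass; ``backward`` must follow a ``forward``
with the same mode.
"""

from __future__ import annotations

import copy

import numpy as np


class Layer:
    params: list[str] = []  # attribute names of learnable arrays

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def param_pairs(self):
        for name in self.params:
            yield self, name, getattr(self, name), getattr(self, "d_" + name)


class Conv2D(Layer):
    """3x3-style same-padding convolution, stride 1, via im2col."""

    params = ["w", "b"]

    def __init__(self, c_in: int, c_out: int, kh: int, kw: int, rng: np.random.Generator):
        self.kh, self.kw = kh, kw
        fan_in = c_in * kh * kw
        self.w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(c_out, c_in, kh, kw))
        self.b = np.zeros(c_out)
        self.d_w = np.zeros_like(self.w)
        self.d_b = np.zeros_like(self.b)

    def _im2col(self, xp: np.ndarray, h: int, w: int) -> np.ndarray:
        n, c = xp.shape[:2]
        cols = np.empty((n, c, self.kh, self.kw, h, w), dtype=xp.dtype)
        for i in range(self.kh):
            for j in range(self.kw):
                cols[:, :, i, j] = xp[:, :, i : i + h, j : j + w]
        return cols.reshape(n, c * self.kh * self.kw, h * w)

    def forward(self, x, train):
        n, c, h, w = x.shape
        ph, pw = self.kh // 2, self.kw // 2
        xp = np.pad(x, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
        cols = self._im2col(xp, h, w)
        self._cols, self._xshape = cols, x.shape
        wm = self.w.reshape(self.w.shape[0], -1)
        out = np.matmul(wm[None], cols)  # (n, c_out, h*w)
        out += self.b[None, :, None]
        return out.reshape(n, -1, h, w)

    def backward(self, dout):
        n, c_out, h, w = dout.shape
        dflat = dout.reshape(n, c_out, h * w)
        wm = self.w.reshape(c_out, -1)
        self.d_w[...] = np.einsum("nof,nkf->ok", dflat, self._cols).reshape(self.w.shape)
        self.d_b[...] = dflat.sum(axis=(0, 2))
        dcols = np.matmul(wm.T[None], dflat)  # (n, k, h*w)
        _, c, hh, ww = self._xshape
        ph, pw = self.kh // 2, self.kw // 2
        dxp = np.zeros((n, c, hh + 2 * ph, ww + 2 * pw))
        dcols = dcols.reshape(n, c, self.kh, self.kw, h, w)
        for i in range(self.kh):
            for j in range(self.kw):
                dxp[:, :, i : i + h, j : j + w] += dcols[:, :, i, j]
        return dxp[:, :, ph : ph + hh, pw : pw + ww]


class BatchNorm(Layer):
    """Batch normalization over (N, H, W) per channel, or N per feature."""

    params = ["gamma", "beta"]

    def __init__(self, n_features: int, spatial: bool, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = np.ones(n_features)
        self.beta = np.zeros(n_features)
        self.d_gamma = np.zeros(n_features)
        self.d_beta = np.zeros(n_features)
        self.running_mean = np.zeros(n_features)
        self.running_var = np.ones(n_features)
        self.spatial = spatial
        self.momentum = momentum
        self.eps = eps

    def _shape(self, v):
        return v.reshape(1, -1, 1, 1) if self.spatial else v.reshape(1, -1)

    def forward(self, x, train):
        axes = (0, 2, 3) if self.spatial else (0,)
        self._train = train
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        self._istd = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - self._shape(mean)) * self._shape(self._istd)
        self._m = x.size // x.shape[1]
        return self._shape(self.gamma) * self._xhat + self._shape(self.beta)

    def backward(self, dout):
        axes = (0, 2, 3) if self.spatial else (0,)
        self.d_gamma[...] = (dout * self._xhat).sum(axis=axes)
        self.d_beta[...] = dout.sum(axis=axes)
        g = self._shape(self.gamma * self._istd)
        if not self._train:
            return dout * g
        m = self._m
        dxhat = dout * self._shape(self.gamma)
        t1 = dxhat - self._shape(dxhat.sum(axis=axes) / m)
        t2 = self._xhat * self._shape((dxhat * self._xhat).sum(axis=axes) / m)
        return self._shape(self._istd) * (t1 - t2)


class ReLU(Layer):
    def forward(self, x, train):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class MaxPool(Layer):
    """Non-overlapping max pooling; remainders are truncated (floor)."""

    def __init__(self, ph: int, pw: int):
        self.ph, self.pw = ph, pw

    def forward(self, x, train):
        n, c, h, w = x.shape
        h2, w2 = h // self.ph, w // self.pw
        if h2 < 1 or w2 < 1:
            raise ValueError(f"pool ({self.ph},{self.pw}) collapses input {h}x{w} below 1")
        self._xshape = x.shape
        if self.ph == 1 and self.pw == 1:
            return x
        xc = x[:, :, : h2 * self.ph, : w2 * self.pw]
        if self.ph == 1:
            # contiguous windows along the last axis: no transpose copy needed
            win = xc.reshape(n, c, h2, w2, self.pw)
        else:
            win = xc.reshape(n, c, h2, self.ph, w2, self.pw).transpose(0, 1, 2, 4, 3, 5)
            win = win.reshape(n, c, h2, w2, self.ph * self.pw)
        self._arg = win.argmax(axis=-1)
        return np.take_along_axis(win, self._arg[..., None], axis=-1)[..., 0]

    def backward(self, dout):
        n, c, h, w = self._xshape
        h2, w2 = h // self.ph, w // self.pw
        if self.ph == 1 and self.pw == 1:
            return dout
        dwin = np.zeros((n, c, h2, w2, self.ph * self.pw))
        np.put_along_axis(dwin, self._arg[..., None], dout[..., None], axis=-1)
        dx = np.zeros(self._xshape)
        if self.ph == 1:
            dx[:, :, :, : w2 * self.pw] = dwin.reshape(n, c, h2, w2 * self.pw)
        else:
            dwin = dwin.reshape(n, c, h2, w2, self.ph, self.pw).transpose(0, 1, 2, 4, 3, 5)
            dx[:, :, : h2 * self.ph, : w2 * self.pw] = dwin.reshape(
                n, c, h2 * self.ph, w2 * self.pw)
        return dx


class Flatten(Layer):
    def forward(self, x, train):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


class Dense(Layer):
    params = ["w", "b"]

    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        self.w = rng.normal(0.0, np.sqrt(2.0 / d_in), size=(d_in, d_out))
        self.b = np.zeros(d_out)
        self.d_w = np.zeros_like(self.w)
        self.d_b = np.zeros_like(self.b)

    def forward(self, x, train):
        self._x = x
        return x @ self.w + self.b

    def backward(self, dout):
        self.d_w[...] = self._x.T @ dout
        self.d_b[...] = dout.sum(axis=0)
        return dout @ self.w.T


class Dropout(Layer):
    """Inverted dropout; identity in eval mode."""

    def __init__(self, rate: float, rng: np.random.Generator):
        self.rate = rate
        self.rng = rng

    def forward(self, x, train):
        if not train or self.rate == 0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.uniform(size=x.shape) < keep) / keep
        return x * self._mask

    def backward(self, dout):
        return dout if self._mask is None else dout * self._mask


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class Network:
    """A sequential stack with softmax head and Adam training support."""

    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train)
        return x  # logits

    def backward(self, dlogits: np.ndarray) -> np.ndarray:
        d = dlogits
        for layer in reversed(self.layers):
            d = layer.backward(d)
        return d

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return softmax(self.forward(x, train=False))

    def loss_and_grad(self, x: np.ndarray, y: np.ndarray, train: bool = True) -> float:
        """Cross-entropy loss; leaves parameter gradients populated."""
        logits = self.forward(x, train=train)
        p = softmax(logits)
        n = x.shape[0]
        loss = -np.mean(np.log(np.clip(p[np.arange(n), y], 1e-12, None)))
        dlogits = p.copy()
        dlogits[np.arange(n), y] -= 1.0
        self.backward(dlogits / n)
        return float(loss)

    def input_gradient(self, x: np.ndarray, target_class: int) -> np.ndarray:
        """d p_target / d x per sample, in eval mode (deterministic)."""
        logits = self.forward(x, train=False)
        p = softmax(logits)
        n = x.shape[0]
        # Jacobian row of softmax at the target: p_t * (e_t - p).
        dlogits = -p * p[:, [target_class]]
        dlogits[:, target_class] += p[:, target_class]
        return self.backward(dlogits)

    def get_weights(self) -> list:
        return [copy.deepcopy([getattr(l, n) for n in l.params]) for l in self.layers] + [
            [copy.deepcopy(getattr(l, "running_mean", None)),
             copy.deepcopy(getattr(l, "running_var", None))]
            for l in self.layers
        ]

    def set_weights(self, weights: list) -> None:
        k = len(self.layers)
        for layer, vals in zip(self.layers, weights[:k]):
            for name, v in zip(layer.params, vals):
                getattr(layer, name)[...] = v
        for layer, (rm, rv) in zip(self.layers, weights[k:]):
            if rm is not None:
                layer.running_mean[...] = rm
                layer.running_var[...] = rv


class Adam:
    """Adam with optional decoupled weight decay (applied to weight
    matrices only, not biases or batch-norm parameters)."""

    def __init__(self, net: Network, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.net = net
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m: dict[tuple[int, str], np.ndarray] = {}
        self.v: dict[tuple[int, str], np.ndarray] = {}

    def step(self) -> None:
        self.t += 1
        for i, layer in enumerate(self.net.layers):
            for _, name, p, g in layer.param_pairs():
                key = (i, name)
                if key not in self.m:
                    self.m[key] = np.zeros_like(p)
                    self.v[key] = np.zeros_like(p)
                self.m[key] = self.beta1 * self.m[key] + (1 - self.beta1) * g
                self.v[key] = self.beta2 * self.v[key] + (1 - self.beta2) * g * g
                mhat = self.m[key] / (1 - self.beta1**self.t)
                vhat = self.v[key] / (1 - self.beta2**self.t)
                p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
                if self.weight_decay and name == "w":
                    p -= self.lr * self.weight_decay * p
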