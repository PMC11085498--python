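"""Minimal NCHW convolutional-network layers with hand-written backprop.

Everything the two-stream classifier needs — 2-D convolution (im2col),
batch normalization, ReLU, max pooling, dense layers, dropout, global
average pooling, the ECA 1-D channel convolution, a fused
softmax/cross-entropy head, and an AdamW optimizer with a
reduce-on-plateau schedule.  Pure numpy; deterministic given the
generators handed in at construction.

Tensor layout is (N, C, H, W).  Every layer implements ``forward(x,
train)`` caching what its ``backward(dy)`` needs; parameters live in
``self.params`` with matching ``self.grads``, and ``decay`` marks which
entries receive decoupled weight decay.
"""

from __future__ import annotations

import numpy as np


class Module:
    """Base layer: parameter registry plus recursive child traversal."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}
        self.buffers: dict[str, np.ndarray] = {}
        self.decay: set[str] = set()

    def add_param(self, name: str, value: np.ndarray, decay: bool = True) -> None:
        self.params[name] = value
        self.grads[name] = np.zeros_like(value)
        if decay:
            self.decay.add(name)

    def children(self):  # noqa: D102 - overridden by containers
        return []

    def modules(self, prefix: str = ""):
        """Yield (path, module) for self and all descendants."""
        yield prefix, self
        for name, child in self.children():
            yield from child.modules(f"{prefix}{name}.")

    def zero_grads(self) -> None:
        for _, m in self.modules():
            for k in m.grads:
                m.grads[k][...] = 0.0

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {}
        for path, m in self.modules():
            for k, v in m.params.items():
                state[f"{path}{k}"] = v.copy()
            for k, v in m.buffers.items():
                state[f"{path}buf.{k}"] = v.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for path, m in self.modules():
            for k in m.params:
                m.params[k][...] = state[f"{path}{k}"]
            for k in m.buffers:
                m.buffers[k][...] = state[f"{path}buf.{k}"]

    def n_parameters(self) -> int:
        return sum(v.size for _, m in self.modules() for v in m.params.values())

    def to_dtype(self, dtype) -> "Module":
        """Convert all parameters, gradients and buffers (e.g. to float32)."""
        for _, m in self.modules():
            for k in m.params:
                m.params[k] = m.params[k].astype(dtype)
                m.grads[k] = np.zeros_like(m.params[k])
            for k in m.buffers:
                m.buffers[k] = m.buffers[k].astype(dtype)
        return self


def _pair(v) -> tuple[int, int]:
    return (v, v) if isinstance(v, int) else tuple(v)


def _same_pad(size: int, k: int, s: int) -> tuple[int, int]:
    """Asymmetric 'same' padding so output size = ceil(size/s)."""
    out = -(-size // s)
    total = max((out - 1) * s + k - size, 0)
    return total // 2, total - total // 2


class Conv2d(Module):
    """2-D convolution via im2col; He-initialized, optional bias."""

    def __init__(self, in_ch, out_ch, kernel, stride=1, rng=None, bias=True):
        super().__init__()
        self.in_ch, self.out_ch = in_ch, out_ch
        self.kh, self.kw = _pair(kernel)
        self.sh, self.sw = _pair(stride)
        rng = rng or np.random.default_rng(0)
        fan_in = in_ch * self.kh * self.kw
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(out_ch, fan_in))
        self.add_param("w", w, decay=True)
        self.use_bias = bias
        if bias:
            self.add_param("b", np.zeros(out_ch), decay=False)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        x = x.astype(self.params["w"].dtype, copy=False)
        n, c, h, w = x.shape
        pt, pb = _same_pad(h, self.kh, self.sh)
        pl, pr = _same_pad(w, self.kw, self.sw)
        xp = np.pad(x, ((0, 0), (0, 0), (pt, pb), (pl, pr)))
        oh = (xp.shape[2] - self.kh) // self.sh + 1
        ow = (xp.shape[3] - self.kw) // self.sw + 1
        cols = np.empty((n, c, self.kh, self.kw, oh, ow), dtype=x.dtype)
        for i in range(self.kh):
            for j in range(self.kw):
                cols[:, :, i, j] = xp[
                    :, :, i : i + self.sh * oh : self.sh, j : j + self.sw * ow : self.sw
                ]
        cols = cols.reshape(n, c * self.kh * self.kw, oh * ow)
        y = np.matmul(self.params["w"][None], cols)
        if self.use_bias:
            y += self.params["b"][None, :, None]
        self._cache = (xp.shape, (pt, pl, h, w), cols, oh, ow)
        return y.reshape(n, self.out_ch, oh, ow)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xp_shape, (pt, pl, h, w), cols, oh, ow = self._cache
        n = dy.shape[0]
        dyf = dy.astype(self.params["w"].dtype, copy=False).reshape(n, self.out_ch, oh * ow)
        self.grads["w"] += np.matmul(dyf, cols.transpose(0, 2, 1)).sum(axis=0)
        if self.use_bias:
            self.grads["b"] += dyf.sum(axis=(0, 2))
        dcols = np.matmul(self.params["w"].T[None], dyf)
        dcols = dcols.reshape(n, self.in_ch, self.kh, self.kw, oh, ow)
        dxp = np.zeros(xp_shape, dtype=dcols.dtype)
        for i in range(self.kh):
            for j in range(self.kw):
                dxp[
                    :, :, i : i + self.sh * oh : self.sh, j : j + self.sw * ow : self.sw
                ] += dcols[:, :, i, j]
        self._cache = None  # release the im2col buffer promptly
        return dxp[:, :, pt : pt + h, pl : pl + w]


class BatchNorm2d(Module):
    """Per-channel batch normalization with running statistics."""

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5):
        super().__init__()
        self.momentum, self.eps = momentum, eps
        self.add_param("gamma", np.ones(channels), decay=False)
        self.add_param("beta", np.zeros(channels), decay=False)
        self.buffers["running_mean"] = np.zeros(channels)
        self.buffers["running_var"] = np.ones(channels)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            m = self.momentum
            self.buffers["running_mean"][...] = m * self.buffers["running_mean"] + (1 - m) * mean
            self.buffers["running_var"][...] = m * self.buffers["running_var"] + (1 - m) * var
        else:
            mean = self.buffers["running_mean"]
            var = self.buffers["running_var"]
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
        self._cache = (xhat, inv, train)
        return self.params["gamma"][None, :, None, None] * xhat + self.params["beta"][None, :, None, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv, train = self._cache
        self.grads["gamma"] += (dy * xhat).sum(axis=(0, 2, 3))
        self.grads["beta"] += dy.sum(axis=(0, 2, 3))
        g = self.params["gamma"][None, :, None, None]
        dxhat = dy * g
        if not train:
            return dxhat * inv[None, :, None, None]
        n = dy.shape[0] * dy.shape[2] * dy.shape[3]
        s1 = dxhat.sum(axis=(0, 2, 3), keepdims=True)
        s2 = (dxhat * xhat).sum(axis=(0, 2, 3), keepdims=True)
        return (inv[None, :, None, None] / n) * (n * dxhat - s1 - xhat * s2)


class ReLU(Module):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class MaxPool2d(Module):
    """Max pooling with 'same'-style padding (pad value -inf)."""

    def __init__(self, kernel, stride):
        super().__init__()
        self.kh, self.kw = _pair(kernel)
        self.sh, self.sw = _pair(stride)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, c, h, w = x.shape
        pt, pb = _same_pad(h, self.kh, self.sh)
        pl, pr = _same_pad(w, self.kw, self.sw)
        xp = np.pad(x, ((0, 0), (0, 0), (pt, pb), (pl, pr)), constant_values=-np.inf)
        oh = (xp.shape[2] - self.kh) // self.sh + 1
        ow = (xp.shape[3] - self.kw) // self.sw + 1
        stack = np.empty((n, c, self.kh * self.kw, oh, ow), dtype=x.dtype)
        for i in range(self.kh):
            for j in range(self.kw):
                stack[:, :, i * self.kw + j] = xp[
                    :, :, i : i + self.sh * oh : self.sh, j : j + self.sw * ow : self.sw
                ]
        arg = stack.argmax(axis=2)
        y = np.take_along_axis(stack, arg[:, :, None], axis=2)[:, :, 0]
        self._cache = (xp.shape, (pt, pl), arg, oh, ow, (h, w))
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xp_shape, (pt, pl), arg, oh, ow, (h, w) = self._cache
        dxp = np.zeros(xp_shape, dtype=dy.dtype)
        for i in range(self.kh):
            for j in range(self.kw):
                mask = arg == (i * self.kw + j)
                dxp[
                    :, :, i : i + self.sh * oh : self.sh, j : j + self.sw * ow : self.sw
                ] += dy * mask
        return dxp[:, :, pt : pt + h, pl : pl + w]


class GlobalAvgPool(Module):
    """(N, C, H, W) -> (N, C) channel means."""

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        return np.broadcast_to(dy[:, :, None, None], self._shape) / (h * w)


class Dense(Module):
    def __init__(self, n_in: int, n_out: int, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.add_param("w", rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_in, n_out)), decay=True)
        self.add_param("b", np.zeros(n_out), decay=False)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._x = x = x.astype(self.params["w"].dtype, copy=False)
        return x @ self.params["w"] + self.params["b"]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dy = dy.astype(self.params["w"].dtype, copy=False)
        self.grads["w"] += self._x.T @ dy
        self.grads["b"] += dy.sum(axis=0)
        return dy @ self.params["w"].T


class Dropout(Module):
    """Inverted dropout; identity at inference."""

    def __init__(self, rate: float, rng: np.random.Generator):
        super().__init__()
        if not 0 <= rate < 1:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate, self.rng = rate, rng

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if not train or self.rate == 0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy if self._mask is None else dy * self._mask


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class EcaConv1d(Module):
    """Shared 1-D convolution across the channel axis of a pooled vector.

    Input (N, C); kernel length k with symmetric zero padding (k-1)/2 and
    stride 1, followed by a sigmoid.  ``forward`` returns the attended
    vector; the weights are exposed through :meth:`attention_weights`.
    """

    def __init__(self, k: int, rng=None, weights: np.ndarray | None = None):
        super().__init__()
        if k < 1 or k % 2 == 0:
            raise ValueError("ECA kernel length must be odd and >= 1")
        self.k = k
        if weights is None:
            rng = rng or np.random.default_rng(0)
            weights = rng.normal(0.0, 1.0 / np.sqrt(k), size=k)
        self.add_param("w", np.asarray(weights, dtype=float).copy(), decay=True)

    def _conv(self, pooled: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        pooled = pooled.astype(self.params["w"].dtype, copy=False)
        n, c = pooled.shape
        p = (self.k - 1) // 2
        padded = np.pad(pooled, ((0, 0), (p, p)))
        mat = np.empty((n, c, self.k), dtype=pooled.dtype)
        for j in range(self.k):
            mat[:, :, j] = padded[:, j : j + c]
        return mat @ self.params["w"], mat

    def forward(self, pooled: np.ndarray, train: bool = False) -> np.ndarray:
        z, mat = self._conv(pooled)
        omega = sigmoid(z)
        self._cache = (pooled, mat, omega)
        return omega * pooled

    def attention_weights(self, pooled: np.ndarray) -> np.ndarray:
        z, _ = self._conv(np.atleast_2d(pooled))
        return sigmoid(z)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        pooled, mat, omega = self._cache
        n, c = pooled.shape
        p = (self.k - 1) // 2
        dz = (dy * pooled * omega * (1.0 - omega)).astype(self.params["w"].dtype, copy=False)
        self.grads["w"] += np.einsum("nc,nck->k", dz, mat)
        dpadded = np.zeros((n, c + 2 * p), dtype=dz.dtype)
        for j in range(self.k):
            dpadded[:, j : j + c] += dz * self.params["w"][j]
        return dy * omega + dpadded[:, p : p + c]


class SoftmaxCrossEntropy:
    """Fused softmax + mean cross-entropy with an eps floor inside the log."""

    def __init__(self, eps: float = 1e-12):
        self.eps = eps

    def probs(self, logits: np.ndarray) -> np.ndarray:
        z = logits - logits.max(axis=1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=1, keepdims=True)

    def forward(self, logits: np.ndarray, y_idx: np.ndarray) -> tuple[float, np.ndarray]:
        p = self.probs(logits)
        n = logits.shape[0]
        loss = -np.log(np.maximum(p[np.arange(n), y_idx], self.eps)).mean()
        self._cache = (p, y_idx)
        return float(loss), p

    def backward(self) -> np.ndarray:
        p, y_idx = self._cache
        n = p.shape[0]
        g = p.copy()
        g[np.arange(n), y_idx] -= 1.0
        return g / n


class ResidualBlock(Module):
    """y = relu(F(x) + shortcut(x)) with F = conv-bn-relu-conv-bn.

    The shortcut is the identity unless the shape changes, in which case a
    strided 1x1 projection convolution (plus batch norm) matches it.  The
    additive shortcut keeps the block's input-output Jacobian at
    (dF/dx + I), so gradients reach shallow layers even when the residual
    path's gradient vanishes.
    """

    def __init__(self, in_ch: int, out_ch: int, stride=1, rng=None):
        super().__init__()
        sh, sw = _pair(stride)
        self.projection = (sh != 1 or sw != 1 or in_ch != out_ch)
        self.conv1 = Conv2d(in_ch, out_ch, 3, (sh, sw), rng, bias=False)
        self.bn1 = BatchNorm2d(out_ch)
        self.relu1 = ReLU()
        self.conv2 = Conv2d(out_ch, out_ch, 3, 1, rng, bias=False)
        self.bn2 = BatchNorm2d(out_ch)
        self.relu_out = ReLU()
        if self.projection:
            self.proj = Conv2d(in_ch, out_ch, 1, (sh, sw), rng, bias=False)
            self.proj_bn = BatchNorm2d(out_ch)

    def children(self):
        names = ["conv1", "bn1", "relu1", "conv2", "bn2", "relu_out"]
        if self.projection:
            names += ["proj", "proj_bn"]
        return [(n, getattr(self, n)) for n in names]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        f = self.bn1.forward(self.conv1.forward(x, train), train)
        f = self.relu1.forward(f, train)
        f = self.bn2.forward(self.conv2.forward(f, train), train)
        s = self.proj_bn.forward(self.proj.forward(x, train), train) if self.projection else x
        return self.relu_out.forward(f + s, train)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        d = self.relu_out.backward(dy)
        df = self.conv1.backward(
            self.bn1.backward(self.relu1.backward(self.conv2.backward(self.bn2.backward(d))))
        )
        ds = self.proj.backward(self.proj_bn.backward(d)) if self.projection else d
        return df + ds


class Sequential(Module):
    def __init__(self, layers: list[tuple[str, Module]]):
        super().__init__()
        self._layers = layers
        for name, layer in layers:
            setattr(self, name, layer)

    def children(self):
        return list(self._layers)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for _, layer in self._layers:
            x = layer.forward(x, train)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for _, layer in reversed(self._layers):
            dy = layer.backward(dy)
        return dy


class AdamW:
    """Adam with decoupled weight decay applied to ``decay``-marked params."""

    def __init__(self, model: Module, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8, weight_decay: float = 0.0):
        self.model = model
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.weight_decay = weight_decay
        self.t = 0
        self._m: dict[str, np.ndarray] = {}
        self._v: dict[str, np.ndarray] = {}
        for path, m in model.modules():
            for k, v in m.params.items():
                self._m[path + k] = np.zeros_like(v)
                self._v[path + k] = np.zeros_like(v)

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.b1, self.b2
        bc1 = 1 - b1**self.t
        bc2 = 1 - b2**self.t
        for path, mod in self.model.modules():
            for k, p in mod.params.items():
                g = mod.grads[k]
                key = path + k
                self._m[key] = b1 * self._m[key] + (1 - b1) * g
                self._v[key] = b2 * self._v[key] + (1 - b2) * g * g
                mhat = self._m[key] / bc1
                vhat = self._v[key] / bc2
                p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
                if self.weight_decay and k in mod.decay:
                    p -= self.lr * self.weight_decay * p


class ReduceLROnPlateau:
    """Multiply lr by ``factor`` after ``patience`` epochs without improvement."""

    def __init__(self, optimizer: AdamW, factor: float = 0.1, patience: int = 1,
                 min_lr: float = 1e-6, min_delta: float = 0.0):
        if not 0 < factor < 1:
            raise ValueError("factor must be in (0, 1)")
        self.opt = optimizer
        self.factor, self.patience, self.min_lr = factor, patience, min_lr
        self.min_delta = min_delta
        self.best = np.inf
        self.bad_epochs = 0
        self.n_reductions = 0

    def step(self, metric: float) -> bool:
        """Record one epoch's monitored value; returns True if lr dropped."""
        if metric < self.best - self.min_delta:
            self.best = metric
            self.bad_epochs = 0
            return False
        self.bad_epochs += 1
        if self.bad_epochs >= self.patience:
            new_lr = max(self.opt.lr * self.factor, self.min_lr)
            dropped = new_lr < self.opt.lr
            self.opt.lr = new_lr
            self.bad_epochs = 0
            if dropped:
                self.n_reductions += 1
            return dropped
        return False
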