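"""Compact numpy neural-network stack (forward + manual backprop).

Implements exactly the layers the expression classifiers need: 1-D
convolution (optionally dilated/causal), batch normalization, ReLU, max
pooling, dropout, residual dilated-causal TCN blocks, LSTM/GRU recurrences,
global average pooling, dense layers, a class-weighted softmax
cross-entropy, and Adam.  Data layout is ``(batch, channels, time)``.

All stochastic elements (initialization, dropout masks) are driven by an
explicit seed, so two builds with the same seed have identical parameters
and identical training trajectories.  Gradient correctness is covered by
finite-difference checks in the test suite.
"""

from __future__ import annotations

import numpy as np


def _kaiming(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)


class Layer:
    """Base layer: ``params`` and ``grads`` are parallel dicts of arrays."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def layers(self) -> list["Layer"]:
        return [self]


class Conv1d(Layer):
    """Same-length 1-D convolution over time; ``causal=True`` pads left only
    (the standard TCN convolution)."""

    def __init__(
        self,
        in_ch: int,
        out_ch: int,
        kernel: int,
        rng: np.random.Generator,
        dilation: int = 1,
        causal: bool = False,
    ) -> None:
        super().__init__()
        self.in_ch, self.out_ch, self.kernel, self.dilation = in_ch, out_ch, kernel, dilation
        self.causal = causal
        self.params["W"] = _kaiming(rng, (out_ch, in_ch * kernel), in_ch * kernel)
        self.params["b"] = np.zeros(out_ch)
        pad = (kernel - 1) * dilation
        self.pad_left = pad if causal else pad // 2
        self.pad_right = 0 if causal else pad - pad // 2

    def _gather(self, x_pad: np.ndarray, T: int) -> np.ndarray:
        B, C, _ = x_pad.shape
        cols = np.empty((B, C, self.kernel, T), dtype=x_pad.dtype)
        for j in range(self.kernel):
            o = j * self.dilation
            cols[:, :, j, :] = x_pad[:, :, o : o + T]
        return cols.reshape(B, C * self.kernel, T)

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        B, C, T = x.shape
        x_pad = np.pad(x, ((0, 0), (0, 0), (self.pad_left, self.pad_right)))
        cols = self._gather(x_pad, T)
        self._cache = (cols, x.shape)
        return np.matmul(self.params["W"], cols) + self.params["b"][:, None]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        cols, x_shape = self._cache
        B, C, T = x_shape
        self.grads["W"] = np.einsum("bot,bkt->ok", grad, cols)
        self.grads["b"] = grad.sum(axis=(0, 2))
        dcols = np.matmul(self.params["W"].T, grad)  # (B, C*K, T)
        dcols = dcols.reshape(B, C, self.kernel, T)
        dx_pad = np.zeros((B, C, T + self.pad_left + self.pad_right))
        for j in range(self.kernel):
            o = j * self.dilation
            dx_pad[:, :, o : o + T] += dcols[:, :, j, :]
        return dx_pad[:, :, self.pad_left : self.pad_left + T]


class BatchNorm1d(Layer):
    def __init__(self, ch: int, momentum: float = 0.1, eps: float = 1e-5) -> None:
        super().__init__()
        self.params["gamma"] = np.ones(ch)
        self.params["beta"] = np.zeros(ch)
        self.momentum, self.eps = momentum, eps
        self.running_mean = np.zeros(ch)
        self.running_var = np.ones(ch)

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if training:
            mu = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mu
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mu, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu[:, None]) * inv[:, None]
        self._cache = (xhat, inv)
        return self.params["gamma"][:, None] * xhat + self.params["beta"][:, None]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        xhat, inv = self._cache
        B, C, T = grad.shape
        n = B * T
        self.grads["gamma"] = (grad * xhat).sum(axis=(0, 2))
        self.grads["beta"] = grad.sum(axis=(0, 2))
        dxhat = grad * self.params["gamma"][:, None]
        s1 = dxhat.sum(axis=(0, 2), keepdims=True)
        s2 = (dxhat * xhat).sum(axis=(0, 2), keepdims=True)
        return (inv[:, None] / n) * (n * dxhat - s1 - xhat * s2)


class ReLU(Layer):
    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * self._mask


class MaxPool1d(Layer):
    """Non-overlapping max pooling over time; trailing remainder dropped."""

    def __init__(self, pool: int = 2) -> None:
        super().__init__()
        self.pool = pool

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        B, C, T = x.shape
        To = T // self.pool
        if To < 1:
            raise ValueError(f"time length {T} shorter than pool {self.pool}")
        xr = x[:, :, : To * self.pool].reshape(B, C, To, self.pool)
        self._arg = xr.argmax(axis=3)
        self._shape = x.shape
        return xr.max(axis=3)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        B, C, To = grad.shape
        dx = np.zeros(self._shape)
        dxr = dx[:, :, : To * self.pool].reshape(B, C, To, self.pool)
        b, c, t = np.ogrid[:B, :C, :To]
        dxr[b, c, t, self._arg] = grad
        return dx


class Dropout(Layer):
    def __init__(self, p: float, rng: np.random.Generator) -> None:
        super().__init__()
        self.p, self.rng = p, rng

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if not training or self.p == 0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.p) / (1 - self.p)
        return x * self._mask

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad if self._mask is None else grad * self._mask


class GlobalAvgPool(Layer):
    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._T = x.shape[2]
        return x.mean(axis=2)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return np.repeat(grad[:, :, None], self._T, axis=2) / self._T


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.params["W"] = _kaiming(rng, (n_in, n_out), n_in)
        self.params["b"] = np.zeros(n_out)

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.grads["W"] = self._x.T @ grad
        self.grads["b"] = grad.sum(axis=0)
        return grad @ self.params["W"].T


class Sequential(Layer):
    def __init__(self, items: list[Layer]) -> None:
        super().__init__()
        self.items = items

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        for layer in self.items:
            x = layer.forward(x, training)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.items):
            grad = layer.backward(grad)
        return grad

    def layers(self) -> list[Layer]:
        return [sub for item in self.items for sub in item.layers()]


class TCNBlock(Layer):
    """Residual block of two dilated causal convolutions with batch norm,
    ReLU and dropout; 1x1 convolution on the skip path when channel counts
    differ.  Output is ReLU(branch(x) + skip(x))."""

    def __init__(
        self,
        in_ch: int,
        out_ch: int,
        kernel: int,
        dilation: int,
        dropout: float,
        rng: np.random.Generator,
    ) -> None:
        super().__init__()
        self.branch = Sequential(
            [
                Conv1d(in_ch, out_ch, kernel, rng, dilation=dilation, causal=True),
                BatchNorm1d(out_ch),
                ReLU(),
                Dropout(dropout, rng),
                Conv1d(out_ch, out_ch, kernel, rng, dilation=dilation, causal=True),
                BatchNorm1d(out_ch),
                ReLU(),
                Dropout(dropout, rng),
            ]
        )
        self.skip = Conv1d(in_ch, out_ch, 1, rng) if in_ch != out_ch else None

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        b = self.branch.forward(x, training)
        s = self.skip.forward(x, training) if self.skip is not None else x
        out = b + s
        self._mask = out > 0
        return out * self._mask

    def backward(self, grad: np.ndarray) -> np.ndarray:
        grad = grad * self._mask
        dx = self.branch.backward(grad)
        if self.skip is not None:
            dx = dx + self.skip.backward(grad)
        else:
            dx = dx + grad
        return dx

    def layers(self) -> list[Layer]:
        out = self.branch.layers()
        if self.skip is not None:
            out += self.skip.layers()
        return out


def tcn_receptive_field(kernel: int, dilations: list[int]) -> int:
    """Receptive field of a stack of two-convolution residual blocks:
    1 + 2*(kernel-1)*sum(dilations)."""
    return 1 + 2 * (kernel - 1) * sum(dilations)


class LSTMLayer(Layer):
    """LSTM over time; input (B, C, T), output the last hidden state (B, H)."""

    def __init__(self, in_ch: int, hidden: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.hidden = hidden
        scale = 1.0 / np.sqrt(hidden)
        self.params["Wx"] = rng.uniform(-scale, scale, (in_ch, 4 * hidden))
        self.params["Wh"] = rng.uniform(-scale, scale, (hidden, 4 * hidden))
        self.params["b"] = np.zeros(4 * hidden)
        # forget-gate bias init at 1 for stable early training
        self.params["b"][hidden : 2 * hidden] = 1.0

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        B, C, T = x.shape
        H = self.hidden
        h = np.zeros((B, H))
        c = np.zeros((B, H))
        self._cache = []
        self._xshape = x.shape
        for t in range(T):
            xt = x[:, :, t]
            a = xt @ self.params["Wx"] + h @ self.params["Wh"] + self.params["b"]
            i = _sigmoid(a[:, :H])
            f = _sigmoid(a[:, H : 2 * H])
            g = np.tanh(a[:, 2 * H : 3 * H])
            o = _sigmoid(a[:, 3 * H :])
            c_new = f * c + i * g
            tc = np.tanh(c_new)
            self._cache.append((xt, h, c, i, f, g, o, tc))
            h, c = o * tc, c_new
        return h

    def backward(self, grad: np.ndarray) -> np.ndarray:
        B, C, T = self._xshape
        H = self.hidden
        for k in ("Wx", "Wh", "b"):
            self.grads[k] = np.zeros_like(self.params[k])
        dx = np.zeros(self._xshape)
        dh, dc = grad, np.zeros((B, H))
        for t in range(T - 1, -1, -1):
            xt, h_prev, c_prev, i, f, g, o, tc = self._cache[t]
            do = dh * tc
            dc = dc + dh * o * (1 - tc * tc)
            di, df, dg = dc * g, dc * c_prev, dc * i
            da = np.concatenate(
                [di * i * (1 - i), df * f * (1 - f), dg * (1 - g * g), do * o * (1 - o)], axis=1
            )
            self.grads["Wx"] += xt.T @ da
            self.grads["Wh"] += h_prev.T @ da
            self.grads["b"] += da.sum(axis=0)
            dx[:, :, t] = da @ self.params["Wx"].T
            dh = da @ self.params["Wh"].T
            dc = dc * f
        return dx


class GRULayer(Layer):
    """GRU over time; input (B, C, T), output the last hidden state (B, H)."""

    def __init__(self, in_ch: int, hidden: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.hidden = hidden
        scale = 1.0 / np.sqrt(hidden)
        self.params["Wx"] = rng.uniform(-scale, scale, (in_ch, 3 * hidden))
        self.params["Wh"] = rng.uniform(-scale, scale, (hidden, 3 * hidden))
        self.params["bx"] = np.zeros(3 * hidden)
        self.params["bh"] = np.zeros(3 * hidden)

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        B, C, T = x.shape
        H = self.hidden
        h = np.zeros((B, H))
        self._cache = []
        self._xshape = x.shape
        for t in range(T):
            xt = x[:, :, t]
            gx = xt @ self.params["Wx"] + self.params["bx"]
            gh = h @ self.params["Wh"] + self.params["bh"]
            z = _sigmoid(gx[:, :H] + gh[:, :H])
            r = _sigmoid(gx[:, H : 2 * H] + gh[:, H : 2 * H])
            hn_lin = gh[:, 2 * H :]
            n = np.tanh(gx[:, 2 * H :] + r * hn_lin)
            h_new = (1 - z) * n + z * h
            self._cache.append((xt, h, z, r, n, hn_lin))
            h = h_new
        return h

    def backward(self, grad: np.ndarray) -> np.ndarray:
        B, C, T = self._xshape
        H = self.hidden
        for k in ("Wx", "Wh", "bx", "bh"):
            self.grads[k] = np.zeros_like(self.params[k])
        dx = np.zeros(self._xshape)
        dh = grad
        for t in range(T - 1, -1, -1):
            xt, h_prev, z, r, n, hn_lin = self._cache[t]
            dn = dh * (1 - z)
            dz = dh * (h_prev - n)
            dh_prev = dh * z
            dan = dn * (1 - n * n)
            dr = dan * hn_lin
            d_hn_lin = dan * r
            daz = dz * z * (1 - z)
            dar = dr * r * (1 - r)
            dgx = np.concatenate([daz, dar, dan], axis=1)
            dgh = np.concatenate([daz, dar, d_hn_lin], axis=1)
            self.grads["Wx"] += xt.T @ dgx
            self.grads["Wh"] += h_prev.T @ dgh
            self.grads["bx"] += dgx.sum(axis=0)
            self.grads["bh"] += dgh.sum(axis=0)
            dx[:, :, t] = dgx @ self.params["Wx"].T
            dh = dh_prev + dgh @ self.params["Wh"].T
        return dx


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    e = np.exp(x[~pos])
    out[~pos] = e / (1.0 + e)
    return out


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class WeightedCrossEntropy:
    """Class-weighted softmax cross-entropy: mean of w_y * CE normalized by
    the mean class weight of the batch."""

    def forward(self, logits: np.ndarray, y: np.ndarray, weights: np.ndarray) -> float:
        self.probs = softmax(logits)
        self.y = y
        self.w = weights[y]
        eps = 1e-12
        self.loss = float(np.sum(self.w * -np.log(self.probs[np.arange(len(y)), y] + eps)) / self.w.sum())
        return self.loss

    def backward(self) -> np.ndarray:
        n, k = self.probs.shape
        onehot = np.zeros((n, k))
        onehot[np.arange(n), self.y] = 1.0
        return (self.probs - onehot) * self.w[:, None] / self.w.sum()


class Adam:
    def __init__(self, net: Layer, lr: float = 1e-3, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8) -> None:
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.state: dict[tuple[int, str], tuple[np.ndarray, np.ndarray]] = {}
        self.net = net

    def step(self) -> None:
        self.t += 1
        for layer in self.net.layers():
            for name, p in layer.params.items():
                g = layer.grads.get(name)
                if g is None:
                    continue
                key = (id(layer), name)
                m, v = self.state.get(key, (np.zeros_like(p), np.zeros_like(p)))
                m = self.b1 * m + (1 - self.b1) * g
                v = self.b2 * v + (1 - self.b2) * g * g
                self.state[key] = (m, v)
                mhat = m / (1 - self.b1**self.t)
                vhat = v / (1 - self.b2**self.t)
                p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def parameter_count(net: Layer) -> int:
    return sum(p.size for layer in net.layers() for p in layer.params.values())


def get_parameters(net: Layer) -> list[np.ndarray]:
    return [p for layer in net.layers() for p in layer.params.values()]


def set_parameters(net: Layer, values: list[np.ndarray]) -> None:
    params = get_parameters(net)
    if len(params) != len(values):
        raise ValueError("parameter list length mismatch")
    for p, v in zip(params, values):
        p[...] = v
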