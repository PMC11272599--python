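"""Minimal NumPy layer stack with explicit backprop, sized for small images.

Layout conventions: images are ``(B, H, W, C)`` float32, sequences are
``(B, T, D)``.  Each layer exposes ``forward(x, train)`` and ``backward(dout)``
and keeps its parameters/gradients in ``params``/``grads`` dicts.  Convolution
forward and backward are both expressed as im2col matrix products (the input
gradient is a correlation with the rotated kernel), so the only Python-level
loops are over GRU time steps.

Weight init is Glorot-uniform from a model-level seeded generator; biases
start at zero.
"""

from __future__ import annotations

import numpy as np

F32 = np.float32


def _glorot(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(F32)


class Layer:
    name: str = "layer"

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def n_params(self) -> int:
        return int(sum(p.size for p in self.params.values()))


class Conv2D(Layer):
    """3x3 same-padding convolution with fused ReLU.

    Both passes are expressed as nine shifted-slice matrix products (one per
    kernel tap), which keeps everything in BLAS without an im2col gather.
    """

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator, name: str = "conv"):
        super().__init__()
        self.name = name
        self.c_in, self.c_out = c_in, c_out
        fan_in, fan_out = 9 * c_in, 9 * c_out
        self.params["W"] = _glorot(rng, (3, 3, c_in, c_out), fan_in, fan_out)
        self.params["b"] = np.zeros(c_out, dtype=F32)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        b, h, w, c = x.shape
        self._xpad = np.pad(x, ((0, 0), (1, 1), (1, 1), (0, 0)))
        W = self.params["W"]
        z = np.tile(self.params["b"], (b * h * w, 1))
        for p in range(3):
            for q in range(3):
                sl = self._xpad[:, p : p + h, q : q + w, :].reshape(-1, c)
                z += sl @ W[p, q]
        z = z.reshape(b, h, w, self.c_out)
        self._mask = z > 0
        return np.where(self._mask, z, 0)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        b, h, w, _ = dout.shape
        W = self.params["W"]
        dz = np.where(self._mask, dout, 0).astype(F32)
        dz_mat = dz.reshape(-1, self.c_out)
        dW = np.empty_like(W)
        dxpad = np.zeros_like(self._xpad)
        for p in range(3):
            for q in range(3):
                sl = self._xpad[:, p : p + h, q : q + w, :].reshape(-1, self.c_in)
                dW[p, q] = sl.T @ dz_mat
                dxpad[:, p : p + h, q : q + w, :] += (dz_mat @ W[p, q].T).reshape(b, h, w, self.c_in)
        self.grads["W"] = dW
        self.grads["b"] = dz_mat.sum(axis=0)
        self._xpad = None
        return dxpad[:, 1:-1, 1:-1, :]


class MaxPool2x2(Layer):
    """2x2 max pooling, stride 2; trailing odd row/column dropped.

    Gradient routing on ties matches argmax order: the first of the four
    window positions (row-major) holding the maximum receives the gradient.
    """

    def __init__(self, name: str = "pool"):
        super().__init__()
        self.name = name

    @staticmethod
    def _quads(x: np.ndarray) -> list[np.ndarray]:
        h2, w2 = (x.shape[1] // 2) * 2, (x.shape[2] // 2) * 2
        return [x[:, p:h2:2, q:w2:2, :] for p in (0, 1) for q in (0, 1)]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._x = x
        quads = self._quads(x)
        out = quads[0]
        for q in quads[1:]:
            out = np.maximum(out, q)
        self._out = out
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dx = np.zeros_like(self._x)
        taken = np.zeros(dout.shape, dtype=bool)
        h2, w2 = (dx.shape[1] // 2) * 2, (dx.shape[2] // 2) * 2
        for p in (0, 1):
            for q in (0, 1):
                sel = (self._x[:, p:h2:2, q:w2:2, :] == self._out) & ~taken
                np.copyto(dx[:, p:h2:2, q:w2:2, :], dout, where=sel)
                taken |= sel
        self._x = self._out = None
        return dx


class Dropout(Layer):
    """Inverted dropout; identity at evaluation time."""

    def __init__(self, rate: float, rng: np.random.Generator, name: str = "dropout"):
        super().__init__()
        if not 0.0 < rate < 1.0:
            raise ValueError("dropout rate must lie in (0, 1)")
        self.rate = rate
        self.rng = rng
        self.name = name

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if not train:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(F32) / F32(keep)
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout if self._mask is None else dout * self._mask


class GlobalAvgPool(Layer):
    """(B, H, W, C) -> (B, C) spatial mean."""

    def __init__(self, name: str = "gap"):
        super().__init__()
        self.name = name

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._in_shape = x.shape
        return x.mean(axis=(1, 2))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        b, h, w, c = self._in_shape
        return np.broadcast_to(dout[:, None, None, :] / F32(h * w), self._in_shape).astype(F32)


class VectorToSequence(Layer):
    """(B, C) -> (B, C, 1): a C-step sequence of scalar features."""

    def __init__(self, name: str = "reshape"):
        super().__init__()
        self.name = name

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        return x[:, :, None]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout[:, :, 0]


class RowsToSequence(Layer):
    """(B, H, W, C) -> (B, H, W*C): image rows as a sequence of features."""

    def __init__(self, name: str = "rows"):
        super().__init__()
        self.name = name

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._in_shape = x.shape
        b, h, w, c = x.shape
        return x.reshape(b, h, w * c)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout.reshape(self._in_shape)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


class GRU(Layer):
    """Gated recurrent unit over (B, T, D), returning the final hidden state.

    Gate equations (update z, reset r, candidate h~, blend) act on the
    concatenation ``[h_{t-1}, x_t]``:

        z = sigmoid([h, x] @ Wz + bz)
        r = sigmoid([h, x] @ Wr + br)
        h~ = tanh([r * h, x] @ Wh + bh)
        h  = (1 - z) * h_prev + z * h~

    Biases are trained by default; zeroing them makes a single step identical
    to the bias-free reference ``net.gru_step``.
    """

    def __init__(self, d: int, units: int, rng: np.random.Generator, bias: bool = True, name: str = "gru"):
        super().__init__()
        self.name = name
        self.d, self.units = d, units
        fi, fo = units + d, units
        for gate in ("Wz", "Wr", "Wh"):
            self.params[gate] = _glorot(rng, (units + d, units), fi, fo)
        self.use_bias = bias
        if bias:
            for gate in ("bz", "br", "bh"):
                self.params[gate] = np.zeros(units, dtype=F32)

    def _bias(self, gate: str) -> np.ndarray | float:
        return self.params[gate] if self.use_bias else 0.0

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        b, T, d = x.shape
        u = self.units
        h = np.zeros((b, u), dtype=F32)
        self._x = x
        self._cache = []
        for t in range(T):
            hx = np.concatenate([h, x[:, t, :]], axis=1)
            z = _sigmoid(hx @ self.params["Wz"] + self._bias("bz"))
            r = _sigmoid(hx @ self.params["Wr"] + self._bias("br"))
            rhx = np.concatenate([r * h, x[:, t, :]], axis=1)
            h_tilde = np.tanh(rhx @ self.params["Wh"] + self._bias("bh"))
            h_new = (1.0 - z) * h + z * h_tilde
            self._cache.append((h, hx, z, r, rhx, h_tilde))
            h = h_new.astype(F32)
        return h

    def backward(self, dout: np.ndarray) -> np.ndarray:
        b, T, d = self._x.shape
        u = self.units
        for k in ("Wz", "Wr", "Wh"):
            self.grads[k] = np.zeros_like(self.params[k])
        if self.use_bias:
            for k in ("bz", "br", "bh"):
                self.grads[k] = np.zeros_like(self.params[k])
        dx = np.zeros_like(self._x)
        dh = dout.astype(F32)
        for t in range(T - 1, -1, -1):
            h_prev, hx, z, r, rhx, h_tilde = self._cache[t]
            dz = dh * (h_tilde - h_prev)
            dh_tilde = dh * z
            dh_prev = dh * (1.0 - z)
            da_h = dh_tilde * (1.0 - h_tilde**2)
            self.grads["Wh"] += rhx.T @ da_h
            if self.use_bias:
                self.grads["bh"] += da_h.sum(axis=0)
            drhx = da_h @ self.params["Wh"].T
            dr = drhx[:, :u] * h_prev
            dh_prev += drhx[:, :u] * r
            dx[:, t, :] += drhx[:, u:]
            da_z = dz * z * (1.0 - z)
            da_r = dr * r * (1.0 - r)
            self.grads["Wz"] += hx.T @ da_z
            self.grads["Wr"] += hx.T @ da_r
            if self.use_bias:
                self.grads["bz"] += da_z.sum(axis=0)
                self.grads["br"] += da_r.sum(axis=0)
            dhx = da_z @ self.params["Wz"].T + da_r @ self.params["Wr"].T
            dh_prev += dhx[:, :u]
            dx[:, t, :] += dhx[:, u:]
            dh = dh_prev.astype(F32)
        self._cache = None
        return dx


class Dense(Layer):
    """Affine layer with optional ReLU."""

    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator, relu: bool = False, name: str = "dense"):
        super().__init__()
        self.name = name
        self.relu = relu
        self.params["W"] = _glorot(rng, (d_in, d_out), d_in, d_out)
        self.params["b"] = np.zeros(d_out, dtype=F32)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._x = x
        z = x @ self.params["W"] + self.params["b"]
        if self.relu:
            self._mask = z > 0
            return np.where(self._mask, z, 0)
        return z

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dz = np.where(self._mask, dout, 0).astype(F32) if self.relu else dout.astype(F32)
        self.grads["W"] = self._x.T @ dz
        self.grads["b"] = dz.sum(axis=0)
        return dz @ self.params["W"].T


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy(probs: np.ndarray, y: np.ndarray) -> float:
    """Mean categorical cross-entropy; ``y`` is an int label vector."""
    p = np.clip(probs[np.arange(len(y)), y], 1e-12, None)
    return float(-np.mean(np.log(p)))


class Sequential:
    """A feed-forward stack ending in logits; softmax/cross-entropy applied here."""

    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        out = x.astype(F32)
        for layer in self.layers:
            out = layer.forward(out, train)
        return out

    def predict_proba(self, x: np.ndarray, batch_size: int = 64) -> np.ndarray:
        outs = [softmax(self.forward(x[i : i + batch_size])) for i in range(0, len(x), batch_size)]
        return np.concatenate(outs, axis=0)

    def loss_and_grads(self, x: np.ndarray, y: np.ndarray, train: bool = True) -> tuple[float, np.ndarray]:
        """One forward/backward pass; returns (loss, probs) and fills layer grads."""
        logits = self.forward(x, train=train)
        probs = softmax(logits)
        loss = cross_entropy(probs, y)
        dlogits = probs.copy()
        dlogits[np.arange(len(y)), y] -= 1.0
        dlogits /= len(y)
        grad = dlogits.astype(F32)
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return loss, probs

    def parameters(self) -> list[tuple[Layer, str]]:
        return [(layer, key) for layer in self.layers for key in layer.params]

    def n_params(self) -> int:
        return sum(layer.n_params() for layer in self.layers)

    def get_weights(self) -> list[np.ndarray]:
        return [layer.params[k].copy() for layer, k in self.parameters()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        for (layer, k), w in zip(self.parameters(), weights):
            layer.params[k] = w.copy()

    def layer_names(self) -> list[str]:
        return [layer.name for layer in self.layers]


class Adam:
    """Adam with the legacy per-update learning-rate decay ``lr / (1 + decay * step)``."""

    def __init__(
        self,
        model: Sequential,
        lr: float = 0.001,
        decay: float = 1e-6,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-7,
    ):
        self.model = model
        self.lr0, self.decay = lr, decay
        self.b1, self.b2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(layer.params[k]) for layer, k in model.parameters()]
        self.v = [np.zeros_like(layer.params[k]) for layer, k in model.parameters()]

    def step(self) -> None:
        lr = self.lr0 / (1.0 + self.decay * self.t)
        self.t += 1
        correction = np.sqrt(1.0 - self.b2**self.t) / (1.0 - self.b1**self.t)
        for i, (layer, k) in enumerate(self.model.parameters()):
            g = layer.grads[k]
            self.m[i] = self.b1 * self.m[i] + (1.0 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1.0 - self.b2) * g * g
            layer.params[k] -= (lr * correction * self.m[i] / (np.sqrt(self.v[i]) + self.eps)).astype(F32)
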