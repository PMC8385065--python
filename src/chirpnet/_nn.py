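"""Minimal numpy neural-network engine (internal).

Layers carry their own weights and gradients and implement
``forward(x, train)`` / ``backward(dout)``; convolution is im2col + BLAS
matmul in a channels-last internal layout.  Everything here is standard
machinery (conv/BN/pool/linear/dropout, BPTT for the recurrent layers,
softmax cross-entropy, Adam); the recurrent update equations themselves live
in :mod:`chirpnet.recurrent_cells` and are re-used by the RNN layers so the
trainable model and the reference step functions share one set of weights.
"""

from __future__ import annotations

import numpy as np

from . import recurrent_cells as rc
from .synthetic_audio import ValidationError


class Layer:
    """Base: stateless unless it has ``weights``/``grads`` dicts."""

    weights: dict = {}
    grads: dict = {}

    def forward(self, x, train: bool = False):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dout):  # pragma: no cover - interface
        raise NotImplementedError

    def param_items(self):
        return [(k, self.weights[k], self.grads[k]) for k in self.weights]

    def buffer_items(self):
        """Non-trainable state that a checkpoint must still capture
        (batch-norm running statistics)."""
        return []

    def zero_grad(self):
        for g in self.grads.values():
            g[...] = 0


def _he_init(rng, shape, fan_in, dtype):
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(dtype)


# ---------------------------------------------------------------------------
# convolution


class Conv2d(Layer):
    """Same-style conv over NCHW input; weights kept as a (kh*kw*Cin, Cout)
    matrix (tap-major ordering) for the im2col matmul."""

    def __init__(self, in_channels, out_channels, kernel=3, stride=1,
                 pad=None, rng=None, dtype=np.float32, bias=True):
        rng = rng or np.random.default_rng(0)
        self.cin, self.cout = in_channels, out_channels
        self.k = kernel
        self.s = stride
        self.p = (kernel // 2) if pad is None else pad
        fan_in = in_channels * kernel * kernel
        self.weights = {
            "W": _he_init(rng, (fan_in, out_channels), fan_in, dtype),
        }
        if bias:
            self.weights["b"] = np.zeros(out_channels, dtype)
        self.grads = {k: np.zeros_like(v) for k, v in self.weights.items()}
        self._cache = None

    def _im2col(self, xt):
        # xt channels-last (N, H, W, C) already padded
        N, Hp, Wp, C = xt.shape
        k, s = self.k, self.s
        OH = (Hp - k) // s + 1
        OW = (Wp - k) // s + 1
        cols = np.empty((N, OH, OW, k * k * C), xt.dtype)
        for ky in range(k):
            for kx in range(k):
                tap = ky * k + kx
                cols[..., tap * C:(tap + 1) * C] = \
                    xt[:, ky:ky + s * OH:s, kx:kx + s * OW:s, :]
        return cols, OH, OW

    def forward(self, x, train: bool = False):
        N, C, H, W = x.shape
        if C != self.cin:
            raise ValidationError(f"expected {self.cin} channels, got {C}")
        xt = np.ascontiguousarray(x.transpose(0, 2, 3, 1))
        p = self.p
        if p:
            xt = np.pad(xt, ((0, 0), (p, p), (p, p), (0, 0)))
        cols, OH, OW = self._im2col(xt)
        out = cols.reshape(-1, cols.shape[-1]) @ self.weights["W"]
        if "b" in self.weights:
            out += self.weights["b"]
        self._cache = (cols, x.shape)
        return out.reshape(N, OH, OW, self.cout).transpose(0, 3, 1, 2)

    def backward(self, dout):
        cols, xshape = self._cache
        N, C, H, W = xshape
        k, s, p = self.k, self.s, self.p
        dflat = np.ascontiguousarray(dout.transpose(0, 2, 3, 1)).reshape(
            -1, self.cout)
        self.grads["W"] += cols.reshape(-1, cols.shape[-1]).T @ dflat
        if "b" in self.weights:
            self.grads["b"] += dflat.sum(axis=0)
        dcols = (dflat @ self.weights["W"].T).reshape(cols.shape)
        OH, OW = cols.shape[1], cols.shape[2]
        dxp = np.zeros((N, H + 2 * p, W + 2 * p, C), dout.dtype)
        for ky in range(k):
            for kx in range(k):
                tap = ky * k + kx
                dxp[:, ky:ky + s * OH:s, kx:kx + s * OW:s, :] += \
                    dcols[..., tap * C:(tap + 1) * C]
        if p:
            dxp = dxp[:, p:-p, p:-p, :]
        return dxp.transpose(0, 3, 1, 2)

    def n_params(self):
        return sum(v.size for v in self.weights.values())


class BatchNorm2d(Layer):
    def __init__(self, channels, momentum=0.1, eps=1e-5, dtype=np.float32):
        self.weights = {"gamma": np.ones(channels, dtype),
                        "beta": np.zeros(channels, dtype)}
        self.grads = {k: np.zeros_like(v) for k, v in self.weights.items()}
        self.running_mean = np.zeros(channels, dtype)
        self.running_var = np.ones(channels, dtype)
        self.momentum = momentum
        self.eps = eps
        self._cache = None

    def forward(self, x, train: bool = False):
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
        self._cache = (xhat, inv, x.shape, train)
        return (self.weights["gamma"][None, :, None, None] * xhat
                + self.weights["beta"][None, :, None, None])

    def backward(self, dout):
        xhat, inv, shape, train = self._cache
        g = self.weights["gamma"]
        self.grads["gamma"] += (dout * xhat).sum(axis=(0, 2, 3))
        self.grads["beta"] += dout.sum(axis=(0, 2, 3))
        dxhat = dout * g[None, :, None, None]
        if not train:
            return dxhat * inv[None, :, None, None]
        N = shape[0] * shape[2] * shape[3]
        sum_d = dxhat.sum(axis=(0, 2, 3))[None, :, None, None]
        sum_dx = (dxhat * xhat).sum(axis=(0, 2, 3))[None, :, None, None]
        return (inv[None, :, None, None] / N) * (
            N * dxhat - sum_d - xhat * sum_dx)

    def buffer_items(self):
        return [("running_mean", self.running_mean),
                ("running_var", self.running_var)]


class ReLU(Layer):
    def forward(self, x, train: bool = False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class MaxPool2d(Layer):
    def __init__(self, kernel=2, stride=None, pad=0):
        self.k = kernel
        self.s = stride or kernel
        self.p = pad

    def forward(self, x, train: bool = False):
        k, s, p = self.k, self.s, self.p
        if p:
            x = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)),
                       constant_values=-np.inf)
        N, C, H, W = x.shape
        OH = (H - k) // s + 1
        OW = (W - k) // s + 1
        windows = np.lib.stride_tricks.sliding_window_view(x, (k, k),
                                                           axis=(2, 3))
        windows = windows[:, :, ::s, ::s][:, :, :OH, :OW]
        flat = windows.reshape(N, C, OH, OW, k * k)
        self._arg = flat.argmax(axis=-1)
        self._inshape = (N, C, H, W)
        return flat.max(axis=-1)

    def backward(self, dout):
        N, C, H, W = self._inshape
        k, s, p = self.k, self.s, self.p
        OH, OW = dout.shape[2], dout.shape[3]
        dx = np.zeros((N, C, H, W), dout.dtype)
        ky, kx = np.divmod(self._arg, k)
        oy, ox = np.meshgrid(np.arange(OH), np.arange(OW), indexing="ij")
        iy = oy[None, None] * s + ky
        ix = ox[None, None] * s + kx
        n_idx = np.arange(N)[:, None, None, None]
        c_idx = np.arange(C)[None, :, None, None]
        np.add.at(dx, (n_idx, c_idx, iy, ix), dout)
        if p:
            dx = dx[:, :, p:-p, p:-p]
        return dx


class AdaptiveAvgPool2d(Layer):
    """Average pool to a fixed (oh, ow) output; bin edges floor/ceil style so
    any input size >= the target works."""

    def __init__(self, out_hw):
        self.oh, self.ow = out_hw

    @staticmethod
    def _edges(n, o):
        starts = (np.arange(o) * n) // o
        ends = -(-(np.arange(1, o + 1) * n) // o)  # ceil
        return starts, ends

    def forward(self, x, train: bool = False):
        N, C, H, W = x.shape
        if H < self.oh or W < self.ow:
            raise ValidationError("input smaller than adaptive-pool target")
        ys, ye = self._edges(H, self.oh)
        xs, xe = self._edges(W, self.ow)
        out = np.empty((N, C, self.oh, self.ow), x.dtype)
        for i in range(self.oh):
            for j in range(self.ow):
                out[:, :, i, j] = x[:, :, ys[i]:ye[i], xs[j]:xe[j]].mean(
                    axis=(2, 3))
        self._cache = (x.shape, ys, ye, xs, xe)
        return out

    def backward(self, dout):
        shape, ys, ye, xs, xe = self._cache
        dx = np.zeros(shape, dout.dtype)
        for i in range(self.oh):
            for j in range(self.ow):
                area = (ye[i] - ys[i]) * (xe[j] - xs[j])
                dx[:, :, ys[i]:ye[i], xs[j]:xe[j]] += \
                    dout[:, :, i, j][:, :, None, None] / area
        return dx


class Flatten(Layer):
    def forward(self, x, train: bool = False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


class Linear(Layer):
    def __init__(self, in_features, out_features, rng=None, dtype=np.float32):
        rng = rng or np.random.default_rng(0)
        lim = np.sqrt(6.0 / (in_features + out_features))
        self.weights = {
            "W": rng.uniform(-lim, lim, (in_features, out_features)).astype(dtype),
            "b": np.zeros(out_features, dtype),
        }
        self.grads = {k: np.zeros_like(v) for k, v in self.weights.items()}

    def forward(self, x, train: bool = False):
        self._x = x
        return x @ self.weights["W"] + self.weights["b"]

    def backward(self, dout):
        self.grads["W"] += self._x.T @ dout
        self.grads["b"] += dout.sum(axis=0)
        return dout @ self.weights["W"].T


class Dropout(Layer):
    def __init__(self, p=0.5, rng=None):
        self.p = p
        self.rng = rng or np.random.default_rng(0)

    def forward(self, x, train: bool = False):
        if not train or self.p == 0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.p) / (1 - self.p)
        return x * self._mask.astype(x.dtype)

    def backward(self, dout):
        if self._mask is None:
            return dout
        return dout * self._mask.astype(dout.dtype)


class ScaleShift(Layer):
    """Fixed (non-trainable) affine input normalization."""

    def __init__(self, scale, shift):
        self.scale, self.shift = scale, shift

    def forward(self, x, train: bool = False):
        return x * self.scale + self.shift

    def backward(self, dout):
        return dout * self.scale


class Sequential(Layer):
    def __init__(self, layers):
        self.layers = list(layers)

    def forward(self, x, train: bool = False):
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, dout):
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    def param_items(self):
        items = []
        for i, layer in enumerate(self.layers):
            items += [(f"{i}.{k}", v, g) for k, v, g in layer.param_items()]
        return items

    def buffer_items(self):
        items = []
        for i, layer in enumerate(self.layers):
            items += [(f"{i}.{k}", v) for k, v in layer.buffer_items()]
        return items

    def zero_grad(self):
        for layer in self.layers:
            layer.zero_grad()


class ResidualBlock(Layer):
    """out = relu(main(x) + shortcut(x)); shortcut defaults to identity."""

    def __init__(self, main: Sequential, shortcut: Sequential | None = None):
        self.main = main
        self.shortcut = shortcut
        self.relu = ReLU()

    def forward(self, x, train: bool = False):
        y = self.main.forward(x, train)
        s = self.shortcut.forward(x, train) if self.shortcut else x
        return self.relu.forward(y + s, train)

    def backward(self, dout):
        d = self.relu.backward(dout)
        dx = self.main.backward(d)
        dx = dx + (self.shortcut.backward(d) if self.shortcut else d)
        return dx

    def param_items(self):
        items = [("main." + k, v, g) for k, v, g in self.main.param_items()]
        if self.shortcut:
            items += [("short." + k, v, g)
                      for k, v, g in self.shortcut.param_items()]
        return items

    def buffer_items(self):
        items = [("main." + k, v) for k, v in self.main.buffer_items()]
        if self.shortcut:
            items += [("short." + k, v)
                      for k, v in self.shortcut.buffer_items()]
        return items

    def zero_grad(self):
        self.main.zero_grad()
        if self.shortcut:
            self.shortcut.zero_grad()


# ---------------------------------------------------------------------------
# recurrent layers (BPTT) — weights shared with recurrent_cells step funcs


class RNNLayerBase(Layer):
    cell = None

    @property
    def weights(self):
        return self.cell.weights

    def param_items(self):
        return [(k, self.weights[k], self.grads[k]) for k in self.weights]


class GRULayer(RNNLayerBase):
    def __init__(self, cell: rc.GRUCell):
        self.cell = cell
        self.grads = {k: np.zeros_like(v) for k, v in cell.weights.items()}

    def forward(self, X, train: bool = False):
        # X: (N, T, p) -> (N, T, n)
        N, T, p = X.shape
        h = self.cell.zero_state(batch=N)
        self._caches = []
        out = np.zeros((N, T, self.cell.hidden_size), X.dtype)
        for t in range(T):
            h, cache = rc.gru_step(self.cell, X[:, t], h, with_cache=True)
            self._caches.append(cache)
            out[:, t] = h
        return out

    def backward(self, dout):
        w, g = self.cell.weights, self.grads
        N, T, n = dout.shape
        dX = np.zeros((N, T, self.cell.input_size), dout.dtype)
        dh_next = np.zeros((N, n), dout.dtype)
        for t in reversed(range(T)):
            c = self._caches[t]
            dh = dout[:, t] + dh_next
            x, h_prev, z, r, rh, h_tilde = (c["x"], c["h"], c["z"], c["r"],
                                            c["rh"], c["h_tilde"])
            dz = dh * (h_tilde - h_prev)
            dht = dh * z
            dh_prev = dh * (1 - z)
            da_c = dht * (1 - h_tilde ** 2)
            g["W_cx"] += da_c.T @ x
            g["W_ch"] += da_c.T @ rh
            g["b_h"] += da_c.sum(axis=0)
            dx = da_c @ w["W_cx"]
            drh = da_c @ w["W_ch"]
            dr = drh * h_prev
            dh_prev = dh_prev + drh * r
            da_z = dz * z * (1 - z)
            g["W_zx"] += da_z.T @ x
            g["W_zh"] += da_z.T @ h_prev
            g["b_z"] += da_z.sum(axis=0)
            dx += da_z @ w["W_zx"]
            dh_prev = dh_prev + da_z @ w["W_zh"]
            da_r = dr * r * (1 - r)
            g["W_rx"] += da_r.T @ x
            g["W_rh"] += da_r.T @ h_prev
            g["b_r"] += da_r.sum(axis=0)
            dx += da_r @ w["W_rx"]
            dh_prev = dh_prev + da_r @ w["W_rh"]
            dX[:, t] = dx
            dh_next = dh_prev
        return dX


class LSTMLayer(RNNLayerBase):
    def __init__(self, cell: rc.LSTMCell):
        self.cell = cell
        self.grads = {k: np.zeros_like(v) for k, v in cell.weights.items()}

    def forward(self, X, train: bool = False):
        N, T, p = X.shape
        h, c = self.cell.zero_state(batch=N)
        self._caches = []
        out = np.zeros((N, T, self.cell.hidden_size), X.dtype)
        for t in range(T):
            h, c, cache = rc.lstm_step(self.cell, X[:, t], h, c,
                                       with_cache=True)
            self._caches.append(cache)
            out[:, t] = h
        return out

    def backward(self, dout):
        w, g = self.cell.weights, self.grads
        N, T, n = dout.shape
        dX = np.zeros((N, T, self.cell.input_size), dout.dtype)
        dh_next = np.zeros((N, n), dout.dtype)
        dc_next = np.zeros((N, n), dout.dtype)
        paper = self.cell.mode == "paper"
        for t in reversed(range(T)):
            cc = self._caches[t]
            dh = dout[:, t] + dh_next
            tanh_c = np.tanh(cc["c_new"])
            do = dh * tanh_c
            dc = dc_next + dh * cc["o"] * (1 - tanh_c ** 2)
            df = dc * cc["c"]
            di = dc * cc["c_tilde"]
            dct = dc * cc["i"]
            dc_next = dc * cc["f"]
            da_c = dct * (cc["c_tilde"] * (1 - cc["c_tilde"]) if paper
                          else (1 - cc["c_tilde"] ** 2))
            dx = np.zeros((N, self.cell.input_size), dout.dtype)
            dh_prev = np.zeros((N, n), dout.dtype)
            for gate, da in (("f", df * cc["f"] * (1 - cc["f"])),
                             ("i", di * cc["i"] * (1 - cc["i"])),
                             ("o", do * cc["o"] * (1 - cc["o"])),
                             ("c", da_c)):
                g[f"W_{gate}x"] += da.T @ cc["x"]
                g[f"W_{gate}h"] += da.T @ cc["h"]
                g[f"b_{gate}"] += da.sum(axis=0)
                dx += da @ w[f"W_{gate}x"]
                dh_prev += da @ w[f"W_{gate}h"]
            dX[:, t] = dx
            dh_next = dh_prev
        return dX


class LMULayer(RNNLayerBase):
    def __init__(self, cell: rc.LMUCellParams):
        self.cell = cell
        self.grads = {k: np.zeros_like(v) for k, v in cell.weights.items()}

    def forward(self, X, train: bool = False):
        N, T, p = X.shape
        h, m = self.cell.zero_state(batch=N)
        self._caches = []
        out = np.zeros((N, T, self.cell.hidden_size), X.dtype)
        for t in range(T):
            h, m, cache = rc.lmu_step(self.cell, X[:, t], h, m,
                                      with_cache=True)
            self._caches.append(cache)
            out[:, t] = h
        self.memory_trace = None  # set by interpret hooks when requested
        return out

    def backward(self, dout):
        w, g = self.cell.weights, self.grads
        sys_ = self.cell.system
        N, T, n = dout.shape
        d = self.cell.memory_size
        dX = np.zeros((N, T, self.cell.input_size), dout.dtype)
        dh_next = np.zeros((N, n), dout.dtype)
        dm_next = np.zeros((N, d), dout.dtype)
        Abar = sys_.Abar.astype(dout.dtype)
        Bbar = sys_.Bbar.astype(dout.dtype)
        for t in reversed(range(T)):
            c = self._caches[t]
            dh = dout[:, t] + dh_next
            da = dh * (1 - c["h_new"] ** 2)
            g["W_x"] += da.T @ c["x"]
            g["W_h"] += da.T @ c["h"]
            g["W_m"] += da.T @ c["m_new"]
            dx = da @ w["W_x"]
            dh_prev = da @ w["W_h"]
            dm = dm_next + da @ w["W_m"]
            dm_prev = dm @ Abar
            du = dm @ Bbar  # (N,)
            g["e_x"] += du @ c["x"]
            g["e_h"] += du @ c["h"]
            g["e_m"] += du @ c["m"]
            dx += np.multiply.outer(du, w["e_x"])
            dh_prev += np.multiply.outer(du, w["e_h"])
            dm_prev += np.multiply.outer(du, w["e_m"])
            dX[:, t] = dx
            dh_next = dh_prev
            dm_next = dm_prev
        return dX

    def last_memory_trace(self, sample: int = 0) -> np.ndarray:
        """Memory state per step from the most recent forward pass:
        array (d, T)."""
        if not self._caches:
            raise ValidationError("no forward pass recorded")
        return np.stack([c["m_new"][sample] for c in self._caches], axis=1)


# ---------------------------------------------------------------------------
# loss and optimizer


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray
                          ) -> tuple[float, np.ndarray]:
    """Mean cross-entropy over the batch and its gradient w.r.t. logits."""
    p = softmax(logits.astype(np.float64))
    n = logits.shape[0]
    eps = 1e-12
    loss = -np.log(p[np.arange(n), labels] + eps).mean()
    dlogits = p
    dlogits[np.arange(n), labels] -= 1.0
    return float(loss), (dlogits / n).astype(logits.dtype)


class Adam:
    def __init__(self, param_items, lr=1e-4, betas=(0.9, 0.999), eps=1e-8):
        self.items = list(param_items)  # (name, value, grad) triples
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(v) for _, v, _ in self.items]
        self.v = [np.zeros_like(v) for _, v, _ in self.items]

    def step(self):
        self.t += 1
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for k, (_, value, grad) in enumerate(self.items):
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * grad
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * grad ** 2
            value -= self.lr * (self.m[k] / b1t) / (
                np.sqrt(self.v[k] / b2t) + self.eps)


def numeric_gradient(f, x, eps=1e-5):
    """Central-difference gradient of scalar f at array x (test helper)."""
    g = np.zeros_like(x, dtype=np.float64)
    it = np.nditer(x, flags=["multi_index"])
    while not it.finished:
        idx = it.multi_index
        old = x[idx]
        x[idx] = old + eps
        fp = f()
        x[idx] = old - eps
        fm = f()
        x[idx] = old
        g[idx] = (fp - fm) / (2 * eps)
        it.iternext()
    return g
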