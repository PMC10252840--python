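"""Minimal NumPy sequence-model engine: layers, BPTT, and Adam.

Implements exactly the layer kinds the hybrid architectures need — a
kernel-size-1 convolution (a pointwise linear map with softmax across
filters), identity max-pooling, simple RNN / LSTM / GRU cells (the GRU in
both the single-bias and the double-bias, reset-after variant),
bidirectional wrapping, dropout, and a dense sigmoid head — each with an
explicit backward pass.  Initialisation mirrors the common Keras defaults:
Glorot-uniform input kernels, orthogonal recurrent kernels, zero biases with
the LSTM forget gate biased to one.

Sequences are (batch, time, features) arrays in a caller-chosen dtype
(float32 for training speed, float64 for gradient checking); recurrent loops
run over time with the input projections hoisted into one matmul and the
per-step elementwise work done in place on preallocated time-major buffers.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Layer",
    "PointwiseConv1D",
    "MaxPool1D",
    "SimpleRNN",
    "LSTM",
    "GRU",
    "Bidirectional",
    "Dropout",
    "Dense",
    "Adam",
    "DivergenceError",
]


class DivergenceError(RuntimeError):
    """Training produced a non-finite loss."""


def _glorot_uniform(rng: np.random.Generator, fan_in: int, fan_out: int, shape=None) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape or (fan_in, fan_out))


def _orthogonal(rng: np.random.Generator, rows: int, cols: int) -> np.ndarray:
    a = rng.standard_normal((max(rows, cols), min(rows, cols)))
    q, r = np.linalg.qr(a)
    q *= np.sign(np.diag(r))
    return q[:rows, :cols] if q.shape != (rows, cols) else q


def _sigmoid(x: np.ndarray) -> np.ndarray:
    # exp(-x) overflowing to inf gives exactly 0.0 — correct and branch-free
    with np.errstate(over="ignore"):
        return 1.0 / (1.0 + np.exp(-x))


class Layer:
    """Base layer: named parameter arrays with matching gradient buffers."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def n_params(self) -> int:
        return sum(int(p.size) for p in self.params.values())

    def zero_grads(self) -> None:
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class PointwiseConv1D(Layer):
    """Conv1D with kernel size 1 and 'valid' padding: z_t = x_t W + b.

    With ``activation='softmax'`` the filter responses at each time step are
    normalised into a probability distribution over the filters, turning the
    layer into a learned soft binning of the input value.  For that reading a
    wide random init (``softmax_init_scale``) is essential: at Glorot scale
    the pre-activations are nearly equal, the softmax output is nearly
    uniform, and the downstream layers see almost no signal.
    """

    def __init__(self, in_features: int, filters: int, activation: str = "softmax",
                 rng: np.random.Generator | None = None, dtype=np.float64,
                 softmax_init_scale: float = 2.5):
        super().__init__()
        if activation not in ("softmax", "relu", "linear"):
            raise ValueError(f"unsupported activation {activation!r}")
        rng = rng or np.random.default_rng()
        self.activation = activation
        if activation == "softmax":
            self.params = {
                "W": rng.normal(0.0, softmax_init_scale, (in_features, filters)).astype(dtype),
                "b": rng.normal(0.0, softmax_init_scale, filters).astype(dtype),
            }
        else:
            self.params = {
                "W": _glorot_uniform(rng, in_features, filters).astype(dtype),
                "b": np.zeros(filters, dtype=dtype),
            }
        self.zero_grads()

    def forward(self, x, training=False):
        self._x = x
        z = x @ self.params["W"] + self.params["b"]
        if self.activation == "softmax":
            z = z - z.max(axis=-1, keepdims=True)
            e = np.exp(z)
            self._y = e / e.sum(axis=-1, keepdims=True)
        elif self.activation == "relu":
            self._y = np.maximum(z, 0.0)
        else:
            self._y = z
        return self._y

    def backward(self, dy):
        if self.activation == "softmax":
            y = self._y
            dz = y * (dy - (dy * y).sum(axis=-1, keepdims=True))
        elif self.activation == "relu":
            dz = dy * (self._y > 0)
        else:
            dz = dy
        flat_x = self._x.reshape(-1, self._x.shape[-1])
        flat_dz = dz.reshape(-1, dz.shape[-1])
        self.grads["W"] += flat_x.T @ flat_dz
        self.grads["b"] += flat_dz.sum(axis=0)
        return dz @ self.params["W"].T


class MaxPool1D(Layer):
    """Max pooling along time; with pool size 1 this is the identity, kept
    for architecture parity with the published layer stacks."""

    def __init__(self, pool_size: int = 1):
        super().__init__()
        if pool_size != 1:
            raise NotImplementedError("only pool_size=1 is used by these architectures")
        self.pool_size = pool_size

    def forward(self, x, training=False):
        return x

    def backward(self, dy):
        return dy


class SimpleRNN(Layer):
    """Elman RNN: h_t = tanh(x_t W + h_{t-1} U + b)."""

    def __init__(self, in_features: int, units: int, return_sequences: bool = False,
                 rng: np.random.Generator | None = None, dtype=np.float64):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.units = units
        self.return_sequences = return_sequences
        self.params = {
            "W": _glorot_uniform(rng, in_features, units).astype(dtype),
            "U": _orthogonal(rng, units, units).astype(dtype),
            "b": np.zeros(units, dtype=dtype),
        }
        self.zero_grads()

    def forward(self, x, training=False):
        B, T, _ = x.shape
        u = self.units
        xw = x @ self.params["W"] + self.params["b"]
        hs = np.empty((T, B, u), dtype=x.dtype)
        h = np.zeros((B, u), dtype=x.dtype)
        U = self.params["U"]
        for t in range(T):
            h = np.tanh(xw[:, t] + h @ U)
            hs[t] = h
        self._x, self._hs = x, hs
        return hs.transpose(1, 0, 2) if self.return_sequences else hs[-1]

    def backward(self, dy):
        x, hs = self._x, self._hs
        B, T, _ = x.shape
        u = self.units
        dz = np.empty((T, B, u), dtype=x.dtype)
        dh = np.zeros((B, u), dtype=x.dtype)
        U = self.params["U"]
        for t in range(T - 1, -1, -1):
            if self.return_sequences:
                dh = dh + dy[:, t]
            elif t == T - 1:
                dh = dh + dy
            d = dh * (1.0 - hs[t] ** 2)
            dz[t] = d
            dh = d @ U.T
        h_prev = np.concatenate([np.zeros((1, B, u), dtype=hs.dtype), hs[:-1]], axis=0)
        flat_dz = dz.reshape(-1, u)
        self.grads["W"] += x.transpose(1, 0, 2).reshape(-1, x.shape[-1]).T @ flat_dz
        self.grads["U"] += h_prev.reshape(-1, u).T @ flat_dz
        self.grads["b"] += flat_dz.sum(axis=0)
        return (dz.transpose(1, 0, 2)) @ self.params["W"].T


class LSTM(Layer):
    """Standard LSTM; gates are packed (input, forget, output, cell-candidate)
    so the three sigmoid gates share one contiguous activation call."""

    def __init__(self, in_features: int, units: int, return_sequences: bool = False,
                 rng: np.random.Generator | None = None, dtype=np.float64):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.units = units
        self.return_sequences = return_sequences
        b = np.zeros(4 * units, dtype=dtype)
        b[units : 2 * units] = 1.0  # forget-gate bias
        self.params = {
            "W": _glorot_uniform(rng, in_features, 4 * units, (in_features, 4 * units)).astype(dtype),
            "U": np.concatenate([_orthogonal(rng, units, units) for _ in range(4)], axis=1).astype(dtype),
            "b": b,
        }
        self.zero_grads()

    def forward(self, x, training=False):
        B, T, _ = x.shape
        u = self.units
        dt = x.dtype
        # time-major contiguous projections; the gate buffer is activated in
        # place step by step (xt[t] holds post-activation gates afterwards)
        xt = np.ascontiguousarray((x @ self.params["W"] + self.params["b"]).transpose(1, 0, 2))
        U = self.params["U"]
        hs = np.empty((T, B, u), dtype=dt)
        cs = np.empty((T, B, u), dtype=dt)
        tcs = np.empty((T, B, u), dtype=dt)
        h = np.zeros((B, u), dtype=dt)
        c = np.zeros((B, u), dtype=dt)
        for t in range(T):
            z = xt[t]
            z += h @ U
            zs = z[:, : 3 * u]
            np.negative(zs, out=zs)
            np.exp(zs, out=zs)
            zs += 1.0
            np.reciprocal(zs, out=zs)
            g = z[:, 3 * u :]
            np.tanh(g, out=g)
            i, f, o = z[:, :u], z[:, u : 2 * u], z[:, 2 * u : 3 * u]
            c_new = cs[t]
            np.multiply(f, c, out=c_new)
            c_new += i * g
            tc = tcs[t]
            np.tanh(c_new, out=tc)
            h = hs[t]
            np.multiply(o, tc, out=h)
            c = c_new
        self._x, self._gates, self._hs, self._cs, self._tcs = x, xt, hs, cs, tcs
        return np.ascontiguousarray(hs.transpose(1, 0, 2)) if self.return_sequences else hs[-1]

    def backward(self, dy):
        x, gates, hs, cs, tcs = self._x, self._gates, self._hs, self._cs, self._tcs
        B, T, _ = x.shape
        u = self.units
        dt = x.dtype
        U = self.params["U"]
        if self.return_sequences:
            dyt = np.ascontiguousarray(dy.transpose(1, 0, 2))
        dz = np.empty((T, B, 4 * u), dtype=dt)
        dh = np.zeros((B, u), dtype=dt)
        dc = np.zeros((B, u), dtype=dt)
        t1 = np.empty((B, u), dtype=dt)
        t2 = np.empty((B, u), dtype=dt)
        for t in range(T - 1, -1, -1):
            if self.return_sequences:
                dh += dyt[t]
            elif t == T - 1:
                dh = dh + dy
            z = gates[t]
            i, f, o, g = z[:, :u], z[:, u : 2 * u], z[:, 2 * u : 3 * u], z[:, 3 * u :]
            c_prev = cs[t - 1] if t > 0 else 0.0
            tc = tcs[t]
            d = dz[t]
            # output gate: dh * tc * o * (1 - o)
            np.multiply(dh, tc, out=t1)
            np.subtract(1.0, o, out=t2)
            t2 *= o
            np.multiply(t1, t2, out=d[:, 2 * u : 3 * u])
            # cell: dc += dh * o * (1 - tc^2)
            np.multiply(tc, tc, out=t1)
            np.subtract(1.0, t1, out=t1)
            t1 *= o
            t1 *= dh
            dc += t1
            # input gate: dc * g * i * (1 - i)
            np.subtract(1.0, i, out=t1)
            t1 *= i
            t1 *= g
            np.multiply(t1, dc, out=d[:, :u])
            # forget gate: dc * c_prev * f * (1 - f)
            np.subtract(1.0, f, out=t1)
            t1 *= f
            t1 *= c_prev
            np.multiply(t1, dc, out=d[:, u : 2 * u])
            # candidate: dc * i * (1 - g^2)
            np.multiply(g, g, out=t1)
            np.subtract(1.0, t1, out=t1)
            t1 *= i
            np.multiply(t1, dc, out=d[:, 3 * u :])
            dh = d @ U.T
            dc *= f
        h_prev = np.concatenate([np.zeros((1, B, u), dtype=hs.dtype), hs[:-1]], axis=0)
        flat_dz = dz.reshape(-1, 4 * u)
        self.grads["W"] += np.ascontiguousarray(x.transpose(1, 0, 2)).reshape(-1, x.shape[-1]).T @ flat_dz
        self.grads["U"] += h_prev.reshape(-1, u).T @ flat_dz
        self.grads["b"] += flat_dz.sum(axis=0)
        return (dz.transpose(1, 0, 2)) @ self.params["W"].T


class GRU(Layer):
    """GRU with gate order (update, reset, candidate).

    ``double_bias=True`` is the reset-after variant with separate input and
    recurrent bias vectors (3u(d+u+2) parameters); ``False`` is the classic
    single-bias form (3u(d+u+1) parameters).
    """

    def __init__(self, in_features: int, units: int, return_sequences: bool = False,
                 double_bias: bool = True, rng: np.random.Generator | None = None,
                 dtype=np.float64):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.units = units
        self.return_sequences = return_sequences
        self.double_bias = double_bias
        self.params = {
            "W": _glorot_uniform(rng, in_features, 3 * units, (in_features, 3 * units)).astype(dtype),
            "U": np.concatenate([_orthogonal(rng, units, units) for _ in range(3)], axis=1).astype(dtype),
            "b": np.zeros(3 * units, dtype=dtype),
        }
        if double_bias:
            self.params["b_rec"] = np.zeros(3 * units, dtype=dtype)
        self.zero_grads()

    def forward(self, x, training=False):
        B, T, _ = x.shape
        u = self.units
        xw = x @ self.params["W"] + self.params["b"]
        U = self.params["U"]
        hs = np.empty((T, B, u), dtype=x.dtype)
        cache = []
        h = np.zeros((B, u), dtype=x.dtype)
        if self.double_bias:
            b_rec = self.params["b_rec"]
            xt = np.ascontiguousarray(xw.transpose(1, 0, 2))
            for t in range(T):
                rec = h @ U
                rec += b_rec
                zr = xt[t, :, : 2 * u]
                zr += rec[:, : 2 * u]
                np.negative(zr, out=zr)
                np.exp(zr, out=zr)
                zr += 1.0
                np.reciprocal(zr, out=zr)
                z, r = zr[:, :u], zr[:, u : 2 * u]
                hh = xt[t, :, 2 * u :]
                hh += r * rec[:, 2 * u :]
                np.tanh(hh, out=hh)
                h_prev = h
                h = z * h_prev + (1.0 - z) * hh
                hs[t] = h
                cache.append((z, r, hh, h_prev, rec[:, 2 * u :]))
        else:
            Uz, Ur, Uh = U[:, :u], U[:, u : 2 * u], U[:, 2 * u :]
            for t in range(T):
                z = _sigmoid(xw[:, t, :u] + h @ Uz)
                r = _sigmoid(xw[:, t, u : 2 * u] + h @ Ur)
                rh = r * h
                hh = np.tanh(xw[:, t, 2 * u :] + rh @ Uh)
                h_prev = h
                h = z * h_prev + (1.0 - z) * hh
                hs[t] = h
                cache.append((z, r, hh, h_prev, rh))
        self._x, self._hs, self._cache = x, hs, cache
        return hs.transpose(1, 0, 2) if self.return_sequences else hs[-1]

    def backward(self, dy):
        x, hs, cache = self._x, self._hs, self._cache
        B, T, _ = x.shape
        u = self.units
        U = self.params["U"]
        dxz = np.empty((T, B, 3 * u), dtype=x.dtype)
        dh = np.zeros((B, u), dtype=x.dtype)
        if self.double_bias:
            drec_all = np.empty((T, B, 3 * u), dtype=x.dtype)
            if self.return_sequences:
                dyt = np.ascontiguousarray(dy.transpose(1, 0, 2))
            t1 = np.empty((B, u), dtype=x.dtype)
            t2 = np.empty((B, u), dtype=x.dtype)
            for t in range(T - 1, -1, -1):
                if self.return_sequences:
                    dh += dyt[t]
                elif t == T - 1:
                    dh = dh + dy
                z, r, hh, h_prev, rec_h = cache[t]
                d_in, d_rec = dxz[t], drec_all[t]
                # update gate: dh * (h_prev - hh) * z * (1 - z)
                np.subtract(h_prev, hh, out=t1)
                t1 *= dh
                np.subtract(1.0, z, out=t2)
                t2 *= z
                t1 *= t2
                d_in[:, :u] = d_rec[:, :u] = t1
                # candidate pre-tanh: dh * (1 - z) * (1 - hh^2)
                np.multiply(hh, hh, out=t1)
                np.subtract(1.0, t1, out=t1)
                np.subtract(1.0, z, out=t2)
                t1 *= t2
                t1 *= dh
                da = d_in[:, 2 * u :]
                da[...] = t1
                # reset gate: da * rec_h * r * (1 - r)
                np.subtract(1.0, r, out=t1)
                t1 *= r
                t1 *= rec_h
                t1 *= da
                d_in[:, u : 2 * u] = d_rec[:, u : 2 * u] = t1
                np.multiply(da, r, out=d_rec[:, 2 * u :])
                dh = dh * z + d_rec @ U.T
            h_prev_all = np.concatenate([np.zeros((1, B, u), dtype=hs.dtype), hs[:-1]], axis=0)
            flat_drec = drec_all.reshape(-1, 3 * u)
            self.grads["U"] += h_prev_all.reshape(-1, u).T @ flat_drec
            self.grads["b_rec"] += flat_drec.sum(axis=0)
        else:
            Uz, Ur, Uh = U[:, :u], U[:, u : 2 * u], U[:, 2 * u :]
            dU = np.zeros_like(U)
            rh_all = np.empty((T, B, u), dtype=x.dtype)
            for t in range(T - 1, -1, -1):
                if self.return_sequences:
                    dh = dh + dy[:, t]
                elif t == T - 1:
                    dh = dh + dy
                z, r, hh, h_prev, rh = cache[t]
                rh_all[t] = rh
                d_in = dxz[t]
                dz_pre = d_in[:, :u] = dh * (h_prev - hh) * z * (1.0 - z)
                da = d_in[:, 2 * u :] = dh * (1.0 - z) * (1.0 - hh * hh)
                drh = da @ Uh.T
                dr_pre = d_in[:, u : 2 * u] = drh * h_prev * r * (1.0 - r)
                dh = dh * z + dz_pre @ Uz.T + dr_pre @ Ur.T + drh * r
            h_prev_all = np.concatenate([np.zeros((1, B, u), dtype=hs.dtype), hs[:-1]], axis=0)
            flat_h_prev = h_prev_all.reshape(-1, u)
            dU[:, :u] = flat_h_prev.T @ dxz[:, :, :u].reshape(-1, u)
            dU[:, u : 2 * u] = flat_h_prev.T @ dxz[:, :, u : 2 * u].reshape(-1, u)
            dU[:, 2 * u :] = rh_all.reshape(-1, u).T @ dxz[:, :, 2 * u :].reshape(-1, u)
            self.grads["U"] += dU
        flat_dxz = dxz.reshape(-1, 3 * u)
        self.grads["W"] += x.transpose(1, 0, 2).reshape(-1, x.shape[-1]).T @ flat_dxz
        self.grads["b"] += flat_dxz.sum(axis=0)
        return (dxz.transpose(1, 0, 2)) @ self.params["W"].T


class Bidirectional(Layer):
    """Concatenates a forward and a time-reversed copy of a recurrent layer."""

    def __init__(self, forward_layer: Layer, backward_layer: Layer):
        super().__init__()
        if forward_layer.return_sequences != backward_layer.return_sequences:
            raise ValueError("forward/backward layers must agree on return_sequences")
        self.fwd = forward_layer
        self.bwd = backward_layer
        self.return_sequences = forward_layer.return_sequences

    @property
    def params(self):  # type: ignore[override]
        return {f"fwd_{k}": v for k, v in self.fwd.params.items()} | {
            f"bwd_{k}": v for k, v in self.bwd.params.items()
        }

    @params.setter
    def params(self, value):
        if value:
            raise AttributeError("set parameters on the wrapped layers")

    @property
    def grads(self):  # type: ignore[override]
        return {f"fwd_{k}": v for k, v in self.fwd.grads.items()} | {
            f"bwd_{k}": v for k, v in self.bwd.grads.items()
        }

    @grads.setter
    def grads(self, value):
        if value:
            raise AttributeError("set gradients on the wrapped layers")

    def zero_grads(self):
        self.fwd.zero_grads()
        self.bwd.zero_grads()

    def forward(self, x, training=False):
        yf = self.fwd.forward(x, training)
        yb = self.bwd.forward(x[:, ::-1], training)
        if self.return_sequences:
            return np.concatenate([yf, yb[:, ::-1]], axis=-1)
        return np.concatenate([yf, yb], axis=-1)

    def backward(self, dy):
        k = dy.shape[-1] // 2
        if self.return_sequences:
            dyf, dyb = dy[..., :k], dy[:, ::-1, k:]
        else:
            dyf, dyb = dy[..., :k], dy[..., k:]
        dxf = self.fwd.backward(dyf)
        dxb = self.bwd.backward(dyb)
        return dxf + dxb[:, ::-1]


class Dropout(Layer):
    """Inverted dropout; identity at inference."""

    def __init__(self, rate: float, rng: np.random.Generator | None = None):
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"dropout rate must be in [0, 1), got {rate}")
        self.rate = rate
        self.rng = rng or np.random.default_rng()

    def forward(self, x, training=False):
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        self._mask = self.rng.random(x.shape) >= self.rate
        return x * self._mask / (1.0 - self.rate)

    def backward(self, dy):
        if self._mask is None:
            return dy
        return dy * self._mask / (1.0 - self.rate)


class Dense(Layer):
    """Fully connected layer; ``backward`` takes the gradient w.r.t. the
    pre-activation so the sigmoid can be fused with the BCE loss."""

    def __init__(self, in_features: int, units: int = 1, activation: str = "sigmoid",
                 rng: np.random.Generator | None = None, dtype=np.float64):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.activation = activation
        self.params = {
            "W": _glorot_uniform(rng, in_features, units).astype(dtype),
            "b": np.zeros(units, dtype=dtype),
        }
        self.zero_grads()

    def forward(self, x, training=False):
        self._x = x
        z = x @ self.params["W"] + self.params["b"]
        return _sigmoid(z) if self.activation == "sigmoid" else z

    def backward(self, dz):
        self.grads["W"] += self._x.T @ dz
        self.grads["b"] += dz.sum(axis=0)
        return dz @ self.params["W"].T


class Adam:
    """Adam with the common framework defaults (lr 1e-3, betas 0.9/0.999)."""

    def __init__(self, layers: list[Layer], lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-7):
        self.layers = layers
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [{k: np.zeros_like(v) for k, v in lay.params.items()} for lay in layers]
        self.v = [{k: np.zeros_like(v) for k, v in lay.params.items()} for lay in layers]

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for lay, m, v in zip(self.layers, self.m, self.v):
            grads = lay.grads
            for k, p in lay.params.items():
                g = grads[k]
                m[k] = self.beta1 * m[k] + (1.0 - self.beta1) * g
                v[k] = self.beta2 * v[k] + (1.0 - self.beta2) * g * g
                p -= self.lr * (m[k] / b1t) / (np.sqrt(v[k] / b2t) + self.eps)


def bce_loss(p: np.ndarray, y: np.ndarray, eps: float = 1e-12) -> float:
    p = np.clip(p, eps, 1.0 - eps)
    return float(-np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))
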