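"""Differentiable layer primitives and the sequential network container.

All layers implement ``forward(x, seg_ids)`` and ``backward(grad_out)`` with
explicit numpy gradients; ``seg_ids`` labels each time bin with its stimulus
snippet so that temporal convolutions never bleed across snippet boundaries
(each snippet is zero-padded independently).

Everything is float64 and fully deterministic: identical parameters and
stimulus give bitwise-identical outputs.
"""

from __future__ import annotations

import numba
import numpy as np

WIDTH_FLOOR = 0.25          # minimum Gaussian spectral width, channel units
_EXP_CLIP = 60.0            # inner-exponent clip for the double exponential


_LAYOUT_CACHE: dict = {}


def _conv_layout(seg_ids: np.ndarray, U: int):
    """Per-bin valid-lag bounds for causal convolution with per-snippet
    zero padding.

    ``back[t]`` is the number of lags u (0-based, < U) for which t-u stays
    inside bin t's snippet; ``fwd[t]`` the same for leads t+u (used by the
    input gradient).  Cached per (segment structure, U).
    """
    key = (seg_ids.tobytes(), U)
    hit = _LAYOUT_CACHE.get(key)
    if hit is not None:
        return hit
    T = seg_ids.size
    idx = np.arange(T)
    new_seg = np.concatenate([[True], seg_ids[1:] != seg_ids[:-1]])
    seg_start = idx[new_seg][np.cumsum(new_seg) - 1]
    ends = np.concatenate([idx[new_seg][1:] - 1, [T - 1]])
    seg_end = ends[np.cumsum(new_seg) - 1]
    back = np.minimum(U, idx - seg_start + 1).astype(np.int64)
    fwd = np.minimum(U, seg_end - idx + 1).astype(np.int64)
    layout = (back, fwd)
    _LAYOUT_CACHE[key] = layout
    return layout


@numba.njit(cache=True)
def _cc_forward(z, taps, back):
    C, T = z.shape
    out = np.zeros_like(z)
    for c in range(C):
        for t in range(T):
            acc = z[c, t] * 0
            for u in range(back[t]):
                acc += taps[c, u] * z[c, t - u]
            out[c, t] = acc
    return out


@numba.njit(cache=True)
def _cc_backward(z, taps, grad_out, back, fwd):
    C, T = z.shape
    U = taps.shape[1]
    grad_taps = np.zeros_like(taps)
    grad_z = np.zeros_like(z)
    for c in range(C):
        for t in range(T):
            g = grad_out[c, t]
            for u in range(back[t]):
                grad_taps[c, u] += g * z[c, t - u]
        for t in range(T):
            acc = z[c, t] * 0
            for u in range(fwd[t]):
                acc += taps[c, u] * grad_out[c, t + u]
            grad_z[c, t] = acc
    return grad_taps, grad_z


def _causal_conv(z: np.ndarray, taps: np.ndarray, seg_ids: np.ndarray,
                 cache: dict | None = None) -> np.ndarray:
    """Per-channel causal FIR convolution with per-snippet zero padding.

    out[c, t] = sum_u taps[c, u] * z[c, t - u], dropping terms whose t-u
    falls in a different snippet.
    """
    back, _ = _conv_layout(seg_ids, taps.shape[1])
    return _cc_forward(np.ascontiguousarray(z),
                       np.ascontiguousarray(taps.astype(z.dtype)), back)


def _causal_conv_grads(z, taps, grad_out, seg_ids, cache: dict | None = None):
    """Gradients of :func:`_causal_conv` w.r.t. taps and input."""
    back, fwd = _conv_layout(seg_ids, taps.shape[1])
    gt, gz = _cc_backward(np.ascontiguousarray(z),
                          np.ascontiguousarray(taps.astype(z.dtype)),
                          np.ascontiguousarray(grad_out), back, fwd)
    return gt, gz


class Layer:
    """Base class; parameters live in ``self.params`` (ordered dict)."""

    def __init__(self):
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def zero_grads(self):
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}

    @property
    def n_params(self) -> int:
        return sum(v.size for v in self.params.values())

    def forward(self, x, seg_ids):      # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, grad_out):       # pragma: no cover - abstract
        raise NotImplementedError


class Conv1D(Layer):
    """Bank of 1-D convolutional units: spectral weighting, causal temporal
    FIR, optional offset-ReLU activation.

    ``spectral='gaussian'`` constrains each unit's weighting over the F input
    channels to an unnormalized Gaussian ``g_j = exp(-(j-mu)^2 / (2 sigma^2))``
    parameterized by center ``mu`` and width ``sigma`` in channel-index units
    (amplitude is absorbed by the temporal taps).  ``spectral='dense'`` uses
    unconstrained weights over input channels (deeper layers).
    The width is floored at ``WIDTH_FLOOR`` channels.
    """

    def __init__(self, n_units, n_taps, n_in, spectral="gaussian",
                 activation="relu"):
        super().__init__()
        if spectral not in ("gaussian", "dense"):
            raise ValueError(spectral)
        self.n_units, self.n_taps, self.n_in = n_units, n_taps, n_in
        self.spectral, self.activation = spectral, activation
        if spectral == "gaussian":
            self.params["mu"] = np.full(n_units, (n_in - 1) / 2.0)
            self.params["sigma"] = np.full(n_units, n_in / 4.0)
        else:
            self.params["w"] = np.zeros((n_units, n_in))
        self.params["taps"] = np.zeros((n_units, n_taps))
        if activation == "relu":
            self.params["offset"] = np.zeros(n_units)
        self.zero_grads()

    # -- spectral weight matrix ------------------------------------------
    def weight_matrix(self):
        if self.spectral == "dense":
            return self.params["w"]
        j = np.arange(self.n_in)
        mu = self.params["mu"][:, None]
        sig = np.maximum(self.params["sigma"], WIDTH_FLOOR)[:, None]
        return np.exp(-((j - mu) ** 2) / (2.0 * sig**2))

    def forward(self, x, seg_ids):
        self._x = x
        self._seg = seg_ids
        W = self.weight_matrix()
        self._W = W
        self._z = W @ x
        self._cache = {}
        self._y = _causal_conv(self._z, self.params["taps"], seg_ids,
                               self._cache)
        if self.activation == "relu":
            pre = self._y - self.params["offset"][:, None]
            self._mask = pre > 0
            return np.where(self._mask, pre, 0.0)
        return self._y

    def backward(self, grad_out):
        if self.activation == "relu":
            grad_out = grad_out * self._mask
            self.grads["offset"] -= grad_out.sum(axis=1)
        gt, gz = _causal_conv_grads(self._z, self.params["taps"], grad_out,
                                    self._seg, self._cache)
        self.grads["taps"] += gt
        gW = gz @ self._x.T
        if self.spectral == "dense":
            self.grads["w"] += gW
        else:
            j = np.arange(self.n_in)
            mu = self.params["mu"][:, None]
            sig_raw = self.params["sigma"]
            sig = np.maximum(sig_raw, WIDTH_FLOOR)[:, None]
            diff = j - mu
            dmu = self._W * diff / sig**2
            dsig = self._W * diff**2 / sig**3
            dsig[sig_raw < WIDTH_FLOOR, :] = 0.0   # clamped: no gradient
            self.grads["mu"] += (gW * dmu).sum(axis=1)
            self.grads["sigma"] += (gW * dsig).sum(axis=1)
        return self._W.T @ gz


class Conv2D(Layer):
    """2-D convolutional layer: joint spectro-temporal kernels.

    Input is (C_in, F, T); each output unit integrates a ``kf x kt`` kernel
    over every input channel.  Causal in time (output at t sees t-kt+1..t),
    'same' zero padding in frequency, offset-ReLU activation.
    """

    def __init__(self, n_units, n_in, kf=3, kt=8, activation="relu"):
        super().__init__()
        self.n_units, self.n_in, self.kf, self.kt = n_units, n_in, kf, kt
        self.activation = activation
        self.params["kernel"] = np.zeros((n_units, n_in, kf, kt))
        if activation == "relu":
            self.params["offset"] = np.zeros(n_units)
        self.zero_grads()

    def forward(self, x, seg_ids):
        if x.ndim == 2:                 # raw spectrogram -> single channel
            x = x[None]
        I, F, T = x.shape
        if F < self.kf:
            raise ValueError("fewer frequency rows than the kernel height")
        self._seg = seg_ids
        pf = self.kf // 2
        xp = np.pad(x, ((0, 0), (pf, self.kf - 1 - pf), (0, 0)))
        self._xp = xp
        K = self.params["kernel"]
        out = np.zeros((self.n_units, F, T), dtype=x.dtype)
        for a in range(self.kf):
            xa = xp[:, a : a + F, :]
            out += np.einsum("oi,ift->oft", K[:, :, a, 0], xa)
            for b in range(1, min(self.kt, T)):
                valid = seg_ids[b:] == seg_ids[:-b]
                out[:, :, b:] += np.einsum("oi,ift->oft", K[:, :, a, b],
                                           xa[:, :, :-b] * valid)
        self._y = out
        if self.activation == "relu":
            pre = out - self.params["offset"][:, None, None]
            self._mask = pre > 0
            return np.where(self._mask, pre, 0.0)
        return out

    def backward(self, grad_out):
        if self.activation == "relu":
            grad_out = grad_out * self._mask
            self.grads["offset"] -= grad_out.sum(axis=(1, 2))
        K = self.params["kernel"]
        O, Fq, T = grad_out.shape
        seg_ids = self._seg
        gxp = np.zeros_like(self._xp)
        gK = self.grads["kernel"]
        for a in range(self.kf):
            xa = self._xp[:, a : a + Fq, :]
            gK[:, :, a, 0] += np.einsum("oft,ift->oi", grad_out, xa)
            gxp[:, a : a + Fq, :] += np.einsum("oi,oft->ift", K[:, :, a, 0],
                                               grad_out)
            for b in range(1, min(self.kt, T)):
                valid = seg_ids[b:] == seg_ids[:-b]
                gm = grad_out[:, :, b:] * valid
                gK[:, :, a, b] += np.einsum("oft,ift->oi", gm, xa[:, :, :-b])
                gxp[:, a : a + Fq, :-b] += np.einsum("oi,oft->ift",
                                                     K[:, :, a, b], gm)
        pf = self.kf // 2
        F = self._xp.shape[1] - (self.kf - 1)
        gx = gxp[:, pf : pf + F, :]
        return gx


class Flatten(Layer):
    """(C, F, T) -> (C*F, T); no parameters."""

    def forward(self, x, seg_ids):
        self._shape = x.shape
        return x.reshape(-1, x.shape[-1])

    def backward(self, grad_out):
        return grad_out.reshape(self._shape)


class Dense(Layer):
    """Fully connected layer over channels, applied at every time bin.

    ``activation='relu'`` applies an offset ReLU ``max(0, Wx - offset)``;
    ``activation=None`` with ``bias=True`` gives the plain linear readout
    used as the temporary output during core-only fitting.
    """

    def __init__(self, n_out, n_in, activation="relu", bias=False):
        super().__init__()
        self.n_out, self.n_in = n_out, n_in
        self.activation, self.bias = activation, bias
        self.params["w"] = np.zeros((n_out, n_in))
        if activation == "relu":
            self.params["offset"] = np.zeros(n_out)
        elif bias:
            self.params["b"] = np.zeros(n_out)
        self.zero_grads()

    def forward(self, x, seg_ids):
        self._x = x
        y = self.params["w"] @ x
        if self.activation == "relu":
            pre = y - self.params["offset"][:, None]
            self._mask = pre > 0
            return np.where(self._mask, pre, 0.0)
        if self.bias:
            y = y + self.params["b"][:, None]
        return y

    def backward(self, grad_out):
        if self.activation == "relu":
            grad_out = grad_out * self._mask
            self.grads["offset"] -= grad_out.sum(axis=1)
        elif self.bias:
            self.grads["b"] += grad_out.sum(axis=1)
        self.grads["w"] += grad_out @ self._x.T
        return self.params["w"].T @ grad_out


class SumChannels(Layer):
    """Sum rank components into a single linear drive (LN model); no params."""

    def forward(self, x, seg_ids):
        self._n = x.shape[0]
        return x.sum(axis=0, keepdims=True)

    def backward(self, grad_out):
        return np.repeat(grad_out, self._n, axis=0)


class DoubleExp(Layer):
    """Per-output double-exponential nonlinearity.

    r = b + a * exp(-exp(k * (y - s))): baseline b, saturation amplitude a,
    threshold s, gain k.  The inner exponent is clipped to avoid overflow;
    the output is bounded between b and b + a for a > 0 and strictly
    monotone in y when a*k != 0.
    """

    def __init__(self, n_out):
        super().__init__()
        self.n_out = n_out
        self.params["b"] = np.zeros(n_out)
        self.params["a"] = np.ones(n_out)
        self.params["s"] = np.zeros(n_out)
        self.params["k"] = np.ones(n_out)
        self.zero_grads()

    def forward(self, x, seg_ids):
        b = self.params["b"][:, None]
        a = self.params["a"][:, None]
        s = self.params["s"][:, None]
        k = self.params["k"][:, None]
        z = np.clip(k * (x - s), -_EXP_CLIP, _EXP_CLIP)
        self._x = x
        self._e = np.exp(z)
        self._w = np.exp(-self._e)
        return b + a * self._w

    def backward(self, grad_out):
        a = self.params["a"][:, None]
        s = self.params["s"][:, None]
        k = self.params["k"][:, None]
        g_awe = grad_out * (a * (self._w * self._e))
        self.grads["b"] += grad_out.sum(axis=1)
        self.grads["a"] += (grad_out * self._w).sum(axis=1)
        self.grads["s"] += self.params["k"] * g_awe.sum(axis=1)
        self.grads["k"] -= (g_awe * (self._x - s)).sum(axis=1)
        return -k * g_awe


class Network:
    """Ordered stack of layers with flat parameter-vector access.

    ``output_start`` marks the first layer of the output block (the final
    per-neuron readout plus its nonlinearity); everything before it is the
    shared core.
    """

    def __init__(self, layers, output_start):
        self.layers = list(layers)
        self.output_start = output_start

    # -- execution --------------------------------------------------------
    def forward(self, x, seg_ids, upto=None):
        for lyr in self.layers[:upto]:
            x = lyr.forward(x, seg_ids)
        return x

    def backward(self, grad_out):
        g = grad_out
        for lyr in reversed(self.layers):
            g = lyr.backward(g)
        return g

    def zero_grads(self):
        for lyr in self.layers:
            lyr.zero_grads()

    # -- flat parameter access --------------------------------------------
    def param_items(self, layer_idx=None):
        idx = range(len(self.layers)) if layer_idx is None else layer_idx
        return [(i, name, self.layers[i].params[name])
                for i in idx for name in self.layers[i].params]

    def get_flat(self, layer_idx=None):
        items = self.param_items(layer_idx)
        if not items:
            return np.zeros(0)
        return np.concatenate([v.ravel() for _, _, v in items])

    def set_flat(self, vec, layer_idx=None):
        pos = 0
        for i, name, v in self.param_items(layer_idx):
            self.layers[i].params[name] = vec[pos : pos + v.size].reshape(v.shape).copy()
            pos += v.size
        if pos != vec.size:
            raise ValueError("parameter vector length mismatch")

    def grad_flat(self, layer_idx=None):
        items = self.param_items(layer_idx)
        return np.concatenate([self.layers[i].grads[name].ravel()
                               for i, name, _ in items])

    @property
    def n_params(self) -> int:
        return sum(l.n_params for l in self.layers)

    @property
    def core_indices(self):
        return list(range(self.output_start))

    @property
    def output_indices(self):
        return list(range(self.output_start, len(self.layers)))
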