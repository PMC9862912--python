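"""Minimal numpy neural-network kernel for the shallow EEG architecture.

Implements exactly the layer sequence needed by the shallow motor-imagery
decoder — temporal convolution (per-channel, strided), spatial convolution
(collapsing the electrode axis), batch normalization, square nonlinearity,
average pooling (stride 1), max pooling, safe log, dense softmax — together
with hand-written backpropagation and an Adam optimizer.  The variational
layer on top (weight sampling, KL gradients) lives in :mod:`bayesmi.model`;
this module is a plain deterministic computation graph whose weight arrays
can be overwritten in place between forward passes.

Data layout: inputs are ``(B, L, c)`` (batch, time, electrodes); all time
axes stay in position 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

LOG_EPS = 1e-6


@dataclass
class ArchitectureSpec:
    """Shape parameters of the shallow ConvNet.

    The derived shape chain at the defaults (input 1000 samples):
    temporal conv (45-tap, stride 2, valid) -> 478 time steps x c x 40;
    spatial conv (1 x c across all 40 maps) -> 478 x 1 x 40; average pool
    (45, stride 1) -> 434; max pool (8, stride 8) -> 54; dense input
    54 * 40 = 2160 features, independent of the electrode count c.
    """

    n_channels: int = 22
    n_classes: int = 4
    input_len: int = 1000
    temporal_filter_len: int = 45
    n_filters: int = 40
    temporal_stride: int = 2
    avg_pool_len: int = 45
    max_pool_len: int = 8
    max_pool_stride: int = 8

    def validate(self) -> None:
        if self.n_channels < 1:
            raise ValueError("need at least one channel")
        if self.n_classes < 2:
            raise ValueError("need at least two classes")
        if self.input_len < self.temporal_filter_len:
            raise ValueError("input shorter than the temporal filter")

    @property
    def temporal_out_len(self) -> int:
        return (self.input_len - self.temporal_filter_len) // self.temporal_stride + 1

    @property
    def avg_pool_out_len(self) -> int:
        return self.temporal_out_len - self.avg_pool_len + 1

    @property
    def max_pool_out_len(self) -> int:
        return self.avg_pool_out_len // self.max_pool_stride

    @property
    def dense_in(self) -> int:
        return self.max_pool_out_len * self.n_filters

    def shape_chain(self) -> dict[str, int]:
        return {
            "temporal_out_len": self.temporal_out_len,
            "avg_pool_out_len": self.avg_pool_out_len,
            "max_pool_out_len": self.max_pool_out_len,
            "dense_in": self.dense_in,
        }


class ShallowNet:
    """Deterministic shallow ConvNet with manual backprop.

    Weights live in :attr:`weights` (a name -> array dict) and may be
    overwritten in place (the variational wrapper does this per sample
    draw).  Batch-norm gamma/beta are ordinary point parameters; running
    mean/variance are tracked for inference mode.
    """

    WEIGHT_KEYS = ("temporal.W", "spatial.W", "dense.W", "dense.b")
    BN_KEYS = ("bn.gamma", "bn.beta")

    def __init__(self, spec: ArchitectureSpec, rng: np.random.Generator,
                 bn_momentum: float = 0.1):
        spec.validate()
        self.spec = spec
        self.bn_momentum = bn_momentum
        F, c, k = spec.n_filters, spec.n_channels, spec.temporal_filter_len

        def glorot(shape, fan_in, fan_out):
            lim = np.sqrt(6.0 / (fan_in + fan_out))
            return rng.uniform(-lim, lim, size=shape)

        self.weights: dict[str, np.ndarray] = {
            "temporal.W": glorot((k, F), k, F),
            "spatial.W": glorot((c, F, F), c * F, F),
            "dense.W": glorot((spec.dense_in, spec.n_classes),
                              spec.dense_in, spec.n_classes),
            "dense.b": np.zeros(spec.n_classes),
            "bn.gamma": np.ones(F),
            "bn.beta": np.zeros(F),
        }
        self.running_mean = np.zeros(F)
        self.running_var = np.ones(F)
        self._cache: dict = {}

    # ---- forward ---------------------------------------------------------

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Map ``(B, L, c)`` inputs to ``(B, s)`` logits."""
        spec, w, cache = self.spec, self.weights, {}
        if x.ndim != 3 or x.shape[1] != spec.input_len \
                or x.shape[2] != spec.n_channels:
            raise ValueError(
                f"expected input (B, {spec.input_len}, {spec.n_channels}), "
                f"got {x.shape}")

        # temporal conv: per-electrode windows x (k, F) filters
        xw = sliding_window_view(x, spec.temporal_filter_len, axis=1)
        xw = xw[:, ::spec.temporal_stride]              # (B, Tt, c, k)
        h = np.einsum("btck,kf->btcf", xw, w["temporal.W"], optimize=True)
        cache["xw"] = xw

        # spatial conv: mix electrodes and temporal maps -> (B, Tt, F)
        cache["h_sp_in"] = h
        h = np.einsum("btcf,cfg->btg", h, w["spatial.W"], optimize=True)

        # batch norm over (B, T) per feature map
        if train:
            mean = h.mean(axis=(0, 1))
            var = h.var(axis=(0, 1))
            m = self.bn_momentum
            self.running_mean = (1 - m) * self.running_mean + m * mean
            self.running_var = (1 - m) * self.running_var + m * var
        else:
            mean, var = self.running_mean, self.running_var
        inv_sd = 1.0 / np.sqrt(var + 1e-5)
        hhat = (h - mean) * inv_sd
        cache["bn"] = (hhat, inv_sd)
        h = w["bn.gamma"] * hhat + w["bn.beta"]

        # square
        cache["sq_in"] = h
        h = h * h

        # average pool, stride 1 (via cumulative sums)
        A = spec.avg_pool_len
        cs = np.cumsum(h, axis=1)
        cs = np.concatenate([np.zeros_like(cs[:, :1]), cs], axis=1)
        h = (cs[:, A:] - cs[:, :-A]) / A                # (B, Ta, F)

        # max pool, stride = width
        M, S = spec.max_pool_len, spec.max_pool_stride
        n_out = spec.max_pool_out_len
        hb = h[:, :n_out * S].reshape(h.shape[0], n_out, S, -1)
        amax = hb.argmax(axis=2)
        cache["max"] = (amax, h.shape)
        h = np.take_along_axis(hb, amax[:, :, None, :], axis=2)[:, :, 0, :]

        # safe log
        cache["log_in"] = h
        h = np.log(h + LOG_EPS)

        # dense
        z = h.reshape(h.shape[0], -1)
        cache["dense_in"] = z
        logits = z @ w["dense.W"] + w["dense.b"]
        self._cache = cache
        return logits

    def predict_proba(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        return softmax(self.forward(x, train=train))

    # ---- backward --------------------------------------------------------

    def backward(self, dlogits: np.ndarray) -> dict[str, np.ndarray]:
        """Gradients of the loss w.r.t. every entry of :attr:`weights`,
        given the gradient at the logits of the last forward pass."""
        spec, w, cache = self.spec, self.weights, self._cache
        g: dict[str, np.ndarray] = {}

        z = cache["dense_in"]
        g["dense.W"] = z.T @ dlogits
        g["dense.b"] = dlogits.sum(axis=0)
        dh = (dlogits @ w["dense.W"].T).reshape(
            -1, spec.max_pool_out_len, spec.n_filters)

        dh = dh / (cache["log_in"] + LOG_EPS)           # safe log

        # max pool backward: scatter into the avg-pool output grid
        amax, avg_shape = cache["max"]
        M, S = spec.max_pool_len, spec.max_pool_stride
        n_out = spec.max_pool_out_len
        davg = np.zeros(avg_shape)
        db = davg[:, :n_out * S].reshape(avg_shape[0], n_out, S, -1)
        np.put_along_axis(db, amax[:, :, None, :], dh[:, :, None, :], axis=2)

        # average pool backward: each input step collects the mean-grad of
        # every window covering it (cumulative-sum trick)
        A = spec.avg_pool_len
        Tt = spec.temporal_out_len
        cs = np.cumsum(davg, axis=1)
        cs = np.concatenate([np.zeros_like(cs[:, :1]), cs], axis=1)
        idx_hi = np.minimum(np.arange(Tt) + 1, davg.shape[1])
        idx_lo = np.maximum(np.arange(Tt) - A + 1, 0)
        dsq = (cs[:, idx_hi] - cs[:, idx_lo]) / A       # (B, Tt, F)

        dsq = dsq * 2.0 * cache["sq_in"]                # square

        # batch norm backward (batch statistics)
        hhat, inv_sd = cache["bn"]
        g["bn.gamma"] = (dsq * hhat).sum(axis=(0, 1))
        g["bn.beta"] = dsq.sum(axis=(0, 1))
        n = hhat.shape[0] * hhat.shape[1]
        dxhat = dsq * w["bn.gamma"]
        dbn = inv_sd / n * (n * dxhat - dxhat.sum(axis=(0, 1))
                            - hhat * (dxhat * hhat).sum(axis=(0, 1)))

        # spatial conv backward
        h_in = cache["h_sp_in"]
        g["spatial.W"] = np.einsum("btg,btcf->cfg", dbn, h_in, optimize=True)
        dtc = np.einsum("btg,cfg->btcf", dbn, w["spatial.W"], optimize=True)

        # temporal conv backward (no input gradient needed)
        g["temporal.W"] = np.einsum("btcf,btck->kf", dtc, cache["xw"],
                                    optimize=True)
        return g

    # ---- state -----------------------------------------------------------

    def copy_weights(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.weights.items()}

    def set_weights(self, weights: dict[str, np.ndarray]) -> None:
        for k, v in weights.items():
            self.weights[k] = np.array(v, dtype=np.float64)

    def bn_state(self) -> tuple[np.ndarray, np.ndarray]:
        return self.running_mean.copy(), self.running_var.copy()

    def set_bn_state(self, state: tuple[np.ndarray, np.ndarray]) -> None:
        self.running_mean, self.running_var = (np.array(s) for s in state)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy(probs: np.ndarray, labels: np.ndarray) -> float:
    """Mean categorical cross-entropy (natural log), labels as int indices."""
    p = probs[np.arange(len(labels)), labels]
    return float(-np.mean(np.log(np.maximum(p, 1e-12))))


def softmax_ce_grad(logits: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    """Loss value and gradient at the logits of mean softmax cross-entropy."""
    probs = softmax(logits)
    loss = cross_entropy(probs, labels)
    grad = probs.copy()
    grad[np.arange(len(labels)), labels] -= 1.0
    return loss, grad / len(labels)


class Adam:
    """Adam optimizer over a dict of parameter arrays (updated in place)."""

    def __init__(self, params: dict[str, np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, gk in grads.items():
            self.m[k] = b1 * self.m[k] + (1 - b1) * gk
            self.v[k] = b2 * self.v[k] + (1 - b2) * gk * gk
            mhat = self.m[k] / (1 - b1 ** self.t)
            vhat = self.v[k] / (1 - b2 ** self.t)
            self.params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
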