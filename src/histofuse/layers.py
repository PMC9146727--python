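"""Layer semantics for the six-branch histology CNN.

Activations are NHWC arrays (a leading batch axis; single HWC images are
accepted and returned without the batch axis).  Convolution is
cross-correlation with stride, zero padding ("same"/"valid"), dilation and
channel groups.  Every operation used by the trainer also has an explicit
backward pass so the network can be fitted with plain SGD on a CPU.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "conv2d",
    "relu",
    "maxpool",
    "global_maxpool",
    "batchnorm",
    "softmax",
    "cross_entropy",
    "BatchNormParams",
]


# ---------------------------------------------------------------------------
# padding helpers


def _pair(v):
    if np.isscalar(v):
        return (int(v), int(v))
    return (int(v[0]), int(v[1]))


def _pad_1d(size: int, k_eff: int, stride: int, padding: str) -> tuple[int, int]:
    if padding == "same":
        out = -(-size // stride)  # ceil
        total = max((out - 1) * stride + k_eff - size, 0)
        return total // 2, total - total // 2
    if padding == "valid":
        return 0, 0
    raise ValueError(f"unknown padding {padding!r}")


def _out_size(size: int, k_eff: int, stride: int, pad: tuple[int, int]) -> int:
    return (size + pad[0] + pad[1] - k_eff) // stride + 1


def _windows(x, kh, kw, stride, dilation, padding, fill=0.0):
    """Extract (N, Ho, Wo, kh, kw, C) patch windows from NHWC ``x``."""
    sh, sw_ = _pair(stride)
    dh, dw = _pair(dilation)
    kh_eff = (kh - 1) * dh + 1
    kw_eff = (kw - 1) * dw + 1
    ph = _pad_1d(x.shape[1], kh_eff, sh, padding)
    pw = _pad_1d(x.shape[2], kw_eff, sw_, padding)
    Hp = x.shape[1] + ph[0] + ph[1]
    Wp = x.shape[2] + pw[0] + pw[1]
    if kh_eff > Hp or kw_eff > Wp:
        raise ValueError(
            f"window {kh_eff}x{kw_eff} larger than padded input {Hp}x{Wp}"
        )
    xp = np.pad(x, ((0, 0), ph, pw, (0, 0)), constant_values=fill)
    win = sliding_window_view(xp, (kh_eff, kw_eff), axis=(1, 2))
    win = win[:, ::sh, ::sw_, :, ::dh, ::dw]          # (N,Ho,Wo,C,kh,kw)
    win = win.transpose(0, 1, 2, 4, 5, 3)             # (N,Ho,Wo,kh,kw,C)
    meta = dict(pad_h=ph, pad_w=pw, padded=(Hp, Wp), stride=(sh, sw_),
                dilation=(dh, dw), ksize=(kh, kw))
    return win, meta


def _scatter_windows(dwin, x_shape, meta):
    """Adjoint of :func:`_windows`: scatter-add window gradients back."""
    N, H, W, C = x_shape
    (sh, sw_), (dh, dw) = meta["stride"], meta["dilation"]
    kh, kw = meta["ksize"]
    Hp, Wp = meta["padded"]
    Ho, Wo = dwin.shape[1], dwin.shape[2]
    dxp = np.zeros((N, Hp, Wp, C), dtype=dwin.dtype)
    for i in range(kh):
        for j in range(kw):
            dxp[:, i * dh:i * dh + Ho * sh:sh,
                j * dw:j * dw + Wo * sw_:sw_, :] += dwin[:, :, :, i, j, :]
    ph, pw = meta["pad_h"], meta["pad_w"]
    return dxp[:, ph[0]:Hp - ph[1], pw[0]:Wp - pw[1], :]


def _batched(x):
    x = np.asarray(x)
    if x.ndim == 3:
        return x[None], True
    if x.ndim == 4:
        return x, False
    raise ValueError(f"expected HWC or NHWC activation, got ndim={x.ndim}")


# ---------------------------------------------------------------------------
# convolution


def conv2d_forward(x, w, b, stride=(1, 1), padding="same", dilation=(1, 1),
                   groups=1):
    x, squeeze = _batched(x)
    w = np.asarray(w)
    if w.ndim != 4:
        raise ValueError("weights must be (kh, kw, c_in/groups, c_out)")
    kh, kw, cin_g, cout = w.shape
    N, H, W, Cin = x.shape
    if cin_g * groups != Cin:
        raise ValueError(
            f"input channels {Cin} incompatible with kernel depth {cin_g} "
            f"x groups {groups}"
        )
    if cout % groups:
        raise ValueError("output channels must divide evenly into groups")
    win, meta = _windows(x, kh, kw, stride, dilation, padding)
    Ho, Wo = win.shape[1], win.shape[2]
    cout_g = cout // groups
    y = np.empty((N, Ho, Wo, cout), dtype=np.result_type(x, w))
    for g in range(groups):
        cols = win[..., g * cin_g:(g + 1) * cin_g].reshape(N * Ho * Wo, -1)
        wg = w[:, :, :, g * cout_g:(g + 1) * cout_g].reshape(-1, cout_g)
        y[..., g * cout_g:(g + 1) * cout_g] = (cols @ wg).reshape(N, Ho, Wo, cout_g)
    if b is not None:
        y += np.asarray(b).reshape(1, 1, 1, cout)
    cache = dict(win=win, meta=meta, x_shape=x.shape, w=w, groups=groups,
                 squeeze=squeeze)
    return (y[0] if squeeze else y), cache


def conv2d(x, w, b=None, stride=(1, 1), padding="same", dilation=(1, 1),
           groups=1):
    """Cross-correlate ``x`` with filter bank ``w`` plus bias ``b``."""
    y, _ = conv2d_forward(x, w, b, stride, padding, dilation, groups)
    return y


def conv2d_backward(dy, cache):
    dy, _ = _batched(dy)
    win, meta, w = cache["win"], cache["meta"], cache["w"]
    groups = cache["groups"]
    kh, kw, cin_g, cout = w.shape
    cout_g = cout // groups
    N, Ho, Wo = dy.shape[:3]
    dwin = np.empty_like(win, dtype=dy.dtype)
    dw = np.empty_like(w, dtype=dy.dtype)
    for g in range(groups):
        cols = win[..., g * cin_g:(g + 1) * cin_g].reshape(N * Ho * Wo, -1)
        dyg = dy[..., g * cout_g:(g + 1) * cout_g].reshape(N * Ho * Wo, cout_g)
        wg = w[:, :, :, g * cout_g:(g + 1) * cout_g].reshape(-1, cout_g)
        dw[:, :, :, g * cout_g:(g + 1) * cout_g] = (cols.T @ dyg).reshape(
            kh, kw, cin_g, cout_g)
        dwin[..., g * cin_g:(g + 1) * cin_g] = (dyg @ wg.T).reshape(
            N, Ho, Wo, kh, kw, cin_g)
    db = dy.sum(axis=(0, 1, 2))
    dx = _scatter_windows(dwin, cache["x_shape"], meta)
    return (dx[0] if cache["squeeze"] else dx), dw, db


# ---------------------------------------------------------------------------
# ReLU


def relu_forward(x):
    x = np.asarray(x)
    mask = x > 0
    return np.where(mask, x, 0), mask


def relu(x):
    """Elementwise max(0, x)."""
    return relu_forward(x)[0]


def relu_backward(dy, mask):
    return dy * mask


# ---------------------------------------------------------------------------
# max pooling


def maxpool_forward(x, window, stride=None, padding="valid"):
    x, squeeze = _batched(x)
    kh, kw = _pair(window)
    if kh < 1 or kw < 1:
        raise ValueError("pooling window must be >= 1")
    if stride is None:
        stride = (kh, kw)
    win, meta = _windows(x, kh, kw, stride, (1, 1), padding, fill=-np.inf)
    N, Ho, Wo = win.shape[:3]
    C = win.shape[-1]
    flat = win.transpose(0, 1, 2, 5, 3, 4).reshape(N, Ho, Wo, C, kh * kw)
    arg = flat.argmax(axis=-1)
    y = np.take_along_axis(flat, arg[..., None], axis=-1)[..., 0]
    cache = dict(arg=arg, meta=meta, x_shape=x.shape, ksize=(kh, kw),
                 squeeze=squeeze)
    return (y[0] if squeeze else y), cache


def maxpool(x, window, stride=None, padding="valid"):
    """Per-channel maximum over each window position."""
    return maxpool_forward(x, window, stride, padding)[0]


def maxpool_backward(dy, cache):
    dy, _ = _batched(dy)
    arg, meta = cache["arg"], cache["meta"]
    kh, kw = cache["ksize"]
    N, Ho, Wo, C = arg.shape
    dwin = np.zeros((N, Ho, Wo, kh, kw, C), dtype=dy.dtype)
    flat = dwin.transpose(0, 1, 2, 5, 3, 4).reshape(N, Ho, Wo, C, kh * kw)
    np.put_along_axis(flat, arg[..., None], dy[..., None], axis=-1)
    dwin = flat.reshape(N, Ho, Wo, C, kh, kw).transpose(0, 1, 2, 4, 5, 3)
    dx = _scatter_windows(dwin, cache["x_shape"], meta)
    return dx[0] if cache["squeeze"] else dx


def global_maxpool_forward(x):
    x, squeeze = _batched(x)
    N, H, W, C = x.shape
    flat = x.reshape(N, H * W, C)
    arg = flat.argmax(axis=1)
    y = np.take_along_axis(flat, arg[:, None, :], axis=1).reshape(N, 1, 1, C)
    cache = dict(arg=arg, x_shape=x.shape, squeeze=squeeze)
    return (y[0] if squeeze else y), cache


def global_maxpool(x):
    """Maximum over the whole spatial extent, one value per channel."""
    return global_maxpool_forward(x)[0]


def global_maxpool_backward(dy, cache):
    dy, _ = _batched(dy)
    N, H, W, C = cache["x_shape"]
    dflat = np.zeros((N, H * W, C), dtype=dy.dtype)
    np.put_along_axis(dflat, cache["arg"][:, None, :], dy.reshape(N, 1, C),
                      axis=1)
    dx = dflat.reshape(N, H, W, C)
    return dx[0] if cache["squeeze"] else dx


# ---------------------------------------------------------------------------
# batch normalisation


@dataclass
class BatchNormParams:
    """Learnable scale/shift plus running moments for one channel axis."""

    gamma: np.ndarray
    beta: np.ndarray
    epsilon: float = 1e-5
    running_mean: np.ndarray = None
    running_var: np.ndarray = None
    momentum: float = 0.1

    def __post_init__(self):
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        self.gamma = np.asarray(self.gamma, dtype=float)
        self.beta = np.asarray(self.beta, dtype=float)
        if self.running_mean is None:
            self.running_mean = np.zeros_like(self.gamma)
        if self.running_var is None:
            self.running_var = np.ones_like(self.gamma)


def batchnorm_forward(x, params: BatchNormParams, mode="train"):
    x = np.asarray(x)
    axes = tuple(range(x.ndim - 1))
    if mode == "train":
        if x.shape[0] < 2:
            raise ValueError("batch normalisation needs batch size >= 2 in train mode")
        mean = x.mean(axis=axes)
        var = x.var(axis=axes)  # biased, mini-batch population variance
        m = params.momentum
        params.running_mean = (1 - m) * params.running_mean + m * mean
        params.running_var = (1 - m) * params.running_var + m * var
    elif mode == "infer":
        mean, var = params.running_mean, params.running_var
    else:
        raise ValueError(f"unknown mode {mode!r}")
    inv_std = 1.0 / np.sqrt(var + params.epsilon)
    xhat = (x - mean) * inv_std
    y = params.gamma * xhat + params.beta
    cache = dict(xhat=xhat, inv_std=inv_std, gamma=params.gamma, axes=axes,
                 n=int(np.prod([x.shape[a] for a in axes])), mode=mode)
    return y, cache


def batchnorm(x, params: BatchNormParams, mode="train"):
    """Normalise per channel with mini-batch moments, then scale and shift."""
    return batchnorm_forward(x, params, mode)[0]


def batchnorm_backward(dy, cache):
    xhat, inv_std, gamma = cache["xhat"], cache["inv_std"], cache["gamma"]
    axes, n = cache["axes"], cache["n"]
    dgamma = (dy * xhat).sum(axis=axes)
    dbeta = dy.sum(axis=axes)
    if cache["mode"] == "infer":
        return dy * gamma * inv_std, dgamma, dbeta
    dxhat = dy * gamma
    dx = (inv_std / n) * (
        n * dxhat - dxhat.sum(axis=axes) - xhat * (dxhat * xhat).sum(axis=axes)
    )
    return dx, dgamma, dbeta


# ---------------------------------------------------------------------------
# dropout / fully connected / softmax


def dropout_forward(x, rate, rng=None, training=True):
    if not 0 <= rate < 1:
        raise ValueError("dropout rate must be in [0, 1)")
    if not training or rate == 0:
        return np.asarray(x), None
    if rng is None:
        rng = np.random.default_rng()
    mask = (rng.random(np.shape(x)) >= rate) / (1.0 - rate)
    return x * mask, mask


def dropout_backward(dy, mask):
    return dy if mask is None else dy * mask


def fc_forward(x, w, b):
    x = np.asarray(x)
    x2 = x.reshape(x.shape[0], -1)
    if x2.shape[1] != w.shape[0]:
        raise ValueError(f"fan-in {x2.shape[1]} does not match weights {w.shape[0]}")
    return x2 @ w + b, dict(x2=x2, w=w, x_shape=x.shape)


def fc_backward(dy, cache):
    x2, w = cache["x2"], cache["w"]
    dw = x2.T @ dy
    db = dy.sum(axis=0)
    dx = (dy @ w.T).reshape(cache["x_shape"])
    return dx, dw, db


def softmax(logits):
    """Multinomial probabilities over the last axis, max-shifted for safety."""
    logits = np.asarray(logits, dtype=float)
    if logits.size == 0 or logits.shape[-1] == 0:
        raise ValueError("softmax of an empty vector is undefined")
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy(logits, labels):
    """Mean cross-entropy loss and its gradient w.r.t. the logits."""
    logits = np.asarray(logits, dtype=float)
    labels = np.asarray(labels)
    n = logits.shape[0]
    z = logits - logits.max(axis=-1, keepdims=True)
    log_p = z - np.log(np.exp(z).sum(axis=-1, keepdims=True))
    loss = -log_p[np.arange(n), labels].mean()
    grad = np.exp(log_p)
    grad[np.arange(n), labels] -= 1.0
    return loss, grad / n
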