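"""Neural-network building blocks on top of :mod:`protoerp.nn.autograd`.

Contains the module/parameter machinery plus the convolution primitives the
EEG encoder needs: a temporal convolution shared across electrodes, a
depthwise (per-map) temporal convolution, and a spatial convolution that
collapses the electrode axis.  Each primitive carries a hand-written
backward rule; correctness is checked against finite differences in the
test suite.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .autograd import Tensor

__all__ = [
    "Parameter",
    "Module",
    "Linear",
    "BatchNorm",
    "Dropout",
    "temporal_conv",
    "depthwise_time_conv",
    "spatial_collapse_conv",
    "avg_pool_time",
]


class Parameter(Tensor):
    """A tensor registered as trainable state of a module.

    float32 by default: the network runs single precision end to end.
    """

    def __init__(self, data, dtype=np.float32):
        super().__init__(np.asarray(data, dtype=dtype), requires_grad=True)


class Module:
    """Base class with parameter/buffer registration and train/eval mode."""

    def __init__(self):
        self._training = True

    # parameters -----------------------------------------------------------

    def named_parameters(self, prefix: str = ""):
        for name, val in vars(self).items():
            if isinstance(val, Parameter):
                yield prefix + name, val
            elif isinstance(val, Module):
                yield from val.named_parameters(prefix + name + ".")
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Parameter):
                        yield f"{prefix}{name}.{i}", item
                    elif isinstance(item, Module):
                        yield from item.named_parameters(f"{prefix}{name}.{i}.")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def num_params(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    # buffers (non-trainable state, e.g. batch-norm running stats) ---------

    def named_buffers(self, prefix: str = ""):
        for name, val in vars(self).items():
            if isinstance(val, Module):
                yield from val.named_buffers(prefix + name + ".")
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        yield from item.named_buffers(f"{prefix}{name}.{i}.")
            elif name.startswith("running_") and isinstance(val, np.ndarray):
                yield prefix + name, val

    def state_dict(self) -> dict:
        state = {f"param:{k}": v.data for k, v in self.named_parameters()}
        state.update({f"buffer:{k}": v for k, v in self.named_buffers()})
        return state

    def load_state_dict(self, state: dict) -> None:
        params = dict(self.named_parameters())
        for key, arr in state.items():
            kind, _, name = key.partition(":")
            if kind == "param":
                params[name].data = np.asarray(arr, dtype=params[name].data.dtype)
            elif kind == "buffer":
                self._set_buffer(name, np.asarray(arr))

    def _set_buffer(self, dotted: str, value: np.ndarray) -> None:
        obj = self
        parts = dotted.split(".")
        for part in parts[:-1]:
            obj = obj[int(part)] if part.isdigit() else getattr(obj, part)
        setattr(obj, parts[-1], value)

    # mode -----------------------------------------------------------------

    def train(self, mode: bool = True):
        self._training = mode
        for val in vars(self).values():
            if isinstance(val, Module):
                val.train(mode)
            elif isinstance(val, (list, tuple)):
                for item in val:
                    if isinstance(item, Module):
                        item.train(mode)
        return self

    def eval(self):
        return self.train(False)

    @property
    def training(self) -> bool:
        return self._training

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None


class Linear(Module):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator):
        super().__init__()
        limit = np.sqrt(6.0 / (in_dim + out_dim))
        self.weight = Parameter(rng.uniform(-limit, limit, size=(in_dim, out_dim)))
        self.bias = Parameter(np.zeros(out_dim))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class BatchNorm(Module):
    """Batch normalization over all axes except ``feature_axis``.

    Training mode normalizes with batch statistics (and updates running
    estimates); eval mode uses the running estimates.
    """

    def __init__(self, num_features: int, feature_axis: int = 1,
                 momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.feature_axis = feature_axis
        self.momentum = momentum
        self.eps = eps
        self.gamma = Parameter(np.ones(num_features))
        self.beta = Parameter(np.zeros(num_features))
        self.running_mean = np.zeros(num_features)
        self.running_var = np.ones(num_features)

    def __call__(self, x: Tensor) -> Tensor:
        axes = tuple(i for i in range(x.ndim) if i != self.feature_axis)
        shape = [1] * x.ndim
        shape[self.feature_axis] = -1
        if self.training:
            mean = x.mean(axis=axes, keepdims=True)
            var = ((x - mean) ** 2).mean(axis=axes, keepdims=True)
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mean.data.ravel()
            self.running_var = (1 - m) * self.running_var + m * var.data.ravel()
        else:
            dt = x.data.dtype
            mean = Tensor(self.running_mean.reshape(shape).astype(dt))
            var = Tensor(self.running_var.reshape(shape).astype(dt))
        xhat = (x - mean) / (var + self.eps).sqrt()
        return xhat * self.gamma.reshape(shape) + self.beta.reshape(shape)


class Dropout(Module):
    """Inverted dropout with an explicit generator for reproducibility."""

    def __init__(self, p: float, rng: np.random.Generator):
        super().__init__()
        self.p = float(p)
        self.rng = rng

    def __call__(self, x: Tensor) -> Tensor:
        if not self.training or self.p <= 0.0:
            return x
        mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * Tensor(mask.astype(x.data.dtype))


# ---------------------------------------------------------------------------
# convolution primitives (stride 1, 'same' padding along the swept axis)
# ---------------------------------------------------------------------------


def _same_pad(k: int):
    left = (k - 1) // 2
    return left, k - 1 - left


def temporal_conv(x: Tensor, w: Tensor) -> Tensor:
    """Convolve along time, sharing the kernel across electrodes.

    x: (N, C, T); w: (F, k)  ->  (N, F, C, T)
    """
    k = w.shape[-1]
    pl, pr = _same_pad(k)
    n, c, T = x.shape
    f = w.shape[0]
    xp = np.pad(x.data, ((0, 0), (0, 0), (pl, pr)))
    win = np.ascontiguousarray(sliding_window_view(xp, k, axis=-1))  # (N,C,T,k)
    flat = win.reshape(n * c * T, k)
    out = (flat @ w.data.T).reshape(n, c, T, f).transpose(0, 3, 1, 2)

    def bwd(g):
        gf = np.ascontiguousarray(g.transpose(0, 2, 3, 1)).reshape(n * c * T, f)
        if w.requires_grad:
            w._accum((gf.T @ flat))
        if x.requires_grad:
            gw = (gf @ w.data).reshape(n, c, T, k)
            gxp = np.zeros_like(xp)
            for i in range(k):
                gxp[..., i:i + T] += gw[..., i]
            x._accum(gxp[..., pl:pl + T])

    return Tensor._make(np.ascontiguousarray(out), (x, w), bwd)


def depthwise_time_conv(x: Tensor, w: Tensor) -> Tensor:
    """Per-map temporal convolution.  x: (N, M, T); w: (M, k) -> (N, M, T)."""
    k = w.shape[-1]
    pl, pr = _same_pad(k)
    xp = np.pad(x.data, ((0, 0), (0, 0), (pl, pr)))
    win = sliding_window_view(xp, k, axis=-1)  # (N, M, T, k)
    out = np.einsum("nmtk,mk->nmt", win, w.data, optimize=True)
    T = x.shape[-1]

    def bwd(g):
        if w.requires_grad:
            w._accum(np.einsum("nmt,nmtk->mk", g, win, optimize=True))
        if x.requires_grad:
            gw = np.einsum("nmt,mk->nmtk", g, w.data, optimize=True)
            gxp = np.zeros_like(xp)
            for i in range(k):
                gxp[..., i:i + T] += gw[..., i]
            x._accum(gxp[..., pl:pl + T])

    return Tensor._make(out, (x, w), bwd)


def spatial_collapse_conv(x: Tensor, w: Tensor) -> Tensor:
    """Depthwise spatial filter collapsing the electrode axis.

    x: (N, M, C, T); w: (M, D, C)  ->  (N, M*D, T)
    """
    n, m, c, t = x.shape
    d = w.shape[1]
    out = np.einsum("nmct,mdc->nmdt", x.data, w.data, optimize=True)

    def bwd(g):
        gr = g.reshape(n, m, d, t)
        if w.requires_grad:
            w._accum(np.einsum("nmdt,nmct->mdc", gr, x.data, optimize=True))
        if x.requires_grad:
            x._accum(np.einsum("nmdt,mdc->nmct", gr, w.data, optimize=True))

    return Tensor._make(out.reshape(n, m * d, t), (x, w), bwd)


def avg_pool_time(x: Tensor, pool: int) -> Tensor:
    """Non-overlapping average pooling along the last axis (trailing samples
    that do not fill a window are dropped)."""
    t = x.shape[-1]
    t_keep = (t // pool) * pool
    trimmed = x[..., :t_keep] if t_keep != t else x
    new_shape = x.shape[:-1] + (t_keep // pool, pool)
    return trimmed.reshape(new_shape).mean(axis=-1)
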