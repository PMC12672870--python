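"""Neural-network building blocks (modules) on top of the autodiff tape.

Layout convention throughout: sequence tensors are (batch, length, channels).
Convolutions therefore slide along axis 1.  All layers accept an explicit
``rng`` (numpy Generator) and ``dtype`` so that model construction is fully
deterministic given a seed.
"""

from __future__ import annotations

from typing import Dict, Iterator, Tuple

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .tensor import Tensor, _make, as_tensor, is_grad_enabled


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(np.asarray(data), requires_grad=True)


class Module:
    """Parameter/submodule registry with train/eval mode and state dicts."""

    def __init__(self):
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_buffers", {})
        object.__setattr__(self, "_modules", {})
        object.__setattr__(self, "training", True)

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self._params[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        object.__setattr__(self, name, value)

    def register_buffer(self, name: str, value: np.ndarray) -> None:
        self._buffers[name] = value
        object.__setattr__(self, name, value)

    def _set_buffer(self, name: str, value: np.ndarray) -> None:
        self._buffers[name] = value
        object.__setattr__(self, name, value)

    def named_parameters(self, prefix: str = "") -> Iterator[Tuple[str, Parameter]]:
        for name, p in self._params.items():
            yield prefix + name, p
        for mname, mod in self._modules.items():
            yield from mod.named_parameters(prefix + mname + ".")

    def parameters(self) -> Iterator[Parameter]:
        for _, p in self.named_parameters():
            yield p

    def named_buffers(self, prefix: str = "") -> Iterator[Tuple[str, np.ndarray]]:
        for name in self._buffers:
            yield prefix + name, self._buffers[name]
        for mname, mod in self._modules.items():
            yield from mod.named_buffers(prefix + mname + ".")

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def train(self, mode: bool = True) -> "Module":
        object.__setattr__(self, "training", mode)
        for mod in self._modules.values():
            mod.train(mode)
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def state_dict(self) -> Dict[str, np.ndarray]:
        out = {name: p.data.copy() for name, p in self.named_parameters()}
        out.update({name: b.copy() for name, b in self.named_buffers()})
        return out

    def load_state_dict(self, state: Dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        bufs = {}

        def collect(mod: Module, prefix: str):
            for name in mod._buffers:
                bufs[prefix + name] = (mod, name)
            for mname, sub in mod._modules.items():
                collect(sub, prefix + mname + ".")

        collect(self, "")
        for key, value in state.items():
            if key in params:
                params[key].data = np.array(value, dtype=params[key].data.dtype)
            elif key in bufs:
                mod, name = bufs[key]
                mod._set_buffer(name, np.array(value, dtype=mod._buffers[name].dtype))
            else:
                raise KeyError(f"unknown state entry {key!r}")

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


# ---------------------------------------------------------------------------


class Linear(Module):
    """Affine map applied to the last axis: y = x W + b."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 dtype=np.float32, init: str = "he"):
        super().__init__()
        if init == "he":
            std = np.sqrt(2.0 / n_in)
            w = rng.normal(0.0, std, size=(n_in, n_out))
        else:  # glorot uniform
            lim = np.sqrt(6.0 / (n_in + n_out))
            w = rng.uniform(-lim, lim, size=(n_in, n_out))
        self.weight = Parameter(w.astype(dtype))
        self.bias = Parameter(np.zeros(n_out, dtype=dtype))

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class Conv1d(Module):
    """1-D convolution along axis 1 of a (B, L, C) tensor, length-preserving.

    ``padding="same"`` uses asymmetric zero padding for even kernels
    (left = K//2, right = K-1-K//2, e.g. 4/3 for K=8) so the output length
    equals the input length exactly.  ``padding="causal"`` left-pads with
    K-1 zeros so position t only sees positions <= t.
    """

    def __init__(self, c_in: int, c_out: int, kernel: int,
                 rng: np.random.Generator, padding: str = "same",
                 dtype=np.float32):
        super().__init__()
        if kernel < 1:
            raise ValueError("kernel must be >= 1")
        if padding == "same":
            self.pad_left = kernel // 2
            self.pad_right = kernel - 1 - kernel // 2
        elif padding == "causal":
            self.pad_left = kernel - 1
            self.pad_right = 0
        else:
            raise ValueError(f"unknown padding {padding!r}")
        self.kernel = kernel
        self.c_in = c_in
        self.c_out = c_out
        std = np.sqrt(2.0 / (kernel * c_in))
        self.weight = Parameter(rng.normal(0.0, std, size=(kernel, c_in, c_out)).astype(dtype))
        self.bias = Parameter(np.zeros(c_out, dtype=dtype))

    def forward(self, x: Tensor) -> Tensor:
        x = as_tensor(x)
        w, b = self.weight, self.bias
        xd = x.data
        if xd.ndim != 3 or xd.shape[2] != self.c_in:
            raise ValueError(
                f"expected (B, L, {self.c_in}) input, got {xd.shape}")
        K, left, right = self.kernel, self.pad_left, self.pad_right
        B, L, _ = xd.shape
        xp = np.pad(xd, ((0, 0), (left, right), (0, 0)))
        win = sliding_window_view(xp, K, axis=1)  # (B, L, Cin, K)
        out_data = np.tensordot(win, w.data, axes=([3, 2], [0, 1])) + b.data

        def backward(g):
            if w.requires_grad:
                gw = np.tensordot(win, g, axes=([0, 1], [0, 1]))  # (Cin, K, Cout)
                w._accumulate(np.swapaxes(gw, 0, 1))
            if b.requires_grad:
                b._accumulate(g.sum(axis=(0, 1)))
            if x.requires_grad:
                gxp = np.zeros_like(xp)
                for k in range(K):
                    gxp[:, k:k + L] += g @ w.data[k].T
                x._accumulate(gxp[:, left:left + L])

        return _make(out_data, (x, w, b), backward)


class LayerNorm(Module):
    """Normalization over the channel (last) axis with learned scale/shift."""

    def __init__(self, dim: int, dtype=np.float32, eps: float = 1e-5):
        super().__init__()
        self.eps = eps
        self.weight = Parameter(np.ones(dim, dtype=dtype))
        self.bias = Parameter(np.zeros(dim, dtype=dtype))

    def forward(self, x: Tensor) -> Tensor:
        x = as_tensor(x)
        g_, b_ = self.weight, self.bias
        xd = x.data
        mu = xd.mean(axis=-1, keepdims=True)
        var = xd.var(axis=-1, keepdims=True)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (xd - mu) * inv
        out_data = xhat * g_.data + b_.data

        def backward(g):
            if g_.requires_grad:
                g_._accumulate((g * xhat).sum(axis=tuple(range(g.ndim - 1))))
            if b_.requires_grad:
                b_._accumulate(g.sum(axis=tuple(range(g.ndim - 1))))
            if x.requires_grad:
                gh = g * g_.data
                m1 = gh.mean(axis=-1, keepdims=True)
                m2 = (gh * xhat).mean(axis=-1, keepdims=True)
                x._accumulate(inv * (gh - m1 - xhat * m2))

        return _make(out_data, (x, g_, b_), backward)


class BatchNorm1d(Module):
    """Per-channel batch normalization over (batch, length) of (B, L, C).

    Batch statistics are used in training mode; exponential running estimates
    (momentum 0.1) are used in evaluation mode.
    """

    def __init__(self, channels: int, dtype=np.float32,
                 momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.weight = Parameter(np.ones(channels, dtype=dtype))
        self.bias = Parameter(np.zeros(channels, dtype=dtype))
        self.register_buffer("running_mean", np.zeros(channels, dtype=dtype))
        self.register_buffer("running_var", np.ones(channels, dtype=dtype))

    def forward(self, x: Tensor) -> Tensor:
        x = as_tensor(x)
        g_, b_ = self.weight, self.bias
        xd = x.data
        if self.training:
            mu = xd.mean(axis=(0, 1))
            var = xd.var(axis=(0, 1))
            m = self.momentum
            self._set_buffer("running_mean",
                             ((1 - m) * self.running_mean + m * mu).astype(xd.dtype))
            self._set_buffer("running_var",
                             ((1 - m) * self.running_var + m * var).astype(xd.dtype))
        else:
            mu, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (xd - mu) * inv
        out_data = xhat * g_.data + b_.data
        use_batch_stats = self.training

        def backward(g):
            if g_.requires_grad:
                g_._accumulate((g * xhat).sum(axis=(0, 1)))
            if b_.requires_grad:
                b_._accumulate(g.sum(axis=(0, 1)))
            if x.requires_grad:
                if use_batch_stats:
                    gh = g * g_.data
                    m1 = gh.mean(axis=(0, 1))
                    m2 = (gh * xhat).mean(axis=(0, 1))
                    x._accumulate(inv * (gh - m1 - xhat * m2))
                else:
                    x._accumulate(g * (g_.data * inv))

        return _make(out_data, (x, g_, b_), backward)


class MaxPool1d(Module):
    """Non-overlapping max pooling along the length axis (kernel = stride)."""

    def __init__(self, kernel: int = 2):
        super().__init__()
        self.kernel = kernel

    def forward(self, x: Tensor) -> Tensor:
        x = as_tensor(x)
        xd = x.data
        B, L, C = xd.shape
        k = self.kernel
        if L < k:
            raise ValueError(f"sequence length {L} shorter than pooling kernel {k}")
        Lo = L // k
        xr = xd[:, :Lo * k].reshape(B, Lo, k, C)
        idx = xr.argmax(axis=2)  # ties -> first occurrence
        out_data = np.take_along_axis(xr, idx[:, :, None, :], axis=2)[:, :, 0, :]

        def backward(g):
            if x.requires_grad:
                gx = np.zeros_like(xd)
                gr = gx[:, :Lo * k].reshape(B, Lo, k, C)
                np.put_along_axis(gr, idx[:, :, None, :], g[:, :, None, :], axis=2)
                x._accumulate(gx)

        return _make(out_data, (x,), backward)


class Dropout(Module):
    """Inverted dropout: active in training mode, identity in evaluation."""

    def __init__(self, p: float, rng: np.random.Generator):
        super().__init__()
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.p = p
        self.rng = rng

    def forward(self, x: Tensor) -> Tensor:
        if not self.training or self.p == 0.0:
            return as_tensor(x)
        x = as_tensor(x)
        keep = (self.rng.random(x.data.shape) >= self.p)
        scale = 1.0 / (1.0 - self.p)
        mask = keep.astype(x.data.dtype) * scale
        out_data = x.data * mask

        def backward(g):
            if x.requires_grad:
                x._accumulate(g * mask)

        return _make(out_data, (x,), backward)
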