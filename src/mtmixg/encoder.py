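"""Hybrid attention / state-space encoder.

A kernel-1 convolutional stem lifts the L x 4 one-hot input to L x C
features, which are split evenly along channels.  The first half feeds a
multi-head self-attention branch (global, position-symmetric mixing); the
second half feeds a Mamba-style branch: LayerNorm, linear lift to d_h, a
causal convolution for short-motif context, a diagonal linear state-space
recurrence, and a sigmoid-free multiplicative gate path.  Each branch output
is fused with its input half by element-wise addition, yielding two L x C/2
maps (H_T, H_M).

No positional encoding is added: order information enters through the causal
convolution, the state-space recurrence and the downstream CNN chain, so the
attention sub-branch on its own is exactly permutation-equivariant.
"""

from __future__ import annotations

from typing import Optional, Tuple

import numpy as np

from . import nn
from .config import ModelConfig
from .nn import Tensor, as_tensor
from .nn.functional import diag_ssm_scan, scaled_dot_attention


def channel_split(f: Tensor) -> Tuple[Tensor, Tensor]:
    """Split an L x C feature map evenly along channels (C must be even)."""
    f = as_tensor(f)
    c = f.shape[-1]
    if c % 2 != 0:
        raise ValueError(f"cannot split odd channel count {c}")
    return f[..., : c // 2], f[..., c // 2:]


def fuse_branches(x_f: Tensor, attn_out, x_s: Tensor, m) -> Tuple[Tensor, Tensor]:
    """Residual fusion: H_T = X_f (+) attention, H_M = X_s (+) Mamba."""
    h_t = as_tensor(x_f) + attn_out if attn_out is not None else as_tensor(x_f)
    h_m = as_tensor(x_s) + m if m is not None else as_tensor(x_s)
    if h_t.shape != x_f.shape or h_m.shape != x_s.shape:
        raise ValueError("fusion changed feature-map shape")
    return h_t, h_m


class ConvStem(nn.Module):
    """Kernel-1 convolution + ReLU: a pointwise lift from 4 to C channels."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator, dtype):
        super().__init__()
        self.conv = nn.Conv1d(4, cfg.channels, kernel=1, rng=rng, dtype=dtype)

    def forward(self, x: Tensor) -> Tensor:
        return nn.relu(self.conv(x))


class MultiHeadSelfAttention(nn.Module):
    """Scaled dot-product self-attention with h heads over L x C/2 features.

    Per head: softmax(Q K^T / sqrt(d_k)) V with learned projections; head
    outputs are concatenated and mapped back to C/2 by W_O.  Set
    ``store_attention`` to keep the last attention matrices (for inspection).
    """

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator, dtype):
        super().__init__()
        d = cfg.half_channels
        self.heads = cfg.heads
        self.head_dim = cfg.head_dim
        self.w_q = nn.Linear(d, cfg.heads * cfg.head_dim, rng, dtype, init="glorot")
        self.w_k = nn.Linear(d, cfg.heads * cfg.head_dim, rng, dtype, init="glorot")
        self.w_v = nn.Linear(d, cfg.heads * cfg.head_dim, rng, dtype, init="glorot")
        self.w_o = nn.Linear(cfg.heads * cfg.head_dim, d, rng, dtype, init="glorot")
        self.store_attention = False
        self.last_attention: Optional[np.ndarray] = None

    def _heads(self, t: Tensor, B: int, L: int) -> Tensor:
        return t.reshape(B, L, self.heads, self.head_dim).swapaxes(1, 2)

    def forward(self, x: Tensor) -> Tensor:
        x = as_tensor(x)
        B, L, _ = x.shape
        q = self._heads(self.w_q(x), B, L)
        k = self._heads(self.w_k(x), B, L)
        v = self._heads(self.w_v(x), B, L)
        out, probs = scaled_dot_attention(q, k, v)  # (B, h, L, d_k)
        if self.store_attention:
            self.last_attention = probs
        out = out.swapaxes(1, 2).reshape(B, L, self.heads * self.head_dim)
        return self.w_o(out)


class SSMCore(nn.Module):
    """Diagonal linear time-invariant SSM run as a left-to-right recurrence.

    h_t = A h_{t-1} + B z_t,  y_t = C h_t + D z_t, with h_0 = 0, a single
    d_s-dimensional state shared across channels, A = diag(sigmoid(a_raw))
    so every transition coefficient lies in (0, 1) and the recurrence is
    bounded.  D is a per-channel diagonal skip.
    """

    def __init__(self, d_h: int, d_s: int, rng: np.random.Generator, dtype):
        super().__init__()
        # spread the state timescales: a = sigmoid(a_raw) in ~[0.3, 0.95]
        a0 = np.linspace(0.3, 0.95, d_s)
        self.a_raw = nn.Parameter(np.log(a0 / (1 - a0)).astype(dtype))
        std = 1.0 / np.sqrt(d_h)
        self.b_mat = nn.Parameter(rng.normal(0, std, size=(d_s, d_h)).astype(dtype))
        self.c_mat = nn.Parameter(rng.normal(0, 1.0 / np.sqrt(d_s),
                                             size=(d_h, d_s)).astype(dtype))
        self.d_skip = nn.Parameter(np.ones(d_h, dtype=dtype))

    def forward(self, z: Tensor) -> Tensor:
        z = as_tensor(z)
        a = nn.sigmoid(self.a_raw)
        u = z @ self.b_mat.T              # (B, L, d_s)
        h = diag_ssm_scan(u, a)           # (B, L, d_s)
        return h @ self.c_mat.T + z * self.d_skip


def ssm_scan(z, params: SSMCore) -> Tensor:
    """Functional form of the SSM readout: y_t = C h_t + D z_t over a scan."""
    return params(as_tensor(z))


class MambaBranch(nn.Module):
    """Normalize, lift, convolve causally, scan, gate and project back.

    X'_s = LayerNorm(X_s); Z0 = X'_s W1 + b1; Z1 = ReLU(CausalConv(Z0));
    Y = SSM(Z1); Z_s = ReLU(X'_s Ws + bs); M = (Y * Z_s) W2 + b2.
    """

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator, dtype):
        super().__init__()
        d = cfg.half_channels
        self.norm = nn.LayerNorm(d, dtype=dtype)
        self.w1 = nn.Linear(d, cfg.ssm_hidden, rng, dtype)
        self.conv = nn.Conv1d(cfg.ssm_hidden, cfg.ssm_hidden,
                              kernel=cfg.ssm_conv_kernel, rng=rng,
                              padding="causal", dtype=dtype)
        self.ssm = SSMCore(cfg.ssm_hidden, cfg.ssm_state, rng, dtype)
        self.w_gate = nn.Linear(d, cfg.ssm_hidden, rng, dtype)
        self.w2 = nn.Linear(cfg.ssm_hidden, d, rng, dtype)

    def forward(self, x_s: Tensor) -> Tensor:
        xn = self.norm(as_tensor(x_s))
        z0 = self.w1(xn)
        z1 = nn.relu(self.conv(z0))
        y = self.ssm(z1)
        z_gate = nn.relu(self.w_gate(xn))
        return self.w2(y * z_gate)


class MTMixEncoder(nn.Module):
    """Stem, channel split, parallel branches and residual fusion.

    ``use_attention`` / ``use_mamba`` switch branches off for ablation
    variants; a disabled branch contributes nothing and its input half
    passes through unchanged.
    """

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator, dtype,
                 use_attention: bool = True, use_mamba: bool = True):
        super().__init__()
        self.stem = ConvStem(cfg, rng, dtype)
        if use_attention:
            self.attention = MultiHeadSelfAttention(cfg, rng, dtype)
        if use_mamba:
            self.mamba = MambaBranch(cfg, rng, dtype)
        self.use_attention = use_attention
        self.use_mamba = use_mamba

    def forward(self, x: Tensor) -> Tuple[Tensor, Tensor]:
        f = self.stem(as_tensor(x))
        x_f, x_s = channel_split(f)
        attn_out = self.attention(x_f) if self.use_attention else None
        m = self.mamba(x_s) if self.use_mamba else None
        return fuse_branches(x_f, attn_out, x_s, m)
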