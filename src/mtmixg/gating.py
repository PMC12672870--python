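"""Dual-path gating and the residual CNN chain.

The gate projects each encoder output (H_T from attention, H_M from the
state-space branch), derives a sigmoid mask from a small same-padded
convolution of the projection, multiplies each projection by its own mask
and sums the two paths.  The chain then stacks residual convolution blocks
(kernel 8, length-preserving via 4/3 asymmetric padding) each ending in
batch-norm, 2x max-pooling and dropout, halving the length per block.
"""

from __future__ import annotations

import numpy as np

from . import nn
from .config import ModelConfig
from .nn import Tensor, as_tensor


class DualPathGate(nn.Module):
    """G = sigmoid(Conv(Project(H))); F = P_T*G_T + P_M*G_M, all L x C/2.

    The projections keep dimension C/2 so the gated sum can feed the CNN
    chain unchanged.
    """

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator, dtype):
        super().__init__()
        d = cfg.half_channels
        self.project_t = nn.Linear(d, d, rng, dtype, init="glorot")
        self.project_m = nn.Linear(d, d, rng, dtype, init="glorot")
        self.conv_t = nn.Conv1d(d, d, kernel=cfg.gate_kernel, rng=rng, dtype=dtype)
        self.conv_m = nn.Conv1d(d, d, kernel=cfg.gate_kernel, rng=rng, dtype=dtype)

    def forward(self, h_t: Tensor, h_m: Tensor) -> Tensor:
        h_t, h_m = as_tensor(h_t), as_tensor(h_m)
        if h_t.shape != h_m.shape:
            raise ValueError(f"gate inputs differ in shape: {h_t.shape} vs {h_m.shape}")
        p_t = self.project_t(h_t)
        p_m = self.project_m(h_m)
        g_t = nn.sigmoid(self.conv_t(p_t))
        g_m = nn.sigmoid(self.conv_m(p_m))
        return p_t * g_t + p_m * g_m


class ResBlock(nn.Module):
    """Three convolutions with a residual add, then BN, 2x pool, dropout.

    Z1 = ReLU(Conv(H_in)); Z2 = ReLU(Conv(Z1)) + H_in;
    Z3 = BN(ReLU(Conv(Z2))); Z4 = MaxPool_2(Z3); H_out = Dropout(Z4, p).
    Output length is floor(L_in / 2); channels are unchanged.
    """

    def __init__(self, channels: int, kernel: int, dropout_p: float,
                 rng: np.random.Generator,
                 dropout_rng: np.random.Generator, dtype):
        super().__init__()
        self.conv1 = nn.Conv1d(channels, channels, kernel, rng, dtype=dtype)
        self.conv2 = nn.Conv1d(channels, channels, kernel, rng, dtype=dtype)
        self.conv3 = nn.Conv1d(channels, channels, kernel, rng, dtype=dtype)
        self.bn = nn.BatchNorm1d(channels, dtype=dtype)
        self.pool = nn.MaxPool1d(2)
        self.dropout = nn.Dropout(dropout_p, dropout_rng)

    def forward(self, h_in: Tensor) -> Tensor:
        h_in = as_tensor(h_in)
        if h_in.shape[1] < 2:
            raise ValueError("input shorter than the pooling kernel")
        z1 = nn.relu(self.conv1(h_in))
        z2 = nn.relu(self.conv2(z1)) + h_in
        z3 = self.bn(nn.relu(self.conv3(z2)))
        z4 = self.pool(z3)
        return self.dropout(z4)


class ResCNNChain(nn.Module):
    """n_blocks sequential residual blocks; length shrinks by floor-halving."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator,
                 dropout_rng: np.random.Generator, dtype):
        super().__init__()
        if cfg.seq_len < 2 ** cfg.n_blocks:
            raise ValueError(
                f"sequence of length {cfg.seq_len} cannot pass "
                f"{cfg.n_blocks} halving blocks")
        self.blocks = []
        for i in range(cfg.n_blocks):
            block = ResBlock(cfg.half_channels, cfg.res_kernel, cfg.dropout_p,
                             rng, dropout_rng, dtype)
            setattr(self, f"block{i}", block)
            self.blocks.append(block)

    def forward(self, f: Tensor) -> Tensor:
        h = as_tensor(f)
        for block in self.blocks:
            h = block(h)
        return h
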