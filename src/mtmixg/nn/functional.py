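"""Fused functional ops with hand-written backward passes.

These two ops are the compute hot spots of the model, so each is written as a
single tape node: scaled dot-product attention (keeps only the probability
matrix for backward instead of every intermediate) and the left-to-right
diagonal state-space recurrence.
"""

from __future__ import annotations

import numpy as np

from .tensor import Tensor, _make, as_tensor


def scaled_dot_attention(q: Tensor, k: Tensor, v: Tensor):
    """softmax(Q K^T / sqrt(d_k)) V over the last two axes.

    ``q, k, v`` have shape (..., L, d_k).  Returns ``(out, probs)`` where
    ``probs`` is the (detached) attention matrix — every row is a probability
    vector — exposed for inspection and testing.
    """
    q, k, v = as_tensor(q), as_tensor(k), as_tensor(v)
    batch_shape = q.data.shape[:-2]
    L, dk = q.data.shape[-2:]
    nb = int(np.prod(batch_shape)) if batch_shape else 1
    scale = np.asarray(1.0 / np.sqrt(dk), dtype=q.data.dtype)
    # flatten batch axes: 3-D batched GEMMs are far faster than >=4-D ones
    qs = np.ascontiguousarray(q.data.reshape(nb, L, dk)) * scale
    k3 = np.ascontiguousarray(k.data.reshape(nb, L, dk))
    v3 = np.ascontiguousarray(v.data.reshape(nb, L, dk))
    probs = np.empty((nb, L, L), dtype=qs.dtype)
    out_data = np.empty((nb, L, dk), dtype=qs.dtype)
    for i in range(nb):  # per-matrix 2-D GEMMs + in-place softmax
        p_i = probs[i]
        np.matmul(qs[i], k3[i].T, out=p_i)
        p_i -= p_i.max(axis=-1, keepdims=True)  # softmax overflow guard
        np.exp(p_i, out=p_i)
        p_i /= p_i.sum(axis=-1, keepdims=True)  # rows sum to 1
        np.matmul(p_i, v3[i], out=out_data[i])
    out_data = out_data.reshape(*batch_shape, L, dk)

    def backward(g):
        g3 = np.ascontiguousarray(g.reshape(nb, L, dk))
        need_qk = q.requires_grad or k.requires_grad
        gv = np.empty((nb, L, dk), dtype=qs.dtype) if v.requires_grad else None
        gq = np.empty((nb, L, dk), dtype=qs.dtype) if q.requires_grad else None
        gk = np.empty((nb, L, dk), dtype=qs.dtype) if k.requires_grad else None
        gp = np.empty((L, L), dtype=qs.dtype) if need_qk else None
        for i in range(nb):
            p_i = probs[i]
            if gv is not None:
                np.matmul(p_i.T, g3[i], out=gv[i])
            if need_qk:
                np.matmul(g3[i], v3[i].T, out=gp)
                gp *= p_i
                gp -= p_i * gp.sum(axis=-1, keepdims=True)
                if gq is not None:  # scale was folded into Q
                    np.matmul(gp, k3[i], out=gq[i])
                    gq[i] *= scale
                if gk is not None:
                    np.matmul(gp.T, qs[i], out=gk[i])
        if gv is not None:
            v._accumulate(gv.reshape(v.data.shape))
        if gq is not None:
            q._accumulate(gq.reshape(q.data.shape))
        if gk is not None:
            k._accumulate(gk.reshape(k.data.shape))

    probs_out = probs.reshape(*batch_shape, L, L)
    return _make(out_data, (q, k, v), backward), probs_out


def diag_ssm_scan(u: Tensor, a: Tensor) -> Tensor:
    """Run ``h_t = a * h_{t-1} + u_t`` along the sequence axis, h_0 = 0.

    ``u`` has shape (B, L, d_s); ``a`` is a length-d_s vector of diagonal
    transition coefficients (expected in (0, 1) so the recurrence is bounded).
    Returns the stacked hidden states H of shape (B, L, d_s).
    """
    u, a = as_tensor(u), as_tensor(a)
    ud, ad = u.data, a.data
    B, L, ds = ud.shape
    H = np.empty_like(ud)
    h = np.zeros((B, ds), dtype=ud.dtype)
    for t in range(L):
        h = ad * h + ud[:, t]
        H[:, t] = h
    if not np.isfinite(h).all():
        raise FloatingPointError("state-space recurrence diverged (non-finite state)")

    def backward(g):
        gu = np.empty_like(g) if u.requires_grad else None
        ga = np.zeros_like(ad) if a.requires_grad else None
        s = np.zeros((B, ds), dtype=ud.dtype)
        for t in range(L - 1, -1, -1):
            s = g[:, t] + ad * s
            if gu is not None:
                gu[:, t] = s
            if ga is not None and t > 0:
                # d h_t / d a picks up h_{t-1} at every step
                ga += (s * H[:, t - 1]).sum(axis=0)
        if gu is not None:
            u._accumulate(gu)
        if ga is not None:
            a._accumulate(ga)

    return _make(H, (u, a), backward)
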