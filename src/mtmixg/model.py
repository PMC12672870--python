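"""Full classifier assembly and the ablation-variant switchboard.

Variants (matching the ablation grid):

* ``M1`` — stem, a linear halving map to C/2, the residual CNN chain and
  the head; no attention, no state-space branch, no gate.
* ``M1+M21`` — CNN chain plus the Mamba branch only; the attention half
  passes through unchanged and the two halves are fused by addition.
* ``M1+M22`` — CNN chain plus the attention branch only, likewise.
* ``M1+M2`` — both encoder branches, fused by addition (no gate).
* ``full`` — both branches refined by the dual-path gate.

Every variant maps an (B, L, 4) one-hot batch to three class probabilities.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from . import nn
from .config import VARIANTS, ModelConfig
from .encoder import MTMixEncoder
from .gating import DualPathGate, ResCNNChain
from .nn import Tensor, as_tensor
from .predictor import PredictionHead


class MTMixGNet(nn.Module):
    """Sequence-to-expression-class network over TSS/TTS flanking DNA."""

    def __init__(self, cfg: ModelConfig, variant: str = "full",
                 seed: int = 0):
        super().__init__()
        if variant not in VARIANTS:
            raise ValueError(f"unknown variant {variant!r}; pick one of {VARIANTS}")
        self.cfg = cfg
        self.variant = variant
        dtype = np.dtype(cfg.dtype)
        init_rng = np.random.default_rng(np.random.SeedSequence([seed, 0]))
        self._dropout_rng = np.random.default_rng(np.random.SeedSequence([seed, 1]))

        if variant == "M1":
            from .encoder import ConvStem
            self.stem = ConvStem(cfg, init_rng, dtype)
            self.reduce = nn.Linear(cfg.channels, cfg.half_channels,
                                    init_rng, dtype)
            self.encoder = None
            self.gate = None
        else:
            self.encoder = MTMixEncoder(
                cfg, init_rng, dtype,
                use_attention=variant in ("M1+M22", "M1+M2", "full"),
                use_mamba=variant in ("M1+M21", "M1+M2", "full"),
            )
            self.gate = (DualPathGate(cfg, init_rng, dtype)
                         if variant == "full" else None)
        self.chain = ResCNNChain(cfg, init_rng, self._dropout_rng, dtype)
        self.head = PredictionHead(cfg, init_rng, self._dropout_rng, dtype)
        self._dtype = dtype

    def forward(self, x) -> Tensor:
        x = as_tensor(np.asarray(x.data if isinstance(x, Tensor) else x,
                                 dtype=self._dtype))
        if x.ndim == 2:
            x = x.reshape(1, *x.shape)
        if self.variant == "M1":
            f = self.reduce(self.stem(x))
        else:
            h_t, h_m = self.encoder(x)
            f = self.gate(h_t, h_m) if self.gate is not None else h_t + h_m
        return self.head(self.chain(f))

    def predict_proba(self, x, batch_size: int = 64) -> np.ndarray:
        """Probabilities in evaluation mode, without building the tape."""
        was_training = self.training
        self.eval()
        try:
            out = []
            with nn.no_grad():
                for i in range(0, len(x), batch_size):
                    out.append(self.forward(x[i:i + batch_size]).data)
            return np.concatenate(out, axis=0)
        finally:
            self.train(was_training)


def build_variant(cfg: ModelConfig, variant: str, seed: int = 0) -> MTMixGNet:
    """Construct one of the ablation variants (see module docstring)."""
    return MTMixGNet(cfg, variant=variant, seed=seed)


def save_checkpoint(path, model: MTMixGNet) -> None:
    """Single-file checkpoint: weights + embedded YAML model config."""
    import dataclasses

    cfg_yaml = yaml.safe_dump(
        {**dataclasses.asdict(model.cfg), "variant": model.variant},
        sort_keys=False)
    state = {f"param::{k}": v for k, v in model.state_dict().items()}
    with open(Path(path), "wb") as fh:  # keep the exact filename
        np.savez(fh, __config__=np.array(cfg_yaml), **state)


def load_checkpoint(path, seed: int = 0) -> MTMixGNet:
    with np.load(Path(path), allow_pickle=False) as data:
        doc = yaml.safe_load(str(data["__config__"]))
        variant = doc.pop("variant")
        doc["head_hidden"] = tuple(doc["head_hidden"])
        cfg = ModelConfig(**doc)
        model = MTMixGNet(cfg, variant=variant, seed=seed)
        state = {k[len("param::"):]: data[k] for k in data.files
                 if k.startswith("param::")}
    model.load_state_dict(state)
    return model
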