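"""Configuration dataclasses and their YAML round-trip.

Three groups mirror how the tool is driven: window/encoding geometry
(:class:`FlankSpec`), architecture (:class:`ModelConfig`) and optimization
(:class:`TrainConfig`); :class:`SimConfig` drives the synthetic-genome
generator.  ``load_config``/``save_config`` read and write a single YAML file
with ``data``/``model``/``train`` sections.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import yaml

VARIANTS = ("M1", "M1+M21", "M1+M22", "M1+M2", "full")


@dataclass
class FlankSpec:
    """Strand-aware window geometry around the TSS and TTS anchors (bases).

    Defaults give the 3 kb input window: 1 kb upstream to 0.5 kb downstream
    of the TSS plus 0.5 kb upstream to 1 kb downstream of the TTS.
    """

    tss_up: int = 1000
    tss_down: int = 500
    tts_up: int = 500
    tts_down: int = 1000

    def __post_init__(self):
        for name in ("tss_up", "tss_down", "tts_up", "tts_down"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def total_length(self) -> int:
        return self.tss_up + self.tss_down + self.tts_up + self.tts_down


@dataclass
class ModelConfig:
    """Every architectural dimension of the classifier.

    ``channels`` is the stem width C; the encoder splits it evenly so each
    branch (attention / state-space) and the downstream CNN chain run at C/2
    channels.  ``heads * head_dim`` must equal C/2 so the concatenated-heads
    output projection is square and the residual fusion shapes match.
    """

    seq_len: int = 3000            # L, rows of the one-hot input
    channels: int = 64             # C, stem output width
    heads: int = 4                 # h, attention heads
    head_dim: int = 8              # d_k
    ssm_hidden: int = 64           # d_h, Mamba-branch hidden width
    ssm_state: int = 16            # d_s, SSM state dimension
    ssm_conv_kernel: int = 4       # causal conv inside the Mamba branch
    gate_kernel: int = 3           # DPGM gate convolution kernel
    res_kernel: int = 8            # CNN-chain convolution kernel
    n_blocks: int = 5              # residual blocks in the chain
    dropout_p: float = 0.25
    head_hidden: Tuple[int, int] = (256, 64)
    n_classes: int = 3
    dtype: str = "float32"

    def __post_init__(self):
        if self.channels % 2 != 0:
            raise ValueError("channels (C) must be even for the channel split")
        if self.heads * self.head_dim != self.channels // 2:
            raise ValueError(
                f"heads*head_dim must equal C/2 "
                f"({self.heads}*{self.head_dim} != {self.channels // 2})")
        if self.seq_len < 2 ** self.n_blocks:
            raise ValueError(
                f"seq_len {self.seq_len} too short for {self.n_blocks} "
                f"halving residual blocks")
        if min(self.channels, self.heads, self.head_dim, self.ssm_hidden,
               self.ssm_state, self.n_classes) < 1:
            raise ValueError("all model dimensions must be >= 1")

    @property
    def half_channels(self) -> int:
        return self.channels // 2

    def chain_out_len(self) -> int:
        L = self.seq_len
        for _ in range(self.n_blocks):
            L //= 2
        return L


@dataclass
class TrainConfig:
    """Optimization schedule: Adam, plateau LR decay and early stopping.

    The learning rate is multiplied by ``lr_factor`` after every run of
    ``lr_patience`` consecutive epochs without a strict improvement of the
    best validation loss; training stops after ``early_stop_patience``
    consecutive non-improving epochs.
    """

    lr0: float = 1e-4
    max_epochs: int = 100
    early_stop_patience: int = 10
    lr_patience: int = 5
    lr_factor: float = 0.1
    batch_size: int = 64
    seeds: List[int] = field(default_factory=lambda: [0, 1, 2, 3, 4])
    variant: str = "full"

    def __post_init__(self):
        if self.early_stop_patience < 1 or self.lr_patience < 1:
            raise ValueError("patiences must be >= 1")
        if not 0.0 < self.lr_factor < 1.0:
            raise ValueError("lr_factor must lie in (0, 1)")
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}")


@dataclass
class SimConfig:
    """Synthetic-genome study conditions.

    Each gene's expression class is determined by class-specific 8-mer motifs
    planted in its TSS-upstream kilobase, and its maxTPM is drawn from a
    class-conditional log-normal whose location parameters are strictly
    ordered low < medium < high (disjoint in practice at ``tpm_sigma`` 0.3
    when ``label_noise`` is 0), so quantile labelling recovers the class.
    """

    n_chromosomes: int = 5
    genes_per_chromosome: int = 200
    class_priors: Tuple[float, float, float] = (0.25, 0.50, 0.25)
    motifs: Tuple[str, str, str] = ("TGACGTCA", "CCAATTGG", "GGCGCGCC")
    motifs_per_gene: int = 3
    label_noise: float = 0.0
    tpm_log2_locations: Tuple[float, float, float] = (0.5, 3.5, 7.0)
    tpm_sigma: float = 0.3
    gene_length_range: Tuple[int, int] = (1000, 3000)
    gene_spacing: int = 3000       # gap between consecutive gene footprints
    flank: FlankSpec = field(default_factory=FlankSpec)
    seed: int = 0

    def __post_init__(self):
        if abs(sum(self.class_priors) - 1.0) > 1e-9:
            raise ValueError("class priors must sum to 1")
        locs = self.tpm_log2_locations
        if not (locs[0] < locs[1] < locs[2]):
            raise ValueError("class TPM locations must be strictly ordered")
        if not 0.0 <= self.label_noise <= 1.0:
            raise ValueError("label_noise must be a probability")
        for m in self.motifs:
            if not m or set(m) - set("ACGT"):
                raise ValueError(f"motif {m!r} must be a non-empty ACGT string")


# ---------------------------------------------------------------------------


def _to_dict(obj) -> dict:
    d = dataclasses.asdict(obj)
    for k, v in d.items():
        if isinstance(v, tuple):
            d[k] = list(v)
    return d


def _from_dict(cls, d: dict):
    kwargs = {}
    for f in dataclasses.fields(cls):
        if f.name not in d:
            continue
        v = d[f.name]
        if f.name == "flank" and isinstance(v, dict):
            v = FlankSpec(**v)
        elif isinstance(v, list) and f.name != "seeds":
            v = tuple(v)
        kwargs[f.name] = v
    return cls(**kwargs)


def save_config(path, flank: Optional[FlankSpec] = None,
                model: Optional[ModelConfig] = None,
                train: Optional[TrainConfig] = None,
                sim: Optional[SimConfig] = None) -> None:
    doc: Dict[str, dict] = {}
    if flank is not None:
        doc["data"] = _to_dict(flank)
    if model is not None:
        doc["model"] = _to_dict(model)
    if train is not None:
        doc["train"] = _to_dict(train)
    if sim is not None:
        doc["sim"] = _to_dict(sim)
        doc["sim"]["flank"] = _to_dict(sim.flank)
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def load_config(path) -> Dict[str, object]:
    doc = yaml.safe_load(Path(path).read_text()) or {}
    out: Dict[str, object] = {}
    if "data" in doc:
        out["flank"] = _from_dict(FlankSpec, doc["data"])
    if "model" in doc:
        out["model"] = _from_dict(ModelConfig, doc["model"])
    if "train" in doc:
        out["train"] = _from_dict(TrainConfig, doc["train"])
    if "sim" in doc:
        out["sim"] = _from_dict(SimConfig, doc["sim"])
    return out
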