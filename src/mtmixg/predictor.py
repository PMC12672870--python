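"""Prediction head, loss and evaluation metrics.

The head flattens the CNN-chain output and passes it through two hidden
fully-connected layers with ReLU and dropout, then an output layer with an
independent sigmoid per class — the three probabilities need not sum to one.
Training minimizes one-hot binary cross-entropy summed over the three
classes and averaged over samples.  Hard decisions are made by argmax (ties
break toward the lower class, i.e. low < medium < high).

Metrics follow the one-vs-rest confusion-count definitions: per class
precision TP/(TP+FP), recall TP/(TP+FN) and their harmonic-mean F1, macro
averaged; accuracy is the exact-match fraction; macro AUC averages
one-vs-rest ROC AUCs computed by the mid-rank Mann-Whitney statistic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from . import nn
from .config import ModelConfig
from .genome_io import CLASSES, LABEL_TO_INDEX
from .nn import Tensor, as_tensor

PROB_CLAMP = 1e-7  # log-stability clamp on predicted probabilities


class PredictionHead(nn.Module):
    """Flatten -> 256 -> 64 -> 3 with ReLU + dropout between hidden layers."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator,
                 dropout_rng: np.random.Generator, dtype):
        super().__init__()
        flat = cfg.chain_out_len() * cfg.half_channels
        h1, h2 = cfg.head_hidden
        self.fc1 = nn.Linear(flat, h1, rng, dtype)
        self.fc2 = nn.Linear(h1, h2, rng, dtype)
        self.fc3 = nn.Linear(h2, cfg.n_classes, rng, dtype, init="glorot")
        self.drop1 = nn.Dropout(cfg.dropout_p, dropout_rng)
        self.drop2 = nn.Dropout(cfg.dropout_p, dropout_rng)
        self.flat = flat

    def forward(self, h: Tensor) -> Tensor:
        h = as_tensor(h)
        B = h.shape[0]
        if int(np.prod(h.shape[1:])) != self.flat:
            raise ValueError(
                f"flattened size {int(np.prod(h.shape[1:]))} != expected {self.flat}")
        z = h.reshape(B, self.flat)
        z = self.drop1(nn.relu(self.fc1(z)))
        z = self.drop2(nn.relu(self.fc2(z)))
        return nn.sigmoid(self.fc3(z))


def classify(probs) -> np.ndarray:
    """Hard labels in {-1, 0, +1} by argmax; ties go to the lower class."""
    p = probs.data if isinstance(probs, Tensor) else np.asarray(probs)
    if p.ndim == 1:
        p = p[None, :]
    idx = np.argmax(p, axis=1)  # numpy argmax: first maximum wins
    return np.asarray(CLASSES, dtype=np.int8)[idx]


def bce_loss(probs, targets) -> Tensor:
    """One-hot binary cross-entropy, summed over classes, averaged over N.

    L = -(1/N) sum_i sum_c [ y log p + (1-y) log(1-p) ], with probabilities
    clamped to [1e-7, 1-1e-7] before the logarithms.
    """
    probs = as_tensor(probs)
    targets = np.asarray(targets.data if isinstance(targets, Tensor) else targets)
    if probs.shape != targets.shape:
        raise ValueError(f"shape mismatch {probs.shape} vs {targets.shape}")
    row_sums = targets.sum(axis=-1)
    if not (np.all(row_sums == 1) and np.all((targets == 0) | (targets == 1))):
        raise ValueError("targets must be one-hot rows")
    n = probs.shape[0]
    p = nn.clip(probs, PROB_CLAMP, 1.0 - PROB_CLAMP)
    ll = targets * nn.log(p) + (1.0 - targets) * nn.log(1.0 - p)
    return -(ll.sum() / n)


@dataclass
class MetricReport:
    """Accuracy, macro F1, macro AUC plus the per-class building blocks."""

    accuracy: float
    macro_f1: float
    macro_auc: float
    precision: Dict[int, float] = field(default_factory=dict)
    recall: Dict[int, float] = field(default_factory=dict)
    f1: Dict[int, float] = field(default_factory=dict)

    def as_dict(self) -> Dict[str, float]:
        out = {"accuracy": self.accuracy, "macro_f1": self.macro_f1,
               "macro_auc": self.macro_auc}
        for c in self.precision:
            out[f"precision_{c}"] = self.precision[c]
            out[f"recall_{c}"] = self.recall[c]
            out[f"f1_{c}"] = self.f1[c]
        return out


def _binary_auc(scores: np.ndarray, positives: np.ndarray) -> float:
    """ROC AUC via the mid-rank Mann-Whitney U statistic (ties -> 0.5)."""
    n_pos = int(positives.sum())
    n_neg = positives.size - n_pos
    ranks = rankdata(scores)  # average (mid) ranks
    u = ranks[positives].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def compute_metrics(pred_labels: Sequence[int], true_labels: Sequence[int],
                    probs: Optional[np.ndarray] = None) -> MetricReport:
    """One-vs-rest confusion metrics over the three expression classes.

    A class absent from the truth has undefined AUC; it is excluded from the
    macro AUC mean with a warning.  Precision/recall with an empty
    denominator are reported as 0.
    """
    pred = np.asarray(pred_labels, dtype=int)
    true = np.asarray(true_labels, dtype=int)
    if pred.shape != true.shape:
        raise ValueError("label vectors differ in length")
    if not set(np.unique(np.concatenate([pred, true]))) <= set(CLASSES):
        raise ValueError(f"labels must lie in {CLASSES}")

    accuracy = float(np.mean(pred == true))
    precision, recall, f1 = {}, {}, {}
    for c in CLASSES:
        tp = int(np.sum((pred == c) & (true == c)))
        fp = int(np.sum((pred == c) & (true != c)))
        fn = int(np.sum((pred != c) & (true == c)))
        pre = tp / (tp + fp) if tp + fp else 0.0
        sen = tp / (tp + fn) if tp + fn else 0.0
        precision[c], recall[c] = pre, sen
        f1[c] = 2 * pre * sen / (pre + sen) if pre + sen else 0.0
    macro_f1 = float(np.mean([f1[c] for c in CLASSES]))

    macro_auc = float("nan")
    if probs is not None:
        probs = np.asarray(probs, dtype=float)
        aucs = []
        for c in CLASSES:
            pos = true == c
            if pos.all() or not pos.any():
                warnings.warn(f"class {c} absent from one side of the truth; "
                              "its AUC is undefined and excluded")
                continue
            aucs.append(_binary_auc(probs[:, LABEL_TO_INDEX[c]], pos))
        if aucs:
            macro_auc = float(np.mean(aucs))
    return MetricReport(accuracy=accuracy, macro_f1=macro_f1,
                        macro_auc=macro_auc, precision=precision,
                        recall=recall, f1=f1)


def write_predictions(path, gene_ids: Sequence[str], probs: np.ndarray) -> None:
    """Prediction TSV: gene_id, p_low, p_med, p_high, predicted_label."""
    probs = np.asarray(probs, dtype=float)
    df = pd.DataFrame({
        "gene_id": list(gene_ids),
        "p_low": probs[:, 0],
        "p_med": probs[:, 1],
        "p_high": probs[:, 2],
        "predicted_label": classify(probs),
    })
    df.to_csv(Path(path), sep="\t", index=False)


def read_predictions(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    need = {"gene_id", "p_low", "p_med", "p_high", "predicted_label"}
    if not need.issubset(df.columns):
        raise ValueError(f"prediction table must have columns {sorted(need)}")
    return df
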