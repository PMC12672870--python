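"""Optimization loop, plateau LR control, chromosome-fold cross-validation.

Training uses Adam from an initial rate of 1e-4, multiplies the rate by 0.1
after every run of 5 consecutive epochs without a strict improvement of the
best validation loss, and stops after 10 consecutive non-improving epochs
(both counters reset on any strict improvement).  The weights checkpointed
at the best validation loss are the ones evaluated on the held-out test
chromosome.

Folds are whole chromosomes (k = number of chromosomes).  Because the held-
out validation split is otherwise unspecified under chromosome-matched CV,
one chromosome from the training folds — chosen round-robin by fold index —
is reserved for early stopping, which preserves the no-leakage property.
Every stochastic element (initialization, shuffling, dropout) derives from
the run seed, so a run is bitwise reproducible.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .config import ModelConfig, TrainConfig
from .genome_io import EncodedDataset, FoldPlan
from .model import MTMixGNet
from .nn import Adam, no_grad
from .predictor import MetricReport, bce_loss, classify, compute_metrics

logger = logging.getLogger(__name__)


class LRController:
    """Plateau learning-rate decay plus early stopping.

    ``update`` is called once per epoch with the validation loss and returns
    ``(lr, stop)``.  "No improvement" means no strict decrease of the best
    loss seen so far.
    """

    def __init__(self, lr0: float, lr_patience: int = 5,
                 lr_factor: float = 0.1, stop_patience: int = 10):
        self.lr = float(lr0)
        self.lr_patience = lr_patience
        self.lr_factor = lr_factor
        self.stop_patience = stop_patience
        self.best = math.inf
        self.bad_epochs = 0

    def update(self, val_loss: float) -> Tuple[float, bool]:
        if val_loss < self.best:
            self.best = val_loss
            self.bad_epochs = 0
            return self.lr, False
        self.bad_epochs += 1
        if self.bad_epochs % self.lr_patience == 0:
            self.lr *= self.lr_factor
        return self.lr, self.bad_epochs >= self.stop_patience


@dataclass
class FoldResult:
    fold: int
    seed: int
    report: MetricReport
    history: List[Dict[str, float]]
    state: Dict[str, np.ndarray]
    test_gene_ids: List[str]
    probs: np.ndarray


@dataclass
class RunSummary:
    """Per-(fold, seed) metric reports plus their mean/sd aggregation."""

    results: List[FoldResult] = field(default_factory=list)

    def table(self) -> pd.DataFrame:
        rows = []
        for r in self.results:
            row = {"fold": r.fold, "seed": r.seed}
            row.update(r.report.as_dict())
            rows.append(row)
        return pd.DataFrame(rows)

    def aggregate(self) -> Dict[str, Dict[str, float]]:
        df = self.table().drop(columns=["fold", "seed"])
        return {col: {"mean": float(df[col].mean()),
                      "sd": float(df[col].std(ddof=1)) if len(df) > 1 else 0.0}
                for col in df.columns}

    def save(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.table().to_csv(out / "per_run_metrics.tsv", sep="\t", index=False)
        (out / "summary.json").write_text(
            json.dumps(self.aggregate(), indent=2, sort_keys=True))


def _epoch_loss(model: MTMixGNet, X: np.ndarray, y: np.ndarray,
                batch_size: int) -> float:
    """Mean BCE over a split in evaluation mode (no dropout, running BN)."""
    was_training = model.training
    model.eval()
    total = 0.0
    try:
        with no_grad():
            for i in range(0, len(X), batch_size):
                xb, yb = X[i:i + batch_size], y[i:i + batch_size]
                total += float(bce_loss(model(xb), yb).data) * len(xb)
    finally:
        model.train(was_training)
    return total / len(X)


def train_fold(dataset: EncodedDataset, plan: FoldPlan, fold: int,
               model_cfg: ModelConfig, train_cfg: TrainConfig,
               seed: int) -> FoldResult:
    """Train with chromosome ``fold`` held out for testing.

    One training chromosome (round-robin by fold index) is reserved as the
    validation split that drives LR decay and early stopping.  Returns the
    best-validation-loss weights and the metric report on the test fold.
    """
    chroms = np.asarray(dataset.chromosomes)
    test_chroms = {c for c, f in plan.chromosome_fold.items() if f == fold}
    if not test_chroms:
        raise ValueError(f"fold {fold} matches no chromosome")
    train_chroms = sorted(set(plan.chromosome_fold) - test_chroms)
    if not train_chroms:
        raise ValueError("no training chromosomes left")
    val_chrom = train_chroms[fold % len(train_chroms)]
    fit_chroms = [c for c in train_chroms if c != val_chrom]
    if not fit_chroms:
        raise ValueError("need >= 3 chromosomes for train/val/test splits")

    idx_fit = np.flatnonzero(np.isin(chroms, fit_chroms))
    idx_val = np.flatnonzero(chroms == val_chrom)
    idx_test = np.flatnonzero(np.isin(chroms, sorted(test_chroms)))
    for name, idx in (("train", idx_fit), ("validation", idx_val),
                      ("test", idx_test)):
        if idx.size == 0:
            raise ValueError(f"empty {name} partition")

    test_ids = {dataset.gene_ids[i] for i in idx_test}
    fit_ids = {dataset.gene_ids[i] for i in idx_fit}
    val_ids = {dataset.gene_ids[i] for i in idx_val}
    assert not (test_ids & (fit_ids | val_ids)), "test-fold leakage detected"
    assert not (fit_ids & val_ids), "train/validation overlap"

    X = dataset.X
    y = dataset.targets()
    model = MTMixGNet(model_cfg, variant=train_cfg.variant, seed=seed)
    optimizer = Adam(model.parameters(), lr=train_cfg.lr0)
    controller = LRController(train_cfg.lr0, train_cfg.lr_patience,
                              train_cfg.lr_factor,
                              train_cfg.early_stop_patience)
    shuffle_rng = np.random.default_rng(np.random.SeedSequence([seed, 2]))

    best_state = model.state_dict()
    best_val = math.inf
    history: List[Dict[str, float]] = []
    bs = train_cfg.batch_size

    for epoch in range(1, train_cfg.max_epochs + 1):
        model.train()
        order = shuffle_rng.permutation(idx_fit)
        train_total = 0.0
        for i in range(0, len(order), bs):
            batch = order[i:i + bs]
            # leakage guard on every optimizer step
            assert not ({dataset.gene_ids[j] for j in batch} & test_ids)
            loss = bce_loss(model(X[batch]), y[batch])
            optimizer.zero_grad()
            loss.backward()
            optimizer.step()
            train_total += float(loss.data) * len(batch)
        train_loss = train_total / len(order)
        val_loss = _epoch_loss(model, X[idx_val], y[idx_val], bs)
        if val_loss < best_val:
            best_val = val_loss
            best_state = model.state_dict()
        lr, stop = controller.update(val_loss)
        optimizer.lr = lr
        history.append({"epoch": epoch, "train_loss": train_loss,
                        "val_loss": val_loss, "lr": lr})
        logger.info("fold=%d seed=%d epoch=%d train_loss=%.4f "
                    "val_loss=%.4f lr=%.2e", fold, seed, epoch,
                    train_loss, val_loss, lr)
        if stop:
            break

    model.load_state_dict(best_state)
    probs = model.predict_proba(X[idx_test], batch_size=bs)
    pred = classify(probs)
    true = dataset.labels[idx_test]
    report = compute_metrics(pred, true, probs)
    return FoldResult(fold=fold, seed=seed, report=report, history=history,
                      state=best_state,
                      test_gene_ids=[dataset.gene_ids[i] for i in idx_test],
                      probs=probs)


def cross_validate(dataset: EncodedDataset, plan: FoldPlan,
                   model_cfg: ModelConfig, train_cfg: TrainConfig,
                   seeds: Optional[Sequence[int]] = None) -> RunSummary:
    """Every fold serves as test once, repeated for each seed."""
    seeds = list(train_cfg.seeds if seeds is None else seeds)
    summary = RunSummary()
    for seed in seeds:
        for fold in range(plan.k):
            summary.results.append(
                train_fold(dataset, plan, fold, model_cfg, train_cfg, seed))
    return summary
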