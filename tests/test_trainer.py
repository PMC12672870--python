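"""Learning-rate controller, fold training, CV integrity, variants."""

import math

import numpy as np
import pytest

from mtmixg.config import ModelConfig, TrainConfig
from mtmixg.genome_io import make_chromosome_folds, GeneRecord
from mtmixg.model import build_variant
from mtmixg.trainer import LRController, cross_validate, train_fold


def controller_oracle(losses, lr0, lr_patience=5, lr_factor=0.1,
                      stop_patience=10):
    """Independent re-simulation: improvement judged against the full-history
    minimum, the non-improving run length recomputed from scratch each epoch.
    Returns the (lr, stop) sequence."""
    out = []
    lr = lr0
    reductions_applied = 0
    for t in range(len(losses)):
        prev_min = min(losses[:t]) if t else math.inf
        # length of the trailing run with no strict improvement
        run = 0
        best = math.inf
        for i in range(t + 1):
            if losses[i] < best:
                best = losses[i]
                run = 0
            else:
                run += 1
        del prev_min
        should_have = 0
        # reductions fire each time a run length crosses a multiple of patience
        best = math.inf
        bad = 0
        for i in range(t + 1):
            if losses[i] < best:
                best = losses[i]
                bad = 0
            else:
                bad += 1
                if bad % lr_patience == 0:
                    should_have += 1
        while reductions_applied < should_have:
            lr *= lr_factor
            reductions_applied += 1
        out.append((lr, run >= stop_patience))
        if run >= stop_patience:
            break
    return out


def run_controller(losses, lr0=1e-4, **kw):
    ctrl = LRController(lr0, **kw)
    out = []
    for loss in losses:
        lr, stop = ctrl.update(loss)
        out.append((lr, stop))
        if stop:
            break
    return out


def test_controller_always_improving_never_stops():
    losses = [1.0 - 0.001 * i for i in range(100)]
    trace = run_controller(losses, lr0=1e-4)
    assert len(trace) == 100
    assert all(lr == 1e-4 and not stop for lr, stop in trace)


def test_controller_flat_trace_reduces_then_stops():
    # 1.0 followed by 12 identical epochs: x0.1 at epoch 6 and again at
    # epoch 11, where the 10-epoch run also triggers the stop
    losses = [1.0] * 13
    trace = run_controller(losses, lr0=1e-4)
    assert len(trace) == 11
    lrs = [lr for lr, _ in trace]
    assert lrs[:5] == [1e-4] * 5
    assert lrs[5] == pytest.approx(1e-5)
    assert lrs[6:10] == [pytest.approx(1e-5)] * 4
    assert lrs[10] == pytest.approx(1e-6)
    assert [s for _, s in trace] == [False] * 10 + [True]


def test_controller_reset_on_improvement():
    losses = [1.0, 1.0, 1.0, 1.0, 0.9, 0.9, 0.9, 0.9, 0.9]
    trace = run_controller(losses, lr0=1e-4)
    # four flat epochs, improvement at epoch 5 resets both counters
    assert all(lr == 1e-4 for lr, _ in trace)
    assert not any(stop for _, stop in trace)


def test_controller_matches_oracle_on_random_sequences(rng):
    for _ in range(1000):
        n = int(rng.integers(1, 30))
        # draw from a small discrete set so plateaus and ties are common
        losses = rng.choice([0.5, 0.6, 0.7, 0.8], size=n).tolist()
        got = run_controller(losses, lr0=1.0)
        expect = controller_oracle(losses, 1.0)
        assert len(got) == len(expect)
        for (lr_g, st_g), (lr_e, st_e) in zip(got, expect):
            assert lr_g == pytest.approx(lr_e) and st_g == st_e


# -- variants ----------------------------------------------------------------


@pytest.fixture
def tiny_cfg():
    return ModelConfig(seq_len=150, channels=8, heads=2, head_dim=2,
                       ssm_hidden=8, ssm_state=4, n_blocks=2,
                       head_hidden=(16, 8), dtype="float32")


def test_variant_capacity_and_structure(tiny_cfg, rng):
    models = {v: build_variant(tiny_cfg, v, seed=0)
              for v in ("M1", "M1+M21", "M1+M22", "M1+M2", "full")}
    assert models["full"].n_parameters() > models["M1"].n_parameters()
    # the attention-only encoder carries no SSM parameters
    attn_only = dict(models["M1+M22"].named_parameters())
    assert not any(".ssm." in k or ".mamba." in k for k in attn_only)
    mamba_only = dict(models["M1+M21"].named_parameters())
    assert any(".ssm." in k for k in mamba_only)
    assert not any(".attention." in k for k in mamba_only)
    X = (rng.random((2, 150, 4)) < 0.25).astype(np.float32)
    for v, m in models.items():
        probs = m.predict_proba(X)
        assert probs.shape == (2, 3)
        assert ((probs > 0) & (probs < 1)).all(), v
    with pytest.raises(ValueError):
        build_variant(tiny_cfg, "M3")


# -- fold training -----------------------------------------------------------


@pytest.fixture
def tiny_train_cfg():
    return TrainConfig(lr0=1e-3, max_epochs=2, batch_size=8, variant="full")


def _plan(dataset):
    genes = [GeneRecord(g, c, "+", 0, 0)
             for g, c in zip(dataset.gene_ids, dataset.chromosomes)]
    return make_chromosome_folds(genes)


def test_train_fold_is_deterministic_given_seed(encoded_tiny, tiny_cfg,
                                                tiny_train_cfg):
    plan = _plan(encoded_tiny)
    r1 = train_fold(encoded_tiny, plan, 0, tiny_cfg, tiny_train_cfg, seed=5)
    r2 = train_fold(encoded_tiny, plan, 0, tiny_cfg, tiny_train_cfg, seed=5)
    assert r1.report.as_dict() == r2.report.as_dict()
    assert r1.history == r2.history
    np.testing.assert_array_equal(r1.probs, r2.probs)


def test_train_fold_keeps_test_genes_out_of_training(encoded_tiny, tiny_cfg,
                                                     tiny_train_cfg):
    plan = _plan(encoded_tiny)
    result = train_fold(encoded_tiny, plan, 1, tiny_cfg, tiny_train_cfg, seed=0)
    test_ids = set(result.test_gene_ids)
    test_chrom = {c for c, f in plan.chromosome_fold.items() if f == 1}
    # the test fold is exactly the held-out chromosome's genes
    expect = {g for g, c in zip(encoded_tiny.gene_ids, encoded_tiny.chromosomes)
              if c in test_chrom}
    assert test_ids == expect
    # history carries one record per epoch with the logged fields
    assert {"epoch", "train_loss", "val_loss", "lr"} <= set(result.history[0])


def test_cross_validate_counts_and_aggregation(encoded_tiny, tiny_cfg):
    cfg = TrainConfig(lr0=1e-3, max_epochs=1, batch_size=8, variant="M1",
                      seeds=[0, 1])
    plan = _plan(encoded_tiny)
    summary = cross_validate(encoded_tiny, plan, tiny_cfg, cfg)
    assert len(summary.results) == plan.k * 2  # k folds x s seeds
    table = summary.table()
    agg = summary.aggregate()
    for col in ("accuracy", "macro_f1", "macro_auc"):
        assert agg[col]["mean"] == pytest.approx(table[col].mean())
        assert agg[col]["sd"] == pytest.approx(table[col].std(ddof=1))


def test_cross_validate_identical_seeds_have_zero_sd(encoded_tiny, tiny_cfg):
    cfg = TrainConfig(lr0=1e-3, max_epochs=1, batch_size=8, variant="M1",
                      seeds=[3, 3])
    plan = _plan(encoded_tiny)
    summary = cross_validate(encoded_tiny, plan, tiny_cfg, cfg)
    table = summary.table()
    per_fold_sd = table.groupby("fold")["accuracy"].std(ddof=1)
    assert (per_fold_sd == 0).all()


def test_summary_save_roundtrip(encoded_tiny, tiny_cfg, tmp_path):
    cfg = TrainConfig(lr0=1e-3, max_epochs=1, batch_size=8, variant="M1",
                      seeds=[0])
    summary = cross_validate(encoded_tiny, _plan(encoded_tiny), tiny_cfg, cfg)
    summary.save(tmp_path)
    assert (tmp_path / "per_run_metrics.tsv").exists()
    assert (tmp_path / "summary.json").exists()


# -- optimization capability -------------------------------------------------


def test_model_can_overfit_small_sample():
    """The full model at reduced size memorizes 64 training windows.

    Stochastic: at least 2 of 3 seeds must reach 100% training accuracy
    within 300 epochs.
    """
    import mtmixg as mx
    from mtmixg.config import FlankSpec, SimConfig
    from mtmixg.nn import Adam

    flank = FlankSpec(384, 128, 0, 0)  # L = 512
    sim = SimConfig(n_chromosomes=2, genes_per_chromosome=32,
                    gene_length_range=(200, 400), gene_spacing=300,
                    flank=flank, seed=2)
    data = mx.simulate(sim)
    labels = mx.assign_labels(data.expression)
    ds = mx.encode_dataset(data.genome, data.genes, labels, flank)
    assert len(ds) == 64
    cfg = ModelConfig(seq_len=512, channels=8, heads=2, head_dim=2,
                      ssm_hidden=8, ssm_state=4, n_blocks=3,
                      head_hidden=(32, 16), dropout_p=0.1, dtype="float32")
    X, y = ds.X, ds.targets()
    successes = 0
    for seed in (0, 1, 2):
        model = mx.MTMixGNet(cfg, "full", seed=seed)
        opt = Adam(model.parameters(), lr=1e-3)
        shuffle = np.random.default_rng(seed)
        reached = False
        for epoch in range(300):
            model.train()
            order = shuffle.permutation(len(ds))
            for i in range(0, len(order), 16):
                b = order[i:i + 16]
                opt.zero_grad()
                loss = mx.bce_loss(model(X[b]), y[b])
                loss.backward()
                opt.step()
            if epoch % 5 == 4:
                pred = mx.classify(model.predict_proba(X, 64))
                if (pred == ds.labels).all():
                    reached = True
                    break
        successes += int(reached)
        if successes == 2:
            break
    assert successes >= 2
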