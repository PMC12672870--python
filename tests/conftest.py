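import numpy as np
import pytest

from mtmixg.config import FlankSpec, ModelConfig, SimConfig


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def toy_genome():
    # 16 nt toy chromosome used by the window-extraction examples
    return {"chr1": "AAAACCCCGGGGTTTT"}


@pytest.fixture
def small_cfg():
    """Small float64 config for tight numerical comparisons with oracles."""
    return ModelConfig(seq_len=32, channels=8, heads=2, head_dim=2,
                       ssm_hidden=6, ssm_state=3, n_blocks=2,
                       dropout_p=0.0, dtype="float64")


@pytest.fixture(scope="session")
def sim_tiny():
    """A quick 3-chromosome cohort with short windows (L = 150)."""
    from mtmixg.simulate import simulate

    flank = FlankSpec(100, 50, 0, 0)
    cfg = SimConfig(n_chromosomes=3, genes_per_chromosome=12,
                    gene_length_range=(120, 200), gene_spacing=300,
                    flank=flank, seed=7)
    return cfg, simulate(cfg)


@pytest.fixture(scope="session")
def encoded_tiny(sim_tiny):
    from mtmixg.genome_io import assign_labels, encode_dataset

    cfg, data = sim_tiny
    labels = assign_labels(data.expression)
    return encode_dataset(data.genome, data.genes, labels, cfg.flank)
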