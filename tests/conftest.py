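import pytest

from seedimprint import synthetic


@pytest.fixture(scope="session")
def small_dataset():
    """A 200-gene reciprocal-cross dataset shared across read-only tests."""
    cfg = synthetic.SimulationConfig(n_genes=200, rng_seed=1)
    return synthetic.simulate_dataset(cfg)


@pytest.fixture(scope="session")
def paperlike_dataset():
    """A dataset at the study-like allelic conditions: pi = 0.028 coding
    divergence, four isolated-endosperm replicates per direction, deep SNP
    coverage, PEG/MEG/ASE genes planted at the generator defaults."""
    cfg = synthetic.SimulationConfig(n_genes=800, rng_seed=7)
    return synthetic.simulate_dataset(cfg)
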