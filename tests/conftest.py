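import pytest

from utrclip.config import SimConfig
from utrclip.simulate import simulate_bundle


@pytest.fixture(scope="session")
def default_bundle():
    """The canonical fixture: default configuration, seed 0."""
    return simulate_bundle(SimConfig())


@pytest.fixture(scope="session")
def default_run():
    """Full pipeline results on the canonical fixture."""
    from utrclip.pipeline import run_all

    return run_all(SimConfig())


@pytest.fixture(scope="session")
def small_genome():
    """A small genome + annotation shared by cheap repeated-seed tests."""
    from utrclip.genome import build_genome

    cfg = SimConfig(seed=11, n_genes=40)
    genome, transcripts = build_genome(cfg)
    return cfg, genome, transcripts
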