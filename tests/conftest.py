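import pytest

from qtlsnp.sim import SimConfig, gen_genome, make_truth


@pytest.fixture(scope="session")
def sim_cfg() -> SimConfig:
    return SimConfig(seed=11)


@pytest.fixture(scope="session")
def toy_world(sim_cfg):
    """(genome, genes, truth) bundle shared by read-only tests."""
    genome, genes = gen_genome(sim_cfg)
    truth = make_truth(genome, genes, sim_cfg)
    return genome, genes, truth
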