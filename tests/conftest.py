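import pytest

from sololtr import SimConfig, candidate_sets, discover, simulate_genome


@pytest.fixture(scope="session")
def sim100():
    """100 kb genome, 6 full ERVs + 6 solo-LTRs, divergence 0."""
    config = SimConfig(genome_length=100_000, n_scaffolds=2,
                       n_full_erv=6, n_solo=6, seed=1)
    genome, truth = simulate_genome(config)
    return config, genome, truth


@pytest.fixture(scope="session")
def discovery100(sim100):
    """Full discovery run on the 100 kb fixture genome."""
    _, genome, truth = sim100
    set_a, set_b = candidate_sets(truth)
    return discover(genome, set_a, set_b)
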