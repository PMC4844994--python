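import pytest

from pectevol.simulate import (
    SimulationConfig,
    apply_wgt_fractionation,
    simulate_ancestral_genome,
)


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(n_genes=200, n_chromosomes=2, n_pg=10, n_pme=12,
                            pme_type1_fraction=7 / 12, n_codons=60, seed=11)


@pytest.fixture(scope="session")
def ancestor(small_config):
    return simulate_ancestral_genome(small_config)


@pytest.fixture(scope="session")
def wgt_genome(small_config, ancestor):
    return apply_wgt_fractionation(ancestor, small_config)
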