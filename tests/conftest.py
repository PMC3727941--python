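import pytest

from famprio.core import PipelineConfig
from famprio.io import GenePanel
from famprio.simulate import SimulationConfig, causal_panel_gene, simulate_family


@pytest.fixture(scope="session")
def cfg():
    return PipelineConfig()


@pytest.fixture(scope="session")
def big_gene():
    """The 17-exon toy deafness gene (4320 coding bases in exons 1-11)."""
    return causal_panel_gene()


@pytest.fixture(scope="session")
def quartet_sim():
    """Default quartet simulation (seed 1): compound-het causal + decoys."""
    return simulate_family(SimulationConfig(random_seed=1))


@pytest.fixture(scope="session")
def quartet_panel(quartet_sim):
    return GenePanel(quartet_sim.config.panel_genes)
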