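import numpy as np
import pytest

from chiptarget.config import PipelineConfig, SimulationParams


@pytest.fixture
def small_params() -> SimulationParams:
    """A quick 200-kbp single-chromosome dataset for unit tests."""
    return SimulationParams(
        genome_length=200_000, n_chromosomes=1, n_genes=40, site_count=10,
        n_chip_reads=30_000, n_input_reads=30_000, seed=11,
    )


@pytest.fixture
def config() -> PipelineConfig:
    return PipelineConfig()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
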