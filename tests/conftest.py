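import numpy as np
import pytest

from mgx.io_formats import RunConfig
from mgx.synthetic import SimulationSpec, generate_expression


@pytest.fixture(scope="session")
def small_matrix():
    """A quickly-separable small cohort: 1,000 genes, 60 Adeno / 20 Meso."""
    spec = SimulationSpec(n_genes=1000, n_adeno=60, n_meso=20,
                          n_informative_blocks=10, block_width=50,
                          effect_size=3.0, seed=3)
    return generate_expression(spec)


@pytest.fixture(scope="session")
def null_matrix():
    """Same shape with no class signal (effect_size = 0)."""
    spec = SimulationSpec(n_genes=1000, n_adeno=60, n_meso=20,
                          n_informative_blocks=10, block_width=50,
                          effect_size=0.0, seed=3)
    return generate_expression(spec)


@pytest.fixture
def desk_config():
    return RunConfig(dr_method="DFA", fsel_method="none", classifier="SVM_linear",
                     target_dim=100, folds=10, seed=5,
                     population=30, iterations=60)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
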