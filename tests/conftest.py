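import numpy as np
import pytest

from cnalineage.profile import average_probes_to_genes
from cnalineage.simulate import CohortConfig, NoiseModel, simulate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """Default-noise cohort, seed 5 (33 mucosal + 3 deep samples)."""
    return simulate_cohort(CohortConfig(seed=5))


@pytest.fixture(scope="session")
def default_matrix(default_cohort):
    return average_probes_to_genes(
        default_cohort.probes, default_cohort.genome.genes_df()
    )


@pytest.fixture(scope="session")
def zero_noise_cohort():
    """Noise-free cohort, seed 5: gene averages are exactly log2(copy/2)."""
    return simulate_cohort(CohortConfig(seed=5, noise=NoiseModel(probe_sd=0.0)))


@pytest.fixture(scope="session")
def zero_noise_matrix(zero_noise_cohort):
    return average_probes_to_genes(
        zero_noise_cohort.probes, zero_noise_cohort.genome.genes_df()
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
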