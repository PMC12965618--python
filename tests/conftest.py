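import numpy as np
import pytest

from viradiel.core_io import AbundanceMatrix, Sample, clock_from_elapsed
from viradiel.syndata import SyntheticConfig, sampling_scheme, simulate_abundance


@pytest.fixture(scope="session")
def sur_samples():
    return sampling_scheme("SUR")


@pytest.fixture(scope="session")
def dcm_samples():
    return sampling_scheme("DCM")


@pytest.fixture
def tiny_matrix():
    """3 populations x 4 SUR-style samples, hand-set values."""
    samples = [
        Sample(sample_id=f"T{int(h)}_S", depth_layer="SUR",
               clock_time=clock_from_elapsed(h), elapsed_hours=h,
               included=True, clean_reads=10**8)
        for h in (0.0, 4.0, 8.0, 12.0)
    ]
    values = np.array([
        [1.0, 2.0, 3.0, 4.0],
        [4.0, 3.0, 2.0, 1.0],
        [5.0, 5.0, 5.0, 5.0],
    ])
    return AbundanceMatrix(population_ids=["a", "b", "c"],
                           samples=samples, values=values)


@pytest.fixture(scope="session")
def planted_sim():
    """The planted-archetype study conditions (shared across tests)."""
    cfg = SyntheticConfig(n_populations=300, fraction_diel=0.5,
                          noise_sd=0.3, seed=0)
    return simulate_abundance(cfg)


def sur_classes(samples, deltat=4.0):
    clock = np.array([s.clock_hours for s in samples])
    c = int(round(24 / deltat))
    return np.round((clock % 24) / deltat).astype(int) % c
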