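import numpy as np
import pytest

from packped.genotypes import AlleleFrequencyTable, ErrorModel
from packped.simulate import SimulationConfig, generate_allele_frequencies, simulate_population


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture(scope="session")
def freqs18():
    """18 loci x 8 alleles, the marker panel scale of the study system."""
    return generate_allele_frequencies(18, 8, seed=7)


@pytest.fixture(scope="session")
def uniform4():
    """One locus, four equifrequent alleles (hand-computable)."""
    return AlleleFrequencyTable([{1: 0.25, 2: 0.25, 3: 0.25, 4: 0.25}])


@pytest.fixture(scope="session")
def small_pop():
    """A small multi-year population reused across pipeline tests."""
    cfg = SimulationConfig(n_groups=5, years=4, samples_per_group_year=20,
                           harvest_rates=(0.0, 0.2, 0.15, 0.1), seed=11)
    return simulate_population(cfg)


@pytest.fixture(scope="session")
def no_error():
    return ErrorModel(0.0, 0.0, 0.0)
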