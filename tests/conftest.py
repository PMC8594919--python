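import numpy as np
import pytest

from coevoscan import simgen


@pytest.fixture(scope="session")
def small_cohort():
    """A deterministic PEL-scale neutral cohort shared across tests."""
    return simgen.simulate_cohort(simgen.pel_like(seed=11))


@pytest.fixture(scope="session")
def neutral_panel():
    """Coalescent haplotypes with realistic LD for EHH/iHS tests."""
    hm, gmap = simgen.simulate_haplotypes(
        n_samples=40, sequence_length=800_000, seed=29
    )
    return hm, gmap


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
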