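import numpy as np
import pytest

from strandchart import SimConfig, StrandChart, synth_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def pilot_cohort():
    """A 20k-patient synthetic pilot block (in-control process)."""
    return synth_cohort(SimConfig(n_patients=20_000, seed=101))


@pytest.fixture(scope="session")
def fitted_chart(pilot_cohort):
    """A 5-strand chart calibrated on the synthetic pilot."""
    return StrandChart().fit(pilot_cohort)
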