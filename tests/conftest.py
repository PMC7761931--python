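import numpy as np
import pytest

from srcnet import CohortConfig, CouplingSpec


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_cohort_config():
    """Two groups x 4 subjects, 6 nodes, one strongly vs one weakly coupled edge."""
    return CohortConfig(
        n_subjects_per_group=4,
        n_nodes=6,
        fs=250.0,
        epoch_seconds=2.0,
        n_epochs=6,
        noise_sd=2.0,
        osc_amplitude=10.0,
        group_coupling=[
            [CouplingSpec("alpha", ((0, 1, 0.3),), 10.0)],
            [CouplingSpec("alpha", ((0, 1, 2.0),), 10.0)],
        ],
        panss_effects=[{"P1": 2.0, "P3": 2.0}, {}],
        seed=99,
    )
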