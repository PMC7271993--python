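import numpy as np
import pytest

from trailcycle import ExperimentConfig, PhaseParams, generate_population


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def nci_params():
    """NCI-H460 phase parameterization with the observed duration coupling."""
    return PhaseParams(1.96, 0.27, 2.18, 0.19, f_g1=0.45).with_duration_corr(0.33)


@pytest.fixture(scope="session")
def midsize_tracks(nci_params):
    """A 4000-cell virtual population treated at z = 3.6 h (shared, read-only)."""
    cfg = ExperimentConfig(n_cells=4000, z_true=3.6,
                           phase_params=nci_params, seed=42)
    return generate_population(cfg)
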