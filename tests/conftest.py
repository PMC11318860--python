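import numpy as np
import pytest

from chillconn import SimulationConfig, simulate_cohort, simulate_parcellation

SMALL_NETWORKS = {"auditory": 4, "reward": 2, "visual": 3, "default_mode": 3}


def small_config(**overrides):
    base = dict(
        n_participants=6,
        n_trials=2,
        trials_per_session=2,
        music_duration=60.0,
        physio_rate=25.0,
        rois_per_network=dict(SMALL_NETWORKS),
        seed=7,
    )
    base.update(overrides)
    return SimulationConfig(**base)


@pytest.fixture(scope="session")
def small_cohort():
    """A fast, fully populated cohort reused across tests."""
    return simulate_cohort(small_config())


@pytest.fixture(scope="session")
def default_parcellation():
    return simulate_parcellation()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
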