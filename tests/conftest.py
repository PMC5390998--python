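import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from emg2lip import synthetic_data as syn
from emg2lip.evaluation import FeatureSetting

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def bundle():
    """One fully simulated synthetic volunteer (default noise levels)."""
    vol = syn.make_volunteer(7, 0)
    return syn.simulate_volunteer(vol)


@pytest.fixture(scope="session")
def dataset_pca(bundle):
    """Volunteer dataset at the PCA route's reference setting."""
    return syn.extract_dataset(
        bundle, FeatureSetting("unipolar", "WAMP", 300, 10.0)
    )


@pytest.fixture(scope="session")
def dataset_grnn(bundle):
    """Volunteer dataset at the GRNN route's reference setting."""
    return syn.extract_dataset(bundle, FeatureSetting("bipolar", "MAV", 50))


@pytest.fixture(scope="session")
def cameras():
    return syn.default_cameras()


@pytest.fixture(scope="session")
def cube():
    return syn.cube_nodes()
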