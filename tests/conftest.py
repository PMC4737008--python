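import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from eegconn.preprocess import assemble_dataset
from eegconn.simulate import simulate_dataset, study_config

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

#: planted couplings of the default study config, as
#: (lead pair, montage positions, baseline r, trained r)
PLANTED_OVERALL = [
    ("F7-T3", (11, 13), 0.67, 0.45),
    ("O1-T6", (9, 16), 0.37, 0.54),
    ("Cz-Fz", (17, 18), 0.53, 0.34),
]


@pytest.fixture(scope="session")
def study_recordings():
    """Simulated full-geometry study dataset (overall-band couplings)."""
    return simulate_dataset(study_config(seed=1))


@pytest.fixture(scope="session")
def study_epochs(study_recordings):
    """Preprocessed 320-epoch dataset (bandpass, middle 40 s, 1024-sample epochs)."""
    return assemble_dataset(study_recordings)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20160123)
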