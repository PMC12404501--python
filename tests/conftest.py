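import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import ramantissue as rt
from ramantissue.preprocess import preprocess_dataset

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def profiles():
    return rt.default_profiles()


@pytest.fixture(scope="session")
def axis():
    return rt.default_axis()


@pytest.fixture(scope="session")
def small_dataset(profiles):
    """40 spectra per class on the default axis (session-wide, seed 123)."""
    rng = np.random.default_rng(123)
    counts = {c: 40 for c in rt.TISSUE_CLASSES}
    return rt.generate_dataset(profiles, counts, rng)


@pytest.fixture(scope="session")
def small_processed(small_dataset):
    return preprocess_dataset(small_dataset)
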