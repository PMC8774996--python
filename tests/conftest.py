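import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import covdet as cd

settings.register_profile(
    "ci", derandomize=True, max_examples=40, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_synth_channels():
    """A small but fully separable synthetic dataset for unit tests."""
    cfg = cd.SynthConfig(n_per_class=8, n_subjects=4, seed=7)
    return cd.gen_dataset(cfg)


@pytest.fixture(scope="session")
def small_feature_table(small_synth_channels):
    return cd.extract_features(small_synth_channels)


@pytest.fixture(scope="session")
def small_labels(small_feature_table):
    return (small_feature_table["label"] == cd.LABEL_SEIZURE).astype(int).to_numpy()


@pytest.fixture
def ramp_channel():
    return cd.RawChannel(np.arange(4097, dtype=float), fs=173.61,
                         label="A", channel_id="ramp")
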