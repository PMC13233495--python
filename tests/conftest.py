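"""Shared fixtures: one small synthetic session reused across unit tests."""

import numpy as np
import pytest

from eegfatigue import (SimulationConfig, generate_session,
                        preprocess_continuous, epoch_and_notch, flag_artifacts,
                        build_feature_tensor)


SMALL_CONFIG = SimulationConfig(sampling_rate=125.0, block_count=2,
                                trials_per_block=3, pre_post_rest_s=30.0,
                                seed=12345)


@pytest.fixture(scope="session")
def small_session():
    return generate_session(SMALL_CONFIG, "mi")


@pytest.fixture(scope="session")
def small_epochs(small_session):
    clean = preprocess_continuous(small_session.eeg)
    ep = epoch_and_notch(clean, small_session.segments, step=2.0)
    return flag_artifacts(ep)


@pytest.fixture(scope="session")
def small_tensor(small_epochs):
    return build_feature_tensor(small_epochs)
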