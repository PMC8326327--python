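"""Shared fixtures: simulated sessions and a trained decoder.

Everything is generated programmatically with fixed seeds; session scope
keeps the expensive simulate -> preprocess -> train chain to one run.
"""

from __future__ import annotations

import numpy as np
import pytest

import p300tour as pt


@pytest.fixture(scope="session")
def training_session():
    """Default-condition training session (seed 1): (eeg, schedule, targets)."""
    return pt.simulate_session("training", seed=1)


@pytest.fixture(scope="session")
def training_features(training_session):
    eeg, schedule, _ = training_session
    return pt.preprocess(eeg, schedule)


@pytest.fixture(scope="session")
def training_epochs(training_session):
    eeg, schedule, _ = training_session
    _, epochs = pt.preprocess(eeg, schedule, return_epochs=True)
    return epochs


@pytest.fixture(scope="session")
def trained_model(training_features):
    return pt.train_swlda(training_features)


@pytest.fixture(scope="session")
def online_session():
    """Default-condition online session (seed 1101)."""
    return pt.simulate_session("online", seed=1101)


@pytest.fixture(scope="session")
def online_features(online_session):
    eeg, schedule, _ = online_session
    return pt.preprocess(eeg, schedule)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240924)
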