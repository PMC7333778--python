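"""Shared synthetic fixtures.

Everything is generated at test time from the synthetic protocol presets with
fixed seeds; the heavier simulations are session-scoped so detection,
clustering and recovery are exercised once and inspected by many tests.
"""

import warnings

import numpy as np
import pytest

from stimdict import StimulationArtifactModel, simulate

warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture(scope="session")
def uniform_sim():
    """200 Hz biphasic train, 4 artifact morphologies, 6 channels, 5 epochs."""
    return simulate("uniform_s1", seed=1, n_channels=6, n_epochs=5)


@pytest.fixture(scope="session")
def uniform_model(uniform_sim):
    rec, _ = uniform_sim
    model = StimulationArtifactModel(rec)
    model.detect()
    return model


@pytest.fixture(scope="session")
def uniform_fit(uniform_model):
    return uniform_model.fit()


@pytest.fixture(scope="session")
def outlier_sim():
    """Uniform train with 5 injected deviant (outlier) pulses."""
    return simulate("uniform_s1", seed=3, n_channels=4, n_epochs=5, n_outliers=5)


@pytest.fixture(scope="session")
def outlier_fit(outlier_sim):
    rec, _ = outlier_sim
    model = StimulationArtifactModel(rec)
    return model, model.fit()


@pytest.fixture(scope="session")
def nonuniform_sim():
    """Two high-amplitude pulses then 38 low ones, with a 100 Hz oscillation."""
    return simulate("nonuniform", seed=2, n_channels=6, n_epochs=8,
                    oscillation_amp=5.0)


@pytest.fixture(scope="session")
def undersampled_fit():
    """1221 Hz acquisition of 200 µs pulses: the failure regime."""
    rec, truth = simulate("undersampled", seed=4, n_channels=6, n_epochs=8)
    model = StimulationArtifactModel(rec)
    return rec, truth, model, model.fit()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
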