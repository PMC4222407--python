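"""Shared fixtures: the calibrated model and its F-I sweeps are expensive
(numba-compiled cable integration), so they are built once per session."""

import numpy as np
import pytest

from l5sim import distribution, engine, experiments
from l5sim.ephys_features import fi_features, spike_count


@pytest.fixture(scope="session")
def control_model():
    return distribution.default_model()


@pytest.fixture(scope="session")
def pkc_model(control_model):
    return experiments.apply_modulation(control_model,
                                        experiments.pkc_modulation())


@pytest.fixture(scope="session")
def control_sweep(control_model):
    """Full 13-amplitude 50-pA F-I family of the control model."""
    return engine.run_fi_protocol(control_model)


@pytest.fixture(scope="session")
def pkc_sweep(pkc_model):
    return engine.run_fi_protocol(pkc_model)


@pytest.fixture(scope="session")
def control_fit(control_sweep):
    return fi_features(control_sweep)


@pytest.fixture(scope="session")
def pkc_fit(pkc_sweep):
    return fi_features(pkc_sweep)


@pytest.fixture(scope="session")
def control_counts(control_sweep):
    return {tr.stimulus_amplitude: spike_count(tr) for tr in control_sweep}


@pytest.fixture(scope="session")
def pkc_counts(pkc_sweep):
    return {tr.stimulus_amplitude: spike_count(tr) for tr in pkc_sweep}


@pytest.fixture(scope="session")
def reduced_grid():
    """7-amplitude grid used for the multi-model analyses."""
    return np.arange(0.0, 601.0, 100.0)
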