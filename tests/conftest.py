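"""Shared fixtures; the expensive ones are session-scoped."""

import numpy as np
import pytest

from vasodyn import synthio


@pytest.fixture(scope="session")
def trace_cohort():
    """50 one-hour traces at moderate rate with ground truth."""
    params = synthio.TraceGenParams(n_vessels=50, spasm_rate=2.0,
                                    magnitude=20.0, noise_sd=0.005, seed=11)
    traces, truth = synthio.gen_vessel_traces(params)
    return params, traces, truth


@pytest.fixture(scope="session")
def stricture_stack():
    """Small volume with one calibrated shift and one focal stricture."""
    params = synthio.StackGenParams(
        shape=(24, 128, 128), voxel_size=(2.0, 0.5, 0.5), n_vessels=3,
        vessel_radius=2.0, n_cells=200, positive_fraction=0.5,
        target_shift=15.0, stricture_spec=((0, 40.0, 1.0),),
        vessel_intensity=200.0, noise_sd=0.0, seed=7)
    stack, truth = synthio.gen_stack(params)
    return params, stack, truth


@pytest.fixture(scope="session")
def coupled_trains():
    params = synthio.TrainGenParams(n_animals=8, session=10.0,
                                    seizure_rate=2.0,
                                    background_spasm_rate=0.5,
                                    coupling_fraction=0.5, seed=3)
    trains, truth = synthio.gen_event_trains(params)
    return params, trains, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
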