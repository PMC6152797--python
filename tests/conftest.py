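import numpy as np
import pandas as pd
import pytest

from thiolife import (
    DECAY,
    SimulationDesign,
    TimecourseSet,
    sample_true_params,
    simulate_decay_timecourse,
)

GRID = (0.0, 2.0, 4.0, 8.0, 16.0, 32.0)


def make_set(values, timepoints=GRID, spike=None, channel=DECAY, ids=None, **kw):
    """Build a TimecourseSet from a plain array of per-transcript series."""
    values = np.atleast_2d(np.asarray(values, dtype=float))
    timepoints = np.asarray(timepoints, dtype=float)[: values.shape[1]]
    if ids is None:
        ids = [f"tx{i}" for i in range(len(values))]
    spike = np.ones(len(timepoints)) if spike is None else np.asarray(spike, float)
    df = pd.DataFrame(values, index=pd.Index(ids, name="transcript_id"), columns=timepoints)
    return TimecourseSet(values=df, spike=pd.Series(spike, index=df.columns),
                         channel=channel, **kw)


@pytest.fixture(scope="session")
def truth_small():
    return sample_true_params(60, seed=101)


@pytest.fixture(scope="session")
def noiseless_decay(truth_small):
    return simulate_decay_timecourse(
        truth_small, SimulationDesign(noise_sigma=0.0, channel=DECAY, seed=0))


@pytest.fixture(scope="session")
def noisy_decay(truth_small):
    return simulate_decay_timecourse(
        truth_small, SimulationDesign(noise_sigma=0.05, channel=DECAY, seed=3))
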