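import numpy as np
import pandas as pd
import pytest

from dpxdyn.data import ChannelSet, SubjectEpochs, TimeAxis
from dpxdyn.simulate import BlockSpec, grid_channel_set, make_trial_sequence


@pytest.fixture
def small_channels() -> ChannelSet:
    return grid_channel_set(4)


@pytest.fixture
def small_axis() -> TimeAxis:
    return TimeAxis.from_span(-0.5, 0.5, 50.0)


def _filled_trials(n: int, rng: np.random.Generator) -> pd.DataFrame:
    block = BlockSpec(n_AX=max(n - 3, 1), n_AY=1, n_BX=1, n_BY=1, n_blocks=1)
    trials = make_trial_sequence(block, rng)
    trials["correct"] = pd.array([True] * len(trials), dtype="boolean")
    trials["response"] = np.where(trials["pair"] == "AX", "target", "nontarget")
    trials["rt"] = rng.uniform(0.2, 0.6, size=len(trials))
    return trials


@pytest.fixture
def small_epochs(small_channels, small_axis) -> SubjectEpochs:
    """10 trials x 4 channels x 51 samples of reproducible random amplitudes."""
    rng = np.random.default_rng(7)
    trials = _filled_trials(10, rng)
    data = rng.normal(0.0, 5.0, size=(len(trials), 4, len(small_axis)))
    return SubjectEpochs("sub-01", data, small_channels, small_axis, trials)


@pytest.fixture
def trials_factory():
    return _filled_trials
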