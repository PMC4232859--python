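import numpy as np
import pytest

from samface.containers import FACE, SCRAMBLED, EpochSet, default_time_axis
from samface.simulate import helmet_sensors


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_sensors():
    return helmet_sensors(24, radius=0.12)


def make_epochs(
    data: np.ndarray,
    sfreq: float,
    labels=None,
    sensors=None,
) -> EpochSet:
    """Wrap raw (trials, channels, time) data in an EpochSet with onset at 0."""
    n_trials, _, n_t = data.shape
    n_pre = n_t // 2
    time = (np.arange(n_t) - n_pre) / sfreq
    if labels is None:
        labels = np.array([FACE, SCRAMBLED] * ((n_trials + 1) // 2))[:n_trials]
    return EpochSet(data=data, sfreq=sfreq, time=time, labels=np.asarray(labels), sensors=sensors)
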