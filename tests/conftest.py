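import numpy as np
import pytest

from eegdyn.io import Recording
from eegdyn.synth import CohortSpec, ConditionParams, generate_recording


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def labels32():
    from eegdyn.montage import MONTAGE_32_LABELS

    return MONTAGE_32_LABELS


@pytest.fixture
def single_channel_spec():
    return CohortSpec(n_participants=2, n_channels=1, fs=250.0, duration=60.0, seed=0)


@pytest.fixture
def plain_background(single_channel_spec):
    """60-s single-channel 1/f recording, no oscillations, no PAC."""
    params = ConditionParams(aperiodic_low=(0.1, 1.0), aperiodic_high=(0.1, 1.0))
    return generate_recording(single_channel_spec, params, 7)


def make_recording(data, fs=250.0, labels=None, **kw):
    data = np.atleast_2d(np.asarray(data, dtype=float))
    if labels is None:
        labels = tuple(f"ch{i}" for i in range(data.shape[0]))
    return Recording(data=data, fs=fs, channel_labels=labels, **kw)


@pytest.fixture
def mk_rec():
    return make_recording
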