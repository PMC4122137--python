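import numpy as np
import pytest

from premovement.preprocess import EventOnsets, downsample_to_200, epoch_trials, exclude_channels
from premovement.synthetic import EMG_LABEL, PlantedEffect, SyntheticConfig, generate_dataset


def epochs_from_dataset(ds, session=0):
    """Downsample, drop the EMG channel and cut premovement epochs."""
    rec = downsample_to_200(ds.recordings[session])
    rec = exclude_channels(rec, [EMG_LABEL])
    events = EventOnsets(onsets=list(ds.events[session]))
    return epoch_trials(rec, events)


@pytest.fixture(scope="session")
def beta_effect_config():
    """One 6 dB beta-band effect planted on a sensorimotor channel."""
    return SyntheticConfig(
        n_channels=6,
        fs=200,
        trials_per_session_per_class=40,
        planted_effects=[
            PlantedEffect(channel=4, f_lo=15.0, f_hi=25.0,
                          class_with_higher_power="hand", magnitude_db=6.0)
        ],
        rng_seed=11,
    )


@pytest.fixture(scope="session")
def beta_effect_dataset(beta_effect_config):
    return generate_dataset(beta_effect_config)


@pytest.fixture(scope="session")
def beta_effect_epochs(beta_effect_dataset):
    return epochs_from_dataset(beta_effect_dataset)


@pytest.fixture(scope="session")
def zero_effect_dataset():
    cfg = SyntheticConfig(
        n_channels=6, fs=200, trials_per_session_per_class=40, rng_seed=5
    )
    return generate_dataset(cfg)


@pytest.fixture(scope="session")
def zero_effect_epochs(zero_effect_dataset):
    return epochs_from_dataset(zero_effect_dataset)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
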