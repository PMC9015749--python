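import datetime as dt

import numpy as np
import pytest

from homesense import synth


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def regular_config():
    """Noiseless household: sleep 23:00-07:00 every day, full sensor response."""
    return synth.HouseholdConfig(
        household_id="reg",
        n_sensors=6,
        n_occupants=2,
        n_days=40,
        start_date=dt.date(2018, 4, 2),  # a Monday
        sleep_onset_mean=(1380,) * 7,
        wake_mean=(420,) * 7,
        schedule_sd=0.0,
        p_active=1.0,
        p_noise=0.0,
        seed=7,
    )


@pytest.fixture
def regular_household(regular_config):
    return synth.generate_household(regular_config)
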