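import numpy as np
import pandas as pd
import pytest

from oddball.containers import EpochSet
from oddball.montage import disc_montage
from oddball.paradigm import build_block, schedule_events


@pytest.fixture(scope="session")
def montage16():
    return disc_montage(16)


@pytest.fixture(scope="session")
def montage24():
    return disc_montage(24)


@pytest.fixture
def timeline12():
    """Small scheduled block: 12 series, seeded."""
    plan = build_block("a", n_series=12, deviant_fraction=0.33, rng_seed=7)
    return schedule_events(plan, rng_seed=8)


def make_epochs(montage, n_trials=20, n_times=100, sfreq=250.0, seed=0,
                states=("PRE",), tmin=-0.2):
    """Random epochs with balanced standard/deviant metadata."""
    rng = np.random.default_rng(seed)
    data = rng.normal(scale=1.0, size=(n_trials, montage.n_sensors, n_times))
    stim = np.where(np.arange(n_trials) % 3 == 0, "deviant", "standard")
    meta = pd.DataFrame(
        {
            "series_index": np.arange(n_trials),
            "stimulus": stim,
            "block_type": ["a"] * n_trials,
            "state": [states[i % len(states)] for i in range(n_trials)],
        }
    )
    times = tmin + np.arange(n_times) / sfreq
    return EpochSet(data=data, sfreq=sfreq, times=times, metadata=meta,
                    montage=montage)


@pytest.fixture
def epochs16(montage16):
    return make_epochs(montage16)
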