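import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from serialdep.circular import wrap_orientation
from serialdep.observer import ObserverParams, OrientationGrid, TransitionModel


@pytest.fixture(scope="session")
def grid():
    return OrientationGrid(360)


@pytest.fixture(scope="session")
def coarse_grid():
    return OrientationGrid(180)


@pytest.fixture(scope="session")
def full_params():
    """Canonical full-model observer used across tests."""
    return ObserverParams(
        sigma_s=10.0,
        enc=TransitionModel(p_same=0.8, sigma_td=11.0),
        dec=TransitionModel(p_same=0.8, sigma_td=8.0),
        tau_enc=8.0,
        tau_dec=1.5,
        variant="full",
    )


def make_trial_table(n_participants=3, n_blocks=2, trials_per_block=50, seed=0,
                     error_sd=6.0, **extra_columns):
    """Small hand-rolled trial table: responses = stimulus + Gaussian error."""
    rng = np.random.default_rng(seed)
    frames = []
    for p in range(n_participants):
        for b in range(n_blocks):
            stim = 180.0 - rng.random(trials_per_block) * 180.0
            resp = wrap_orientation(stim + rng.normal(0.0, error_sd, trials_per_block))
            frame = pd.DataFrame({
                "participant": p,
                "block": b,
                "trial_index": np.arange(1, trials_per_block + 1),
                "stimulus": stim,
                "response": resp,
            })
            for col, values in extra_columns.items():
                frame[col] = rng.choice(values, size=trials_per_block)
            frames.append(frame)
    return pd.concat(frames, ignore_index=True)


@pytest.fixture
def small_table():
    return make_trial_table()
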