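"""Shared fixtures: small synthetic datasets generated at test time."""

import numpy as np
import pandas as pd
import pytest

from msvp.preprocess import Epochs, GRID_TIMES_MS, N_GRID, rate_of_pupil_change
from msvp.simulate import default_config, simulate_dataset


@pytest.fixture(scope="session")
def small_table():
    """8-participant constrained-gaze dataset at the default study structure."""
    return simulate_dataset(default_config(n_participants=8, seed=11))


@pytest.fixture(scope="session")
def small_epochs(small_table):
    from msvp.preprocess import preprocess

    epochs, _ = preprocess(small_table)
    return epochs


@pytest.fixture(scope="session")
def free_table():
    return simulate_dataset(default_config(gaze_mode="free", n_participants=8,
                                           seed=12))


@pytest.fixture(scope="session")
def free_epochs(free_table):
    from msvp.preprocess import preprocess

    epochs, _ = preprocess(free_table)
    return epochs


def build_epochs(values_by_participant, condition_cycle=("familiar", "control1",
                                                         "control2"),
                 measure_noise=0.0, rng=None):
    """Construct an Epochs object directly from per-trial trace arrays.

    ``values_by_participant`` maps participant id -> (n_trials, 250) pupil
    array; conditions cycle through ``condition_cycle`` per participant.
    """
    rng = rng or np.random.default_rng(0)
    rows, mats = [], []
    for pid, mat in values_by_participant.items():
        mat = np.asarray(mat, dtype=float)
        assert mat.shape[1] == N_GRID
        for i in range(mat.shape[0]):
            rows.append(
                {
                    "participant_id": pid,
                    "trial_index": i,
                    "condition": condition_cycle[i % len(condition_cycle)],
                    "critical_position": 5,
                    "critical_direction": 1,
                    "baseline_au": 0.0,
                }
            )
        mats.append(mat)
    pupil = np.vstack(mats)
    if measure_noise:
        pupil = pupil + rng.normal(0, measure_noise, size=pupil.shape)
    valid = np.ones_like(pupil, dtype=bool)
    rate, rate_valid = rate_of_pupil_change(pupil, valid)
    return Epochs(
        trials=pd.DataFrame(rows),
        pupil_bl=pupil,
        gaze_signed=pupil.copy(),
        pupil_rate=rate,
        valid=valid,
        rate_valid=rate_valid,
    )


@pytest.fixture
def epoch_builder():
    return build_epochs
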