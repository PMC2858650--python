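import numpy as np
import pandas as pd
import pytest

import aepstats as ap
from aepstats.containers import Evoked, default_times


@pytest.fixture(scope="session")
def montage():
    return ap.default_montage()


@pytest.fixture(scope="session")
def small_trial_study(montage):
    """Trial-level study small enough to run the full pipeline on."""
    cfg = ap.SimConfig(n_subjects_per_group=2, sessions=(1, 2),
                       trials_per_block=12, noise_sd=15.0,
                       artifact_rate=0.2, seed=11)
    study, truth = ap.simulate_study(cfg, montage=montage)
    return cfg, study, truth


@pytest.fixture(scope="session")
def planted_evokeds(montage):
    """Evoked-level study with the default planted P2 gain (10/group,
    sessions 1-3, matched-to-trial-level noise for noise_sd = 1 µV)."""
    cfg = ap.SimConfig(n_subjects_per_group=10, sessions=(1, 2, 3),
                       seed=42, noise_sd=1.0)
    evokeds, truth = ap.simulate_study_evoked(cfg)
    return cfg, evokeds, truth


def make_evoked(data, channels, times=None, subject="s0", group=1,
                session=1, stimulus="mba"):
    times = times if times is not None else default_times()
    return Evoked(data=np.asarray(data, float), times=times,
                  channels=list(channels), subject=subject, group=group,
                  session=session, stimulus=stimulus, n_trials_included=1)


@pytest.fixture
def make_ev():
    return make_evoked
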