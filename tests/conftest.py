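import numpy as np
import pytest

from gaitwave.events import AccelTrial
from gaitwave.pipeline import materialize
from gaitwave.simulate import GaitParams, generate_cohort, generate_trial


@pytest.fixture(scope="session")
def clean_trial():
    """One noiseless, jitter-free normal-speed trial resampled to 250 Hz."""
    p = GaitParams.for_condition("normal", noise_sd=0.0, drift_amp=0.0, step_time_cv=0.0)
    st = generate_trial(p, seed=7)
    trials, refs = materialize([st], fs_target=250.0)
    return trials[0], refs[0], st


@pytest.fixture(scope="session")
def default_trial():
    """One default (noisy) normal-speed trial resampled to 250 Hz."""
    st = generate_trial(GaitParams.for_condition("normal"), seed=11)
    trials, refs = materialize([st], fs_target=250.0)
    return trials[0], refs[0], st


@pytest.fixture(scope="session")
def mini_cohort():
    """A small seeded cohort (4 subjects x 3 conditions x 3 trials) at 250 Hz."""
    cohort = generate_cohort(n_subjects=4, trials_per_condition=3, seed=5)
    trials, refs = materialize(cohort, fs_target=250.0)
    return cohort, trials, refs


@pytest.fixture()
def constant_trial():
    return AccelTrial(
        accel=__import__("gaitwave").Signal(np.full(500, 2.0), fs=250.0)
    )
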