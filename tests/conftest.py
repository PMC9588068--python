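import numpy as np
import pytest

from pitchcomp.core import FoTrajectory
from pitchcomp.synthetic import SubjectParams, make_trial_design


def make_traj(values, onset=0, offset=None, **kwargs):
    """Trajectory from a list where None marks missing samples."""
    arr = np.array([np.nan if v is None else float(v) for v in values])
    return FoTrajectory(values=arr, onset_index=onset, offset_index=offset, **kwargs)


@pytest.fixture
def clean_subject():
    return SubjectParams("S00", sigma_slow=0.0, sigma_fast=0.0, gain=0.4, base_fo=150.0)

@pytest.fixture
def noisy_subject():
    return SubjectParams("S01", sigma_slow=13.0, sigma_fast=3.5, gain=0.4, base_fo=150.0)


@pytest.fixture
def design_a():
    return make_trial_design("S01", seed=3)
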