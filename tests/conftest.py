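import numpy as np
import pytest

from imugrf.io_store import read_manifest
from imugrf.synthetic_runner import RunnerProfile, simulate_cohort, simulate_force


@pytest.fixture
def profile():
    return RunnerProfile(participant_id="P01", mass_kg=70.0)


@pytest.fixture
def noiseless_trial(profile):
    """60 s noiseless trial at a mid-range velocity, with ground truth."""
    force, gt = simulate_force(profile, 3.35, 60.0, seed=0)
    return force, gt


@pytest.fixture
def summed_bw(noiseless_trial):
    force, gt = noiseless_trial
    total = (force.force_left + force.force_right) / force.body_weight
    return np.where(total < 0.05, 0.0, total), gt


@pytest.fixture(scope="session")
def small_cohort(tmp_path_factory):
    """2 participants x 2 paces x 60 s, noiseless, shared across tests."""
    out = tmp_path_factory.mktemp("cohort")
    paths = simulate_cohort(2, 2, 60.0, seed=7, out_dir=out)
    return out, [read_manifest(p) for p in paths]
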