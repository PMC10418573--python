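import numpy as np
import pytest

from visattn.gaze_io import AttentionMap, Fixation, FixationSequence, Group
from visattn.synthetic import CohortConfig, gen_cohort, gen_stimuli


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_cfg():
    """A scaled-down cohort for structural tests (fast, not the study scale)."""
    return CohortConfig(
        n_clinicians=4,
        n_non_clinicians=4,
        n_stimuli=4,
        n_affected=2,
        image_px=112,
        fixations_per_trial=12.0,
        seed=7,
    )


@pytest.fixture(scope="session")
def default_cohort():
    """The full-scale synthetic study at seed 0, shared across tests."""
    cfg = CohortConfig(seed=0)
    stimuli, sequences, responses = gen_cohort(cfg)
    return cfg, stimuli, sequences, responses


@pytest.fixture
def small_cohort(small_cfg):
    return (small_cfg, *gen_cohort(small_cfg))


def make_sequence(points, group=Group.CLINICIAN, participant="p1", stimulus="s1"):
    """Build a FixationSequence from (x, y, onset, duration) tuples."""
    fixes = [Fixation(x, y, o, d) for x, y, o, d in points]
    return FixationSequence(participant, group, stimulus, fixes)


def random_map(rng, shape=(20, 20), kind="gaze"):
    return AttentionMap(rng.random(shape), kind=kind)
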