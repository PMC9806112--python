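import numpy as np
import pytest

from limbuse.data_model import ImuRecording
from limbuse.simulate import SimConfig, simulate_arm, simulate_cohort

COHORT_SEED = 11


@pytest.fixture(scope="session")
def sim_arm_default():
    """One simulated arm with the default task mix."""
    return simulate_arm(SimConfig(seed=5))


@pytest.fixture(scope="session")
def small_cohort():
    """Four-subject cohort for pipeline-level unit tests."""
    return simulate_cohort(4, seed=COHORT_SEED)


@pytest.fixture(scope="session")
def default_cohort():
    """The default 15-subject synthetic cohort (10 controls, 5 patients)."""
    return simulate_cohort(15, seed=COHORT_SEED)


@pytest.fixture(scope="session")
def traditional_eval(default_cohort):
    """Traditional-measure metrics for every subject/arm of the cohort."""
    from limbuse.pipeline import evaluate_subjects
    subjects, _ = default_cohort
    return evaluate_subjects(subjects)


def static_recording(pose=(0.0, 0.0, 1.0), n=3000, rate=50.0, noise=0.01,
                     seed=0, with_mag=True):
    """A motionless recording in a fixed pose with sensor noise."""
    rng = np.random.default_rng(seed)
    g = np.asarray(pose, dtype=float)
    g = g / np.linalg.norm(g)
    accel = np.tile(g, (n, 1)) + rng.normal(0, noise, (n, 3))
    gyro = rng.normal(0, 0.2, (n, 3))
    mag = None
    if with_mag:
        mag = np.tile([0.5, 0.1, -0.8], (n, 1)) + rng.normal(0, 0.01, (n, 3))
    return ImuRecording(np.arange(n) / rate, accel, gyro, mag, rate)
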