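import numpy as np
import pytest

from facescreen.synthcohort import (CohortConfig, SubjectParams,
                                    landmarks_from_params,
                                    sample_subject_params)


@pytest.fixture
def default_params() -> SubjectParams:
    """A fixed mid-range subject: 10 deg smile gain, mild asymmetry."""
    return SubjectParams(group="control", neutral_corner_angle=70.0,
                         smile_angle_gain=10.0, asymmetry=1.0,
                         mouth_width=60.0, interocular=100.0,
                         texture_contrast=1.0)


@pytest.fixture
def small_cohort_config() -> CohortConfig:
    return CohortConfig(n_patient=10, n_control=10, n_frames=7, rng_seed=7)


def random_landmarks(rng: np.random.Generator):
    """A random but geometrically sane landmark set: a random subject's
    face at a random expression phase, optionally jittered."""
    params = sample_subject_params(CohortConfig(rng_seed=0), "control", rng)
    lm = landmarks_from_params(params, rng.uniform(0, 1))
    jitter = rng.normal(0, 0.5, size=(68, 2))
    from facescreen.facenorm import LandmarkSet

    return LandmarkSet(lm.points + jitter)
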