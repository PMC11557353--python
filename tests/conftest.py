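import numpy as np
import pytest

from nirswalk.montage import build_default_montage
from nirswalk.synthetic import (
    NoiseSpec,
    PD_SPEC,
    TaskTimeline,
    generate_subject_fc_target,
    simulate_cohort,
    simulate_recording,
)


@pytest.fixture(scope="session")
def montage():
    return build_default_montage()


@pytest.fixture(scope="session")
def timeline():
    return TaskTimeline()


@pytest.fixture(scope="session")
def quiet_noise():
    """All nuisance components off: the forward model becomes exactly
    invertible by the Beer-Lambert steps."""
    return NoiseSpec(
        cardiac_amp_um=0.0,
        respiratory_amp_um=0.0,
        mayer_amp_um=0.0,
        measurement_noise_sd=0.0,
        artifact_rate_per_min=0.0,
    )


@pytest.fixture(scope="session")
def clean_recording(montage, timeline, quiet_noise):
    """One noiseless, artifact-free trial with planted truth."""
    rng = np.random.default_rng(7)
    target = generate_subject_fc_target(PD_SPEC, rng)
    return simulate_recording(target, timeline, montage, quiet_noise, rng)


@pytest.fixture(scope="session")
def default_recording(montage, timeline):
    rng = np.random.default_rng(11)
    target = generate_subject_fc_target(PD_SPEC, rng)
    return simulate_recording(target, timeline, montage, NoiseSpec(), rng)


@pytest.fixture(scope="session")
def tiny_cohort():
    """Two subjects per group: the end-to-end smoke fixture."""
    return simulate_cohort(2, 2, seed=5)
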