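import dataclasses

import numpy as np
import pytest

from ldaep_lab.cohort import CohortSpec, SubjectProfile, generate_cohort
from ldaep_lab.paradigm import ParadigmSpec, generate_paradigm
from ldaep_lab.simulate import simulate_recording


@pytest.fixture(scope="session")
def small_paradigm():
    """Reduced paradigm (6 trials/intensity) for fast simulations."""
    return ParadigmSpec(trials_per_intensity=6, seed=11)


@pytest.fixture(scope="session")
def small_events(small_paradigm):
    return generate_paradigm(small_paradigm)


def make_profile(**overrides) -> SubjectProfile:
    base = dict(
        subject_id="sub-001",
        group="current_user",
        hc_type="combined",
        age=25.0,
        bdi_cognitive=4,
        bdi_somatic_affective=5,
        menstrual_phase="luteal",
        adverse_mood=False,
        true_n1_intercept_uv=-4.0,
        true_n1_slope_uv_per_db=-0.080,
        true_p2_intercept_uv=4.5,
        true_p2_slope_uv_per_db=0.120,
        noise_sigma_uv=6.0,
        blink_rate_hz=0.15,
        line_amp_uv=5.0,
    )
    base.update(overrides)
    return SubjectProfile(**base)


def noiseless_profile(**overrides) -> SubjectProfile:
    return make_profile(noise_sigma_uv=0.0, blink_rate_hz=0.0, line_amp_uv=0.0,
                        **overrides)


@pytest.fixture(scope="session")
def noiseless_recording(small_events):
    return simulate_recording(noiseless_profile(), small_events, seed=5,
                              eog_noise_uv=0.0)


@pytest.fixture(scope="session")
def default_cohort():
    return generate_cohort(CohortSpec(seed=3))
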