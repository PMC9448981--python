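"""Shared fixtures: small synthetic cohorts generated once per session."""

import numpy as np
import pytest

from vdtscreen import scoring, telemetry
from vdtscreen.cohort import CohortSpec, generate_cohort


@pytest.fixture(scope="session")
def small_spec() -> CohortSpec:
    """Desk-scale cohort: 30 participants, 60 s sessions, 3 zones."""
    return CohortSpec(
        n_participants=30,
        hand_prevalence=0.5,
        n_channels=9,
        n_zones=3,
        session_duration=60.0,
        n_informative_variables=8,
        effect_size=1.5,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_cohort(small_spec):
    return generate_cohort(small_spec)


@pytest.fixture(scope="session")
def small_features(small_cohort):
    sessions, _, _ = small_cohort
    return telemetry.summarize_variables(sessions)


@pytest.fixture(scope="session")
def small_labels(small_cohort) -> np.ndarray:
    _, cnpa, _ = small_cohort
    return np.array([s.hand for s in scoring.score_cohort(cnpa)], dtype=int)
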