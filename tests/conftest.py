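import numpy as np
import pytest

from contactlayouts import (
    CohortSpec,
    ParticipantProfile,
    StudyConfig,
    build_question,
    enumerate_contacts,
    simulate_study,
)


@pytest.fixture
def config():
    return StudyConfig()


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def contact_family(config):
    return enumerate_contacts(config.n_segments, config.min_separation)


@pytest.fixture
def question_bank(config, contact_family, rng):
    return [build_question(c, config, rng) for c in contact_family]


@pytest.fixture(scope="session")
def small_table():
    """Three small cohorts with distinct behavioral profiles."""
    cohorts = [
        CohortSpec("circular", 6, ParticipantProfile(p_correct=0.9, memory=0.8)),
        CohortSpec("half_matrix", 6, ParticipantProfile(p_correct=0.75, memory=0.5)),
        CohortSpec("matrix", 6, ParticipantProfile(p_correct=0.7, memory=0.6)),
    ]
    return simulate_study(cohorts, StudyConfig(), seed=7)
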