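import numpy as np
import pytest

from engramtrack import CohortConfig, generate_cohort
from engramtrack.simulate import Session

TINY_SCHEDULE = (
    Session("H", 0, "habituation"),
    Session("1", 1, "training"),
    Session("19", 2, "training"),
    Session("C1", 3, "control"),
    Session("R1", 4, "retention"),
    Session("R2", 5, "retention"),
)


@pytest.fixture(scope="session")
def default_cohort():
    """One default-parameter cohort shared across read-only tests."""
    return generate_cohort(CohortConfig(seed=7))


@pytest.fixture()
def tiny_config():
    """A small cohort (2 animals, 60 cells, 6 sessions) for fast smoke runs."""
    return CohortConfig(
        n_animals=2,
        n_cells_per_animal=60,
        session_schedule=TINY_SCHEDULE,
        seed=3,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
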