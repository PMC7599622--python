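import numpy as np
import pytest

from gaprunner import BlockConfig, Schedule, build_default_schedule, generate_cohort


@pytest.fixture(scope="session")
def default_schedule() -> Schedule:
    return build_default_schedule()


@pytest.fixture
def toy_schedule() -> Schedule:
    return Schedule(
        blocks=(
            BlockConfig("T1", trunk_length=8.0, gap_length=2.0, speed=5.0, n_gaps=1),
            BlockConfig("T2", trunk_length=13.0, gap_length=2.0, speed=5.0, n_gaps=1),
        )
    )


@pytest.fixture(scope="session")
def small_cohort():
    """12 participants on the default schedule, fixed seed."""
    return generate_cohort(n=12, seed=7)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
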